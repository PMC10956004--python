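"""Price-to-walk curve estimation.

A participant's bids across a session rise with fatigue and are well
described by a first-order exponential in session time,

    Y(t) = k · exp(b · c · t),

where k is the initial price, b the fatigue rate per walked minute, and c
the participant's win rate.  c rescales session time toward walking time —
fatigue accrues only during walked intervals — and is fixed from the log,
not fitted.  Both winning and losing bids enter the least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .auction import AuctionError
from .session import SessionLog

__all__ = ["DegenerateModelError", "PriceToWalkFit", "compute_win_rate", "fit_price_to_walk", "fit_from_points"]


class DegenerateModelError(ValueError):
    """The exponential model is unidentifiable for this input (e.g. c = 0)."""


@dataclass(frozen=True)
class PriceToWalkFit:
    """Fitted price-to-walk curve with diagnostics.

    ``effective_rate`` = b_hat · c is the composite exponential rate in
    session time; cumulative prices integrate exp(effective_rate · t).
    """

    k_hat: float          # USD
    b_hat: float          # per walked minute
    c: float              # win rate, dimensionless in [0, 1]
    effective_rate: float  # b_hat * c, per session minute
    r_squared: float
    n_bids: int
    condition: str = ""

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.k_hat * np.exp(self.effective_rate * np.asarray(t, dtype=float))


def compute_win_rate(log: SessionLog) -> float:
    """Fraction of auctions the participant won."""
    if not log.records:
        raise AuctionError("empty session log")
    wins = sum(rec.human_walked for rec in log.records)
    return wins / log.n_auctions


def fit_from_points(
    times: np.ndarray,
    bids: np.ndarray,
    c: float,
    condition: str = "",
    nonnegative_rate: bool = True,
) -> PriceToWalkFit:
    """Least-squares fit of k·exp(b·c·t) to (t, bid) pairs with c fixed.

    Initialization: k0 = first bid; b0 from OLS of log(bid) on c·t.
    Bounds k > 0, b ≥ 0 by default (bids trend upwards with fatigue);
    ``nonnegative_rate=False`` removes the lower bound on b.
    """
    times = np.asarray(times, dtype=float)
    bids = np.asarray(bids, dtype=float)
    if times.shape != bids.shape or times.ndim != 1:
        raise AuctionError("times and bids must be 1-D arrays of equal length")
    n = len(bids)
    if n < 3:
        raise DegenerateModelError(f"need at least 3 bids to fit, got {n}")
    if c == 0:
        raise DegenerateModelError("win rate c = 0: participant never walked; the fatigue model is unidentifiable")
    if np.any(bids <= 0):
        raise AuctionError("bids must be positive")

    ss_tot = float(np.sum((bids - bids.mean()) ** 2))

    if np.all(bids == bids[0]):
        # Flat data: exact degenerate solution, R^2 = 1 by convention
        # (zero residual on zero total variance).
        return PriceToWalkFit(float(bids[0]), 0.0, c, 0.0, 1.0, n, condition)

    x = c * times
    slope, intercept = np.polyfit(x, np.log(bids), 1)
    k0 = float(bids[0])
    b0 = float(slope)
    if nonnegative_rate:
        b0 = max(b0, 0.0)
        bounds = ([1e-9, 0.0], [np.inf, np.inf])
    else:
        bounds = ([1e-9, -np.inf], [np.inf, np.inf])

    def residuals(theta: np.ndarray) -> np.ndarray:
        k, b = theta
        return k * np.exp(b * x) - bids

    sol = least_squares(
        residuals,
        x0=[max(k0, 1e-6), b0],
        bounds=bounds,
        xtol=1e-8,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=10_000,
    )
    k_hat, b_hat = map(float, sol.x)
    ss_res = float(np.sum(sol.fun**2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PriceToWalkFit(k_hat, b_hat, c, b_hat * c, r_squared, n, condition)


def fit_price_to_walk(log: SessionLog, nonnegative_rate: bool = True) -> PriceToWalkFit:
    """Fit the price-to-walk curve to one session's bids (wins and losses)."""
    c = compute_win_rate(log)
    pts = log.human_bids()
    times = np.array([t for t, _ in pts])
    bids = np.array([b for _, b in pts])
    return fit_from_points(times, bids, c, condition=log.condition, nonnegative_rate=nonnegative_rate)
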