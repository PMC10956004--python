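"""File formats: bid-log CSV, session-metadata sidecar, report tables.

The bid log is a plain UTF-8 CSV with one row per bidder per interval and
fixed two-decimal dollar strings, so a write → read round trip is lossless
at cent precision.  Session-level facts that the CSV cannot carry exactly
(scheduled duration, seed, subject id, agent parameters) live in a YAML
sidecar sufficient to re-simulate the session bit-exactly.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Any

import yaml

from .agents import HumanAgentParams, RoboBidderParams
from .auction import SealedBid
from .session import HUMAN_BIDDER_ID, IntervalRecord, SessionConfig, SessionLog

__all__ = [
    "BidLogError",
    "BID_LOG_COLUMNS",
    "write_bid_log",
    "read_bid_log",
    "bid_log_to_string",
    "write_session_meta",
    "read_session_meta",
    "write_fit_report",
    "write_mv_report",
]

BID_LOG_COLUMNS = [
    "session_id",
    "condition",
    "interval_index",
    "t_start_min",
    "bidder_id",
    "bid_usd",
    "won",
    "clearing_price_usd",
    "human_walked",
]


class BidLogError(ValueError):
    """A bid-log file is malformed."""


def _usd(x: float) -> str:
    return f"{x:.2f}"


def bid_log_to_string(log: SessionLog) -> str:
    """Serialize a session log to its canonical CSV text."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(BID_LOG_COLUMNS)
    for rec in log.records:
        for bid in rec.bids:
            writer.writerow(
                [
                    log.session_id,
                    log.condition,
                    rec.interval_index,
                    f"{rec.t_start:g}",
                    bid.bidder_id,
                    _usd(bid.amount),
                    int(bid.bidder_id == rec.winner_id),
                    _usd(rec.clearing_price),
                    int(rec.human_walked),
                ]
            )
    return buf.getvalue()


def write_bid_log(log: SessionLog, path: str | Path) -> None:
    Path(path).write_text(bid_log_to_string(log), encoding="utf-8")


def read_bid_log(path: str | Path, meta_path: str | Path | None = None) -> SessionLog:
    """Parse a bid-log CSV back into a SessionLog.

    Malformed rows are reported with their line number; exactly one winner
    per interval is enforced.  Without a metadata sidecar the scheduled
    duration is reconstructed as n_intervals × interval_minutes and the
    subject id defaults to the session id.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise BidLogError(f"{path}: empty bid-log file")
    reader = csv.DictReader(_io.StringIO(text))
    if reader.fieldnames is None or set(BID_LOG_COLUMNS) - set(reader.fieldnames):
        missing = set(BID_LOG_COLUMNS) - set(reader.fieldnames or [])
        raise BidLogError(f"{path}: missing columns {sorted(missing)}")

    intervals: dict[int, dict[str, Any]] = {}
    session_id = None
    condition = None
    for lineno, row in enumerate(reader, start=2):
        try:
            idx = int(row["interval_index"])
            t_start = float(row["t_start_min"])
            amount = round(float(row["bid_usd"]), 2)
            won = bool(int(row["won"]))
            clearing = round(float(row["clearing_price_usd"]), 2)
            walked = bool(int(row["human_walked"]))
        except (TypeError, ValueError) as exc:
            raise BidLogError(f"{path}:{lineno}: malformed row ({exc})") from exc
        if amount <= 0:
            raise BidLogError(f"{path}:{lineno}: non-positive bid amount {amount}")
        session_id = session_id or row["session_id"]
        condition = condition or row["condition"]
        iv = intervals.setdefault(
            idx,
            {
                "t_start": t_start,
                "bids": [],
                "winner": None,
                "clearing": clearing,
                "walked": walked,
            },
        )
        iv["bids"].append(SealedBid.from_usd(row["bidder_id"], amount))
        if won:
            if iv["winner"] is not None:
                raise BidLogError(
                    f"{path}:{lineno}: two winners in interval {idx} "
                    f"({iv['winner']!r} and {row['bidder_id']!r})"
                )
            iv["winner"] = row["bidder_id"]

    if not intervals:
        raise BidLogError(f"{path}: no data rows")

    records = []
    for idx in sorted(intervals):
        iv = intervals[idx]
        if iv["winner"] is None:
            raise BidLogError(f"{path}: interval {idx} has no winner")
        records.append(
            IntervalRecord(
                interval_index=idx,
                t_start=iv["t_start"],
                bids=tuple(iv["bids"]),
                winner_id=iv["winner"],
                clearing_price=iv["clearing"],
                human_walked=iv["walked"],
            )
        )

    meta = read_session_meta(meta_path) if meta_path is not None else {}
    n = len(records)
    interval_minutes = float(
        meta.get("interval_min", records[1].t_start - records[0].t_start if n > 1 else 2.0)
    )
    config = SessionConfig(
        interval_minutes=interval_minutes,
        duration_lo=float(meta.get("duration_lo", interval_minutes * n)),
        duration_hi=float(meta.get("duration_hi", interval_minutes * n)),
        n_robo=int(meta.get("n_robo", len(records[0].bids) - 1)),
        condition=str(meta.get("condition", condition)),
        seed=meta.get("seed"),
    )
    earnings = round(
        sum(rec.clearing_price for rec in records if rec.human_walked), 2
    )
    walk_minutes = interval_minutes * sum(rec.human_walked for rec in records)
    return SessionLog(
        config=config,
        scheduled_minutes=float(meta.get("scheduled_duration_min", interval_minutes * n)),
        records=tuple(records),
        human_earnings=earnings,
        human_walk_minutes=walk_minutes,
        session_id=str(meta.get("session_id", session_id)),
        subject_id=str(meta.get("subject_id", session_id)),
    )


def write_session_meta(
    log: SessionLog,
    path: str | Path,
    human: HumanAgentParams | None = None,
    robos: list[RoboBidderParams] | None = None,
) -> None:
    """YAML sidecar with everything needed to re-simulate the session."""
    doc: dict[str, Any] = {
        "session_id": log.session_id,
        "subject_id": log.subject_id,
        "condition": log.condition,
        "scheduled_duration_min": log.scheduled_minutes,
        "interval_min": log.config.interval_minutes,
        "duration_lo": log.config.duration_lo,
        "duration_hi": log.config.duration_hi,
        "n_robo": log.config.n_robo,
        "seed": log.config.seed,
    }
    if human is not None:
        doc["human"] = {
            "k_true": human.k_true,
            "b_true": human.b_true,
            "bid_noise_sd": human.bid_noise_sd,
            "strategy": human.strategy,
        }
    if robos is not None:
        doc["robo_bidders"] = [
            {"k_init": r.k_init, "b_rate": r.b_rate, "noise_sd": r.noise_sd}
            for r in robos
        ]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def read_session_meta(path: str | Path) -> dict[str, Any]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict):
        raise BidLogError(f"{path}: metadata sidecar is not a mapping")
    return doc


def write_fit_report(rows: list[dict[str, Any]], path: str | Path) -> None:
    """TSV fit report: one row per session with k, b, c, R², n."""
    _write_tsv(rows, path, ["session_id", "subject_id", "condition", "k_hat", "b_hat", "c", "effective_rate", "r_squared", "n_bids"])


def write_mv_report(rows: list[dict[str, Any]], path: str | Path) -> None:
    """TSV MV report: one row per subject × condition pair."""
    _write_tsv(
        rows,
        path,
        ["subject_id", "comparison", "baseline_condition", "comparison_condition", "mv_usd", "mv_percent", "t1_min", "t2_min"],
    )


def _write_tsv(rows: list[dict[str, Any]], path: str | Path, columns: list[str]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow({col: row.get(col, "") for col in columns})
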