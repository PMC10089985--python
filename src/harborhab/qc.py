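"""Detection quality control.

Reproduces the standard telemetry filtering chain for coded acoustic
transmitters, applied in a fixed order:

1. minimum-delay filter — detections of the same tag at the same receiver
   closer together than the tag's minimum transmission delay (default 45 s)
   are physically impossible and the later record of each violating pair is
   removed (greedy keep-first scan);
2. single-detection filter — detections with no other same-tag detection
   (any receiver) within one hour are likely code collisions and are
   removed, iterating to a fixpoint since a removal can isolate a
   neighbour;
3. dead-tag filter — tags detected repeatedly over multiple weeks at a
   single receiver and never elsewhere afterwards are flagged as mortality
   or tag shedding, and their detections from the onset of the stationary
   run are removed.

Each filter returns a subset of its input.  Active tracking windows (first
to last retained detection per tag) are computed after filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("harborhab.qc")

DEFAULT_MIN_DELAY_S = 45.0


@dataclass(frozen=True)
class ActiveWindow:
    tag_id: str
    first_detection: pd.Timestamp
    last_detection: pd.Timestamp


@dataclass(frozen=True)
class DeadTagFlag:
    tag_id: str
    onset: pd.Timestamp
    terminal_receiver: str


def _ns(ts: pd.Series) -> np.ndarray:
    return ts.to_numpy().astype("datetime64[ns]").astype(np.int64)


def filter_min_delay(detections: pd.DataFrame, tags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Remove same-tag same-receiver detections closer than the minimum delay.

    A greedy forward scan per (tag, receiver): the earliest detection of a
    violating pair is kept, so consecutive retained detections differ by at
    least ``min_delay_s`` (gaps of exactly the delay are kept — the rule is
    "less than").  Tags missing from ``tags`` fall back to the 45 s default
    with a logged warning.
    """
    delays: dict = {}
    if tags is not None:
        delays = dict(zip(tags["tag_id"], tags["min_delay_s"].astype(float)))
    det = detections.sort_values(["tag_id", "receiver_id", "timestamp"], kind="mergesort")
    t = _ns(det["timestamp"])
    group_ids = pd.factorize(
        det["tag_id"].astype(str) + "\x00" + det["receiver_id"].astype(str))[0]
    tag_arr = det["tag_id"].to_numpy()

    warned: set = set()
    keep = np.ones(len(det), dtype=bool)
    last_kept = -np.inf
    cur = -1
    delay_ns = 0.0
    for i in range(len(det)):
        if group_ids[i] != cur:
            cur = group_ids[i]
            tag = tag_arr[i]
            if tags is not None and tag not in delays and tag not in warned:
                logger.warning("tag %s missing from tag table; using default %.0f s delay",
                               tag, DEFAULT_MIN_DELAY_S)
                warned.add(tag)
            delay_ns = delays.get(tag, DEFAULT_MIN_DELAY_S) * 1e9
            last_kept = t[i]
            continue
        if t[i] - last_kept < delay_ns:
            keep[i] = False
        else:
            last_kept = t[i]
    out = det[keep].sort_index()
    logger.info("min-delay filter removed %d of %d detections", len(det) - len(out), len(det))
    return out


def filter_single_detections(detections: pd.DataFrame, window_s: float = 3600.0) -> pd.DataFrame:
    """Remove detections with no same-tag neighbour within ``window_s``.

    Neighbours count across all receivers.  Applied iteratively to a
    fixpoint: removing an isolated detection can strand a former neighbour,
    which is then removed on the next pass.
    """
    det = detections.sort_values(["tag_id", "timestamp"], kind="mergesort")
    n0 = len(det)
    window_ns = window_s * 1e9
    while True:
        if det.empty:
            break
        t = _ns(det["timestamp"])
        tag_codes = pd.factorize(det["tag_id"])[0]
        same_prev = np.empty(len(det), dtype=bool)
        same_next = np.empty(len(det), dtype=bool)
        same_prev[0] = False
        same_prev[1:] = tag_codes[1:] == tag_codes[:-1]
        same_next[-1] = False
        same_next[:-1] = tag_codes[:-1] == tag_codes[1:]
        gap_prev = np.full(len(det), np.inf)
        gap_next = np.full(len(det), np.inf)
        gap_prev[1:] = np.where(same_prev[1:], t[1:] - t[:-1], np.inf)
        gap_next[:-1] = np.where(same_next[:-1], t[1:] - t[:-1], np.inf)
        keep = (gap_prev <= window_ns) | (gap_next <= window_ns)
        if keep.all():
            break
        det = det[keep]
    out = det.sort_index()
    logger.info("single-detection filter removed %d of %d detections", n0 - len(out), n0)
    return out


def flag_dead_tags(detections: pd.DataFrame, min_span_days: float = 14.0,
                   min_active_frac: float = 0.5) -> list[DeadTagFlag]:
    """Identify stationary ("dead") tags.

    A tag is flagged iff its terminal run — all detections after the last
    time it was seen at any other receiver — is confined to one receiver,
    spans at least ``min_span_days`` and has detections on at least
    ``min_active_frac`` of the days in that span.  The onset is the first
    detection of the terminal run.
    """
    flags = []
    for tag, grp in detections.groupby("tag_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        recv = grp["receiver_id"].to_numpy()
        ts = grp["timestamp"].to_numpy()
        terminal = recv[-1]
        other = np.nonzero(recv != terminal)[0]
        start_idx = other[-1] + 1 if len(other) else 0
        run = grp.iloc[start_idx:]
        onset, last = run["timestamp"].iloc[0], run["timestamp"].iloc[-1]
        span_days = (last - onset).total_seconds() / 86400.0
        if span_days < min_span_days:
            continue
        active_days = run["timestamp"].dt.normalize().nunique()
        if active_days / max(np.ceil(span_days), 1.0) < min_active_frac:
            continue
        flags.append(DeadTagFlag(tag_id=tag, onset=onset, terminal_receiver=terminal))
        _ = ts  # noqa: F841
    logger.info("flagged %d dead tags", len(flags))
    return flags


def remove_dead_detections(detections: pd.DataFrame,
                           flags: list[DeadTagFlag]) -> pd.DataFrame:
    """Drop detections of flagged tags at/after their onset; keep the tag's
    earlier (live) detections."""
    if not flags:
        return detections
    keep = np.ones(len(detections), dtype=bool)
    for f in flags:
        keep &= ~((detections["tag_id"] == f.tag_id).to_numpy()
                  & (detections["timestamp"] >= f.onset).to_numpy())
    return detections[keep]


def compute_active_windows(detections: pd.DataFrame) -> pd.DataFrame:
    """First-to-last retained detection per tag.

    Returns a frame ``(tag_id, first_detection, last_detection)`` with one
    row per tag that retained at least one detection.
    """
    if detections.empty:
        return pd.DataFrame(columns=["tag_id", "first_detection", "last_detection"])
    agg = detections.groupby("tag_id")["timestamp"].agg(["min", "max"]).reset_index()
    return agg.rename(columns={"min": "first_detection", "max": "last_detection"})


@dataclass
class QCResult:
    """Cleaned detections plus per-filter bookkeeping."""
    detections: pd.DataFrame
    windows: pd.DataFrame
    flags: list[DeadTagFlag]
    removed_min_delay: int
    removed_single: int
    removed_dead: int

    def report(self) -> dict:
        return {
            "n_retained": int(len(self.detections)),
            "removed_min_delay": self.removed_min_delay,
            "removed_single": self.removed_single,
            "removed_dead": self.removed_dead,
            "dead_tags": [
                {"tag_id": f.tag_id, "onset": str(f.onset),
                 "terminal_receiver": f.terminal_receiver} for f in self.flags],
        }


def run_qc(detections: pd.DataFrame, tags: pd.DataFrame | None = None,
           min_span_days: float = 14.0, min_active_frac: float = 0.5) -> QCResult:
    """The full filtering chain: min-delay -> single-detection -> dead-tag,
    followed by active-window computation."""
    a = filter_min_delay(detections, tags)
    b = filter_single_detections(a)
    flags = flag_dead_tags(b, min_span_days=min_span_days, min_active_frac=min_active_frac)
    c = remove_dead_detections(b, flags)
    return QCResult(
        detections=c.reset_index(drop=True),
        windows=compute_active_windows(c),
        flags=flags,
        removed_min_delay=len(detections) - len(a),
        removed_single=len(a) - len(b),
        removed_dead=len(b) - len(c),
    )
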