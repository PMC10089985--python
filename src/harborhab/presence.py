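"""Daily presence/absence table construction.

Converts QC'd detections into the model's analysis table: one row per
receiver node x calendar day x species, with a binary ``present`` response,
the season, the node's habitat covariates, and the count of actively
tracked conspecifics that day.  A species is scored present at a node-day
when at least one individual of that species has at least two detections at
that node on that day; with ``per_node=False`` an individual instead
qualifies with two detections anywhere that day and registers presence at
every node where it was detected.  Absences are scored only on node-days
with receiver coverage, and days with fewer than ``n_min`` actively tracked
conspecifics are dropped from the final table.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConsistencyError

SEASONS = ("winter", "spring", "summer", "fall")

#: Month -> season. Dec-Feb winter, Mar-May spring, Jun-Aug summer, Sep-Nov fall.
DEFAULT_SEASON_BY_MONTH: dict[int, str] = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
}


def assign_season(dates, season_by_month: Mapping[int, str] | None = None) -> pd.Series:
    """Map dates to seasons by calendar month.

    Parameters
    ----------
    dates
        Anything convertible by :func:`pandas.to_datetime` (scalar or array).
    season_by_month
        Optional replacement for the default month mapping; must cover all
        twelve months.

    Returns a Series of season labels (or a scalar for scalar input).
    """
    mapping = dict(season_by_month or DEFAULT_SEASON_BY_MONTH)
    if sorted(mapping) != list(range(1, 13)):
        raise ValueError("season_by_month must map every month 1-12")
    scalar = np.isscalar(dates) or isinstance(dates, (pd.Timestamp,)) or (
        not hasattr(dates, "__len__")
    )
    idx = pd.to_datetime(pd.Series([dates]) if scalar else pd.Series(dates))
    out = idx.dt.month.map(mapping)
    if scalar:
        return out.iloc[0]
    out.index = getattr(dates, "index", out.index)
    return out.rename("season")


def node_coverage(deployments: pd.DataFrame) -> pd.DataFrame:
    """Days on which each node could have logged a detection.

    A day is covered iff at least one receiver of the node was deployed on
    that day; deployment ``start``/``end`` dates are inclusive.

    Returns a frame with columns ``node_id``, ``date`` (one row per covered
    node-day, duplicates from overlapping receivers collapsed).
    """
    frames = []
    for row in deployments.itertuples(index=False):
        days = pd.date_range(
            pd.Timestamp(row.start).normalize(), pd.Timestamp(row.end).normalize(), freq="D"
        )
        frames.append(pd.DataFrame({"node_id": row.node_id, "date": days}))
    if not frames:
        return pd.DataFrame(columns=["node_id", "date"])
    cov = pd.concat(frames, ignore_index=True).drop_duplicates()
    return cov.sort_values(["node_id", "date"]).reset_index(drop=True)


def node_covariates(receiver_values: pd.DataFrame) -> pd.DataFrame:
    """Aggregate receiver-level habitat measurements to node level.

    ``receiver_values`` has one row per receiver with ``node_id`` plus any
    numeric covariate columns; node covariates are the arithmetic mean over
    the node's receivers (categorical columns such as ``region`` must be
    constant within a node and are carried through).
    """
    num_cols = [c for c in receiver_values.columns
                if c not in ("node_id", "receiver_id")
                and pd.api.types.is_numeric_dtype(receiver_values[c])]
    cat_cols = [c for c in receiver_values.columns
                if c not in ("node_id", "receiver_id") and c not in num_cols]
    grouped = receiver_values.groupby("node_id", sort=True)
    out = grouped[num_cols].mean()
    for c in cat_cols:
        uniq = grouped[c].nunique()
        if (uniq > 1).any():
            raise ConsistencyError(f"categorical covariate {c!r} varies within a node")
        out[c] = grouped[c].first()
    return out.reset_index()


def compute_n_active(windows: pd.DataFrame, tags: pd.DataFrame,
                     dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Count actively tracked individuals per species per day.

    An individual is actively tracked on every day between its first and
    last retained detections (inclusive).  Returns a long frame
    ``(date, species, n_active)`` over the supplied dates.
    """
    w = windows.merge(tags[["tag_id", "species"]], on="tag_id", how="left")
    out = []
    for species, grp in w.groupby("species"):
        starts = grp["first_detection"].dt.normalize().sort_values().to_numpy()
        ends = grp["last_detection"].dt.normalize().sort_values().to_numpy()
        d = dates.to_numpy()
        n_started = np.searchsorted(starts, d, side="right")
        n_ended = np.searchsorted(ends, d, side="left")
        out.append(pd.DataFrame({"date": dates, "species": species,
                                 "n_active": n_started - n_ended}))
    if not out:
        return pd.DataFrame(columns=["date", "species", "n_active"])
    return pd.concat(out, ignore_index=True)


def build_daily_presence(
    detections: pd.DataFrame,
    deployments: pd.DataFrame,
    nodes: pd.DataFrame,
    tags: pd.DataFrame,
    windows: pd.DataFrame,
    *,
    min_detections: int = 2,
    per_node: bool = True,
    season_by_month: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Build the daily node x species presence/absence table.

    Parameters
    ----------
    detections
        Fully QC'd detections (``det_id, timestamp, receiver_id, tag_id``).
    deployments, nodes, tags
        The study tables (receiver->node mapping with windows; node habitat;
        tag->species).
    windows
        Active tracking windows from :func:`harborhab.qc.compute_active_windows`.
    min_detections
        Detections required from a single individual to register a
        species-level presence (default two).
    per_node
        If True (default) the ``min_detections`` rule is enforced per
        node-day; if False an individual with ``min_detections`` anywhere
        that day registers presence at every node where it was detected.

    Returns one row per covered node-day and species with columns
    ``date, node_id, species, present, season, region, depth_m, sav_pct,
    exposure_m, n_active``.
    """
    det = detections.merge(
        deployments[["receiver_id", "node_id"]].drop_duplicates(), on="receiver_id", how="left"
    )
    if det["node_id"].isna().any():
        bad = det.loc[det["node_id"].isna(), "receiver_id"].unique()
        raise ConsistencyError(f"detections at receivers with no deployment record: {bad[:5]}")
    det["date"] = det["timestamp"].dt.normalize()
    det = det.merge(tags[["tag_id", "species"]], on="tag_id", how="left")

    cov = node_coverage(deployments)
    cov_idx = pd.MultiIndex.from_frame(cov[["node_id", "date"]])
    det_idx = pd.MultiIndex.from_frame(det[["node_id", "date"]])
    if not det_idx.isin(cov_idx).all():
        raise ConsistencyError("detection logged on a node-day without receiver coverage")

    # individual-level qualification
    per = det.groupby(["species", "tag_id", "node_id", "date"], sort=False).size().rename("n_det").reset_index()
    if per_node:
        qual = per[per["n_det"] >= min_detections]
    else:
        day_tot = per.groupby(["tag_id", "date"])["n_det"].transform("sum")
        qual = per[day_tot >= min_detections]
    presence = qual[["species", "node_id", "date"]].drop_duplicates()
    presence["present"] = 1

    species_list = sorted(tags["species"].unique())
    grid = (
        cov.assign(key=1)
        .merge(pd.DataFrame({"species": species_list, "key": 1}), on="key")
        .drop(columns="key")
    )
    table = grid.merge(presence, on=["species", "node_id", "date"], how="left")
    table["present"] = table["present"].fillna(0).astype(int)

    table["season"] = assign_season(table["date"], season_by_month).to_numpy()
    table = table.merge(nodes[["node_id", "region", "depth_m", "sav_pct", "exposure_m"]],
                        on="node_id", how="left")

    all_dates = pd.DatetimeIndex(sorted(table["date"].unique()))
    n_active = compute_n_active(windows, tags, all_dates)
    table = table.merge(n_active, on=["date", "species"], how="left")
    table["n_active"] = table["n_active"].fillna(0).astype(int)

    cols = ["date", "node_id", "species", "present", "season", "region",
            "depth_m", "sav_pct", "exposure_m", "n_active"]
    return table[cols].sort_values(["species", "node_id", "date"]).reset_index(drop=True)


def filter_min_active(records: pd.DataFrame, n_min: int = 5) -> pd.DataFrame:
    """Keep only rows where at least ``n_min`` conspecifics were actively
    tracked that day (boundary inclusive)."""
    return records[records["n_active"] >= n_min].reset_index(drop=True)
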