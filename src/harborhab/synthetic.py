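"""Synthetic acoustic-telemetry study generator.

Emulates a harbour-scale tracking study: ~36 receiver nodes in six regions
with depth / SAV / wind-exposure covariates, multi-year variable receiver
deployment windows, seven fish species with season-dependent habitat
preferences, coded-transmitter detection streams with a minimum
inter-transmission delay, plus the two contaminants the QC filters exist to
remove (isolated spurious detections and stationary "dead" tags).  Every
stage is deterministic under a seed and exports ground truth for recovery
tests.

The occupancy model is intentionally simple: each individual makes a daily
multinomial choice among the receiver nodes plus an "undetectable"
alternative, with node log-odds given by its species' habitat-preference
score.  This induces the node-level habitat-use signal the downstream
models estimate without simulating trajectories.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError
from .presence import DEFAULT_SEASON_BY_MONTH, SEASONS, assign_season
from .reference import SPECIES

DEFAULT_REGIONS = (
    "Outer Harbour", "TTP", "Toronto Islands",
    "West Channel", "East Channel", "Inner Harbour",
)

SECONDS_PER_DAY = 86_400


def stage_seed(master: int, *labels) -> int:
    """Derive a deterministic sub-seed (< 2**31) for a named stage.

    Independent of execution order, so per-species stages can run in any
    order (or in parallel) with identical results.
    """
    key = ":".join([str(int(master))] + [str(x) for x in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PiecewiseResponse:
    """Piecewise-linear response on the logit scale, defined by knots.

    Values outside the knot range are held at the boundary knots.
    """
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self):
        if len(self.x) != len(self.y) or len(self.x) < 1:
            raise ConfigurationError("response needs matching, non-empty knots")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ConfigurationError("response knots must be strictly increasing in x")

    def __call__(self, v):
        return np.interp(np.asarray(v, dtype=float), self.x, self.y)


@dataclass(frozen=True)
class SpeciesPreference:
    """Habitat preference of one species on the logit scale.

    ``score = beta0 + m(season) * f_<interaction_on> + other responses
    + season_effects[season]`` where ``m`` defaults to 1; the daily
    probability of choosing a node is softmax of the node scores against a
    zero-score "undetectable" alternative.
    """
    species: str
    beta0: float
    f_sav: PiecewiseResponse
    f_depth: PiecewiseResponse
    f_exposure: PiecewiseResponse
    season_effects: dict[str, float] = field(default_factory=dict)
    season_interactions: dict[str, float] = field(default_factory=dict)
    interaction_on: str = "sav"

    def score(self, sav, depth, exposure, season: str):
        parts = {
            "sav": self.f_sav(sav),
            "depth": self.f_depth(depth),
            "exposure": self.f_exposure(exposure),
        }
        m = self.season_interactions.get(season, 1.0)
        parts[self.interaction_on] = m * parts[self.interaction_on]
        return (self.beta0 + parts["sav"] + parts["depth"] + parts["exposure"]
                + self.season_effects.get(season, 0.0))


def default_preferences(species_names=SPECIES) -> dict[str, SpeciesPreference]:
    """Curated preferences emulating the qualitative habitat associations
    of the seven harbour species (strong SAV affinity for largemouth bass,
    low-SAV/off-summer walleye, winter-absent bowfin, ...).  Unknown species
    names receive a generic moderate-SAV preference."""
    P = PiecewiseResponse
    curated = {
        "largemouth_bass": SpeciesPreference(
            "largemouth_bass", beta0=-3.0,
            f_sav=P((0, 35, 50, 70, 100), (-1.2, -0.6, 0.8, 2.6, 3.0)),
            f_depth=P((1, 3, 7, 12, 25), (0.3, 0.6, 0.6, 0.0, -0.6)),
            f_exposure=P((100, 1000, 5000, 10000), (0.6, 0.0, -0.8, -1.2)),
        ),
        "northern_pike": SpeciesPreference(
            "northern_pike", beta0=-3.2,
            f_sav=P((0, 35, 60, 100), (0.8, 0.4, -0.4, -1.0)),
            f_depth=P((1, 25), (0.0, 0.2)),
            f_exposure=P((100, 10000), (0.2, -0.2)),
            season_effects={"spring": 0.8, "summer": 0.4, "fall": 0.2, "winter": -0.8},
        ),
        "walleye": SpeciesPreference(
            "walleye", beta0=-3.1,
            f_sav=P((0, 30, 100), (0.8, 0.0, -1.2)),
            f_depth=P((1, 4, 10, 25), (-0.2, 0.6, 0.8, -0.2)),
            f_exposure=P((100, 10000), (-0.1, 0.3)),
            season_effects={"spring": 0.8, "summer": -2.5, "fall": 0.4},
            season_interactions={"spring": -0.5}, interaction_on="depth",
        ),
        "yellow_perch": SpeciesPreference(
            "yellow_perch", beta0=-3.1,
            f_sav=P((0, 40, 70, 100), (-0.4, 0.8, 0.4, -0.2)),
            f_depth=P((1, 6, 25), (0.3, 0.4, -0.4)),
            f_exposure=P((100, 10000), (0.2, -0.4)),
            season_effects={"summer": -2.0, "winter": 0.4},
        ),
        "bowfin": SpeciesPreference(
            "bowfin", beta0=-3.0,
            f_sav=P((0, 50, 100), (-1.0, 1.5, 2.5)),
            f_depth=P((1, 5, 12, 25), (0.8, 0.6, -0.5, -1.2)),
            f_exposure=P((100, 5000, 10000), (0.5, -0.6, -1.0)),
            season_effects={"winter": -2.5, "fall": 0.3},
        ),
        "common_carp": SpeciesPreference(
            "common_carp", beta0=-3.0,
            f_sav=P((0, 40, 100), (-0.6, 1.0, 1.8)),
            f_depth=P((1, 5, 15, 25), (0.5, 0.3, -0.2, -0.5)),
            f_exposure=P((100, 5000, 10000), (0.4, -0.5, -0.9)),
            season_effects={"spring": 0.4, "summer": 0.3, "fall": -0.1},
        ),
        "white_sucker": SpeciesPreference(
            "white_sucker", beta0=-3.1,
            f_sav=P((0, 40, 100), (0.6, 0.0, -0.8)),
            f_depth=P((1, 8, 25), (-0.2, 0.4, 0.0)),
            f_exposure=P((100, 10000), (0.0, 0.1)),
            season_effects={"spring": -0.8, "summer": -1.0, "fall": 0.5, "winter": 0.4},
        ),
    }
    generic = lambda name: SpeciesPreference(  # noqa: E731
        name, beta0=-3.1,
        f_sav=P((0, 50, 100), (-0.5, 0.5, 1.0)),
        f_depth=P((1, 8, 25), (0.3, 0.3, -0.3)),
        f_exposure=P((100, 10000), (0.2, -0.2)),
    )
    return {s: curated.get(s, generic(s)) for s in species_names}


@dataclass
class SimConfig:
    """Study-design parameters of the simulated tracking system.

    Defaults emulate the harbour study design: 36 nodes in 6 regions, a
    two-year study period, 7 species x 15 tags, 45 s minimum transmitter
    delay, ~20 detections per present individual-day, one dead tag per
    species and a couple hundred isolated spurious detections.
    """
    n_nodes: int = 36
    regions: tuple[str, ...] = DEFAULT_REGIONS
    start: str = "2016-01-01"
    n_days: int = 730
    species: tuple[str, ...] = SPECIES
    n_per_species: int = 15
    depth_range: tuple[float, float] = (1.0, 25.0)
    sav_range: tuple[float, float] = (0.0, 100.0)
    exposure_range: tuple[float, float] = (100.0, 10_000.0)
    min_delay_s: float = 45.0
    release_window_days: int = 30
    absent_prob: float = 0.05          # out-migration: fully undetectable day
    lambda_detections: float = 20.0    # mean detections per present individual-day
    bout_gap_mean_s: float = 200.0     # mean extra gap between in-bout detections
    n_spurious: int = 200
    dead_tags_per_species: int = 1
    dead_ping_interval_s: float = 1800.0
    death_window: tuple[float, float] = (0.4, 0.7)  # fraction of study period
    deploy_margin_days: int = 120       # variable deployment starts
    deploy_end_margin_days: int = 21    # array largely maintained to study end
    n_gap_nodes: int = 6
    gap_days: tuple[int, int] = (30, 90)
    season_by_month: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_SEASON_BY_MONTH))

    def validate(self):
        if self.n_nodes < 2:
            raise ConfigurationError("n_nodes must be >= 2")
        if len(self.species) == 0:
            raise ConfigurationError("species list must not be empty")
        if len(self.regions) < 1:
            raise ConfigurationError("need at least one region label")
        if self.n_per_species < 5:
            raise ConfigurationError("every species needs >= 5 tags")
        for lo, hi in (self.depth_range, self.sav_range, self.exposure_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError("covariate ranges must be finite with lo < hi")

    @property
    def start_ts(self) -> pd.Timestamp:
        return pd.Timestamp(self.start).normalize()

    @property
    def end_ts(self) -> pd.Timestamp:
        """First day *after* the study period."""
        return self.start_ts + pd.Timedelta(days=self.n_days)


@dataclass
class TelemetrySystem:
    """The physical study: node habitat, receiver deployments, tags."""
    nodes: pd.DataFrame          # node_id, region, depth_m, sav_pct, exposure_m
    deployments: pd.DataFrame    # receiver_id, node_id, start, end
    tags: pd.DataFrame           # tag_id, species, release_date, min_delay_s, death_date
    preferences: dict[str, SpeciesPreference]
    config: SimConfig


@dataclass
class SimTruth:
    """Generator-side ground truth for recovery tests."""
    occupancy: pd.DataFrame          # tag_id, date, node_id (realized presence days)
    species_node_probs: pd.DataFrame  # species, season, node_id, p (daily choice prob)
    p_absent: pd.DataFrame           # species, season, p (prob of an undetectable day)
    dead_tag_onsets: dict[str, pd.Timestamp] = field(default_factory=dict)
    false_detection_ids: set[int] = field(default_factory=set)


def simulate_system(config: SimConfig, seed: int) -> TelemetrySystem:
    """Generate node habitat, receiver deployments and tag metadata.

    Deterministic given ``(config, seed)``.  Node depths are uniform over
    ``depth_range``, SAV is Beta-distributed (right-skewed, most nodes low
    cover), exposure is log-uniform; each node's deployments span at least
    one year, with a subset of nodes carrying a mid-study coverage gap
    split across two receivers.
    """
    config.validate()
    rng = np.random.default_rng(stage_seed(seed, "system"))

    n = config.n_nodes
    node_ids = [f"N{i:02d}" for i in range(1, n + 1)]
    regions = np.array(config.regions)[np.arange(n) % len(config.regions)]
    rng.shuffle(regions)
    d_lo, d_hi = config.depth_range
    s_lo, s_hi = config.sav_range
    e_lo, e_hi = config.exposure_range
    nodes = pd.DataFrame({
        "node_id": node_ids,
        "region": regions,
        "depth_m": rng.uniform(d_lo, d_hi, n),
        "sav_pct": s_lo + rng.beta(0.8, 1.6, n) * (s_hi - s_lo),
        "exposure_m": np.exp(rng.uniform(np.log(e_lo), np.log(e_hi), n)),
    })

    start, end = config.start_ts, config.end_ts - pd.Timedelta(days=1)
    gap_nodes = set(rng.choice(n, size=min(config.n_gap_nodes, n), replace=False))
    # margins + gaps are budgeted so every node's deployments still span a year
    budget = max(0, config.n_days - 365)
    rows = []
    for i, node in enumerate(node_ids):
        a = int(rng.integers(0, min(config.deploy_margin_days, budget) + 1))
        b = int(rng.integers(0, min(config.deploy_end_margin_days, budget - a) + 1))
        w_start, w_end = start + pd.Timedelta(days=a), end - pd.Timedelta(days=b)
        if i in gap_nodes:
            g = min(int(rng.integers(*config.gap_days)), budget - a - b)
            mid = w_start + (w_end - w_start) / 2
            rows.append((f"R{i:02d}A", node, w_start, (mid - pd.Timedelta(days=g / 2)).normalize()))
            rows.append((f"R{i:02d}B", node, (mid + pd.Timedelta(days=g / 2)).normalize(), w_end))
        else:
            rows.append((f"R{i:02d}A", node, w_start, w_end))
    deployments = pd.DataFrame(rows, columns=["receiver_id", "node_id", "start", "end"])

    tag_rows = []
    k = 0
    for sp in config.species:
        dead = set(rng.choice(config.n_per_species, size=config.dead_tags_per_species,
                              replace=False)) if config.dead_tags_per_species else set()
        for j in range(config.n_per_species):
            k += 1
            release = start + pd.Timedelta(days=int(rng.integers(0, config.release_window_days + 1)))
            death = pd.NaT
            if j in dead:
                frac = rng.uniform(*config.death_window)
                death = start + pd.Timedelta(days=int(frac * config.n_days))
            tag_rows.append((f"T{k:03d}", sp, release, config.min_delay_s, death))
    tags = pd.DataFrame(tag_rows,
                        columns=["tag_id", "species", "release_date", "min_delay_s", "death_date"])

    return TelemetrySystem(nodes=nodes, deployments=deployments, tags=tags,
                           preferences=default_preferences(config.species), config=config)


def _choice_probs(pref: SpeciesPreference, nodes: pd.DataFrame, season: str,
                  absent_prob: float) -> np.ndarray:
    """Daily choice probabilities over [nodes..., undetectable]."""
    s = pref.score(nodes["sav_pct"].to_numpy(), nodes["depth_m"].to_numpy(),
                   nodes["exposure_m"].to_numpy(), season)
    e = np.exp(s)
    p_nodes = (1.0 - absent_prob) * e / (1.0 + e.sum())
    return np.append(p_nodes, 1.0 - p_nodes.sum())


def simulate_occupancy(system: TelemetrySystem,
                       preferences: dict[str, SpeciesPreference] | None = None,
                       seed: int = 0) -> SimTruth:
    """Realize daily node occupancy for every individual.

    Each tracked day (release to death/end of study) the individual picks a
    node with probability proportional to exp(preference score), or the
    "undetectable" alternative (softmax baseline plus the configured
    out-migration probability ``absent_prob``).
    """
    config = system.config
    preferences = preferences or system.preferences
    missing = set(system.tags["species"]) - set(preferences)
    if missing:
        raise ConsistencyError(f"no preference supplied for species: {sorted(missing)}")
    rng = np.random.default_rng(stage_seed(seed, "occupancy"))

    node_ids = system.nodes["node_id"].to_numpy()
    all_days = pd.date_range(config.start_ts, periods=config.n_days, freq="D")
    day_season = assign_season(pd.Series(all_days), config.season_by_month).to_numpy()

    prob_rows, probs = [], {}
    for sp in config.species:
        for season in SEASONS:
            p = _choice_probs(preferences[sp], system.nodes, season, config.absent_prob)
            probs[(sp, season)] = p
            prob_rows.extend(
                [(sp, season, nid, p[i]) for i, nid in enumerate(node_ids)])
    species_node_probs = pd.DataFrame(
        prob_rows, columns=["species", "season", "node_id", "p"])
    p_absent = pd.DataFrame(
        [(sp, season, probs[(sp, season)][-1]) for sp in config.species for season in SEASONS],
        columns=["species", "season", "p"])

    occ_tag, occ_date, occ_node = [], [], []
    for tag in system.tags.itertuples(index=False):
        t_end = tag.death_date if pd.notna(tag.death_date) else all_days[-1] + pd.Timedelta(days=1)
        mask = (all_days >= tag.release_date) & (all_days < t_end)
        days = all_days[mask]
        seasons = day_season[mask]
        choice = np.empty(len(days), dtype=int)
        for season in SEASONS:
            sel = seasons == season
            if not sel.any():
                continue
            cum = np.cumsum(probs[(tag.species, season)])
            choice[sel] = np.searchsorted(cum, rng.random(sel.sum()), side="right")
        present = choice < len(node_ids)
        occ_tag.extend([tag.tag_id] * int(present.sum()))
        occ_date.append(days[present])
        occ_node.append(node_ids[choice[present]])
    occupancy = pd.DataFrame({
        "tag_id": occ_tag,
        "date": pd.DatetimeIndex(np.concatenate([d.to_numpy() for d in occ_date])
                                 if occ_date else []),
        "node_id": np.concatenate(occ_node) if occ_node else [],
    })
    return SimTruth(occupancy=occupancy, species_node_probs=species_node_probs,
                    p_absent=p_absent)


def _coverage_receiver(system: TelemetrySystem) -> pd.DataFrame:
    """One receiver per covered node-day (alternating when several overlap)."""
    frames = []
    for row in system.deployments.itertuples(index=False):
        days = pd.date_range(pd.Timestamp(row.start), pd.Timestamp(row.end), freq="D")
        frames.append(pd.DataFrame(
            {"node_id": row.node_id, "date": days, "receiver_id": row.receiver_id}))
    cov = pd.concat(frames, ignore_index=True).sort_values(
        ["node_id", "date", "receiver_id"], kind="mergesort")
    rank = cov.groupby(["node_id", "date"]).cumcount()
    ncand = cov.groupby(["node_id", "date"])["receiver_id"].transform("size")
    pick = cov["date"].dt.day_of_year % ncand
    return cov[rank == pick][["node_id", "date", "receiver_id"]]


def simulate_detections(occupancy: SimTruth, system: TelemetrySystem,
                        seed: int = 0) -> tuple[pd.DataFrame, SimTruth]:
    """Emit the detection table and complete the ground truth.

    Per present individual-node-day a near-Poisson number of detections is
    generated with inter-detection gaps of at least the minimum tag delay;
    detections are only emitted on days the node had a deployed receiver.
    Contaminants are then injected: isolated spurious detections (no
    same-tag detection within one hour) and, for tags with a death date,
    continuous pings at one fixed receiver from death to deployment end.
    """
    config = system.config
    occ = occupancy.occupancy
    if not set(occ["node_id"]).issubset(set(system.nodes["node_id"])):
        raise ConsistencyError("occupancy refers to nodes not in the system")
    if not set(occ["tag_id"]).issubset(set(system.tags["tag_id"])):
        raise ConsistencyError("occupancy refers to tags not in the system")
    rng = np.random.default_rng(stage_seed(seed, "detections"))

    cov = _coverage_receiver(system)
    rows = occ.merge(cov, on=["node_id", "date"], how="inner")
    n_rows = len(rows)
    counts = rng.poisson(config.lambda_detections, n_rows)
    counts = np.maximum(counts, 0)
    total = int(counts.sum())

    # detections arrive in a clustered bout (fish near the receiver), with
    # exponential inter-detection gaps offset by the minimum tag delay; the
    # segmented-cumsum construction guarantees gaps >= min_delay_s within a
    # day and, because times live in [delay, 86400 - delay], across day
    # boundaries too
    delay = float(config.min_delay_s)
    gaps = rng.exponential(config.bout_gap_mean_s, total) + delay
    first_idx = np.concatenate(([0], np.cumsum(counts)))[:-1][counts > 0]
    starts = delay + rng.uniform(0, SECONDS_PER_DAY * 0.8, n_rows)
    gaps[first_idx] = starts[counts > 0]
    cs = np.cumsum(gaps)
    seg_base = np.repeat(cs[first_idx] - gaps[first_idx], counts[counts > 0])
    secs = np.empty(total)
    secs[:] = cs - seg_base if total else cs
    keep = secs <= SECONDS_PER_DAY - delay

    det = pd.DataFrame({
        "timestamp": np.repeat(rows["date"].to_numpy(), counts)
                     + pd.to_timedelta(secs, unit="s"),
        "receiver_id": np.repeat(rows["receiver_id"].to_numpy(), counts),
        "tag_id": np.repeat(rows["tag_id"].to_numpy(), counts),
    })[keep]
    det["is_false"] = False

    # dead tags: fixed-receiver pings from death until deployment end
    onsets: dict[str, pd.Timestamp] = {}
    dead_frames = []
    dep = system.deployments
    for tag in system.tags[system.tags["death_date"].notna()].itertuples(index=False):
        death = pd.Timestamp(tag.death_date)
        cands = dep[dep["end"] >= death]
        if cands.empty:
            continue
        term = cands.loc[cands["end"].idxmax()]
        t0 = max(death, pd.Timestamp(term["start"]))
        t_end = min(pd.Timestamp(term["end"]) + pd.Timedelta(days=1), config.end_ts)
        n_pings = int((t_end - t0).total_seconds() // config.dead_ping_interval_s)
        if n_pings <= 0:
            continue
        jitter = rng.uniform(0, config.dead_ping_interval_s / 6, n_pings)
        times = t0 + pd.to_timedelta(
            np.arange(n_pings) * config.dead_ping_interval_s + jitter, unit="s")
        # drop any live detections at/after death (fish is dead)
        det = det[~((det["tag_id"] == tag.tag_id) & (det["timestamp"] >= death))]
        dead_frames.append(pd.DataFrame({
            "timestamp": times, "receiver_id": term["receiver_id"],
            "tag_id": tag.tag_id, "is_false": False}))
        onsets[tag.tag_id] = times[0]
    if dead_frames:
        det = pd.concat([det] + dead_frames, ignore_index=True)

    # isolated spurious detections
    live_tags = system.tags[system.tags["death_date"].isna()]["tag_id"].to_numpy()
    by_tag = {t: np.sort(g["timestamp"].to_numpy().astype("datetime64[ns]").astype(np.int64))
              for t, g in det.groupby("tag_id")}
    hour_ns = int(3600 * 1e9)
    spur = []
    n_placed = 0
    attempts = 0
    dep_idx = dep.reset_index(drop=True)
    while n_placed < config.n_spurious and attempts < config.n_spurious * 1000:
        attempts += 1
        tag = str(rng.choice(live_tags))
        d = dep_idx.iloc[int(rng.integers(0, len(dep_idx)))]
        span = (pd.Timestamp(d["end"]) + pd.Timedelta(days=1) - pd.Timestamp(d["start"]))
        ts = pd.Timestamp(d["start"]) + pd.Timedelta(seconds=float(
            rng.uniform(0, span.total_seconds())))
        t_ns = ts.value
        arr = by_tag.get(tag, np.array([], dtype=np.int64))
        i = np.searchsorted(arr, t_ns)
        if (i > 0 and t_ns - arr[i - 1] <= hour_ns) or (i < len(arr) and arr[i] - t_ns <= hour_ns):
            continue
        by_tag[tag] = np.insert(arr, i, t_ns)
        spur.append((ts, d["receiver_id"], tag, True))
        n_placed += 1
    if n_placed < config.n_spurious:
        raise ConsistencyError("could not place all configured spurious detections")
    if spur:
        det = pd.concat([det, pd.DataFrame(
            spur, columns=["timestamp", "receiver_id", "tag_id", "is_false"])],
            ignore_index=True)

    det = det.sort_values(["timestamp", "tag_id"], kind="mergesort").reset_index(drop=True)
    det.insert(0, "det_id", np.arange(len(det), dtype=np.int64))
    false_ids = set(det.loc[det["is_false"], "det_id"].tolist())
    det = det.drop(columns="is_false")

    truth = replace(occupancy, dead_tag_onsets=onsets, false_detection_ids=false_ids)
    return det, truth


def true_response(preferences: dict[str, SpeciesPreference], species: str,
                  predictor: str, grid, nodes: pd.DataFrame,
                  absent_prob: float = 0.0) -> np.ndarray:
    """Closed-form true marginal occupancy-probability curve.

    Returns, for each grid value of ``predictor`` (one of ``sav_pct``,
    ``depth_m``, ``exposure_m``, ``season``), the inverse-logit of the
    preference score with the other continuous covariates held at the
    system (node-table) means, averaged over seasons (or evaluated per
    season when ``predictor == 'season'``), scaled by ``1 - absent_prob``.
    This is the oracle against which fitted partial-dependence curves are
    compared; it is a monotone transform of the generator's softmax
    occupancy probabilities, so rank-based comparisons are exact.
    """
    pref = preferences[species]
    means = {"sav": nodes["sav_pct"].mean(), "depth": nodes["depth_m"].mean(),
             "exposure": nodes["exposure_m"].mean()}
    name_map = {"sav_pct": "sav", "depth_m": "depth", "exposure_m": "exposure"}

    def score_at(vals: dict[str, float], season: str) -> float:
        return pref.score(vals["sav"], vals["depth"], vals["exposure"], season)

    out = []
    if predictor == "season":
        for season in grid:
            s = score_at(means, season)
            out.append(1.0 / (1.0 + np.exp(-s)))
    elif predictor in name_map:
        for v in np.asarray(grid, dtype=float):
            vals = dict(means)
            vals[name_map[predictor]] = v
            ps = [1.0 / (1.0 + np.exp(-score_at(vals, season))) for season in SEASONS]
            out.append(float(np.mean(ps)))
    else:
        raise ConfigurationError(f"unknown predictor {predictor!r}")
    return (1.0 - absent_prob) * np.asarray(out, dtype=float)


@dataclass
class SimStudy:
    """A complete simulated study: system tables, detections, ground truth."""
    system: TelemetrySystem
    detections: pd.DataFrame
    truth: SimTruth

    @property
    def nodes(self): return self.system.nodes
    @property
    def deployments(self): return self.system.deployments
    @property
    def tags(self): return self.system.tags


def simulate_study(config: SimConfig | None = None, seed: int = 0) -> SimStudy:
    """Run all generation stages under one master seed."""
    config = config or SimConfig()
    system = simulate_system(config, seed)
    occ = simulate_occupancy(system, seed=seed)
    detections, truth = simulate_detections(occ, system, seed=seed)
    return SimStudy(system=system, detections=detections, truth=truth)


def write_study(study: SimStudy, out_dir) -> None:
    """Write the four study tables plus the ground-truth bundle as text."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    det = study.detections.copy()
    det["timestamp"] = det["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    det.to_csv(out / "detections.csv", index=False)
    study.deployments.to_csv(out / "deployments.csv", index=False, date_format="%Y-%m-%d")
    study.nodes.to_csv(out / "nodes.csv", index=False)
    study.tags.drop(columns="death_date").to_csv(out / "tags.csv", index=False,
                                                 date_format="%Y-%m-%d")
    truth = study.truth
    truth.occupancy.to_csv(out / "truth_occupancy.csv", index=False, date_format="%Y-%m-%d")
    truth.species_node_probs.to_csv(out / "truth_node_probs.csv", index=False)
    truth.p_absent.to_csv(out / "truth_p_absent.csv", index=False)
    with open(out / "truth_contaminants.json", "w") as fh:
        json.dump({
            "dead_tag_onsets": {k: str(v) for k, v in truth.dead_tag_onsets.items()},
            "false_detection_ids": sorted(truth.false_detection_ids),
        }, fh, indent=1)
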