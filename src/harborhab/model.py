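"""Class-weighted random-forest presence/absence models.

Per species, a random forest is fit to daily node presence/absence with
habitat predictors {SAV %, depth, exposure, season, region}.  Because the
response is zero-inflated (>70 % absences), an unweighted forest favours
specificity; class weights are therefore tuned on a held-out tuning split
to balance sensitivity against specificity while keeping the model's
categorical partial dependencies close to the empirical presence rates.

The learner is scikit-learn's RandomForestClassifier behind a small
wrapper (:class:`HabitatRF`) that owns the one-hot encoding of the
categorical predictors, so interpretation routines can permute or grid a
categorical predictor as one unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, ModelDegenerateError
from .presence import SEASONS

PREDICTORS = ("sav_pct", "depth_m", "exposure_m", "season", "region")
CATEGORICAL = ("season", "region")
DEFAULT_WEIGHT_GRID = (1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 20.0, 30.0, 50.0)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/tune/test partition, stratified by presence."""
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if any(f <= 0 for f in self.fractions) or abs(sum(self.fractions) - 1) > 1e-9:
            raise ConfigurationError("split fractions must be positive and sum to 1")


@dataclass(frozen=True)
class ModelConfig:
    """Forest hyper-parameters.

    ``mtry`` is the number of (encoded) features tried at each split;
    ``None`` means floor(sqrt(number of encoded features)).  Class weights
    enter through the learner's class-weighting mechanism.
    """
    n_trees: int = 1000
    mtry: int | None = None
    presence_weight: float = 1.0
    absence_weight: float = 1.0
    min_samples_leaf: int = 1

    def __post_init__(self):
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.presence_weight <= 0 or self.absence_weight <= 0:
            raise ConfigurationError("class weights must be > 0")

    @property
    def class_weights(self) -> dict[int, float]:
        return {0: self.absence_weight, 1: self.presence_weight}


def split_data(records: pd.DataFrame, split_spec: SplitSpec
               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Random row-level partition into (train, tune, test).

    Stratified by the ``present`` column with largest-remainder rounding,
    so each part's class mix matches the whole table; disjoint and
    exhaustive; deterministic per seed.
    """
    rng = np.random.default_rng(split_spec.seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for _, grp in records.groupby("present", sort=True):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        nc = len(idx)
        raw = np.array(split_spec.fractions) * nc
        sizes = np.floor(raw).astype(int)
        rema = raw - sizes
        for k in np.argsort(-rema)[: nc - sizes.sum()]:
            sizes[k] += 1
        stops = np.cumsum(sizes)
        parts[0].append(idx[:stops[0]])
        parts[1].append(idx[stops[0]:stops[1]])
        parts[2].append(idx[stops[1]:stops[2]])
    out = []
    for chunks in parts:
        sel = np.sort(np.concatenate(chunks)) if chunks else np.array([], dtype=int)
        out.append(records.loc[sel].reset_index(drop=True))
    return tuple(out)


@dataclass
class HabitatRF:
    """A fitted presence/absence forest plus its feature encoding."""
    estimator: RandomForestClassifier
    predictors: tuple[str, ...]
    cat_levels: dict[str, tuple]
    feature_names: tuple[str, ...]
    config: ModelConfig
    seed: int

    def encode(self, records: pd.DataFrame) -> np.ndarray:
        cols = []
        names = []
        for p in self.predictors:
            if p in self.cat_levels:
                cat = pd.Categorical(records[p], categories=self.cat_levels[p])
                onehot = pd.get_dummies(cat, prefix=p)
                cols.append(onehot.to_numpy(dtype=float))
                names.extend(onehot.columns)
            else:
                cols.append(records[p].to_numpy(dtype=float)[:, None])
                names.append(p)
        X = np.hstack(cols)
        assert tuple(names) == self.feature_names
        return X

    def predict_prob(self, records: pd.DataFrame) -> np.ndarray:
        """Per-row presence probability in [0, 1]."""
        proba = self.estimator.predict_proba(self.encode(records))
        pos = list(self.estimator.classes_).index(1)
        return proba[:, pos]


def _encoding_plan(train: pd.DataFrame, predictors) -> tuple[dict, tuple]:
    cat_levels = {}
    names: list[str] = []
    for p in predictors:
        if p in CATEGORICAL:
            levels = tuple(SEASONS) if p == "season" else tuple(sorted(train[p].unique()))
            cat_levels[p] = levels
            names.extend(f"{p}_{lv}" for lv in levels)
        else:
            names.append(p)
    return cat_levels, tuple(names)


def fit_weighted_rf(train: pd.DataFrame, model_config: ModelConfig | None = None,
                    seed: int = 0, predictors=PREDICTORS) -> HabitatRF:
    """Fit the class-weighted forest on the training split.

    Raises :class:`ModelDegenerateError` when the training data contain a
    single class.
    """
    model_config = model_config or ModelConfig()
    y = train["present"].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelDegenerateError("training data contain a single presence class")
    cat_levels, names = _encoding_plan(train, predictors)
    mtry = model_config.mtry or max(1, int(np.sqrt(len(names))))
    if not 1 <= mtry <= len(names):
        raise ConfigurationError(f"mtry must lie in [1, {len(names)}]")
    est = RandomForestClassifier(
        n_estimators=model_config.n_trees,
        max_features=mtry,
        min_samples_leaf=model_config.min_samples_leaf,
        class_weight=model_config.class_weights,
        random_state=seed,
        n_jobs=1,
    )
    model = HabitatRF(estimator=est, predictors=tuple(predictors),
                      cat_levels=cat_levels, feature_names=names,
                      config=model_config, seed=seed)
    est.fit(model.encode(train), y)
    return model


def predict_presence(model: HabitatRF, records: pd.DataFrame,
                     threshold: float = 0.5) -> pd.DataFrame:
    """Presence probability and thresholded class per row.

    The decision threshold is fixed at 0.5; class balancing is done through
    the tuned class weights, not by moving the threshold.
    """
    prob = model.predict_prob(records)
    return pd.DataFrame({"prob": prob, "pred": (prob >= threshold).astype(int)},
                        index=records.index)


@dataclass
class TuningResult:
    """Outcome of the class-weight grid scan."""
    grid: tuple[float, ...]
    balance_scores: tuple[float, ...]      # |sensitivity - specificity| on tune
    calibration_scores: tuple[float, ...]  # categorical PDP vs empirical rate
    composite: tuple[float, ...]
    selected_weight: float
    lam: float = 1.0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "presence_weight": self.grid,
            "balance_score": self.balance_scores,
            "calibration_score": self.calibration_scores,
            "composite": self.composite,
            "selected": [w == self.selected_weight for w in self.grid],
        })


def _calibration_score(model: HabitatRF, tune: pd.DataFrame, background_n: int,
                       seed: int) -> float:
    """Mean absolute gap between one-way categorical partial dependence and
    the empirical presence rate at each level, averaged over the
    categorical predictors, on the tuning split."""
    from .interpret import GridSpec, partial_dependence

    rng = np.random.default_rng(seed)
    bg = tune if len(tune) <= background_n else tune.iloc[
        np.sort(rng.choice(len(tune), background_n, replace=False))]
    per_var = []
    for var in (v for v in model.predictors if v in model.cat_levels):
        pdp = partial_dependence(model, bg, [var], GridSpec())
        emp = tune.groupby(var, observed=False)["present"].mean()
        diffs = [abs(yh - emp[lv]) for lv, yh in
                 zip(pdp.values[var], pdp.values["yhat"]) if lv in emp.index
                 and not np.isnan(emp[lv])]
        if diffs:
            per_var.append(float(np.mean(diffs)))
    return float(np.mean(per_var)) if per_var else float("nan")


def tune_class_weights(train: pd.DataFrame, tune: pd.DataFrame,
                       grid=DEFAULT_WEIGHT_GRID,
                       model_config: ModelConfig | None = None, seed: int = 0,
                       lam: float = 1.0, tuning_trees: int | None = None,
                       calibration_background_n: int = 300) -> TuningResult:
    """Scan presence-class weights and pick the best-balanced model.

    For each candidate presence weight the forest is refit on the training
    split and scored on the tuning split: the class-balance score is
    |sensitivity - specificity| and the calibration score is the mean
    absolute gap between the categorical one-way partial dependencies and
    the empirical presence rates at each level.  The composite is
    ``balance + lam * calibration``; ties are broken toward the weight
    closest to 1 (then the smaller weight).  ``tuning_trees`` optionally
    reduces the forest size for the scan only.
    """
    from .metrics import compute_fit_metrics, confusion_counts

    grid = tuple(float(w) for w in grid)
    if len(grid) == 0:
        raise ConfigurationError("weight grid must not be empty")
    model_config = model_config or ModelConfig()
    balance, calibration = [], []
    for w in grid:
        cfg = replace(model_config, presence_weight=w,
                      n_trees=tuning_trees or model_config.n_trees)
        m = fit_weighted_rf(train, cfg, seed=seed)
        pred = predict_presence(m, tune)
        fm = compute_fit_metrics(confusion_counts(tune["present"], pred["pred"]))
        b = abs(fm.sensitivity - fm.specificity)
        balance.append(float(b) if np.isfinite(b) else 2.0)
        c = _calibration_score(m, tune, calibration_background_n, seed)
        calibration.append(c if np.isfinite(c) else 0.0)
    composite = [b + lam * c for b, c in zip(balance, calibration)]
    best = min(composite)
    cands = [w for w, comp in zip(grid, composite) if comp <= best + 1e-12]
    selected = min(cands, key=lambda w: (abs(np.log(w)), w))
    return TuningResult(grid=grid, balance_scores=tuple(balance),
                        calibration_scores=tuple(calibration),
                        composite=tuple(composite), selected_weight=selected, lam=lam)
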