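"""Model interpretation: partial dependence, permutation importance,
interaction strength, and community-level habitat suitability.

Partial dependence uses the standard background-averaging estimator: each
grid value is substituted into every background row and the predictions
averaged, so the curve reflects the marginal effect of the predictor over
the empirical distribution of the remaining covariates (an at-means
profile variant is available via ``GridSpec(at_means=True)``).  Variable
importance is permutation-based mean decrease in accuracy on a held-out
evaluation set, with one-hot groups of a categorical predictor permuted
jointly.  Interaction strength between two predictors is Friedman's
H-statistic in its centered partial-dependence form, evaluated on a seeded
subsample of the background.  Community-level habitat suitability indices
average the season x habitat partial dependencies across species models.

All routines accept either a fitted :class:`harborhab.model.HabitatRF` or
any callable mapping a predictor DataFrame to presence probabilities,
which keeps them testable against analytic stub predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ConsistencyError

logger = logging.getLogger("harborhab.interpret")

COMMUNITY_VARIABLES = ("sav_pct", "depth_m", "region")


def _predict_fn(model):
    if callable(model) and not hasattr(model, "predict_prob"):
        return model
    return model.predict_prob


def _variable_grid(var: str, background: pd.DataFrame, model, grid_spec) -> np.ndarray:
    if grid_spec.values and var in grid_spec.values:
        return np.asarray(grid_spec.values[var])
    levels = getattr(model, "cat_levels", {})
    if var in levels:
        return np.asarray(levels[var], dtype=object)
    col = background[var]
    if not pd.api.types.is_numeric_dtype(col):
        return np.asarray(sorted(col.unique()), dtype=object)
    lo, hi = float(col.min()), float(col.max())
    if lo == hi:
        return np.asarray([lo])
    return np.linspace(lo, hi, grid_spec.n_points)


@dataclass(frozen=True)
class GridSpec:
    """Grid construction for partial dependence.

    ``n_points`` evenly spaced values within the observed range for
    continuous predictors (categoricals always use their levels); explicit
    grids may be supplied per variable through ``values``.  With
    ``at_means=True`` the background collapses to a single profile row
    (continuous covariates at their means, categoricals at their modes).
    """
    n_points: int = 20
    values: dict | None = None
    at_means: bool = False


@dataclass
class PartialDependence:
    """A 1- or 2-way partial-dependence surface.

    ``values`` holds one row per grid point: the variable column(s) plus
    ``yhat``, the mean predicted presence probability.
    """
    variables: tuple[str, ...]
    values: pd.DataFrame
    background_n: int


@dataclass(frozen=True)
class ImportanceResult:
    variable: str
    mda: float


@dataclass(frozen=True)
class InteractionResult:
    pair: tuple[str, str]
    h: float
    sample_n: int


def partial_dependence(model, background: pd.DataFrame, variables,
                       grid_spec: GridSpec | None = None) -> PartialDependence:
    """Background-averaged partial dependence for one or two predictors."""
    grid_spec = grid_spec or GridSpec()
    variables = list(variables)
    if not 1 <= len(variables) <= 2:
        raise ConfigurationError("partial dependence takes 1 or 2 variables")
    if background.empty:
        raise ConfigurationError("background must be non-empty")
    for v in variables:
        if v not in background.columns:
            raise ConfigurationError(f"unknown variable {v!r}")
    predict = _predict_fn(model)

    if grid_spec.at_means:
        profile = {}
        for c in background.columns:
            profile[c] = (background[c].mean()
                          if pd.api.types.is_numeric_dtype(background[c])
                          else background[c].mode().iloc[0])
        bg = pd.DataFrame([profile])
    else:
        bg = background

    grids = [_variable_grid(v, background, model, grid_spec) for v in variables]
    if len(variables) == 1:
        points = [(g,) for g in grids[0]]
    else:
        points = [(a, b) for a in grids[0] for b in grids[1]]

    chunks = []
    for pt in points:
        rep = bg.copy()
        for v, val in zip(variables, pt):
            rep[v] = val
        chunks.append(rep)
    big = pd.concat(chunks, ignore_index=True)
    yhat = predict(big)
    yhat = np.asarray(yhat, dtype=float).reshape(len(points), len(bg)).mean(axis=1)

    values = pd.DataFrame(points, columns=variables)
    values["yhat"] = yhat
    return PartialDependence(variables=tuple(variables), values=values,
                             background_n=len(bg))


def mda_importance(model, eval_set: pd.DataFrame, n_permutations: int = 5,
                   seed: int = 0, predictors=None,
                   threshold: float = 0.5) -> list[ImportanceResult]:
    """Permutation mean decrease in accuracy, in percent of baseline.

    Each predictor's values are permuted (one-hot groups move together,
    since permutation happens on the raw column before encoding) and the
    drop in classification accuracy on ``eval_set`` is averaged over
    ``n_permutations`` shuffles: ``mda = 100 * (acc0 - mean(acc_perm)) / acc0``.
    """
    rng = np.random.default_rng(seed)
    predict = _predict_fn(model)
    predictors = list(predictors or getattr(model, "predictors", None)
                      or [c for c in eval_set.columns if c != "present"])
    y = eval_set["present"].to_numpy(dtype=int)
    acc0 = float(((predict(eval_set) >= threshold).astype(int) == y).mean())
    out = []
    for var in predictors:
        accs = []
        for _ in range(n_permutations):
            perm = eval_set.copy()
            perm[var] = rng.permutation(perm[var].to_numpy())
            accs.append(float(((predict(perm) >= threshold).astype(int) == y).mean()))
        out.append(ImportanceResult(variable=var,
                                    mda=100.0 * (acc0 - float(np.mean(accs))) / acc0))
    return sorted(out, key=lambda r: -r.mda)


def _pd_at_sample(predict, sample: pd.DataFrame, cols: list[str]) -> np.ndarray:
    """PD of ``cols`` evaluated at the sample's own values of those columns,
    averaging over the sample as background.  Returns one value per row."""
    m = len(sample)
    big = pd.concat([sample] * m, ignore_index=True)  # background blocks
    for c in cols:
        big[c] = np.repeat(sample[c].to_numpy(), m)
    return np.asarray(_as_float(predict(big))).reshape(m, m).mean(axis=1)


def _as_float(x):
    return np.asarray(x, dtype=float)


def friedman_h(model, background: pd.DataFrame, var_j: str, var_k: str,
               sample_n: int = 300, seed: int = 0) -> InteractionResult:
    """Friedman's H-statistic for the (var_j, var_k) interaction.

    Centered partial-dependence form on a seeded subsample x_1..x_m of the
    background::

        H^2 = sum_i [PD_jk(x_i) - PD_j(x_i) - PD_k(x_i)]^2 / sum_i PD_jk(x_i)^2

    with every PD mean-centered over the sample; ``h = sqrt(max(H^2, 0))``
    clipped to [0, 1].  A constant two-way surface (zero denominator) gives
    a missing (NaN) h.
    """
    if len(background) < 2:
        raise ConfigurationError("need at least 2 background rows")
    rng = np.random.default_rng(seed)
    if len(background) > sample_n:
        take = np.sort(rng.choice(len(background), sample_n, replace=False))
        sample = background.iloc[take].reset_index(drop=True)
    else:
        sample = background.reset_index(drop=True)
    predict = _predict_fn(model)

    pd_j = _pd_at_sample(predict, sample, [var_j])
    pd_k = _pd_at_sample(predict, sample, [var_k])
    pd_jk = _pd_at_sample(predict, sample, [var_j, var_k])
    pd_j = pd_j - pd_j.mean()
    pd_k = pd_k - pd_k.mean()
    pd_jk = pd_jk - pd_jk.mean()

    denom = float((pd_jk**2).sum())
    if denom <= 1e-12:
        h = float("nan")
    else:
        h2 = float(((pd_jk - pd_j - pd_k) ** 2).sum()) / denom
        h = float(np.clip(np.sqrt(max(h2, 0.0)), 0.0, 1.0))
    return InteractionResult(pair=(var_j, var_k), h=h, sample_n=len(sample))


def community_hsi(per_species_pdp: dict[str, dict[str, PartialDependence]]
                  ) -> pd.DataFrame:
    """Cross-species mean of the season x habitat partial dependencies.

    ``per_species_pdp`` maps species -> variable -> two-way (season,
    variable) PartialDependence on a shared grid.  Only SAV, depth and
    region are aggregated (exposure is excluded at the community level).
    Returns a long frame ``(variable, season, value, mean_yhat, n_species)``.
    """
    frames = []
    for var in COMMUNITY_VARIABLES:
        per_species = []
        ref = None
        for species, pdps in sorted(per_species_pdp.items()):
            if var not in pdps:
                continue
            pdp = pdps[var]
            if tuple(pdp.variables) != ("season", var):
                raise ConfigurationError(
                    f"expected a (season, {var}) surface for {species}")
            vals = pdp.values.sort_values(["season", var]).reset_index(drop=True)
            key = vals[["season", var]]
            if ref is None:
                ref = key
            elif not ref.equals(key):
                raise ConsistencyError(f"species grids differ for {var!r}")
            per_species.append(vals["yhat"].to_numpy())
        if not per_species:
            continue
        mean = np.mean(per_species, axis=0)
        out = ref.copy()
        out.insert(0, "variable", var)
        out = out.rename(columns={var: "value"})
        out["mean_yhat"] = mean
        out["n_species"] = len(per_species)
        frames.append(out)
    if not frames:
        return pd.DataFrame(columns=["variable", "season", "value", "mean_yhat", "n_species"])
    return pd.concat(frames, ignore_index=True)


def plot_partial_dependence(pdp: PartialDependence, ax=None):
    """Quick matplotlib rendering of a 1-way curve or 2-way set of curves
    (one line per level of the first variable)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = pdp.values
    if len(pdp.variables) == 1:
        var = pdp.variables[0]
        if pd.api.types.is_numeric_dtype(v[var]):
            ax.plot(v[var], v["yhat"], marker="o")
        else:
            ax.bar(v[var].astype(str), v["yhat"])
        ax.set_xlabel(var)
    else:
        a, b = pdp.variables
        for lv, grp in v.groupby(a, sort=False):
            if pd.api.types.is_numeric_dtype(v[b]):
                ax.plot(grp[b], grp["yhat"], marker="o", label=str(lv))
            else:
                ax.plot(grp[b].astype(str), grp["yhat"], marker="o", label=str(lv))
        ax.set_xlabel(b)
        ax.legend(title=a)
    ax.set_ylabel("partial dependence (yhat)")
    return ax
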