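"""Model evaluation: metrics, species-augmented regression, bootstrap, LMG.

The headline model regresses a chlorophyll-fluorescence parameter on the
optimal spectral index plus species identity (reference-level dummy
coding).  Coefficients are aggregated over case-resampling bootstrap
replicates, and the Lindeman-Merenda-Gold (LMG) decomposition splits the
model R^2 between the index and the species term by averaging each
group's incremental R^2 over both orders of entry.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .chlf import PARAM_COLUMNS
from .errors import ConfigError, FitError
from .indices import compute_empirical, load_registry
from .io import SpectraMatrix

__all__ = [
    "Metrics",
    "ModelReport",
    "metrics",
    "fit_species_mlr",
    "bootstrap_train",
    "relative_importance_lmg",
    "evaluate_empirical_panel",
]


@dataclass(frozen=True)
class Metrics:
    r_squared: float
    pearson_r: float
    rmse: float
    mae: float


@dataclass
class ModelReport:
    """Bootstrap-aggregated regression of a parameter on index + species."""

    terms: list[str]
    coef_full: np.ndarray          # plain OLS on the full data
    coef_boot_mean: np.ndarray
    coef_ci_low: np.ndarray        # 2.5 percentile
    coef_ci_high: np.ndarray       # 97.5 percentile
    metrics: Metrics               # boot-mean coefficients on full data
    oob_metrics: Metrics | None    # out-of-bag aggregated predictions
    relative_importance: dict[str, float]
    n: int
    n_boot: int
    seed: int | None
    redraws: int = 0
    predictions: np.ndarray | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "terms": self.terms,
            "coef_full": self.coef_full.tolist(),
            "coef_boot_mean": self.coef_boot_mean.tolist(),
            "coef_ci_low": self.coef_ci_low.tolist(),
            "coef_ci_high": self.coef_ci_high.tolist(),
            "metrics": vars(self.metrics),
            "oob_metrics": vars(self.oob_metrics) if self.oob_metrics else None,
            "relative_importance": self.relative_importance,
            "n": self.n, "n_boot": self.n_boot, "seed": self.seed,
            "redraws": self.redraws,
        }
        return out


def metrics(pred, obs) -> Metrics:
    """R^2 (1 - RSS/TSS), Pearson r, RMSE and MAE of predictions.

    R^2 and r are NaN when the observations (or predictions) have zero
    variance.
    """
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 2:
        raise ConfigError("need two aligned vectors of length >= 2")
    keep = np.isfinite(pred) & np.isfinite(obs)
    pred, obs = pred[keep], obs[keep]
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        return Metrics(np.nan, np.nan, rmse, mae)
    r2 = 1.0 - float(resid @ resid) / tss
    if np.std(pred) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(pred, obs)[0, 1])
    return Metrics(float(r2), r, rmse, mae)


def _design(index_values, species):
    """Design matrix [1, index, species dummies] with term names.

    Reference level = first species alphabetically; rejects a single
    species level or a singular design.
    """
    x = np.asarray(index_values, float)
    cat = pd.Categorical(np.asarray(species, dtype=object))
    levels = sorted(cat.categories.tolist())
    if len(levels) < 2:
        raise ConfigError("need >= 2 species levels for the species term")
    if not np.all(np.isfinite(x)):
        raise ConfigError("index values must be finite")
    cols = [np.ones_like(x), x]
    names = ["intercept", "index"]
    codes = np.asarray(species, dtype=object)
    for lvl in levels[1:]:
        cols.append((codes == lvl).astype(float))
        names.append(f"species[{lvl}]")
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("singular design: species collinear with index")
    return design, names


def fit_species_mlr(index_values, species, y):
    """OLS of y on index + species dummies (statsmodels results object)."""
    design, names = _design(index_values, species)
    y = np.asarray(y, float)
    model = sm.OLS(y, pd.DataFrame(design, columns=names))
    return model.fit()


def _r2_of_subset(y, blocks):
    """R^2 of OLS on intercept plus the given predictor blocks."""
    cols = [np.ones_like(y)] + blocks
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise FitError("target has zero variance")
    return 1.0 - float(resid @ resid) / tss


def relative_importance_lmg(index_values, species, y) -> dict[str, float]:
    """LMG shares of model R^2 for two predictor groups: index vs species.

    Averages each group's incremental R^2 over the two orders of entry;
    the shares are nonnegative up to rounding and sum to the full-model
    R^2 exactly.
    """
    design, _ = _design(index_values, species)
    y = np.asarray(y, float)
    index_block = design[:, 1:2]
    species_block = design[:, 2:]
    r2_index = _r2_of_subset(y, [index_block])
    r2_species = _r2_of_subset(y, [species_block])
    r2_full = _r2_of_subset(y, [index_block, species_block])
    share_index = 0.5 * (r2_index + (r2_full - r2_species))
    share_species = 0.5 * (r2_species + (r2_full - r2_index))
    return {
        "index": float(share_index),
        "species": float(share_species),
        "model_r2": float(r2_full),
    }


def bootstrap_train(
    index_values,
    species,
    y,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> ModelReport:
    """Case-resampling bootstrap of the index + species regression.

    Each replicate resamples rows with replacement and refits; replicates
    that lose all but one species level (or go singular) are redrawn, up
    to 10x ``n_boot`` redraws.  Reported coefficients are bootstrap means
    with 2.5/97.5 percentile intervals; the headline metrics apply the
    bootstrap-mean coefficient vector to the full dataset.  Out-of-bag
    metrics (each sample predicted only by replicates that excluded it)
    are also reported.
    """
    if n_boot < 1:
        raise ConfigError("n_boot must be >= 1")
    design, names = _design(index_values, species)
    y = np.asarray(y, float)
    n, p = design.shape
    rng = np.random.default_rng(seed)
    species_arr = np.asarray(species, dtype=object)

    coefs = np.empty((n_boot, p))
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        sub = design[idx]
        if len(set(species_arr[idx])) < 2 or np.linalg.matrix_rank(sub) < p:
            redraws += 1
            if redraws > 10 * n_boot:
                raise FitError("too many degenerate bootstrap resamples")
            continue
        coef, *_ = np.linalg.lstsq(sub, y[idx], rcond=None)
        coefs[b] = coef
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if oob.size:
            oob_sum[oob] += design[oob] @ coef
            oob_count[oob] += 1
        b += 1

    coef_full, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef_mean = coefs.mean(axis=0)
    pred = design @ coef_mean
    seen = oob_count > 0
    oob_metrics = None
    if seen.sum() >= 2:
        oob_pred = oob_sum[seen] / oob_count[seen]
        oob_metrics = metrics(oob_pred, y[seen])
    return ModelReport(
        terms=names,
        coef_full=coef_full,
        coef_boot_mean=coef_mean,
        coef_ci_low=np.percentile(coefs, 2.5, axis=0),
        coef_ci_high=np.percentile(coefs, 97.5, axis=0),
        metrics=metrics(pred, y),
        oob_metrics=oob_metrics,
        relative_importance=relative_importance_lmg(index_values, species, y),
        n=n, n_boot=n_boot, seed=seed, redraws=redraws,
        predictions=pred,
    )


def evaluate_empirical_panel(
    spectra: SpectraMatrix,
    params: pd.DataFrame,
    registry: dict[str, str] | None = None,
    parameters=PARAM_COLUMNS,
) -> pd.DataFrame:
    """Univariate screening of the published empirical indices.

    For each leaf group x parameter x registry index: OLS R^2, RMSE,
    slope p-value and a significance band (``**`` p<0.01, ``*`` p<0.05,
    ``ns`` otherwise).  Constant or all-missing index columns are
    reported as skipped.
    """
    if spectra.group is None:
        raise ConfigError("spectra need leaf-group metadata for the panel")
    registry = load_registry() if registry is None else registry
    values = {name: compute_empirical(spectra, name, registry) for name in registry}
    rows = []
    for g in pd.unique(spectra.group):
        sel = spectra.group == g
        for param in parameters:
            y_all = params.loc[sel, param].to_numpy(float)
            for name, v in values.items():
                x = v[sel]
                keep = np.isfinite(x) & np.isfinite(y_all)
                row = {"group": g, "parameter": param, "index": name}
                if keep.sum() < 3 or np.std(x[keep]) == 0:
                    row.update(r2=np.nan, rmse=np.nan, p_value=np.nan,
                               stars="skipped", n=int(keep.sum()))
                else:
                    fit = stats.linregress(x[keep], y_all[keep])
                    pred = fit.intercept + fit.slope * x[keep]
                    m = metrics(pred, y_all[keep])
                    p = float(fit.pvalue)
                    stars_label = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
                    row.update(r2=m.r_squared, rmse=m.rmse, p_value=p,
                               stars=stars_label, n=int(keep.sum()))
                rows.append(row)
    return pd.DataFrame(rows)
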