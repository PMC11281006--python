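"""Exhaustive band-pair search with AIC model selection.

For each index type the search enumerates every wavelength combination
on a coarse grid (default 10-nm spacing over the data range), computes
the candidate index for all samples at once, regresses the target
parameter on it by ordinary least squares, and keeps the candidate with
the lowest Akaike information criterion

    AIC = n * ln(RSS / n) + 2 k,        k = 3 (intercept, slope, sigma^2).

Within an index type (constant k, constant n) the AIC winner is also
the R^2 winner; across types AIC mediates parsimony.  Candidates whose
index is missing (vanishing denominator on derivative spectra) for more
than a small fraction of samples are excluded so that tiny-n artifacts
cannot win.  Ties break deterministically towards the smaller lambda1,
then the smaller lambda2/delta.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, FitError
from .indices import (
    ALL_INDEX_TYPES,
    OFFSET_TYPES,
    TWO_BAND_TYPES,
    IndexSpec,
)
from .io import SpectraMatrix

__all__ = [
    "SearchGrid",
    "SearchResult",
    "enumerate_candidates",
    "candidate_matrix",
    "fit_univariate",
    "search_optimal",
    "search_matrix",
    "overall_winners",
    "AIC_K",
]

AIC_K = 3
_RSS_FLOOR = 1e-300  # keeps ln() finite on numerically perfect fits


@dataclass(frozen=True)
class SearchGrid:
    """Coarse candidate grid: every ``step_nm`` within the data range."""

    step_nm: int = 10
    lo_nm: int | None = None  # default: data range
    hi_nm: int | None = None

    def __post_init__(self) -> None:
        if self.step_nm < 1:
            raise ConfigError("grid step must be >= 1 nm")

    def bands(self, wavelengths: np.ndarray) -> np.ndarray:
        lo = int(wavelengths[0]) if self.lo_nm is None else self.lo_nm
        hi = int(wavelengths[-1]) if self.hi_nm is None else self.hi_nm
        if lo < wavelengths[0] or hi > wavelengths[-1] or lo > hi:
            raise ConfigError(
                f"grid [{lo}, {hi}] outside data range "
                f"[{wavelengths[0]}, {wavelengths[-1]}]"
            )
        return np.arange(lo, hi + 1, self.step_nm, dtype=int)


@dataclass(frozen=True)
class SearchResult:
    """Winning candidate of one search cell."""

    index_spec: IndexSpec
    aic: float
    r_squared: float
    slope: float
    intercept: float
    n_used: int
    missing_fraction: float


def enumerate_candidates(
    index_type: str, grid: SearchGrid, wavelengths: np.ndarray
) -> list[IndexSpec]:
    """All admissible IndexSpecs of one type, in tie-break order.

    R: one per band.  SR: all ordered pairs.  D/ND/ID: unordered pairs
    with lambda1 < lambda2 (swapping only flips the sign, leaving the
    linear fit's AIC unchanged).  Offset types: all (lambda1, delta)
    with lambda1 +- delta inside the data range.
    """
    bands, pairs = _candidate_pairs(index_type, grid, wavelengths)
    tag = "unspecified"
    if index_type == "R":
        return [IndexSpec("R", int(b), transform_tag=tag) for b in bands]
    if index_type in TWO_BAND_TYPES:
        return [
            IndexSpec(index_type, int(bands[i]), lambda2_nm=int(bands[j]),
                      transform_tag=tag)
            for i, j in pairs
        ]
    return [
        IndexSpec(index_type, int(bands[i]), delta_nm=int(d), transform_tag=tag)
        for i, d in pairs
    ]


def _candidate_pairs(index_type, grid, wavelengths):
    """Band list plus (i, j) position pairs / (i, delta) combos."""
    bands = grid.bands(np.asarray(wavelengths))
    m = bands.size
    if index_type == "R":
        return bands, None
    if index_type in TWO_BAND_TYPES:
        if index_type == "SR":  # ordered pairs, lexicographic
            i, j = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
            keep = i != j
            return bands, np.column_stack([i[keep], j[keep]])
        i, j = np.triu_indices(m, k=1)  # unordered, lambda1 < lambda2
        return bands, np.column_stack([i, j])
    if index_type in OFFSET_TYPES:
        lo, hi = wavelengths[0], wavelengths[-1]
        combos = []
        for i, b in enumerate(bands):
            max_d = min(b - lo, hi - b)
            for d in range(grid.step_nm, max_d + 1, grid.step_nm):
                combos.append((i, d))
        combos.sort()  # (lambda1, delta) ascending = tie-break order
        return bands, np.array(combos, dtype=int).reshape(-1, 2)
    raise ConfigError(f"unknown index type {index_type!r}")


def candidate_matrix(
    spectra: SpectraMatrix, index_type: str, grid: SearchGrid
) -> tuple[np.ndarray, list[IndexSpec]]:
    """All candidate index values at once: (n_samples, n_candidates).

    Column order matches :func:`enumerate_candidates`.  Vanishing
    denominators become NaN per sample.
    """
    wl = spectra.wavelengths
    bands, pairs = _candidate_pairs(index_type, grid, wl)
    pos = np.array([spectra.band_index(int(b)) for b in bands])
    B = spectra.values[:, pos]  # samples x grid bands

    with np.errstate(divide="ignore", invalid="ignore"):
        if index_type == "R":
            X = B.copy()
        elif index_type in TWO_BAND_TYPES:
            r1 = B[:, pairs[:, 0]]
            r2 = B[:, pairs[:, 1]]
            if index_type == "SR":
                X = r1 / _nan_small(r2)
            elif index_type == "D":
                X = r1 - r2
            elif index_type == "ND":
                X = (r1 - r2) / _nan_small(r1 + r2)
            else:  # ID
                X = (r2 - r1) / _nan_small(r1 * r2)
        else:
            step = grid.step_nm
            i1 = pairs[:, 0]
            doff = pairs[:, 1] // step  # delta in grid-position units
            r0 = B[:, i1]
            rm = B[:, i1 - doff]
            rp = B[:, i1 + doff]
            if index_type == "DDn":
                X = 2 * r0 - rm - rp
            elif index_type == "mSR1":
                X = (rm - r0) / _nan_small(rp)
            elif index_type == "mSR2":
                X = (rm - r0) / _nan_small(rp - r0)
            else:  # mND
                X = (rm - r0) / _nan_small(rm + r0 - 2 * rp)
    specs = enumerate_candidates(index_type, grid, wl)
    specs = [
        IndexSpec(s.index_type, s.lambda1_nm, s.lambda2_nm, s.delta_nm,
                  transform_tag=spectra.transform_tag)
        for s in specs
    ]
    return X, specs


def _nan_small(den: np.ndarray) -> np.ndarray:
    return np.where(np.abs(den) < 1e-12, np.nan, den)


def fit_univariate(x, y, k: int = AIC_K):
    """OLS fit y = b0 + b1 x on finite pairs: (aic, r_squared, slope, intercept).

    Pairs with a missing index value are dropped; needs >= 3 finite pairs
    and nonzero variance in x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise FitError(f"need >= 3 finite pairs, got {n}")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise FitError("zero variance in index values")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if tss == 0 else max(0.0, 1.0 - rss / tss)
    aic = n * np.log(max(rss, _RSS_FLOOR) / n) + 2 * k
    return float(aic), float(r2), float(slope), float(intercept)


def _fit_all(X: np.ndarray, y: np.ndarray, k: int = AIC_K):
    """Vectorised OLS of y on every column of X, NaN-aware.

    Returns dict of per-candidate arrays: aic, r2, slope, intercept, n,
    missing_fraction, valid (enough data and nonzero x-variance).
    """
    finite_y = np.isfinite(y)
    mask = np.isfinite(X) & finite_y[:, None]
    n = mask.sum(axis=0).astype(float)
    n_total = float(finite_y.sum())
    Xz = np.where(mask, X, 0.0)
    yz = np.where(finite_y, y, 0.0)
    sx = Xz.sum(axis=0)
    sxx = np.einsum("ij,ij->j", Xz, Xz)
    sxy = yz @ Xz
    sy = mask.T @ yz
    syy = mask.T @ (yz**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = n * sxx - sx**2
        slope = (n * sxy - sx * sy) / den
        intercept = (sy - slope * sx) / n
        rss = np.maximum(syy - intercept * sy - slope * sxy, 0.0)
        # guard against cancellation: a constant target leaves tss at
        # rounding-noise scale relative to syy
        tss = syy - sy**2 / n
        has_var = tss > np.maximum(syy, 1e-30) * 1e-12
        r2 = np.where(
            has_var, np.clip(1.0 - rss / np.where(has_var, tss, 1.0), 0.0, 1.0), 0.0
        )
        aic = n * np.log(np.maximum(rss, _RSS_FLOOR) / n) + 2 * k
    # numerical guard: den can underflow to ~0 for constant candidates
    valid = (n >= 3) & (den > np.finfo(float).tiny * np.maximum(n * sxx, 1.0))
    missing_fraction = 1.0 - n / n_total if n_total else np.ones_like(n)
    return {
        "aic": aic, "r2": r2, "slope": slope, "intercept": intercept,
        "n": n.astype(int), "missing_fraction": missing_fraction,
        "valid": valid & np.isfinite(aic),
    }


def search_optimal(
    spectra: SpectraMatrix,
    y,
    index_type: str,
    grid: SearchGrid | None = None,
    max_missing: float = 0.05,
) -> SearchResult:
    """Best candidate of one index type for one target parameter.

    Minimises AIC among candidates with a missing-value fraction at or
    below ``max_missing``; deterministic tie-break on (lambda1, then
    lambda2/delta).
    """
    grid = grid or SearchGrid()
    y = np.asarray(y, float)
    if y.shape != (spectra.n_samples,):
        raise ConfigError("target vector must align with samples")
    X, specs = candidate_matrix(spectra, index_type, grid)
    fits = _fit_all(X, y)
    admissible = fits["valid"] & (fits["missing_fraction"] <= max_missing)
    if not admissible.any():
        raise FitError(
            f"no admissible {index_type} candidate (all skipped or too many "
            "missing values)"
        )
    aic = np.where(admissible, fits["aic"], np.inf)
    best = int(np.argmin(aic))  # first minimum = tie-break order
    return SearchResult(
        index_spec=specs[best],
        aic=float(fits["aic"][best]),
        r_squared=float(fits["r2"][best]),
        slope=float(fits["slope"][best]),
        intercept=float(fits["intercept"][best]),
        n_used=int(fits["n"][best]),
        missing_fraction=float(fits["missing_fraction"][best]),
    )


def search_matrix(
    spectra_by_transform: dict[str, SpectraMatrix],
    params: pd.DataFrame,
    groups,
    index_types=ALL_INDEX_TYPES,
    grid: SearchGrid | None = None,
    parameters=None,
    max_missing: float = 0.05,
) -> pd.DataFrame:
    """Best index per (group x parameter x transform x index type).

    ``spectra_by_transform`` maps transform tags to already-transformed
    matrices sharing sample order with ``params`` (a per-sample parameter
    table) and ``groups`` (leaf-group labels).  Returns a long table,
    one row per completed search cell.
    """
    if not spectra_by_transform:
        raise ConfigError("empty transform list")
    grid = grid or SearchGrid()
    groups = np.asarray(groups, dtype=object)
    parameters = list(parameters or params.columns)
    group_levels = pd.unique(groups)
    rows = []
    for tag, spectra in spectra_by_transform.items():
        if spectra.n_samples != len(params):
            raise ConfigError(f"transform {tag!r} misaligned with parameter table")
        for index_type in index_types:
            X, specs = candidate_matrix(spectra, index_type, grid)
            for g in group_levels:
                sel = groups == g
                for param in parameters:
                    y = params.loc[sel, param].to_numpy(float)
                    fits = _fit_all(X[sel], y)
                    admissible = fits["valid"] & (
                        fits["missing_fraction"] <= max_missing
                    )
                    if not admissible.any():
                        rows.append(
                            {
                                "group": g, "parameter": param,
                                "transform": tag, "index_type": index_type,
                                "lambda1": np.nan, "lambda2_or_delta": np.nan,
                                "aic": np.nan, "r2": np.nan,
                                "slope": np.nan, "intercept": np.nan,
                                "n_used": 0, "skipped": True,
                            }
                        )
                        continue
                    aic = np.where(admissible, fits["aic"], np.inf)
                    b = int(np.argmin(aic))
                    spec = specs[b]
                    rows.append(
                        {
                            "group": g, "parameter": param,
                            "transform": tag, "index_type": index_type,
                            "lambda1": spec.lambda1_nm,
                            "lambda2_or_delta": spec.second,
                            "aic": float(fits["aic"][b]),
                            "r2": float(fits["r2"][b]),
                            "slope": float(fits["slope"][b]),
                            "intercept": float(fits["intercept"][b]),
                            "n_used": int(fits["n"][b]),
                            "skipped": False,
                        }
                    )
    return pd.DataFrame(rows)


def overall_winners(table: pd.DataFrame) -> pd.DataFrame:
    """Per (group, parameter): the AIC-minimal row across transforms/types."""
    ok = table[~table["skipped"]]
    idx = ok.groupby(["group", "parameter"], sort=True)["aic"].idxmin()
    return ok.loc[idx].reset_index(drop=True)
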