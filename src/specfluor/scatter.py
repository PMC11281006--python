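"""Scatter-correction and absorbance transforms: Log, SNV, MSC, EMSC.

All four operate per sample (row); MSC and EMSC additionally share a
reference spectrum, by default the dataset mean, which callers may
freeze on a training set and reuse.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, SpectraError
from .io import SpectraMatrix

__all__ = [
    "TransformSpec",
    "log_transform",
    "snv",
    "msc",
    "emsc",
    "mean_reference",
]

_ALLOWED = ("log", "snv", "msc", "emsc")


@dataclass(frozen=True)
class TransformSpec:
    """Named scatter transform plus its options."""

    name: str
    reference: np.ndarray | None = None  # MSC/EMSC; None = dataset mean
    emsc_poly_degree: int = 2

    def __post_init__(self) -> None:
        if self.name not in _ALLOWED:
            raise ConfigError(f"transform must be one of {_ALLOWED}")
        if self.emsc_poly_degree not in (1, 2):
            raise ConfigError("emsc_poly_degree must be 1 or 2")


def _chain_tag(tag: str, name: str) -> str:
    return name if tag == "reflectance" else f"{tag}|{name}"


def log_transform(spectra: SpectraMatrix, natural: bool = False) -> SpectraMatrix:
    """Absorbance-style transform log10(1/R) (or ln(R) with ``natural=True``).

    Requires strictly positive values; offending samples are named.
    """
    bad = ~np.all(spectra.values > 0, axis=1)
    if bad.any():
        ids = spectra.sample_ids[bad][:5].tolist()
        raise SpectraError(f"nonpositive values in samples {ids}; cannot take log")
    values = np.log(spectra.values) if natural else -np.log10(spectra.values)
    return spectra.replace(
        values=values, transform_tag=_chain_tag(spectra.transform_tag, "log")
    )


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: centre and scale each spectrum across bands.

    Uses the sample (n-1) standard deviation.  A constant spectrum has no
    variance to scale by and is rejected.
    """
    x = spectra.values
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0):
        ids = spectra.sample_ids[sd == 0][:5].tolist()
        raise SpectraError(f"constant spectra cannot be SNV-scaled: {ids}")
    values = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra.replace(
        values=values, transform_tag=_chain_tag(spectra.transform_tag, "snv")
    )


def mean_reference(spectra: SpectraMatrix) -> np.ndarray:
    """Dataset-mean reference spectrum for MSC/EMSC."""
    if spectra.n_samples < 2:
        raise SpectraError("need >= 2 samples to form a mean reference")
    return spectra.values.mean(axis=0)


def msc(spectra: SpectraMatrix, reference: np.ndarray | None = None) -> SpectraMatrix:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference, x = a + b * ref, and
    returned as (x - a) / b, removing additive offset and multiplicative
    scatter.  The reference defaults to the dataset mean; pass the frozen
    training reference to correct new data consistently.
    """
    ref = mean_reference(spectra) if reference is None else np.asarray(reference, float)
    if ref.shape != (spectra.n_bands,):
        raise SpectraError("reference length does not match band count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise SpectraError("reference spectrum is constant")
    x = spectra.values
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    if np.any(b == 0):
        ids = spectra.sample_ids[b == 0][:5].tolist()
        raise SpectraError(f"zero multiplicative coefficient for samples {ids}")
    a = x.mean(axis=1) - b * ref.mean()
    values = (x - a[:, None]) / b[:, None]
    return spectra.replace(
        values=values, transform_tag=_chain_tag(spectra.transform_tag, "msc")
    )


def emsc(
    spectra: SpectraMatrix,
    reference: np.ndarray | None = None,
    poly_degree: int = 2,
) -> SpectraMatrix:
    """Extended MSC: also removes a low-order wavelength polynomial.

    Fits x = a + b*ref + c1*u + c2*u^2 with u the wavelength rescaled to
    [-1, 1], then returns (x - a - c1*u - c2*u^2) / b.  ``poly_degree``
    may be 1 or 2; degree 0 degenerates to plain MSC and is rejected.
    """
    if poly_degree not in (1, 2):
        raise ConfigError("emsc poly_degree must be 1 or 2 (use msc for 0)")
    ref = mean_reference(spectra) if reference is None else np.asarray(reference, float)
    if ref.shape != (spectra.n_bands,):
        raise SpectraError("reference length does not match band count")
    wl = spectra.wavelengths.astype(float)
    u = (2 * wl - wl[0] - wl[-1]) / (wl[-1] - wl[0])
    cols = [np.ones_like(u), ref] + [u**d for d in range(1, poly_degree + 1)]
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SpectraError("EMSC design is singular (reference collinear with polynomial)")
    coef, *_ = np.linalg.lstsq(design, spectra.values.T, rcond=None)
    a, b = coef[0], coef[1]
    if np.any(b == 0):
        ids = spectra.sample_ids[b == 0][:5].tolist()
        raise SpectraError(f"zero multiplicative coefficient for samples {ids}")
    baseline = design[:, 2:] @ coef[2:]  # bands x samples
    values = (spectra.values - a[:, None] - baseline.T) / b[:, None]
    return spectra.replace(
        values=values, transform_tag=_chain_tag(spectra.transform_tag, "emsc")
    )
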