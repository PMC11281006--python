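"""Spectral index families and the published empirical-index registry.

Nine developable index types combine one or two bands (or a band and an
offset) of any transformed spectrum:

=======  ==================  =======================================
type     wavelengths         formula
=======  ==================  =======================================
R        l1                  R(l1)
SR       l1, l2              R(l1) / R(l2)
D        l1, l2              R(l1) - R(l2)
ND       l1, l2              (R(l1) - R(l2)) / (R(l1) + R(l2))
ID       l1, l2              1/R(l1) - 1/R(l2)
DDn      l1, d               2 R(l1) - R(l1-d) - R(l1+d)
mSR1     l1, d               (R(l1-d) - R(l1)) / R(l1+d)
mSR2     l1, d               (R(l1-d) - R(l1)) / (R(l1+d) - R(l1))
mND      l1, d               (R(l1-d) - R(l1)) / (R(l1-d) + R(l1) - 2 R(l1+d))
=======  ==================  =======================================

On derivative or scatter-corrected spectra a denominator may vanish;
ratio indices then yield a missing value for that sample (counted, never
an infinity), and the band search penalises candidates with too many
missing entries.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, SpectraError
from .io import SpectraMatrix

__all__ = [
    "IndexSpec",
    "TWO_BAND_TYPES",
    "OFFSET_TYPES",
    "ALL_INDEX_TYPES",
    "compute_index",
    "load_registry",
    "compute_empirical",
]

log = logging.getLogger(__name__)

TWO_BAND_TYPES = ("SR", "D", "ND", "ID")
OFFSET_TYPES = ("DDn", "mSR1", "mSR2", "mND")
ALL_INDEX_TYPES = ("R",) + TWO_BAND_TYPES + OFFSET_TYPES

_DENOM_EPS = 1e-12
_BAND_RE = re.compile(r"R(\d+)")


@dataclass(frozen=True)
class IndexSpec:
    """One concrete index: type + wavelength parameters + source transform.

    Two-band types use ``lambda1_nm``/``lambda2_nm``; offset types use
    ``lambda1_nm``/``delta_nm``; type R uses ``lambda1_nm`` only.
    """

    index_type: str
    lambda1_nm: int
    lambda2_nm: int | None = None
    delta_nm: int | None = None
    transform_tag: str = "reflectance"

    def __post_init__(self) -> None:
        t = self.index_type
        if t not in ALL_INDEX_TYPES:
            raise ConfigError(f"unknown index type {t!r}; expected {ALL_INDEX_TYPES}")
        if t == "R":
            if self.lambda2_nm is not None or self.delta_nm is not None:
                raise ConfigError("type R uses lambda1 only")
        elif t in TWO_BAND_TYPES:
            if self.lambda2_nm is None or self.delta_nm is not None:
                raise ConfigError(f"type {t} needs lambda1 and lambda2")
        else:
            if self.delta_nm is None or self.lambda2_nm is not None:
                raise ConfigError(f"type {t} needs lambda1 and delta")
            if self.delta_nm <= 0:
                raise ConfigError("delta must be positive")

    @property
    def second(self) -> int | None:
        """The second parameter (lambda2 or delta), for reporting."""
        return self.delta_nm if self.index_type in OFFSET_TYPES else self.lambda2_nm

    def __str__(self) -> str:
        if self.index_type == "R":
            args = f"{self.lambda1_nm}"
        else:
            args = f"{self.lambda1_nm},{self.second}"
        return f"{self.index_type}:{self.transform_tag}:{args}"

    @classmethod
    def parse(cls, text: str) -> "IndexSpec":
        """Parse ``"ND:fod:0.9:540,1660"`` style strings (CLI syntax)."""
        head, _, args = text.rpartition(":")
        index_type, _, tag = head.partition(":")
        tag = tag or "reflectance"
        nums = [int(a) for a in args.split(",") if a]
        if index_type == "R":
            return cls(index_type, nums[0], transform_tag=tag)
        if index_type in TWO_BAND_TYPES:
            return cls(index_type, nums[0], lambda2_nm=nums[1], transform_tag=tag)
        return cls(index_type, nums[0], delta_nm=nums[1], transform_tag=tag)


def _safe_div(num: np.ndarray, den: np.ndarray, context: str) -> np.ndarray:
    """Elementwise division with near-zero denominators mapped to NaN."""
    bad = np.abs(den) < _DENOM_EPS
    n_bad = int(bad.sum())
    if n_bad:
        log.debug("%s: %d sample(s) with vanishing denominator", context, n_bad)
        den = np.where(bad, np.nan, den)
    return num / den


def compute_index(
    spectra: SpectraMatrix, spec: IndexSpec, check_tag: bool = True
) -> np.ndarray:
    """Per-sample values of one index on the given spectra.

    ``check_tag`` enforces that the spectra's provenance matches the
    transform the spec was defined on.
    """
    if check_tag and spec.transform_tag != spectra.transform_tag:
        raise SpectraError(
            f"index defined on {spec.transform_tag!r} but spectra are "
            f"{spectra.transform_tag!r}"
        )
    t = spec.index_type
    r1 = spectra.band(spec.lambda1_nm)
    if t == "R":
        return r1.copy()
    if t in TWO_BAND_TYPES:
        r2 = spectra.band(spec.lambda2_nm)
        if t == "SR":
            return _safe_div(r1, r2, str(spec))
        if t == "D":
            return r1 - r2
        if t == "ND":
            return _safe_div(r1 - r2, r1 + r2, str(spec))
        return _safe_div(r2 - r1, r1 * r2, str(spec))  # ID = 1/R1 - 1/R2
    d = spec.delta_nm
    rm = spectra.band(spec.lambda1_nm - d)
    rp = spectra.band(spec.lambda1_nm + d)
    if t == "DDn":
        return 2 * r1 - rm - rp
    if t == "mSR1":
        return _safe_div(rm - r1, rp, str(spec))
    if t == "mSR2":
        return _safe_div(rm - r1, rp - r1, str(spec))
    return _safe_div(rm - r1, rm + r1 - 2 * rp, str(spec))  # mND


# -- published empirical indices ---------------------------------------

def load_registry(path: str | Path | None = None) -> dict[str, str]:
    """Load the empirical-index registry (name -> expression over R###)."""
    if path is None:
        source = resources.files("specfluor").joinpath(
            "registry/empirical_indices.yaml"
        )
        text = source.read_text()
    else:
        text = Path(path).read_text()
    registry = yaml.safe_load(text)
    if not isinstance(registry, dict):
        raise ConfigError("registry must map index names to expressions")
    return {str(k): str(v) for k, v in registry.items()}


def compute_empirical(
    spectra: SpectraMatrix,
    name: str,
    registry: dict[str, str] | None = None,
) -> np.ndarray:
    """Evaluate a published empirical index on untransformed reflectance."""
    if spectra.transform_tag != "reflectance":
        raise SpectraError(
            "empirical indices are defined on reflectance spectra, got "
            f"{spectra.transform_tag!r}"
        )
    registry = load_registry() if registry is None else registry
    if name not in registry:
        raise ConfigError(
            f"unknown empirical index {name!r}; registry has "
            f"{sorted(registry)}"
        )
    expr = registry[name]
    namespace: dict[str, np.ndarray] = {}
    for band in set(_BAND_RE.findall(expr)):
        namespace[f"R{band}"] = spectra.band(int(band))
    with np.errstate(divide="ignore", invalid="ignore"):
        value = eval(expr, {"__builtins__": {}}, namespace)  # noqa: S307 - config expressions
    value = np.asarray(value, float)
    value[~np.isfinite(value)] = np.nan
    return value
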