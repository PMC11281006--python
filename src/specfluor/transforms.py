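"""Dispatch spectral transforms by provenance tag.

A tag is either ``"reflectance"`` (identity), ``"fod:<alpha>"`` for a
Grünwald–Letnikov derivative, or one of ``log``, ``snv``, ``msc``,
``emsc``.  Used by the synthetic generator, search driver and CLI so a
single string fully names the spectra an index is computed on.
"""
from __future__ import annotations

import numpy as np

from . import scatter
from .errors import ConfigError
from .fod import fod
from .io import SpectraMatrix

__all__ = ["apply_transform", "fod_tags"]


def apply_transform(
    spectra: SpectraMatrix,
    tag: str,
    reference: np.ndarray | None = None,
) -> SpectraMatrix:
    """Return ``spectra`` transformed according to ``tag``.

    ``reference`` (optional) is the frozen MSC/EMSC reference spectrum;
    the dataset mean is used when absent.
    """
    if tag == "reflectance":
        return spectra
    if tag.startswith("fod:"):
        try:
            alpha = float(tag.split(":", 1)[1])
        except ValueError as exc:
            raise ConfigError(f"bad FOD tag {tag!r}") from exc
        return fod(spectra, alpha)
    if tag == "log":
        return scatter.log_transform(spectra)
    if tag == "snv":
        return scatter.snv(spectra)
    if tag == "msc":
        return scatter.msc(spectra, reference)
    if tag == "emsc":
        return scatter.emsc(spectra, reference)
    raise ConfigError(f"unknown transform tag {tag!r}")


def fod_tags(start: float = 0.0, stop: float = 2.0, step: float = 0.1) -> list[str]:
    """Tags for a scan of derivative orders, e.g. fod:0, fod:0.1, ... fod:2."""
    n = int(round((stop - start) / step)) + 1
    return [f"fod:{start + i * step:g}" for i in range(n)]
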