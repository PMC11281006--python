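"""Grünwald–Letnikov fractional-order derivatives of spectra.

The discrete G-L derivative of order ``alpha`` on a unit grid is a causal
convolution with the signed generalized binomial coefficients

    c_0 = 1,   c_k = c_{k-1} * (k - 1 - alpha) / k   (= (-1)^k C(alpha, k)),

so that d^a f(l) ~ sum_k c_k f(l - k).  Order 1 reduces to the backward
first difference, order 2 to the second difference, and order 0 to the
identity.  Orders compose: applying 0.5 twice equals applying 1 once
(the coefficient sequences convolve as the power series (1-z)^alpha).

The expanding-history policy keeps every available term back to the
first band (no padding); a fixed memory of ``m`` points truncates the
series, as some spectroscopy workflows prefer.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .errors import ConfigError
from .io import SpectraMatrix

__all__ = ["FodSettings", "gl_coefficients", "fod"]

_FOD_TAG = re.compile(r"^fod:([0-9.]+)$")


@dataclass(frozen=True)
class FodSettings:
    """Derivative order plus window policy.

    alpha : fractional order, >= 0 (0.1 .. 2.0 in typical scans).
    memory : None for the full expanding history, else a fixed number of
        series terms m >= 1.
    burn_in_nm : number of leading bands to flag as boundary-affected
        (informational; off by default because short-wavelength bands are
        routinely selected by the index search).
    """

    alpha: float
    memory: int | None = None
    burn_in_nm: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigError(f"alpha must be >= 0, got {self.alpha}")
        if self.memory is not None and self.memory < 1:
            raise ConfigError("fixed memory length must be >= 1")
        if self.burn_in_nm < 0:
            raise ConfigError("burn_in_nm must be >= 0")


def gl_coefficients(alpha: float, n_terms: int) -> np.ndarray:
    """First ``n_terms`` G-L convolution weights for order ``alpha``.

    Computed by the stable recurrence c_k = c_{k-1} (k - 1 - alpha)/k,
    which never evaluates the gamma function at its poles.  For integer
    alpha the sequence terminates: alpha=1 -> [1, -1, 0, ...],
    alpha=2 -> [1, -2, 1, 0, ...].
    """
    if alpha < 0:
        raise ConfigError(f"alpha must be >= 0, got {alpha}")
    if n_terms < 1:
        raise ConfigError("n_terms must be >= 1")
    c = np.empty(n_terms)
    c[0] = 1.0
    for k in range(1, n_terms):
        c[k] = c[k - 1] * (k - 1 - alpha) / k
    return c


def _combined_tag(tag: str, alpha: float) -> str:
    if tag == "reflectance":
        return f"fod:{alpha:g}"
    m = _FOD_TAG.match(tag)
    if m:  # orders add under the expanding-history policy
        return f"fod:{float(m.group(1)) + alpha:g}"
    return f"{tag}|fod:{alpha:g}"


def fod(
    spectra: SpectraMatrix,
    alpha: float | None = None,
    *,
    settings: FodSettings | None = None,
    memory: int | None = None,
) -> SpectraMatrix:
    """Fractional-order derivative of every spectrum in the matrix.

    Either pass ``alpha`` (and optionally ``memory``) directly or a
    ``FodSettings``.  Requires the 1-nm grid the container enforces, so
    the grid step Delta-lambda is 1 and wavelengths map 1:1 to series
    terms.  ``alpha=0`` returns the values unchanged (tag updated).
    """
    if settings is not None:
        alpha, memory = settings.alpha, settings.memory
    if alpha is None:
        raise ConfigError("fod() needs an order alpha")
    if alpha < 0:
        raise ConfigError(f"alpha must be >= 0, got {alpha}")
    n = spectra.n_bands
    tag = _combined_tag(spectra.transform_tag, alpha)
    if alpha == 0 and memory is None:
        return spectra.replace(values=spectra.values.copy(), transform_tag=tag)
    c = gl_coefficients(alpha, n)
    if memory is not None:
        c = c.copy()
        c[memory:] = 0.0
    # out[:, i] = sum_k c_k f[:, i-k]: multiply by the lower-triangular
    # Toeplitz operator T[i, j] = c[i-j].  Exact (no FFT round-off).
    T = toeplitz(c, np.zeros(n))
    values = spectra.values @ T.T
    return spectra.replace(values=values, transform_tag=tag)


def boundary_mask(n_bands: int, burn_in_nm: int) -> np.ndarray:
    """Boolean mask flagging the first ``burn_in_nm`` bands as boundary-affected."""
    mask = np.zeros(n_bands, dtype=bool)
    mask[: min(burn_in_nm, n_bands)] = True
    return mask
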