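"""Chlorophyll-fluorescence parameters from raw PAM readings.

A pulse-amplitude-modulation (PAM) protocol yields four fluorescence
levels per leaf: the dark-adapted minimum F0 and maximum Fm, and the
light-adapted steady state Fs and maximum F'm.  From these the module
derives

* PSII_max = (Fm - F0)/Fm, the maximum photochemical efficiency (Fv/Fm);
* NPQ = (Fm - F'm)/F'm, non-photochemical quenching;
* F'0 = F0 / (PSII_max + F0/F'm), the light-adapted minimum
  (Oxborough-Baker estimate);
* qL = (F'm - Fs)/(F'm - F'0) * F'0/Fs, the fraction of open PSII
  centres in the lake model;
* the rate-constant partitioning of absorbed excitation energy into
  photochemistry (KP), regulated heat dissipation (KN), fluorescence
  (KF = 0.05) and constitutive dissipation (KD, a temperature ramp with
  a floor), and the corresponding quantum yields
  Phi_X = K_X / (KP + KN + KF + KD), which sum to one exactly.

All operations accept scalars or aligned numpy arrays.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SpectraError

__all__ = [
    "KF_DEFAULT",
    "FluorescenceRecord",
    "ChlFParams",
    "psii_max",
    "npq",
    "f0_prime",
    "ql",
    "kd_constant",
    "quantum_yields",
    "derive_table",
    "validate_records",
    "describe_parameters",
    "PARAM_COLUMNS",
]

#: Rate constant of fluorescence emission (relative units).
KF_DEFAULT = 0.05

#: The six headline parameters, in reporting order.
PARAM_COLUMNS = ("psii_max", "npq", "ql", "phi_p", "phi_n", "phi_f")


@dataclass(frozen=True)
class FluorescenceRecord:
    """One leaf's raw PAM readings (relative fluorescence units, deg C)."""

    F0: float
    Fm: float
    Fs: float
    Fm_prime: float
    T_celsius: float = 25.0

    def validate(self) -> None:
        if not (0 < self.F0 < self.Fm):
            raise SpectraError(f"need 0 < F0 < Fm, got F0={self.F0}, Fm={self.Fm}")
        if not (0 < self.Fs < self.Fm_prime <= self.Fm):
            raise SpectraError(
                f"need 0 < Fs < F'm <= Fm, got Fs={self.Fs}, "
                f"F'm={self.Fm_prime}, Fm={self.Fm}"
            )


@dataclass(frozen=True)
class ChlFParams:
    """Derived parameters plus intermediates (scalars or aligned arrays)."""

    psii_max: np.ndarray | float
    npq: np.ndarray | float
    ql: np.ndarray | float
    phi_p: np.ndarray | float
    phi_n: np.ndarray | float
    phi_f: np.ndarray | float
    phi_d: np.ndarray | float
    f0_prime: np.ndarray | float
    kp: np.ndarray | float
    kn: np.ndarray | float
    kd: np.ndarray | float
    kf: float = KF_DEFAULT


def psii_max(F0, Fm):
    """Maximum photochemical efficiency (Fm - F0)/Fm."""
    F0, Fm = np.asarray(F0, float), np.asarray(Fm, float)
    if np.any(Fm <= 0):
        raise SpectraError("Fm must be positive")
    return (Fm - F0) / Fm


def npq(Fm, Fm_prime):
    """Non-photochemical quenching (Fm - F'm)/F'm."""
    Fm, Fm_prime = np.asarray(Fm, float), np.asarray(Fm_prime, float)
    if np.any(Fm_prime <= 0):
        raise SpectraError("F'm must be positive")
    return (Fm - Fm_prime) / Fm_prime


def f0_prime(F0, psii_max_value, Fm_prime):
    """Light-adapted minimum fluorescence, F0 / (Fv/Fm + F0/F'm).

    Satisfies the identity f0_prime = F0 when F'm = Fm.
    """
    F0 = np.asarray(F0, float)
    den = np.asarray(psii_max_value, float) + F0 / np.asarray(Fm_prime, float)
    if np.any(den <= 0):
        raise SpectraError("nonpositive denominator in F'0 estimate")
    return F0 / den


def ql(Fs, Fm_prime, f0_prime_value):
    """Fraction of open PSII centres, (F'm - Fs)/(F'm - F'0) * F'0/Fs.

    Values outside [0, 1] (possible with noisy readings) are clipped with
    a warning rather than silently.
    """
    Fs = np.asarray(Fs, float)
    Fm_prime = np.asarray(Fm_prime, float)
    f0p = np.asarray(f0_prime_value, float)
    if np.any(Fm_prime <= f0p):
        raise SpectraError("need F'm > F'0 for qL")
    if np.any(Fs <= 0):
        raise SpectraError("Fs must be positive")
    value = (Fm_prime - Fs) / (Fm_prime - f0p) * f0p / Fs
    out_of_range = (value < 0) | (value > 1)
    if np.any(out_of_range):
        warnings.warn(
            f"qL outside [0, 1] for {int(np.sum(out_of_range))} record(s); clipped",
            stacklevel=2,
        )
        value = np.clip(value, 0.0, 1.0)
    return value


def kd_constant(T_celsius, slope: float = 0.03, offset: float = 0.0773,
                floor: float = 0.87):
    """Constitutive heat-dissipation rate constant max(0.03*T + 0.0773, 0.87).

    Piecewise linear in leaf temperature with a floor; at 25 deg C the
    floor binds and the constant is 0.87.
    """
    T = np.asarray(T_celsius, float)
    if not np.all(np.isfinite(T)):
        raise SpectraError("leaf temperature must be finite")
    return np.maximum(slope * T + offset, floor)


def quantum_yields(
    F0, Fm, Fs, Fm_prime, T_celsius=25.0, kf: float = KF_DEFAULT
) -> ChlFParams:
    """Full rate-constant partitioning for one record or aligned arrays.

    KN = (Fm - F'm)/F'm * (KF + KD);  KP = (F'm - Fs)/Fs * (KF + KD + KN);
    yields are each constant over the total KP + KN + KF + KD, so
    Phi_P + Phi_N + Phi_F + Phi_D = 1 identically.
    """
    F0 = np.asarray(F0, float)
    Fm = np.asarray(Fm, float)
    Fs = np.asarray(Fs, float)
    Fm_prime = np.asarray(Fm_prime, float)
    psii = psii_max(F0, Fm)
    npq_v = npq(Fm, Fm_prime)
    f0p = f0_prime(F0, psii, Fm_prime)
    ql_v = ql(Fs, Fm_prime, f0p)
    kd = kd_constant(T_celsius)
    kn = npq_v * (kf + kd)
    kp = (Fm_prime - Fs) / Fs * (kf + kd + kn)
    total = kp + kn + kf + kd
    return ChlFParams(
        psii_max=psii, npq=npq_v, ql=ql_v,
        phi_p=kp / total, phi_n=kn / total, phi_f=kf / total, phi_d=kd / total,
        f0_prime=f0p, kp=kp, kn=kn, kd=kd, kf=kf,
    )


def validate_records(fluor: pd.DataFrame) -> None:
    """Check PAM ordering constraints per sample, reporting violators."""
    bad = ~(
        (fluor["F0"] > 0)
        & (fluor["F0"] < fluor["Fm"])
        & (fluor["Fs"] > 0)
        & (fluor["Fs"] < fluor["Fm_prime"])
        & (fluor["Fm_prime"] <= fluor["Fm"])
    )
    if bad.any():
        raise SpectraError(
            f"invalid PAM ordering for samples {fluor.index[bad][:5].tolist()} "
            "(need 0 < F0 < Fm and 0 < Fs < F'm <= Fm)"
        )


def derive_table(fluor: pd.DataFrame, kf: float = KF_DEFAULT) -> pd.DataFrame:
    """Per-sample parameter table from a raw fluorescence DataFrame.

    Input columns: F0, Fm, Fs, Fm_prime, T_celsius (index = sample_id).
    """
    validate_records(fluor)
    p = quantum_yields(
        fluor["F0"].to_numpy(), fluor["Fm"].to_numpy(),
        fluor["Fs"].to_numpy(), fluor["Fm_prime"].to_numpy(),
        fluor["T_celsius"].to_numpy() if "T_celsius" in fluor else 25.0,
        kf=kf,
    )
    return pd.DataFrame(
        {
            "psii_max": p.psii_max, "npq": p.npq, "ql": p.ql,
            "phi_p": p.phi_p, "phi_n": p.phi_n, "phi_f": p.phi_f,
            "phi_d": p.phi_d, "f0_prime": p.f0_prime,
            "kp": p.kp, "kn": p.kn, "kd": p.kd, "kf": p.kf,
        },
        index=fluor.index,
    )


def describe_parameters(
    params: pd.DataFrame, group, columns=PARAM_COLUMNS
) -> pd.DataFrame:
    """Descriptive statistics per leaf group and parameter.

    Returns mean, median, min, max, CV% (100 * sample sd / mean),
    skewness and excess kurtosis (moment definitions), indexed by
    (group, parameter).  Constant columns get CV 0 and NA shape
    statistics.
    """
    group = pd.Series(np.asarray(group, dtype=object), index=params.index)
    rows = []
    for g, sub in params.groupby(group, sort=True):
        if len(sub) < 3:
            raise ConfigError(f"group {g!r} has fewer than 3 samples")
        for col in columns:
            x = sub[col].to_numpy(float)
            sd = x.std(ddof=1)
            constant = sd == 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                skew = np.nan if constant else float(stats.skew(x, bias=True))
                kurt = np.nan if constant else float(stats.kurtosis(x, bias=True))
            rows.append(
                {
                    "group": g, "parameter": col,
                    "mean": x.mean(), "median": np.median(x),
                    "minimum": x.min(), "maximum": x.max(),
                    "cv_pct": 0.0 if x.mean() == 0 else 100.0 * sd / abs(x.mean()),
                    "skewness": skew, "kurtosis": kurt,
                }
            )
    return pd.DataFrame(rows).set_index(["group", "parameter"])
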