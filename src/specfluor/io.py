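"""Spectral matrices: the in-memory container plus CSV read/write/trim/average.

The container keeps reflectance (or transformed) spectra on a strict
integer 1-nm wavelength grid together with per-sample metadata
(species, leaf group).  All downstream stages operate on this object.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SpectraError

__all__ = [
    "SpectraMatrix",
    "read_spectra",
    "write_spectra",
    "read_fluorescence",
    "write_fluorescence",
    "trim_range",
    "average_replicates",
]

_WL_COL = re.compile(r"^[Rr]?(\d+)(?:\s*nm)?$")
_META_COLS = ("sample_id", "species", "group")


@dataclass
class SpectraMatrix:
    """Samples x wavelengths block of leaf spectra with metadata.

    Attributes
    ----------
    wavelengths : ndarray of int
        Ascending wavelength grid in nm, constant 1-nm step.
    values : ndarray, shape (n_samples, n_bands)
        Reflectance (in (0, 1)) or transformed values.
    sample_ids : ndarray of str
        Unique sample identifiers, one per row.
    species, group : ndarray of str or None
        Optional categorical metadata per sample; ``group`` is
        conventionally "shaded" or "sunlit".
    transform_tag : str
        Provenance label, e.g. ``"reflectance"``, ``"fod:0.9"``, ``"snv"``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sample_ids: np.ndarray
    species: np.ndarray | None = None
    group: np.ndarray | None = None
    transform_tag: str = "reflectance"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.species is not None:
            self.species = np.asarray(self.species, dtype=object)
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=object)
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        wl = self.wavelengths
        if wl.ndim != 1 or wl.size < 2:
            raise SpectraError("need at least two wavelengths")
        steps = np.diff(wl)
        if not np.all(steps == 1):
            bad = wl[:-1][steps != 1]
            raise SpectraError(
                f"wavelength grid must be ascending with a 1-nm step; "
                f"irregular steps after {bad[:5].tolist()}"
            )
        if self.values.ndim != 2 or self.values.shape[1] != wl.size:
            raise SpectraError(
                f"values shape {self.values.shape} does not match "
                f"{wl.size} wavelengths"
            )
        if self.sample_ids.shape != (self.values.shape[0],):
            raise SpectraError("sample_ids must align with value rows")
        uniq, counts = np.unique(self.sample_ids.astype(str), return_counts=True)
        if np.any(counts > 1):
            raise SpectraError(
                f"duplicate sample ids: {uniq[counts > 1][:5].tolist()}"
            )
        for name in ("species", "group"):
            meta = getattr(self, name)
            if meta is not None and meta.shape != (self.values.shape[0],):
                raise SpectraError(f"{name} must align with value rows")
        if self.transform_tag == "reflectance":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
                raise SpectraError(
                    "reflectance values must lie strictly in (0, 1); "
                    f"observed range [{finite.min():.4g}, {finite.max():.4g}]"
                )

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def band_index(self, wavelength_nm: int) -> int:
        """Exact position of a wavelength on the grid (no interpolation)."""
        lo = int(self.wavelengths[0])
        i = int(wavelength_nm) - lo
        if i < 0 or i >= self.n_bands or self.wavelengths[i] != wavelength_nm:
            raise SpectraError(f"wavelength {wavelength_nm} nm not on grid")
        return i

    def band(self, wavelength_nm: int) -> np.ndarray:
        """Column of values at one wavelength."""
        return self.values[:, self.band_index(wavelength_nm)]

    def replace(self, **kwargs) -> "SpectraMatrix":
        return _dc_replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: sample_id, species, group, R400 ... columns."""
        df = pd.DataFrame(
            self.values, columns=[f"R{w}" for w in self.wavelengths]
        )
        df.insert(0, "sample_id", self.sample_ids)
        if self.species is not None:
            df.insert(1, "species", self.species)
        if self.group is not None:
            df.insert(2 if self.species is not None else 1, "group", self.group)
        return df


def _parse_wavelength_columns(columns) -> dict[str, int]:
    out = {}
    for c in columns:
        if str(c).strip().lower() in _META_COLS:
            continue
        m = _WL_COL.match(str(c).strip())
        if m:
            out[c] = int(m.group(1))
    return out


def _check_contiguous(wl: np.ndarray) -> None:
    wl = np.sort(wl)
    missing = sorted(set(range(int(wl[0]), int(wl[-1]) + 1)) - set(wl.tolist()))
    if missing:
        shown = ", ".join(str(m) for m in missing[:10])
        raise SpectraError(
            f"wavelength grid has {len(missing)} missing band(s): {shown}"
        )


def read_spectra(
    path: str | Path,
    metadata_path: str | Path | None = None,
    transform_tag: str = "reflectance",
) -> SpectraMatrix:
    """Read a spectral CSV in wide or long layout.

    Wide layout: one row per sample, wavelength columns named ``R400``,
    ``400`` or ``400nm``, optional ``sample_id``/``species``/``group``
    columns.  Long layout: columns ``sample_id`` (or ``sample``),
    ``wavelength``, ``value``.  A separate metadata CSV with
    ``sample_id, species, group`` may be joined on.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    lower = {str(c).strip().lower(): c for c in df.columns}
    if "wavelength" in lower:  # long layout
        sample_col = lower.get("sample_id", lower.get("sample"))
        value_col = lower.get("value", lower.get("reflectance"))
        if sample_col is None or value_col is None:
            raise SpectraError(
                "long layout needs sample_id/sample, wavelength and value columns"
            )
        wide = df.pivot_table(
            index=sample_col, columns=lower["wavelength"], values=value_col,
            sort=False,
        )
        wide = wide.reindex(sorted(wide.columns), axis=1)
        wl = np.asarray(wide.columns, dtype=int)
        _check_contiguous(wl)
        values = wide.to_numpy(dtype=float)
        sample_ids = wide.index.to_numpy(dtype=object)
        species = group = None
    else:  # wide layout
        wl_map = _parse_wavelength_columns(df.columns)
        if not wl_map:
            raise SpectraError(f"no wavelength columns recognised in {path}")
        cols = sorted(wl_map, key=wl_map.get)
        wl = np.array([wl_map[c] for c in cols], dtype=int)
        _check_contiguous(wl)
        block = df[cols].apply(pd.to_numeric, errors="coerce")
        bad = block.isna() & df[cols].notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise SpectraError(
                f"non-numeric cell at row {r}, column {cols[c]!r}"
            )
        if block.isna().to_numpy().any():
            r, c = np.argwhere(block.isna().to_numpy())[0]
            raise SpectraError(f"missing value at row {r}, column {cols[c]!r}")
        values = block.to_numpy(dtype=float)
        if "sample_id" in lower:
            sample_ids = df[lower["sample_id"]].to_numpy(dtype=object)
        else:
            sample_ids = np.array([f"s{i}" for i in range(len(df))], dtype=object)
        species = df[lower["species"]].to_numpy(dtype=object) if "species" in lower else None
        group = df[lower["group"]].to_numpy(dtype=object) if "group" in lower else None

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path).set_index("sample_id")
        meta = meta.reindex(np.asarray(sample_ids, dtype=meta.index.dtype))
        if meta.isna().all(axis=1).any():
            missing = meta.index[meta.isna().all(axis=1)][:5].tolist()
            raise SpectraError(f"metadata missing for samples {missing}")
        if "species" in meta:
            species = meta["species"].to_numpy(dtype=object)
        if "group" in meta:
            group = meta["group"].to_numpy(dtype=object)

    return SpectraMatrix(
        wavelengths=wl, values=values, sample_ids=sample_ids,
        species=species, group=group, transform_tag=transform_tag,
    )


def write_spectra(spectra: SpectraMatrix, path: str | Path) -> None:
    """Write the wide CSV layout (``sample_id, species, group, R400 ...``)."""
    # %.17g round-trips IEEE doubles exactly
    spectra.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_fluorescence(path: str | Path) -> pd.DataFrame:
    """Read raw PAM readings: sample_id, F0, Fm, Fs, Fm_prime, T_celsius."""
    df = pd.read_csv(path)
    required = {"sample_id", "F0", "Fm", "Fs", "Fm_prime"}
    missing = required - set(df.columns)
    if missing:
        raise SpectraError(f"fluorescence CSV missing columns {sorted(missing)}")
    if "T_celsius" not in df.columns:
        df["T_celsius"] = 25.0
    return df.set_index("sample_id")


def write_fluorescence(df: pd.DataFrame, path: str | Path) -> None:
    df.reset_index().to_csv(path, index=False)


def trim_range(
    spectra: SpectraMatrix, lo_nm: int = 400, hi_nm: int = 2400
) -> SpectraMatrix:
    """Restrict the spectral range, dropping detector-edge bands.

    Idempotent; errors if the requested window is empty or exceeds the
    measured range.
    """
    if lo_nm > hi_nm:
        raise SpectraError(f"invalid range: lo {lo_nm} > hi {hi_nm}")
    wl = spectra.wavelengths
    if lo_nm < wl[0] or hi_nm > wl[-1]:
        raise SpectraError(
            f"requested [{lo_nm}, {hi_nm}] exceeds measured "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    return spectra.replace(wavelengths=wl[keep], values=spectra.values[:, keep])


def average_replicates(spectra: SpectraMatrix, replicate_ids) -> SpectraMatrix:
    """Arithmetic mean over replicate measurements of the same leaf.

    `replicate_ids` is a sequence aligned with samples; rows sharing an id
    are averaged.  Species and group labels must agree within a replicate
    set.  Output order follows first appearance of each replicate id.
    """
    rep = np.asarray(replicate_ids, dtype=object)
    if rep.shape != (spectra.n_samples,):
        raise SpectraError("replicate_ids must align with samples")
    order = pd.unique(rep)
    rows, species, group = [], [], []
    for rid in order:
        mask = rep == rid
        rows.append(spectra.values[mask].mean(axis=0))
        for store, meta in ((species, spectra.species), (group, spectra.group)):
            if meta is None:
                continue
            labels = set(meta[mask].tolist())
            if len(labels) > 1:
                raise SpectraError(
                    f"replicate set {rid!r} mixes labels {sorted(labels)}"
                )
            store.append(labels.pop())
    return SpectraMatrix(
        wavelengths=spectra.wavelengths,
        values=np.vstack(rows),
        sample_ids=np.asarray(order, dtype=object),
        species=np.asarray(species, dtype=object) if spectra.species is not None else None,
        group=np.asarray(group, dtype=object) if spectra.group is not None else None,
        transform_tag=spectra.transform_tag,
    )
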