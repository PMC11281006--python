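"""End-to-end orchestration: simulate/load -> derive -> transform -> search -> evaluate.

One :class:`RunConfig` drives the whole workflow and every artifact is
written under a single output directory:

* ``chlf_params.csv``   per-sample derived fluorescence parameters
* ``descriptives.csv``  per-group summary statistics of those parameters
* ``empirical_panel.csv`` univariate screening of published indices
* ``search_results.csv`` best candidate per search cell (long table)
* ``winners.csv``       AIC-overall winner per (group, parameter)
* ``mlr_reports/``      bootstrap regression reports (JSON) + predictions CSV
* ``manifest.json``     config, seed, package version, stage timings
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chlf import PARAM_COLUMNS, derive_table, describe_parameters
from .errors import ConfigError
from .evaluation import bootstrap_train, evaluate_empirical_panel
from .indices import ALL_INDEX_TYPES, IndexSpec
from .io import read_fluorescence, read_spectra, trim_range, write_spectra
from .search import SearchGrid, search_matrix, overall_winners
from .synthetic import SyntheticConfig, generate_dataset
from .transforms import apply_transform, fod_tags

__all__ = ["RunConfig", "run"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    output_dir: str | Path = "specfluor_run"
    # either paths to measured data ...
    spectra_path: str | Path | None = None
    fluorescence_path: str | Path | None = None
    metadata_path: str | Path | None = None
    # ... or a synthetic configuration
    synthetic: SyntheticConfig | None = None
    transforms: tuple[str, ...] = tuple(fod_tags()) + ("log", "snv", "msc", "emsc")
    index_types: tuple[str, ...] = ALL_INDEX_TYPES
    grid_step_nm: int = 10
    bootstrap_n: int = 1000
    seed: int = 0
    trim_lo_nm: int = 400
    trim_hi_nm: int = 2400

    def validate(self) -> None:
        from_files = self.spectra_path is not None
        if from_files == (self.synthetic is not None):
            raise ConfigError(
                "configure exactly one input: spectra/fluorescence paths or "
                "a synthetic block"
            )
        if from_files and self.fluorescence_path is None:
            raise ConfigError("measured runs need a fluorescence CSV")
        for p in (self.spectra_path, self.fluorescence_path, self.metadata_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not self.transforms:
            raise ConfigError("transform list must not be empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            if "species_labels" in syn:
                syn["species_labels"] = tuple(syn["species_labels"])
            raw["synthetic"] = SyntheticConfig(**syn)
        for key in ("transforms", "index_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, Path):
        return str(o)
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def run(config: RunConfig) -> dict:
    """Execute the workflow; returns the manifest dictionary."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "mlr_reports").mkdir(exist_ok=True)
    timings: dict[str, float] = {}
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
    }

    def stage(name):
        t0 = time.perf_counter()

        def done():
            timings[name] = round(time.perf_counter() - t0, 3)
            log.info("stage %s finished in %.2fs", name, timings[name])

        return done

    # -- input ---------------------------------------------------------
    end = stage("input")
    if config.synthetic is not None:
        syn = config.synthetic.replace(seed=config.seed)
        spectra, fluor = generate_dataset(syn)
        write_spectra(spectra, out / "spectra.csv")
        fluor.reset_index().to_csv(out / "fluorescence.csv", index=False)
    else:
        spectra = read_spectra(config.spectra_path, config.metadata_path)
        fluor = read_fluorescence(config.fluorescence_path)
        fluor = fluor.reindex(np.asarray(spectra.sample_ids, dtype=fluor.index.dtype))
    spectra = trim_range(spectra, config.trim_lo_nm, config.trim_hi_nm)
    if spectra.group is None or spectra.species is None:
        raise ConfigError("spectra need species and group metadata")
    end()

    # -- derived parameters --------------------------------------------
    end = stage("chlf")
    params = derive_table(fluor)
    params.to_csv(out / "chlf_params.csv")
    describe_parameters(params, spectra.group).to_csv(out / "descriptives.csv")
    end()

    # -- empirical panel -----------------------------------------------
    end = stage("empirical")
    panel = evaluate_empirical_panel(spectra, params)
    panel.to_csv(out / "empirical_panel.csv", index=False)
    end()

    # -- transforms + exhaustive search --------------------------------
    end = stage("search")
    by_transform = {t: apply_transform(spectra, t) for t in config.transforms}
    grid = SearchGrid(step_nm=config.grid_step_nm)
    table = search_matrix(
        by_transform, params[list(PARAM_COLUMNS)], spectra.group,
        index_types=config.index_types, grid=grid,
    )
    table.to_csv(out / "search_results.csv", index=False)
    winners = overall_winners(table)
    winners.to_csv(out / "winners.csv", index=False)
    end()

    # -- species MLR + bootstrap per winner ----------------------------
    end = stage("mlr")
    predictions = []
    for _, row in winners.iterrows():
        g, param = row["group"], row["parameter"]
        sel = spectra.group == g
        spec = _row_to_spec(row)
        transformed = by_transform[row["transform"]]
        x_all = _index_values(transformed, spec)
        x, y = x_all[sel], params.loc[sel, param].to_numpy(float)
        keep = np.isfinite(x)
        report = bootstrap_train(
            x[keep], spectra.species[sel][keep], y[keep],
            n_boot=config.bootstrap_n, seed=config.seed,
        )
        payload = report.to_dict()
        payload["group"] = g
        payload["parameter"] = param
        payload["index_spec"] = str(spec)
        (out / "mlr_reports" / f"{g}_{param}.json").write_text(
            json.dumps(payload, indent=2, default=_json_default)
        )
        for sid, obs, pred in zip(
            spectra.sample_ids[sel][keep], y[keep], report.predictions
        ):
            predictions.append(
                {"group": g, "parameter": param, "sample_id": sid,
                 "observed": obs, "predicted": pred}
            )
    pd.DataFrame(predictions).to_csv(out / "predictions.csv", index=False)
    end()

    manifest["timings_s"] = timings
    manifest["n_samples"] = spectra.n_samples
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    return manifest


def _row_to_spec(row) -> IndexSpec:
    t = row["index_type"]
    second = None if pd.isna(row["lambda2_or_delta"]) else int(row["lambda2_or_delta"])
    if t == "R":
        return IndexSpec(t, int(row["lambda1"]), transform_tag=row["transform"])
    if t in ("SR", "D", "ND", "ID"):
        return IndexSpec(t, int(row["lambda1"]), lambda2_nm=second,
                         transform_tag=row["transform"])
    return IndexSpec(t, int(row["lambda1"]), delta_nm=second,
                     transform_tag=row["transform"])


def _index_values(transformed, spec) -> np.ndarray:
    from .indices import compute_index

    return compute_index(transformed, spec)
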