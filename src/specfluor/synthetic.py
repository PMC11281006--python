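"""Synthetic leaf spectra and PAM fluorescence with known structure.

The generator emulates the statistical shape of a two-group (shaded /
sunlit), six-species leaf dataset:

* reflectance on the 1-nm grid 400-2400 nm, built as a smooth continuum
  attenuated by Gaussian absorption features at pigment (~430, 460,
  670 nm), carotenoid (~490 nm), water (~1200, 1450, 1940 nm) and
  dry-matter (~1720, 2100, 2300 nm) wavelengths, with per-sample latent
  traits (chlorophyll, carotenoid, water, dry matter) scaling feature
  depths;
* raw PAM readings (F0, Fm, Fs, F'm, T) constructed by inverting the
  standard fluorescence relations from latent parameter draws, so the
  ordering constraints F0 < Fm and Fs < F'm <= Fm hold for every record
  and the derived parameters land in published physiological envelopes;
* optional *planted links*: local spectral perturbations at chosen bands
  plus a parameter latent defined as an affine function of a chosen
  spectral index, giving downstream search and regression stages a known
  ground truth to recover.

Everything is driven by one root seed; independent streams are derived
for traits, measurement noise, fluorescence draws and planted bumps, so
the same configuration reproduces bit-identical output.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, PlantingError
from .indices import IndexSpec, compute_index
from .io import SpectraMatrix
from .transforms import apply_transform

__all__ = [
    "PlantedLink",
    "SyntheticConfig",
    "generate_spectra",
    "generate_fluorescence",
    "generate_dataset",
    "plant_relationship",
    "calibrate_link",
]

_WL = np.arange(400, 2401)

#: Gaussian absorption features: (centre nm, width nm, depth) per trait.
_FEATURES = {
    "chlorophyll": ((430, 30, 1.6), (460, 35, 1.2), (670, 45, 2.2)),
    "carotenoid": ((490, 30, 1.0),),
    "water": ((1200, 60, 0.25), (1450, 45, 0.9), (1940, 70, 1.3)),
    "dry_matter": ((1720, 55, 0.35), (2100, 90, 0.5), (2300, 70, 0.45)),
}

_DEFAULT_TRAITS = {
    "shaded": {
        "chlorophyll": (1.15, 0.18), "carotenoid": (0.90, 0.15),
        "water": (1.00, 0.15), "dry_matter": (0.80, 0.12),
    },
    "sunlit": {
        "chlorophyll": (1.00, 0.15), "carotenoid": (1.10, 0.15),
        "water": (1.15, 0.15), "dry_matter": (1.15, 0.15),
    },
}

# Latent fluorescence-parameter draws: (mean, sd, lower, upper) truncated
# normals per leaf group, calibrated to published field envelopes for
# canopy-bottom vs canopy-top leaves.
_DEFAULT_FLUOR = {
    "shaded": {
        "psii_max": (0.77, 0.009, 0.75, 0.80),
        "npq": (0.96, 0.29, 0.49, 1.54),
        "ql": (0.30, 0.126, 0.08, 0.51),
    },
    "sunlit": {
        "psii_max": (0.79, 0.0096, 0.76, 0.82),
        "npq": (0.55, 0.24, 0.24, 1.22),
        "ql": (0.48, 0.09, 0.26, 0.74),
    },
}

# Additive species offsets on parameter latents, one per species slot.
_DEFAULT_SPECIES_EFFECTS = {
    "npq": tuple(np.linspace(-0.10, 0.10, 6)),
    "ql": tuple(np.linspace(-0.05, 0.05, 6)),
}

_HARD_BOUNDS = {"psii_max": (1e-3, 1 - 1e-3), "npq": (0.0, 10.0), "ql": (1e-6, 1.0)}


@dataclass(frozen=True)
class PlantedLink:
    """A known index -> parameter relationship to inject.

    ``target`` names the latent parameter ("psii_max", "npq" or "ql");
    the parameter latent becomes ``slope * index + intercept + noise``,
    where the index is computed on the configured transform of the
    generated spectra.  ``bump_scale`` is the relative (multiplicative)
    amplitude SD of the narrow Gaussian perturbations injected at the
    link's bands, and ``bump_sigma_nm`` their width.
    """

    target: str
    index: IndexSpec
    slope: float
    intercept: float
    noise_sd: float = 0.0
    bump_scale: float = 0.15
    bump_sigma_nm: float = 4.0

    def __post_init__(self) -> None:
        if self.target not in _HARD_BOUNDS:
            raise ConfigError(
                f"planted target must be one of {sorted(_HARD_BOUNDS)}"
            )
        if self.noise_sd < 0 or self.bump_scale < 0 or self.bump_sigma_nm <= 0:
            raise ConfigError("link noise/bump parameters must be nonnegative")

    def bands(self) -> tuple[int, ...]:
        s = self.index
        if s.index_type == "R":
            return (s.lambda1_nm,)
        if s.lambda2_nm is not None:
            return (s.lambda1_nm, s.lambda2_nm)
        d = s.delta_nm
        return (s.lambda1_nm - d, s.lambda1_nm, s.lambda1_nm + d)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated field campaign: 189 leaves, six
    species, roughly equal shaded/sunlit split, 1-nm spectra over
    400-2400 nm with mild additive sensor noise, leaf temperature
    25 degC during light adaptation.
    """

    n_samples: int = 189
    species_labels: tuple[str, ...] = tuple(f"species_{i}" for i in range(1, 7))
    group_fractions: dict = field(
        default_factory=lambda: {"shaded": 0.5, "sunlit": 0.5}
    )
    trait_distributions: dict = field(default_factory=lambda: _DEFAULT_TRAITS)
    fluor_distributions: dict = field(default_factory=lambda: _DEFAULT_FLUOR)
    species_effects: dict = field(
        default_factory=lambda: _DEFAULT_SPECIES_EFFECTS
    )
    species_trait_scale: float = 0.04
    planted_links: tuple[PlantedLink, ...] = ()
    noise_sd_reflectance: float = 0.002
    t_celsius: float = 25.0
    fm_mean: float = 1.0
    fm_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        fracs = list(self.group_fractions.values())
        if any(f < 0 or f > 1 for f in fracs) or abs(sum(fracs) - 1) > 1e-9:
            raise ConfigError("group fractions must lie in [0,1] and sum to 1")
        if self.noise_sd_reflectance < 0:
            raise ConfigError("noise SD must be >= 0")
        for g, traits in self.trait_distributions.items():
            for t, (mean, sd) in traits.items():
                if sd < 0:
                    raise ConfigError(f"trait SD for {g}/{t} must be >= 0")
                if mean <= 0:
                    raise ConfigError(f"trait mean for {g}/{t} must be > 0")
        for g, params in self.fluor_distributions.items():
            for p, (mean, sd, lo, hi) in params.items():
                if sd < 0 or lo >= hi:
                    raise ConfigError(f"bad latent distribution for {g}/{p}")
        if self.fm_sd < 0 or self.fm_mean <= 0:
            raise ConfigError("Fm scale must be positive with nonnegative SD")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("traits", "noise", "fluor", "fm", "links")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _assign_metadata(config: SyntheticConfig):
    """Deterministic group and species assignment per sample index."""
    groups_sorted = sorted(config.group_fractions)
    counts = {}
    remaining = config.n_samples
    for i, g in enumerate(groups_sorted):
        if i == len(groups_sorted) - 1:
            counts[g] = remaining
        else:
            counts[g] = int(round(config.group_fractions[g] * config.n_samples))
            remaining -= counts[g]
    group = np.concatenate(
        [np.full(counts[g], g, dtype=object) for g in groups_sorted]
    )
    ns = len(config.species_labels)
    species = np.array(
        [config.species_labels[i % ns] for i in range(config.n_samples)],
        dtype=object,
    )
    return group, species


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_spectra(config: SyntheticConfig) -> SpectraMatrix:
    """Leaf reflectance spectra with metadata (and planted bumps, if any)."""
    rngs = _streams(config.seed)
    group, species = _assign_metadata(config)
    n = config.n_samples

    traits = {}
    for t in ("chlorophyll", "carotenoid", "water", "dry_matter"):
        x = np.empty(n)
        for g in pd.unique(group):
            mean, sd = config.trait_distributions[g][t]
            sel = group == g
            x[sel] = _truncnorm(rngs["traits"], mean, sd, 0.05, np.inf, int(sel.sum()))
        traits[t] = x

    # small species-specific multiplicative trait offsets
    ns = len(config.species_labels)
    eff = np.linspace(-1.0, 1.0, ns) * config.species_trait_scale
    sp_index = np.array(
        [config.species_labels.index(s) for s in species]
    )
    for t in traits:
        traits[t] = traits[t] * (1.0 + eff[sp_index])

    absorbance = np.tile(0.15 + 0.25 * (_WL - 400) / 2000.0, (n, 1))
    for t, features in _FEATURES.items():
        for centre, width, depth in features:
            shape = np.exp(-0.5 * ((_WL - centre) / width) ** 2)
            absorbance += depth * np.outer(traits[t], shape)
    values = 0.02 + 0.50 * np.exp(-absorbance)

    if config.noise_sd_reflectance > 0:
        values = values + rngs["noise"].normal(
            0.0, config.noise_sd_reflectance, size=values.shape
        )

    spectra = SpectraMatrix(
        wavelengths=_WL,
        values=values,
        sample_ids=np.array([f"s{i:04d}" for i in range(n)], dtype=object),
        species=species,
        group=group,
        transform_tag="reflectance",
    )
    for link in config.planted_links:
        spectra = plant_relationship(spectra, link, rng=rngs["links"])
    return spectra


def plant_relationship(
    spectra: SpectraMatrix,
    link: PlantedLink,
    rng: np.random.Generator | None = None,
) -> SpectraMatrix:
    """Inject narrow multiplicative Gaussian bumps at the link's bands.

    Per sample and band an amplitude ``a ~ N(0, bump_scale)`` scales the
    reflectance locally by ``1 + a * exp(-(wl - band)^2 / 2 sigma^2)``,
    giving the link's index independent sample-to-sample variation while
    leaving the spectrum untouched more than a few bump widths away.
    Raises rather than clipping if the perturbation would leave (0, 1).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    wl = spectra.wavelengths.astype(float)
    values = spectra.values.copy()
    for band in link.bands():
        spectra.band_index(band)  # validates the band is on the grid
        amp = rng.normal(0.0, link.bump_scale, size=spectra.n_samples)
        shape = np.exp(-0.5 * ((wl - band) / link.bump_sigma_nm) ** 2)
        values *= 1.0 + np.outer(amp, shape)
    if values.min() <= 0.0 or values.max() >= 1.0:
        raise PlantingError(
            f"planted bumps at {link.bands()} push reflectance outside (0, 1); "
            "reduce bump_scale"
        )
    return spectra.replace(values=values)


def _planted_latents(spectra: SpectraMatrix, config: SyntheticConfig, rng):
    """target -> latent vector from each planted link, in link order."""
    out = {}
    for link in config.planted_links:
        transformed = apply_transform(spectra, link.index.transform_tag)
        idx = compute_index(transformed, link.index)
        if not np.all(np.isfinite(idx)):
            raise PlantingError(
                f"planted index {link.index} is undefined for "
                f"{int(np.sum(~np.isfinite(idx)))} sample(s)"
            )
        latent = link.slope * idx + link.intercept
        if link.noise_sd > 0:
            latent = latent + rng.normal(0.0, link.noise_sd, size=latent.shape)
        lo, hi = _HARD_BOUNDS[link.target]
        if latent.min() < lo or latent.max() > hi:
            raise ConfigError(
                f"planted {link.target} latent leaves [{lo}, {hi}] "
                f"(range [{latent.min():.3g}, {latent.max():.3g}]); "
                "rescale slope/intercept or reduce noise"
            )
        out[link.target] = latent
    return out


def generate_fluorescence(
    spectra: SpectraMatrix, config: SyntheticConfig
) -> pd.DataFrame:
    """Raw PAM readings whose derived parameters match the latent draws.

    Latent PSII_max, NPQ and qL are drawn per leaf group (truncated
    normals), shifted by additive species offsets, then inverted exactly:

        F0  = Fm (1 - PSII_max),         F'm = Fm / (1 + NPQ),
        F'0 = F0 / (PSII_max + F0/F'm),  Fs  = F'm F'0 / (qL (F'm - F'0) + F'0),

    so re-deriving the parameters from the returned readings reproduces
    the latents to machine precision.  Planted links override the latent
    of their target parameter.
    """
    rngs = _streams(config.seed)
    n = spectra.n_samples
    group = spectra.group
    species = spectra.species
    if group is None or species is None:
        raise ConfigError("spectra must carry group and species metadata")

    latents = {}
    for p in ("psii_max", "npq", "ql"):
        x = np.empty(n)
        for g in pd.unique(group):
            mean, sd, lo, hi = config.fluor_distributions[g][p]
            sel = group == g
            x[sel] = _truncnorm(rngs["fluor"], mean, sd, lo, hi, int(sel.sum()))
        if p in config.species_effects:
            offsets = np.asarray(config.species_effects[p], float)
            sp_index = np.array(
                [config.species_labels.index(s) for s in species]
            )
            x = x + offsets[sp_index]
            # keep offset latents inside each group's stated envelope
            for g in pd.unique(group):
                _, _, lo, hi = config.fluor_distributions[g][p]
                sel = group == g
                x[sel] = np.clip(x[sel], lo, hi)
        latents[p] = x

    latents.update(_planted_latents(spectra, config, rngs["fluor"]))

    fm = _truncnorm(rngs["fm"], config.fm_mean, config.fm_sd,
                    0.5 * config.fm_mean, 1.5 * config.fm_mean, n)
    psii, npq_l, ql_l = latents["psii_max"], latents["npq"], latents["ql"]
    f0 = fm * (1.0 - psii)
    fm_prime = fm / (1.0 + npq_l)
    f0_prime = f0 / (psii + f0 / fm_prime)
    fs = fm_prime * f0_prime / (ql_l * (fm_prime - f0_prime) + f0_prime)
    fluor = pd.DataFrame(
        {
            "F0": f0, "Fm": fm, "Fs": fs, "Fm_prime": fm_prime,
            "T_celsius": np.full(n, config.t_celsius),
        },
        index=pd.Index(spectra.sample_ids, name="sample_id"),
    )
    return fluor


def generate_dataset(config: SyntheticConfig):
    """Spectra plus matching fluorescence records in one call."""
    spectra = generate_spectra(config)
    fluor = generate_fluorescence(spectra, config)
    return spectra, fluor


# comfortable working ranges per plantable parameter (inside _HARD_BOUNDS)
_SAFE_RANGE = {"psii_max": (0.05, 0.95), "npq": (0.02, 5.0), "ql": (0.02, 0.98)}


def calibrate_link(
    config: SyntheticConfig,
    index_spec: IndexSpec,
    target: str,
    target_mean: float,
    target_sd: float,
    r_squared: float = 1.0,
    bump_scale: float = 0.15,
    bump_sigma_nm: float = 4.0,
) -> PlantedLink:
    """Build a planted link mapping the realised index onto a parameter scale.

    Generates the spectra once (with provisional unit-slope bumps under
    the same seed, so the bump draws match the final run), measures the
    realised index distribution, and chooses slope/intercept so the
    noiseless latent has roughly the requested mean and SD.  Ratio
    indices on derivative spectra can be heavy-tailed; the slope is then
    shrunk just enough that every latent (with a 4.5-sigma noise margin)
    stays inside the parameter's physiological range -- an affine
    rescaling, so the planted linear relationship and its R^2 are
    unaffected.  ``r_squared < 1`` adds Gaussian noise sized so the
    planted relationship explains the requested fraction of the latent
    variance.
    """
    if not 0 < r_squared <= 1:
        raise ConfigError("r_squared must be in (0, 1]")
    probe = PlantedLink(target, index_spec, 1.0, 0.0, 0.0,
                        bump_scale=bump_scale, bump_sigma_nm=bump_sigma_nm)
    base = config.replace(planted_links=(probe,))
    spectra = generate_spectra(base)
    transformed = apply_transform(spectra, index_spec.transform_tag)
    idx = compute_index(transformed, index_spec)
    if not np.all(np.isfinite(idx)):
        raise PlantingError(f"index {index_spec} undefined on probe spectra")
    mu, sd = float(np.mean(idx)), float(np.std(idx, ddof=1))
    if sd == 0:
        raise PlantingError(f"index {index_spec} has no variance to plant on")
    slope = target_sd / sd
    noise_factor = (
        0.0 if r_squared >= 1.0 else float(np.sqrt((1 - r_squared) / r_squared))
    )
    # shrink slope (and noise with it) until extremes + noise margin fit
    lo, hi = _SAFE_RANGE[target]
    for extreme in (float(idx.min()), float(idx.max())):
        span = slope * (extreme - mu) + np.sign(extreme - mu) * (
            4.5 * noise_factor * slope * sd
        )
        if target_mean + span > hi:
            slope *= (hi - target_mean) / span
        elif target_mean + span < lo:
            slope *= (lo - target_mean) / span
    intercept = target_mean - slope * mu
    noise_sd = noise_factor * slope * sd
    return PlantedLink(target, index_spec, slope, intercept, noise_sd,
                       bump_scale=bump_scale, bump_sigma_nm=bump_sigma_nm)
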