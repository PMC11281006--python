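import numpy as np
import pytest

from specfluor import chlf
from specfluor.errors import ConfigError
from specfluor.indices import IndexSpec, compute_index
from specfluor.synthetic import (
    PlantedLink,
    SyntheticConfig,
    calibrate_link,
    generate_dataset,
    generate_fluorescence,
    generate_spectra,
    plant_relationship,
)
from specfluor.transforms import apply_transform


class TestConfig:
    def test_defaults_valid(self):
        cfg = SyntheticConfig()
        assert cfg.n_samples == 189
        assert len(cfg.species_labels) == 6

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_samples=0),
            dict(group_fractions={"shaded": 0.7, "sunlit": 0.7}),
            dict(group_fractions={"shaded": -0.1, "sunlit": 1.1}),
            dict(noise_sd_reflectance=-0.01),
            dict(fm_mean=-1.0),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SyntheticConfig(**kwargs)

    def test_negative_trait_sd_rejected(self):
        traits = {
            g: {t: (m, -0.1) for t, (m, _) in d.items()}
            for g, d in SyntheticConfig().trait_distributions.items()
        }
        with pytest.raises(ConfigError):
            SyntheticConfig(trait_distributions=traits)


class TestSpectra:
    def test_bit_identical_under_seed(self):
        a = generate_spectra(SyntheticConfig(n_samples=12, seed=42))
        b = generate_spectra(SyntheticConfig(n_samples=12, seed=42))
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.species, b.species)

    def test_zero_trait_sd_gives_identical_spectra_within_species(self):
        cfg = SyntheticConfig(n_samples=12, seed=0, noise_sd_reflectance=0.0)
        traits = {
            g: {t: (m, 0.0) for t, (m, _) in d.items()}
            for g, d in cfg.trait_distributions.items()
        }
        sp = generate_spectra(cfg.replace(trait_distributions=traits))
        # same species + same group -> same latent traits -> same spectrum
        for g in ("shaded", "sunlit"):
            for s in set(sp.species):
                rows = sp.values[(sp.species == s) & (sp.group == g)]
                if len(rows) > 1:
                    np.testing.assert_allclose(rows, rows[0], atol=1e-15)

    def test_default_envelope_and_grid(self):
        sp = generate_spectra(SyntheticConfig(seed=5))
        assert sp.n_samples == 189 and sp.n_bands == 2001
        assert sp.wavelengths[0] == 400 and sp.wavelengths[-1] == 2400
        assert sp.values.min() > 0.0 and sp.values.max() < 1.0

    def test_spectra_are_smooth(self):
        sp = generate_spectra(SyntheticConfig(n_samples=30, seed=1))
        steps = np.abs(np.diff(sp.values, axis=1))
        assert steps.max() < 0.05

    def test_group_counts_follow_fractions(self):
        sp = generate_spectra(SyntheticConfig(n_samples=100, seed=2))
        assert int(np.sum(sp.group == "shaded")) == 50


class TestFluorescence:
    def test_ordering_constraints_every_record(self):
        _, fluor = generate_dataset(SyntheticConfig(seed=3))
        assert (fluor["F0"] > 0).all()
        assert (fluor["F0"] < fluor["Fm"]).all()
        assert (fluor["Fs"] < fluor["Fm_prime"]).all()
        assert (fluor["Fm_prime"] <= fluor["Fm"]).all()

    def test_derived_parameters_in_physiological_envelopes(self):
        spectra, fluor = generate_dataset(SyntheticConfig(seed=4))
        params = chlf.derive_table(fluor)
        assert params["psii_max"].between(0.70, 0.85).all()
        assert params["npq"].between(0.2, 1.6).all()
        assert params["ql"].between(0.05, 0.80).all()

    def test_shaded_psii_mean_matches_field_calibration(self):
        spectra, fluor = generate_dataset(SyntheticConfig(seed=6))
        params = chlf.derive_table(fluor)
        shaded = params.loc[np.asarray(spectra.group == "shaded"), "psii_max"]
        assert shaded.mean() == pytest.approx(0.77, abs=0.05)

    def test_group_npq_separation_reproduced(self):
        spectra, fluor = generate_dataset(SyntheticConfig(n_samples=160, seed=7))
        params = chlf.derive_table(fluor)
        npq = params["npq"]
        shaded = npq[np.asarray(spectra.group == "shaded")].mean()
        sunlit = npq[np.asarray(spectra.group == "sunlit")].mean()
        assert shaded == pytest.approx(0.96, abs=0.1)
        assert sunlit == pytest.approx(0.55, abs=0.1)
        assert shaded > sunlit

    def test_deterministic(self):
        a = generate_dataset(SyntheticConfig(n_samples=20, seed=8))[1]
        b = generate_dataset(SyntheticConfig(n_samples=20, seed=8))[1]
        assert a.equals(b)


class TestPlantedLinks:
    SPEC = IndexSpec("ND", 540, lambda2_nm=1660, transform_tag="fod:0.9")

    def test_noiseless_link_is_exact(self):
        cfg = SyntheticConfig(n_samples=60, seed=9)
        link = calibrate_link(cfg, self.SPEC, "ql", 0.4, 0.08, r_squared=1.0)
        spectra, fluor = generate_dataset(cfg.replace(planted_links=(link,)))
        params = chlf.derive_table(fluor)
        # recompute the index independently and compare
        idx = compute_index(apply_transform(spectra, "fod:0.9"), self.SPEC)
        expected = link.slope * idx + link.intercept
        np.testing.assert_allclose(params["ql"], expected, atol=1e-9)
        r = np.corrcoef(idx, params["ql"])[0, 1]
        assert abs(abs(r) - 1.0) < 1e-9

    def test_bump_locality(self):
        cfg = SyntheticConfig(n_samples=10, seed=10, noise_sd_reflectance=0.0)
        base = generate_spectra(cfg)
        link = PlantedLink(
            "ql", IndexSpec("D", 800, lambda2_nm=1200, transform_tag="reflectance"),
            1.0, 0.0,
        )
        planted = plant_relationship(base, link, rng=np.random.default_rng(0))
        delta = np.abs(planted.values - base.values)
        wl = base.wavelengths
        far = np.ones(wl.size, bool)
        for band in (800, 1200):
            far &= np.abs(wl - band) > 30
        assert delta[:, far].max() < 1e-6
        assert delta[:, ~far].max() > 1e-4  # the bumps are actually there

    def test_planted_r2_is_calibrated(self):
        """Monte-Carlo: construction noise tuned for R*^2 = 0.5 lands nearby."""
        spec = IndexSpec("D", 540, lambda2_nm=1660, transform_tag="fod:0.9")
        realised = []
        for seed in range(5):
            cfg = SyntheticConfig(n_samples=200, seed=30 + seed)
            link = calibrate_link(cfg, spec, "ql", 0.45, 0.06, r_squared=0.5)
            spectra, fluor = generate_dataset(cfg.replace(planted_links=(link,)))
            params = chlf.derive_table(fluor)
            idx = compute_index(apply_transform(spectra, "fod:0.9"), spec)
            realised.append(np.corrcoef(idx, params["ql"])[0, 1] ** 2)
        assert all(0.35 <= r2 <= 0.65 for r2 in realised)

    def test_unreachable_bump_raises(self):
        cfg = SyntheticConfig(n_samples=10, seed=11, noise_sd_reflectance=0.0)
        base = generate_spectra(cfg)
        link = PlantedLink(
            "ql", IndexSpec("R", 800, transform_tag="reflectance"),
            1.0, 0.0, bump_scale=3.0,
        )
        from specfluor.errors import PlantingError

        with pytest.raises(PlantingError):
            plant_relationship(base, link, rng=np.random.default_rng(1))

    def test_unknown_target_rejected(self):
        with pytest.raises(ConfigError):
            PlantedLink("phi_q", IndexSpec("R", 800), 1.0, 0.0)
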