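"""Cohort generator: CVs, truncation, independence, treatment transform."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coagsim.population import (
    DEFAULT_CV_PERCENT,
    FactorProfile,
    PopulationSpec,
    ProteinVariability,
    TreatmentIntensity,
    apply_treatment,
    default_population_spec,
    mean_profile,
    sample_multipliers,
    sample_population,
)


class TestDefaultSpec:
    def test_literature_cvs(self, network):
        spec = default_population_spec(network)
        expected = {
            "II": 11.95,
            "V": 31.88,
            "VII": 26.33,   # median of five published determinations
            "VIII": 31.165,  # median of two
            "IX": 33.11,
            "X": 25.07,
            "XI": 23.42,
            "ATIII": 18.35,
            "TFPI": 35.16,
        }
        assert {v.protein: v.cv_percent for v in spec.variabilities} == expected

    def test_means_are_network_defaults(self, network):
        spec = default_population_spec(network)
        for protein, mean in spec.mean_levels.items():
            if protein in network.index:
                assert mean == network.species[network.index[protein]].initial_nM
        assert spec.mean_levels["XI"] == 1.0  # inert nominal level

    def test_cv_bounds_enforced(self):
        with pytest.raises(ValueError):
            ProteinVariability("II", 100.0)
        with pytest.raises(ValueError):
            ProteinVariability("II", -1.0)


class TestSampling:
    def test_zero_cv_gives_mean_profiles(self, network):
        spec = default_population_spec(network, n_individuals=5, seed=0)
        spec = PopulationSpec(
            variabilities=tuple(
                ProteinVariability(v.protein, 0.0) for v in spec.variabilities
            ),
            mean_levels=spec.mean_levels,
            n_individuals=5,
            seed=0,
        )
        with pytest.warns(UserWarning, match="XI"):
            profiles = sample_population(spec, network)
        ref = mean_profile(spec, network)
        for p in profiles:
            assert p.levels_nM == ref.levels_nM

    def test_seed_reproducibility(self, network):
        spec = default_population_spec(network, n_individuals=20, seed=3)
        with pytest.warns(UserWarning):
            a = sample_population(spec, network)
            b = sample_population(spec, network)
            c = sample_population(
                default_population_spec(network, n_individuals=20, seed=4), network
            )
        assert all(x.levels_nM == y.levels_nM for x, y in zip(a, b))
        assert any(x.levels_nM != y.levels_nM for x, y in zip(a, c))

    def test_viia_shares_vii_multiplier(self, network):
        spec = default_population_spec(network, n_individuals=50, seed=1)
        with pytest.warns(UserWarning):
            profiles = sample_population(spec, network)
        viia_mean = network.species[network.index["VIIa"]].initial_nM
        for p in profiles:
            assert p.multipliers["VIIa"] == p.multipliers["VII"]
            assert p.levels_nM["VIIa"] == pytest.approx(
                viia_mean * p.multipliers["VII"]
            )

    def test_large_sample_recovers_cv_with_small_truncation_bias(self, network):
        # the generator must reproduce its own CVs: zero-truncation bias
        # stays small even at the largest literature CV
        spec = default_population_spec(network, n_individuals=50_000, seed=11)
        rng = np.random.default_rng(spec.seed)
        mult = sample_multipliers(spec, rng)
        proteins = spec.proteins
        for j, protein in enumerate(proteins):
            cv_in = spec.cv(protein)
            sample_cv = 100.0 * mult[:, j].std(ddof=1) / mult[:, j].mean()
            if protein == "II":  # low CV: truncation essentially never fires
                assert sample_cv == pytest.approx(cv_in, abs=0.3)
            # high-CV proteins lose a sliver of spread to zero-truncation
            assert sample_cv == pytest.approx(cv_in, rel=0.02), protein
            assert abs(mult[:, j].mean() - 1.0) < 0.005, protein

    def test_independence_across_proteins(self, network):
        spec = default_population_spec(network, n_individuals=50_000, seed=5)
        mult = sample_multipliers(spec, np.random.default_rng(spec.seed))
        corr = np.corrcoef(mult.T)
        off = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.abs(off).max() < 0.02

    def test_all_levels_strictly_positive(self, network):
        spec = default_population_spec(network, n_individuals=2000, seed=9)
        with pytest.warns(UserWarning):
            profiles = sample_population(spec, network)
        assert all(min(p.levels_nM.values()) > 0 for p in profiles)

    @settings(max_examples=25, deadline=None)
    @given(
        cv=st.floats(min_value=0.0, max_value=60.0, exclude_max=True),
        seed=st.integers(min_value=0, max_value=2**20),
    )
    def test_multipliers_positive_for_any_cv(self, cv, seed):
        spec = PopulationSpec(
            variabilities=(ProteinVariability("II", cv),),
            mean_levels={"II": 1400.0},
            n_individuals=200,
            seed=seed,
        )
        mult = sample_multipliers(spec, np.random.default_rng(seed))
        assert np.all(mult > 0.0)


class TestTreatment:
    def test_identity_at_full_fraction(self, network, small_spec):
        with pytest.warns(UserWarning):
            p = sample_population(small_spec, network)[0]
        assert apply_treatment(p, TreatmentIntensity(1.0)).levels_nM == p.levels_nM

    def test_scales_only_vitamin_k_factors(self):
        p = FactorProfile(
            0,
            {"II": 1400.0, "V": 20.0, "VII": 10.0, "VIIa": 0.1, "IX": 90.0, "X": 160.0},
            {},
        )
        t = apply_treatment(p, TreatmentIntensity(0.2))
        assert t.levels_nM["II"] == pytest.approx(280.0)
        assert t.levels_nM["VII"] == pytest.approx(2.0)
        assert t.levels_nM["VIIa"] == pytest.approx(0.02)
        assert t.levels_nM["V"] == 20.0
        assert p.levels_nM["II"] == 1400.0  # input untouched

    def test_cohort_sd_scales_linearly(self, network):
        spec = default_population_spec(network, n_individuals=400, seed=2)
        with pytest.warns(UserWarning):
            profiles = sample_population(spec, network)
        f = 0.2
        before = np.array([p.levels_nM["II"] for p in profiles])
        after = np.array(
            [apply_treatment(p, TreatmentIntensity(f)).levels_nM["II"] for p in profiles]
        )
        assert after.std() == pytest.approx(f * before.std(), rel=1e-12)

    def test_treatment_commutes_with_sampling(self, network, small_spec):
        # scaling sampled levels equals scaling the means first and
        # reusing the same multipliers
        with pytest.warns(UserWarning):
            profiles = sample_population(small_spec, network)
        f = 0.4
        for p in profiles:
            t = apply_treatment(p, TreatmentIntensity(f))
            for protein in ("II", "VII", "IX", "X"):
                scaled_mean = small_spec.mean_levels[protein] * f
                assert t.levels_nM[protein] == pytest.approx(
                    scaled_mean * p.multipliers[protein]
                )

    def test_intensity_bounds(self):
        with pytest.raises(ValueError):
            TreatmentIntensity(0.0)
        with pytest.raises(ValueError):
            TreatmentIntensity(1.2)


class TestInertFactorXI:
    def test_warning_names_xi(self, network, small_spec):
        with pytest.warns(UserWarning, match="XI"):
            sample_population(small_spec, network)

    def test_xi_has_no_kinetic_effect(self, network, conditions, default_profile):
        from coagsim.assay import simulate_clotting

        lo = dict(default_profile, XI=0.5)
        hi = dict(default_profile, XI=2.0)
        pt_lo = simulate_clotting(network, lo, conditions).prothrombin_time_s
        pt_hi = simulate_clotting(network, hi, conditions).prothrombin_time_s
        assert pt_lo == pt_hi


class TestSpecSerialization:
    def test_yaml_round_trip_is_lossless(self, network, tmp_path):
        from coagsim.population import load_population_spec, save_population_spec

        spec = default_population_spec(network, n_individuals=77, seed=13)
        path = tmp_path / "spec.yaml"
        save_population_spec(spec, path)
        assert load_population_spec(path) == spec
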