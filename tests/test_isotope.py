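"""Forward labeling model: distributions, natural abundance, convolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgng.errors import ConfigurationError, DomainError
from fgng.isotope import (
    GLUCOSE_PENTAACETATE_169,
    FragmentModel,
    IsotopologueDistribution,
    background_distribution,
    convolve,
    convolve_background,
    label_distribution,
    natural_abundance_m1,
)

_C_RATIO = 0.0107 / 0.9893  # 13C/12C from the pinned table


class TestLabelDistribution:
    @pytest.mark.parametrize("fgng_true", [0.0, 0.3, 1.0])
    def test_unlabeled_water_gives_point_mass(self, fgng_true):
        d = label_distribution(0.0, fgng_true, mode="binomial")
        assert d.probabilities[0] == pytest.approx(1.0, abs=1e-15)
        assert np.all(d.probabilities[1:] == pytest.approx(0.0, abs=1e-15))

    def test_binomial_m1_mass_fully_gluconeogenic(self):
        # single-deuteration mass of Binomial(6, 0.06): 6 * 0.06 * 0.94^5
        d = label_distribution(0.06, 1.0, mode="binomial")
        assert len(d) == 7
        assert d.probabilities[1] == pytest.approx(6 * 0.06 * 0.94**5, rel=1e-12)

    def test_linear_mode_ratio_is_f_n_p(self):
        d = label_distribution(0.06, 0.5, mode="linear")
        assert len(d) == 2
        assert d.ratio_m1_m0 == pytest.approx(0.5 * 6 * 0.06, rel=1e-12)

    @pytest.mark.parametrize(
        "p_water,fgng", [(-0.1, 0.5), (1.1, 0.5), (0.05, -0.01), (0.05, 1.5)]
    )
    def test_out_of_range_fractions_raise(self, p_water, fgng):
        with pytest.raises(DomainError):
            label_distribution(p_water, fgng)

    def test_unknown_mode_raises(self):
        with pytest.raises(DomainError):
            label_distribution(0.05, 0.5, mode="exact")

    @settings(deadline=None, derandomize=True)
    @given(
        p_water=st.floats(0.0, 1.0),
        fgng=st.floats(0.0, 1.0),
        mode=st.sampled_from(["linear", "binomial"]),
    )
    def test_always_a_valid_distribution(self, p_water, fgng, mode):
        d = label_distribution(p_water, fgng, mode=mode)
        p = d.probabilities
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12
        assert len(d) == (2 if mode == "linear" else 7)

    def test_ratio_strictly_increasing_in_both_arguments(self):
        # monotone in p_water over the physiological precursor range (below
        # 1/n_sites the single-label mass still grows with p); monotone in
        # the gluconeogenic fraction everywhere
        p_grid = np.linspace(0.005, 0.16, 25)
        f_grid = np.linspace(0.02, 0.98, 25)
        for f in (0.2, 0.6, 0.95):
            ratios = [
                label_distribution(p, f, mode="binomial").ratio_m1_m0 for p in p_grid
            ]
            assert np.all(np.diff(ratios) > 0)
        for p in (0.02, 0.06, 0.5):
            ratios = [
                label_distribution(p, f, mode="binomial").ratio_m1_m0 for f in f_grid
            ]
            assert np.all(np.diff(ratios) > 0)

    @pytest.mark.parametrize("p_water", [0.001, 0.005, 0.01])
    def test_linear_matches_binomial_at_small_enrichment(self, p_water):
        # fully gluconeogenic: gap is exactly p/(1-p), ~1% at p = 0.01
        lin = label_distribution(p_water, 1.0, mode="linear").ratio_m1_m0
        full = label_distribution(p_water, 1.0, mode="binomial").ratio_m1_m0
        assert abs(full / lin - 1) <= p_water / (1 - p_water) + 1e-12
        # mixtures: relative gap vanishes linearly in n * p_water
        for f in (0.3, 0.7):
            lin = label_distribution(p_water, f, mode="linear").ratio_m1_m0
            full = label_distribution(p_water, f, mode="binomial").ratio_m1_m0
            assert abs(full / lin - 1) <= 6 * p_water


class TestNaturalAbundance:
    def test_empty_composition_is_zero(self):
        assert natural_abundance_m1(GLUCOSE_PENTAACETATE_169) == 0.0

    def test_single_carbon_ratio(self):
        frag = FragmentModel(elemental_composition={"C": 1})
        assert natural_abundance_m1(frag) == pytest.approx(_C_RATIO, rel=1e-12)
        assert natural_abundance_m1(frag) == pytest.approx(0.01082, abs=5e-6)

    def test_multi_atom_ratio_matches_polynomial_expansion(self):
        # brute-force product of per-atom (light, heavy) polynomials
        frag = FragmentModel(elemental_composition={"C": 8, "H": 11, "O": 5})
        full = background_distribution(frag)
        assert natural_abundance_m1(frag) == pytest.approx(
            full.probabilities[1] / full.probabilities[0], rel=1e-10
        )
        # and the first-order sum is n_C contributions of the single-carbon ratio
        c8 = FragmentModel(elemental_composition={"C": 8})
        assert natural_abundance_m1(c8) == pytest.approx(8 * _C_RATIO, rel=1e-12)

    def test_unknown_element_raises(self):
        with pytest.raises(ConfigurationError):
            natural_abundance_m1(FragmentModel(elemental_composition={"Xx": 2}))


class TestConvolution:
    def test_point_mass_overlay_leaves_background_ratio(self):
        frag = FragmentModel(elemental_composition={"C": 6})
        point = IsotopologueDistribution(np.array([1.0]))
        out = convolve_background(point, frag)
        assert out.ratio_m1_m0 == pytest.approx(natural_abundance_m1(frag), rel=1e-10)

    def test_empty_composition_is_identity(self):
        labeled = label_distribution(0.06, 0.5, mode="binomial")
        out = convolve_background(labeled, GLUCOSE_PENTAACETATE_169)
        np.testing.assert_allclose(out.probabilities, labeled.probabilities)

    def test_hand_convolution(self):
        a = IsotopologueDistribution(np.array([0.9, 0.1]))
        b = IsotopologueDistribution(np.array([0.95, 0.05]))
        np.testing.assert_allclose(
            convolve(a, b).probabilities, [0.855, 0.14, 0.005], atol=1e-15
        )

    def test_matches_brute_force_double_sum(self, rng):
        for _ in range(20):
            a = rng.dirichlet(np.ones(rng.integers(1, 6)))
            b = rng.dirichlet(np.ones(rng.integers(1, 6)))
            expected = np.zeros(len(a) + len(b) - 1)
            for i, pa in enumerate(a):
                for j, pb in enumerate(b):
                    expected[i + j] += pa * pb
            out = convolve(
                IsotopologueDistribution(a / a.sum()),
                IsotopologueDistribution(b / b.sum()),
            )
            np.testing.assert_allclose(out.probabilities, expected, atol=1e-12)


class TestFragmentModel:
    @pytest.mark.parametrize(
        "kwargs",
        [{"n_sites": 0}, {"base_mz": 0}, {"elemental_composition": {"C": -1}}],
    )
    def test_invalid_models_raise(self, kwargs):
        with pytest.raises(ConfigurationError):
            FragmentModel(**kwargs)

    def test_invalid_distribution_raises(self):
        with pytest.raises(DomainError):
            IsotopologueDistribution(np.array([0.5, 0.4]))
        with pytest.raises(DomainError):
            IsotopologueDistribution(np.array([1.2, -0.2]))
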