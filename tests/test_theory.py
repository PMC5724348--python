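"""Closed-form length laws: exact values, normalization, shape properties."""

import math

import numpy as np
import pytest
from scipy.special import comb

from kpeakdist import theory
from kpeakdist.theory import ModelParams


class TestNegbinMatchPmf:
    def test_exact_values(self):
        assert theory.negbin_match_pmf(0, 0.5, 0) == pytest.approx(0.5)
        # C(5,2) * 0.25**3 * 0.75**3
        assert theory.negbin_match_pmf(5, 0.25, 2) == pytest.approx(0.06591796875, rel=1e-12)

    @pytest.mark.parametrize("p,k", [(0.25, 2), (0.5, 0), (0.7, 5), (0.9, 12)])
    def test_matches_direct_formula_and_normalizes(self, p, k):
        n = np.arange(k, k + 200)
        pmf = theory.negbin_match_pmf(n, p, k)
        direct = comb(n, k) * p ** (n - k) * (1 - p) ** (k + 1)
        np.testing.assert_allclose(pmf, direct, rtol=1e-9)
        full = theory.negbin_match_pmf(np.arange(k, k + 3000), p, k)
        assert full.sum() == pytest.approx(1.0, abs=1e-9)

    def test_below_support_is_zero(self):
        assert theory.negbin_match_pmf(1, 0.5, 3) == 0.0

    def test_invalid_match_prob_raises(self):
        with pytest.raises(ValueError):
            theory.negbin_match_pmf(5, 1.0, 2)


class TestExactLongestPmf:
    def test_normalizes(self):
        params = ModelParams(p=0.6, L=10_000, k=0)
        n = np.arange(0, params.L + 1)
        assert theory.exact_longest_pmf(n, params).sum() == pytest.approx(1.0, abs=1e-6)

    def test_no_homology_reduces_to_background_law(self):
        # p -> q: the law collapses to the pure background difference form
        q = 0.25
        params = ModelParams(p=q + 1e-10, L=5000, k=0, q=q)
        n = np.arange(1, 60)
        bg_cdf = lambda nn: (1 - q ** nn) ** (params.L - nn + 1.0)
        expected = bg_cdf(n + 1.0) - bg_cdf(n * 1.0)
        np.testing.assert_allclose(theory.exact_longest_pmf(n, params), expected, atol=1e-6)


class TestKmismatchLongestCdf:
    def test_boundaries(self):
        params = ModelParams(p=0.7, L=2000, k=3)
        assert theory.kmismatch_longest_cdf(3, params) == 0.0
        assert theory.kmismatch_longest_cdf(2001, params) == 1.0

    def test_monotone_nondecreasing(self):
        params = ModelParams(p=0.7, L=2000, k=3)
        n = np.arange(4, 500)
        cdf = theory.kmismatch_longest_cdf(n, params)
        assert np.all(np.diff(cdf) >= -1e-12)

    def test_pmf_normalizes(self):
        params = ModelParams(p=0.7, L=2000, k=3)
        n = np.arange(0, params.L)
        assert theory.kmismatch_longest_pmf(n, params).sum() == pytest.approx(1.0, abs=1e-6)


class TestTheorem1:
    def test_requires_k_at_least_one(self):
        with pytest.raises(ValueError):
            theory.theorem1_pmf(10, ModelParams(p=0.6, L=1000, k=0))

    def test_bimodal_components_at_operating_point(self):
        # expected counts for L=100 kb, p=0.6, k=20: background mode left of
        # the homologous mode, both components unimodal over the scan range
        params = ModelParams(p=0.6, L=100_000, k=20)
        m = np.arange(20, 120)
        hom, bg = theory.theorem1_pmf(m, params)
        m_hom = m[np.argmax(hom)]
        m_bg = m[np.argmax(bg)]
        assert m_bg < m_hom
        assert hom.max() > 0 and bg.max() > 0

    def test_total_is_component_sum_and_near_normalized(self):
        params = ModelParams(p=0.7, L=2000, k=5)
        spec = theory.theorem1_spectrum(params, lengths=np.arange(0, 400), expected_counts=False)
        np.testing.assert_allclose(spec.total, spec.homologous + spec.background, rtol=1e-12)
        # edge-effect truncation allowed; mass within 1e-6 over a generous range
        assert spec.total.sum() == pytest.approx(1.0, abs=1e-3)


class TestExtensionPmf:
    def test_mixture_normalizes(self):
        params = ModelParams(p=0.6, L=100_000, k=20)
        m = np.arange(0, 5000)
        hom, bg = theory.extension_pmf(m, params)
        assert (hom + bg).sum() == pytest.approx(1.0, abs=1e-9)

    def test_homologous_recursion(self):
        # H_k(m+1) = (m+1)/(m+1-k) * p * H_k(m), to machine precision
        params = ModelParams(p=0.5, L=500_000, k=10)
        m = np.arange(10, 200)
        hom, _ = theory.extension_pmf(m, params)
        lhs = hom[1:]
        rhs = (m[:-1] + 1) / (m[:-1] + 1 - params.k) * params.p * hom[:-1]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_components_unimodal(self):
        params = ModelParams(p=0.5, L=500_000, k=70)
        m = np.arange(70, 2000)
        hom, bg = theory.extension_pmf(m, params)
        for comp in (hom, bg):
            signs = np.sign(np.diff(comp))
            signs = signs[signs != 0]
            flips = np.count_nonzero(np.diff(signs))
            assert flips == 1

    def test_second_peak_needs_large_k(self):
        # small k: homologous maximum swallowed by the background peak;
        # large k: the expected spectrum shows a detectable second peak
        from kpeakdist.spectrum import SmoothedSpectrum, find_second_peak

        for k, expect_found in ((10, False), (70, True)):
            params = ModelParams(p=0.5, L=500_000, k=k)
            spec = theory.extension_spectrum(params)
            call = find_second_peak(SmoothedSpectrum(spec.total, w=1))
            assert call.found is expect_found
            if expect_found:
                assert call.m_star == theory.peak_positions(params).m_H


class TestPeakPositions:
    def test_discussion_operating_point(self):
        params = ModelParams(p=0.5, L=500_000, k=90)
        pp = theory.peak_positions(params)
        assert pp.m_H == 179
        assert pp.m_B == 119

    def test_background_mode_brute_force(self):
        params = ModelParams(p=0.5, L=500_000, k=90)
        m = np.arange(90, 401)
        bg = theory.negbin_match_pmf(m, 0.25, 90)
        assert m[np.argmax(bg)] == theory.peak_positions(params).m_B == 119

    @pytest.mark.parametrize("k", [1, 2, 3, 5, 10, 20, 50])
    def test_formula_equals_brute_force_argmax(self, k):
        for p in np.arange(0.1, 0.95, 0.1):
            params = ModelParams(p=float(p), q=0.05, L=10_000, k=k)
            m = np.arange(k, k + 5 + int(20 * k / (1 - p)))
            hom = theory.negbin_match_pmf(m, float(p), k)
            # leftmost among near-ties: exact integer k/(1-p) gives an
            # analytic tie that float noise would otherwise decide
            brute = int(m[hom >= hom.max() * (1 - 1e-9)][0])
            assert brute == theory.peak_positions(params).m_H

    def test_degenerate_match_prob_raises(self):
        with pytest.raises(ValueError):
            theory.peak_positions(ModelParams(p=1.0, L=100, k=5))


class TestProbHomologous:
    def test_one_percent_at_figure_conditions(self):
        val = theory.prob_homologous(ModelParams(p=0.6, L=100_000, k=20))
        assert val == pytest.approx(0.01, abs=0.002)

    def test_monotone_in_p(self):
        vals = [
            theory.prob_homologous(ModelParams(p=p, L=100_000, k=20))
            for p in np.arange(0.3, 0.95, 0.05)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_limit_p_to_one(self):
        assert theory.prob_homologous(ModelParams(p=0.9999999, L=1000, k=2)) > 0.999


class TestJukesCantor:
    @pytest.mark.parametrize(
        "p_hat,expected,digits", [(0.5, 0.824, 3), (0.6, 0.57, 2), (1.0, 0.0, 6)]
    )
    def test_reference_values(self, p_hat, expected, digits):
        assert round(theory.jukes_cantor_distance(p_hat), digits) == pytest.approx(expected)

    def test_saturation_raises(self):
        with pytest.raises(theory.SaturationError):
            theory.jukes_cantor_distance(0.25)

    def test_roundtrip_with_inverse(self):
        for d in (0.0, 0.1, 0.5, 1.0, 2.0):
            p = theory.jukes_cantor_match_prob(d)
            assert theory.jukes_cantor_distance(p) == pytest.approx(d, abs=1e-12)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p=0.2, L=100, k=5),  # p below q
            dict(p=0.5, L=0, k=0),
            dict(p=0.5, L=100, k=100),
            dict(p=1.1, L=100, k=5),
        ],
    )
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_background_q_from_frequencies(self):
        assert theory.estimate_background_q([0.25] * 4, [0.25] * 4) == pytest.approx(0.25)
        assert theory.estimate_background_q([1, 0, 0, 0], [0, 1, 0, 0]) == 0.0
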