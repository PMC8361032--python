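"""Normalization, balancing, decay fitting, significance, DI, subtraction."""

import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from loopdom.contacts import (balance_matrix, call_significant_interactions,
                              directionality_index, fit_decay,
                              normalize_library_size, subtract_maps)
from loopdom.genomics import ContactMatrix
from loopdom.simulate import SimConfig, simulate_hic, PlantedLoop


def _symmetric(counts):
    return ContactMatrix("chr1", 10_000, counts)


def _power_law_matrix(n=300, c=50.0, alpha=1.0, bin_size=10_000):
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    counts = np.zeros((n, n))
    nz = dist > 0
    counts[nz] = c * dist[nz] ** (-alpha)
    return ContactMatrix("chr1", bin_size, counts)


class TestNormalize:
    def test_scales_to_target(self):
        mat = _symmetric(np.array([[0., 4.], [4., 0.]]))
        out = normalize_library_size(mat, 2.0)
        np.testing.assert_allclose(out.counts, [[0, 2], [2, 0]])
        assert out.total_contacts == pytest.approx(2.0)

    def test_identity_at_current_total(self):
        mat = _power_law_matrix(50)
        out = normalize_library_size(mat, mat.total_contacts)
        np.testing.assert_allclose(out.counts, mat.counts)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            normalize_library_size(_symmetric(np.zeros((3, 3))), 1.0)

    def test_common_target_equalizes_totals(self):
        a = _power_law_matrix(40, c=10)
        b = _power_law_matrix(40, c=33)
        na = normalize_library_size(a, 1e5)
        nb = normalize_library_size(b, 1e5)
        assert na.total_contacts == pytest.approx(nb.total_contacts)


class TestBalance:
    def test_already_balanced_unchanged(self, rng):
        n = 30
        # build a doubly-balanced symmetric matrix with a simple scaling loop
        a = rng.uniform(1, 2, (n, n))
        a = a + a.T
        for _ in range(500):
            s = a.sum(axis=1)
            d = np.sqrt(s / s.mean())
            a = a / np.outer(d, d)
        mat = _symmetric(a)
        out = balance_matrix(mat)
        np.testing.assert_allclose(out.counts, a, rtol=1e-4)

    def test_recovers_balanced_matrix_up_to_scale(self, rng):
        n = 30
        a = rng.uniform(1, 2, (n, n))
        a = a + a.T
        for _ in range(500):
            s = a.sum(axis=1)
            d = np.sqrt(s / s.mean())
            a = a / np.outer(d, d)
        dvec = rng.uniform(0.2, 5.0, n)
        perturbed = a * np.outer(dvec, dvec)
        out = balance_matrix(_symmetric(perturbed), max_iter=2000, tol=1e-10)
        ratio = out.counts / a
        assert np.nanstd(ratio) / np.nanmean(ratio) < 1e-4

    def test_zero_row_masked_and_symmetry_kept(self, rng):
        n = 20
        a = rng.uniform(1, 2, (n, n))
        a = a + a.T
        a[5, :] = 0
        a[:, 5] = 0
        out = balance_matrix(_symmetric(a))
        assert np.all(out.counts[5, :] == 0)
        np.testing.assert_allclose(out.counts, out.counts.T)
        sums = np.delete(out.counts.sum(axis=1), 5)
        assert np.ptp(sums) / sums.mean() < 1e-4


class TestFitDecay:
    def test_exact_power_law_matches_analytic(self):
        mat = _power_law_matrix(400, c=100.0)
        model = fit_decay(mat, n_strata=20)
        n = mat.n_bins
        total = mat.total_contacts
        phats = [s.p_hat for s in model.strata]
        assert all(a > b for a, b in zip(phats, phats[1:]))
        for s in model.strata:
            # analytic expected probability = stratum counts / (N * pairs)
            k_lo = max(int(np.ceil(s.d_lo / mat.bin_size)), 1)
            k_hi = int(np.ceil(s.d_hi / mat.bin_size))
            analytic = sum(100.0 * k ** -1.0 * (n - k)
                           for k in range(k_lo, k_hi)) / (total * s.n_pairs)
            assert s.p_hat == pytest.approx(analytic, rel=0.02)

    def test_uniform_matrix_gives_flat_probabilities(self):
        n = 300
        counts = np.ones((n, n)) - np.eye(n)
        model = fit_decay(ContactMatrix("chr1", 10_000, counts), n_strata=10)
        phats = {round(s.p_hat, 15) for s in model.strata}
        assert len(phats) == 1

    def test_strata_cover_range_without_gaps_and_respect_dmin(self):
        mat = _power_law_matrix(400)
        model = fit_decay(mat, n_strata=15, d_min=30_000, d_max=2_000_000)
        assert model.strata[0].d_lo == 30_000
        assert model.strata[-1].d_hi == 2_000_000
        for a, b in zip(model.strata, model.strata[1:]):
            assert a.d_hi == b.d_lo
        assert model.offsets().min() * mat.bin_size >= 30_000


class TestSignificance:
    def test_binomial_tail_agrees_with_summation_oracle(self, rng):
        from loopdom.contacts import _binomial_tail
        for _ in range(100):
            n = int(rng.integers(10, 10_000))
            p = float(rng.uniform(1e-5, 0.1))
            x = int(rng.integers(0, min(n, 30)))
            got = float(_binomial_tail(np.array([x]), n, np.array([p]))[0])
            ks = np.arange(x, n + 1)
            logpmf = (gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
                      + ks * np.log(p) + (n - ks) * np.log1p(-p))
            oracle = float(np.exp(logsumexp(logpmf)))
            assert got == pytest.approx(oracle, rel=1e-8, abs=1e-300)

    def test_expected_count_is_never_significant(self):
        cfg = SimConfig(seed=5, chrom_lengths=(("chr1", 6_000_000),),
                        background_depth=2e5)
        mats, _ = simulate_hic(cfg)
        mat = mats["chr1"]
        decay = fit_decay(mat, n_strata=30)
        sig = call_significant_interactions(mat, decay)
        assert len(sig) == 0

    def test_planted_loop_reaches_q_below_cutoff(self):
        loop = PlantedLoop("chr1", 100, 115, 10.0)
        cfg = SimConfig(seed=6, chrom_lengths=(("chr1", 6_000_000),),
                        background_depth=2e5, planted_loops=(loop,))
        mats, _ = simulate_hic(cfg)
        decay = fit_decay(mats["chr1"], n_strata=30)
        sig = call_significant_interactions(mats["chr1"], decay)
        hits = [s for s in sig
                if abs(s.bin_i - 100) <= 1 and abs(s.bin_j - 115) <= 1]
        assert hits and min(h.q_value for h in hits) < 0.01

    def test_observed_beyond_total_rejected(self):
        mat = _power_law_matrix(200)
        decay = fit_decay(mat, n_strata=10)
        bad = ContactMatrix("chr1", 10_000,
                            mat.counts + np.full_like(mat.counts, 1e9)
                            - np.diag(np.full(mat.n_bins, 1e9)))
        with pytest.raises(ValueError):
            call_significant_interactions(bad, decay)


class TestDirectionalityIndex:
    def test_symmetric_bin_is_zero(self):
        counts = np.full((11, 11), 2.0)
        np.fill_diagonal(counts, 0)
        di = directionality_index(_symmetric(counts), 3)
        assert di[5] == 0

    def test_hand_computed_value(self):
        # A = 0 upstream, B = 20 downstream -> E = 10, DI = +20
        n = 7
        counts = np.zeros((n, n))
        counts[3, 4] = counts[4, 3] = 20.0
        di = directionality_index(_symmetric(counts), 2)
        assert di[3] == pytest.approx(20.0)
        assert di[4] == pytest.approx(-20.0)

    def test_reflection_negates_di(self, rng):
        n = 40
        a = rng.poisson(3.0, (n, n)).astype(float)
        a = np.triu(a, 1) + np.triu(a, 1).T
        mat = _symmetric(a)
        ref = _symmetric(a[::-1, ::-1])
        di = directionality_index(mat, 5)
        di_ref = directionality_index(ref, 5)
        np.testing.assert_allclose(di_ref, -di[::-1])


class TestSubtractMaps:
    def test_self_subtraction_is_zero(self):
        mat = _power_law_matrix(50)
        np.testing.assert_allclose(subtract_maps(mat, mat), 0.0, atol=1e-12)

    def test_depth_scaling_cancels(self):
        a = _power_law_matrix(50)
        b = ContactMatrix("chr1", 10_000, 2 * a.counts)
        np.testing.assert_allclose(subtract_maps(a, b), 0.0, atol=1e-9)

    def test_planted_gain_is_positive_focal_difference(self):
        loop = PlantedLoop("chr1", 60, 80, 10.0)
        base = SimConfig(seed=9, chrom_lengths=(("chr1", 3_000_000),),
                         background_depth=2e5)
        gain = SimConfig(seed=9, chrom_lengths=(("chr1", 3_000_000),),
                         background_depth=2e5, planted_loops=(loop,))
        (mb, _), (mg, _) = simulate_hic(base), simulate_hic(gain)
        diff = subtract_maps(mg["chr1"], mb["chr1"])
        assert diff[60, 80] > 5 * np.abs(np.median(diff))

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            subtract_maps(_power_law_matrix(50), _power_law_matrix(40))
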