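"""Contact-matrix analytics: balancing, decay, compartments, domains,
site classification and pairwise aggregation."""

import numpy as np
import pytest

from smbridge.chromatin import (classify_sites, cluster_filter, compartment_e1,
                                fit_ps_slope, ice_normalize, insulation_tads,
                                pair_fold_change, paired_center_score_test,
                                pairwise_aggregate, ps_curve)
from smbridge.errors import EmptyInputError
from smbridge.genome import ContactMatrix, IntervalSet
from smbridge.simulate import ContactMapSpec, simulate_contact_map


def brute_force_ice(mat, n_iter=2000):
    """Oracle: plain iteration without any cleverness."""
    work = mat.astype(float).copy()
    for _ in range(n_iter):
        s = work.sum(axis=0)
        s = s / s.mean()
        work /= np.outer(s, s)
    return work / work.sum(axis=0).mean()


class TestIce:
    def test_symmetric_marginals_already_balanced(self):
        m = ContactMatrix("chr1", 10, np.array([[2.0, 1.0], [1.0, 2.0]]))
        out = ice_normalize(m)
        ratio = m.matrix / out.matrix
        assert np.allclose(ratio, ratio[0, 0])

    def test_converges_to_brute_force(self):
        m = ContactMatrix("chr1", 10, np.array([[4.0, 1.0], [1.0, 1.0]]))
        out = ice_normalize(m, max_iter=500, tol=1e-10)
        np.testing.assert_allclose(out.matrix, brute_force_ice(m.matrix),
                                   rtol=1e-6)
        s = out.matrix.sum(axis=0)
        assert s.std() / s.mean() < 1e-4

    def test_masked_bin_contract(self):
        mat = np.array([[4.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
        out = ice_normalize(ContactMatrix("chr1", 10, mat))
        assert np.isnan(out.bias[2])
        assert np.all(out.matrix[2] == 0)
        s = out.matrix.sum(axis=0)[:2]
        assert s.std() / s.mean() < 1e-4

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        raw = rng.poisson(20, (30, 30)).astype(float)
        raw = np.triu(raw) + np.triu(raw, 1).T
        out1 = ice_normalize(ContactMatrix("chr1", 10, raw), tol=1e-6)
        out2 = ice_normalize(out1, tol=1e-6)
        mask = ~np.isnan(out1.bias)
        np.testing.assert_allclose(out2.matrix[np.ix_(mask, mask)],
                                   out1.matrix[np.ix_(mask, mask)], rtol=1e-4)

    def test_all_zero_matrix(self):
        with pytest.raises(EmptyInputError):
            ice_normalize(ContactMatrix("chr1", 10, np.zeros((4, 4))))


class TestPsCurve:
    def test_planted_slope_recovered(self):
        spec = ContactMapSpec("chr1", 10_000_000, 25_000, ps_exponent=-1.0,
                              depth=5_000_000, seed=1)
        m, _ = simulate_contact_map(spec)
        s, P = ps_curve(m)
        slope = fit_ps_slope(s, P, s_range=(50_000, 500_000))
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_uniform_matrix_flat(self):
        m = ContactMatrix("chr1", 10_000, np.full((80, 80), 7.0))
        s, P = ps_curve(m)
        assert fit_ps_slope(s, P) == pytest.approx(0.0, abs=0.05)

    def test_depth_invariance(self):
        spec1 = ContactMapSpec("chr1", 5_000_000, 25_000, depth=2_000_000, seed=3)
        spec2 = ContactMapSpec("chr1", 5_000_000, 25_000, depth=8_000_000, seed=4)
        s1, P1 = ps_curve(simulate_contact_map(spec1)[0])
        s2, P2 = ps_curve(simulate_contact_map(spec2)[0])
        n = min(len(P1), len(P2))
        np.testing.assert_allclose(P1[:n], P2[:n], rtol=0.15)

    def test_too_small(self):
        with pytest.raises(ValueError):
            ps_curve(ContactMatrix("chr1", 10, np.ones((1, 1))))


def checkerboard_spec(seed=0, n_bins=200, block=10, fold=2.5):
    labels = np.where((np.arange(n_bins) // block) % 2 == 0, 1, -1)
    spec = ContactMapSpec("chr1", n_bins * 20_000, 20_000, ps_exponent=-1.0,
                          compartment_track=labels, compartment_fold=fold,
                          depth=4_000_000, seed=seed)
    return spec, labels


class TestCompartments:
    def test_planted_checkerboard_recovered(self):
        spec, labels = checkerboard_spec(seed=7)
        m, _ = simulate_contact_map(spec)
        bal = ice_normalize(m)
        track, saddle, _ = compartment_e1(bal, orient_track=labels.astype(float))
        sel = np.isfinite(track.values)
        r = np.corrcoef(track.values[sel], labels[sel])[0, 1]
        assert abs(r) >= 0.9
        # orientation is positive by construction
        assert r > 0
        # saddle corners: same-label (AA/BB) enriched over cross-label
        assert saddle[0, 0] > saddle[0, -1]
        assert saddle[-1, -1] > saddle[-1, 0]

    def test_sign_convention_follows_orientation(self):
        spec, labels = checkerboard_spec(seed=8)
        m, _ = simulate_contact_map(spec)
        bal = ice_normalize(m)
        t1, _, _ = compartment_e1(bal, orient_track=labels.astype(float))
        t2, _, _ = compartment_e1(bal, orient_track=-labels.astype(float))
        sel = np.isfinite(t1.values)
        np.testing.assert_allclose(t1.values[sel], -t2.values[sel], rtol=1e-9)

    def test_uniform_matrix_compartment_free(self):
        rng = np.random.default_rng(2)
        n = 300
        raw = rng.poisson(50, (n, n)).astype(float)
        raw = np.triu(raw) + np.triu(raw, 1).T
        m = ice_normalize(ContactMatrix("chr1", 20_000, raw))
        _, _, var = compartment_e1(m, orient_track=np.ones(n))
        assert var < 0.10


def tad_spec(boundaries, seed=0, n_bins=300, fold=3.0, depth=6_000_000):
    return ContactMapSpec("chr1", n_bins * 20_000, 20_000, ps_exponent=-1.0,
                          tad_boundaries=list(boundaries), tad_fold=fold,
                          depth=depth, seed=seed)


class TestInsulation:
    def test_single_shared_boundary_called(self):
        m, _ = simulate_contact_map(tad_spec([150], seed=5))
        bal = ice_normalize(m)
        _, bounds, _ = insulation_tads(bal)
        called = bounds.starts // 20_000
        assert len(called) == 1
        assert abs(int(called[0]) - 150) <= 1

    def test_uniform_matrix_no_boundaries(self):
        rng = np.random.default_rng(9)
        raw = rng.poisson(60, (300, 300)).astype(float)
        raw = np.triu(raw) + np.triu(raw, 1).T
        bal = ice_normalize(ContactMatrix("chr1", 20_000, raw))
        _, bounds, _ = insulation_tads(bal)
        assert len(bounds) == 0

    def test_strength_increases_with_contrast(self):
        strengths = []
        for fold in (1.5, 3.0, 6.0):
            m, _ = simulate_contact_map(
                tad_spec([100, 200], seed=11, fold=fold))
            bal = ice_normalize(m)
            _, _, s = insulation_tads(bal)
            strengths.append(s)
        assert strengths[0] < strengths[1] < strengths[2]

    def test_boundary_recovery_rate(self):
        # planted boundaries recovered within +-1 bin across random maps
        recovered = total = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            bounds = np.sort(rng.choice(np.arange(60, 241, 30), 3, replace=False))
            m, _ = simulate_contact_map(tad_spec(bounds, seed=seed, fold=3.0))
            bal = ice_normalize(m)
            _, called, _ = insulation_tads(bal)
            called_bins = called.starts // 20_000
            for b in bounds:
                total += 1
                if np.any(np.abs(called_bins - b) <= 1):
                    recovered += 1
        assert recovered / total >= 0.95

    def test_span_guard(self):
        with pytest.raises(ValueError):
            insulation_tads(ContactMatrix("chr1", 20_000, np.ones((50, 50))))


class TestSiteClassification:
    def test_one_bp_overlap_rule(self):
        a = IntervalSet.from_records([("chr1", 100, 200)])
        b = IntervalSet.from_records([("chr1", 199, 300)])
        out = classify_sites(a, b)
        assert len(out.shared) == 1 and len(out.a_only) == 0

    def test_half_open_adjacency_not_shared(self):
        a = IntervalSet.from_records([("chr1", 100, 200)])
        b = IntervalSet.from_records([("chr1", 200, 300)])
        out = classify_sites(a, b)
        assert len(out.shared) == 0 and len(out.a_only) == 1
        assert len(out.b_only) == 1

    def test_partition_accounting(self):
        rng = np.random.default_rng(4)
        recs_a = [("chr1", int(s), int(s) + 200)
                  for s in rng.integers(0, 1_000_000, 50)]
        recs_b = [("chr1", int(s), int(s) + 200)
                  for s in rng.integers(0, 1_000_000, 50)]
        a = IntervalSet.from_records(recs_a)
        b = IntervalSet.from_records(recs_b)
        out = classify_sites(a, b)
        assert len(out.a_only) + len(out.shared) == len(a)
        assert len(out.b_only) + len(out.shared_b) == len(b)

    def test_chromosomes_do_not_mix(self):
        a = IntervalSet.from_records([("chr1", 100, 200)])
        b = IntervalSet.from_records([("chr2", 100, 200)])
        assert len(classify_sites(a, b).shared) == 0

    def test_cluster_filter_counts_midpoints(self):
        peaks = IntervalSet.from_records([
            ("chr1", 1000, 1400), ("chr1", 9000, 9400), ("chr1", 20000, 20400),
            ("chr1", 30000, 30400)])
        bins = cluster_filter(peaks, resolution=25_000, min_peaks=2)
        assert bins.records() == [("chr1", 0, 25_000)]

    def test_malformed_interval(self):
        with pytest.raises(ValueError):
            IntervalSet.from_records([("chr1", 200, 100)])


def aggregation_map(anchor_fold=3.0, seed=0, n_bins=600, depth=30_000_000):
    anchors = list(range(60, 541, 48))  # well-separated anchor bins
    spec = ContactMapSpec("chr1", n_bins * 25_000, 25_000, ps_exponent=0.0,
                          anchor_bins=anchors, anchor_fold=anchor_fold,
                          depth=depth, seed=seed)
    return simulate_contact_map(spec)


class TestPairwiseAggregate:
    def test_uniform_matrix_flat_grid(self):
        m = ContactMatrix("chr1", 25_000, np.full((200, 200), 4.0))
        anchors = IntervalSet.from_records(
            [("chr1", b * 25_000, (b + 1) * 25_000) for b in (20, 80, 140, 180)])
        grid = pairwise_aggregate(m, anchors)
        np.testing.assert_allclose(grid.grid, 1.0, atol=1e-12)
        np.testing.assert_allclose(grid.center_scores, 1.0, atol=1e-12)

    def test_background_pair_count_is_400(self):
        m = ContactMatrix("chr1", 25_000, np.full((200, 200), 4.0))
        anchors = IntervalSet.from_records(
            [("chr1", b * 25_000, (b + 1) * 25_000) for b in (20, 120)])
        grid = pairwise_aggregate(m, anchors, flank=250_000, window=25_000)
        assert np.all(grid.background_pair_count == 400)

    def test_planted_enrichment_recovered(self):
        m, anchors = aggregation_map(anchor_fold=3.0, seed=6)
        bal = ice_normalize(m)
        grid = pairwise_aggregate(bal, anchors)
        center = grid.grid[grid.grid.shape[0] // 2, grid.grid.shape[1] // 2]
        assert center == pytest.approx(3.0, rel=0.10)
        F = grid.grid.shape[0] // 2
        flank_cells = grid.grid.copy()
        flank_cells[F, :] = np.nan  # anchor row/col keep planted signal
        flank_cells[:, F] = np.nan
        assert np.nanmax(np.abs(flank_cells - 1.0)) < 0.05

    def test_no_planted_signal_flat(self):
        m, anchors = aggregation_map(anchor_fold=1.0, seed=12)
        bal = ice_normalize(m)
        grid = pairwise_aggregate(bal, anchors)
        np.testing.assert_allclose(grid.grid, 1.0, atol=0.06)

    def test_scaling_invariance(self):
        m, anchors = aggregation_map(anchor_fold=2.0, seed=13)
        g1 = pairwise_aggregate(m, anchors)
        m2 = ContactMatrix(m.chrom, m.resolution, m.matrix * 7.5)
        g2 = pairwise_aggregate(m2, anchors)
        np.testing.assert_allclose(g1.grid, g2.grid, rtol=1e-12)

    def test_no_eligible_pairs(self):
        m = ContactMatrix("chr1", 25_000, np.full((60, 60), 2.0))
        anchors = IntervalSet.from_records([("chr1", 30 * 25_000, 31 * 25_000)])
        with pytest.raises(EmptyInputError):
            pairwise_aggregate(m, anchors)

    def test_off_binning_anchors_rejected(self):
        m = ContactMatrix("chr1", 25_000, np.full((100, 100), 2.0))
        anchors = IntervalSet.from_records([("chr1", 12_345, 37_345),
                                            ("chr1", 50_000, 75_000)])
        with pytest.raises(ValueError):
            pairwise_aggregate(m, anchors)


class TestFoldChange:
    def _matrix(self, value, n=40):
        # a faint far corner keeps the data-driven pseudocount negligible
        mat = np.full((n, n), float(value))
        mat[0, n - 1] = mat[n - 1, 0] = value * 1e-4
        return ContactMatrix("chr1", 25_000, mat)

    def test_identity_gives_zero(self):
        m = self._matrix(3.0)
        fc = pair_fold_change(m, m, [(5, 20), (10, 30)])
        np.testing.assert_allclose(fc, 0.0, atol=1e-12)

    def test_doubling_gives_one(self):
        fc = pair_fold_change(self._matrix(8.0), self._matrix(4.0), [(5, 20)])
        assert fc[0] == pytest.approx(1.0, abs=0.01)

    def test_binning_mismatch(self):
        with pytest.raises(ValueError):
            pair_fold_change(self._matrix(1.0, 40), self._matrix(1.0, 50), [(0, 1)])

    def test_paired_t_identity(self):
        out = paired_center_score_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out.statistic == 0.0 and out.pvalue == 1.0

    def test_paired_t_constant_difference_degenerate(self):
        out = paired_center_score_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert out.degenerate

    def test_paired_t_matches_textbook(self):
        rng = np.random.default_rng(5)
        a = rng.normal(1.0, 0.3, 12)
        b = rng.normal(0.8, 0.3, 12)
        out = paired_center_score_test(a, b)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out.statistic == pytest.approx(t_oracle, rel=1e-9)
        assert out.dof == 11
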