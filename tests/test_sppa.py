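import numpy as np
import pytest

import pointscape as ps
from pointscape.imaging import ValidationError
from pointscape.sppa import _epanechnikov_sums

import oracles


def seeded_marked_pattern(seed, n=60, L=3):
    pat = ps.simulate_csr_n(n, seed=seed)
    pat = ps.randomize_marks(pat, "iid", p=[1 / L] * L, seed=seed + 500)
    return pat.with_marks(
        pat.marks, values=np.random.default_rng(seed + 900).uniform(0.5, 1.5, n)
    )


class TestKFunction:
    def test_two_point_hand_case(self):
        pat = ps.MarkedPointPattern([0.3, 0.6], [0.5, 0.5], (0, 1, 0, 1))
        est = ps.k_function(pat, r=[0.1, 0.29, 0.3, 0.45], correction="none")
        np.testing.assert_allclose(est.estimate, [0.0, 0.0, 1.0, 1.0])

    @pytest.mark.parametrize("correction", ["none", "translation", "toroidal"])
    def test_matches_naive_oracle(self, correction):
        r = np.linspace(0.02, 0.25, 7)
        for seed in range(5):
            pat = ps.simulate_csr_n(50, seed=seed)
            est = ps.k_function(pat, r, correction)
            np.testing.assert_allclose(
                est.estimate, oracles.naive_k(pat, r, correction), atol=1e-10
            )

    def test_monotone_nondecreasing(self):
        pat = ps.simulate_csr_n(120, seed=3)
        est = ps.k_function(pat)
        assert (np.diff(est.estimate) >= -1e-12).all()

    def test_preconditions(self):
        one = ps.MarkedPointPattern([0.5], [0.5], (0, 1, 0, 1))
        with pytest.raises(ValidationError):
            ps.k_function(one)
        pat = ps.simulate_csr_n(10, seed=0)
        with pytest.raises(ValidationError, match="half"):
            ps.k_function(pat, r=[0.7])


class TestCrossK:
    def test_reduces_to_k_when_types_equal(self, csr_marked):
        r = np.linspace(0.02, 0.2, 6)
        est = ps.cross_k_function(csr_marked, 1, 1, r)
        sub = ps.split_by_mark(csr_marked)[1]
        np.testing.assert_allclose(
            est.estimate, ps.k_function(sub, r).estimate, atol=1e-12
        )

    def test_symmetry_on_seeded_fixtures(self):
        r = np.linspace(0.02, 0.2, 5)
        for seed in range(20):
            pat = seeded_marked_pattern(seed)
            kij = ps.cross_k_function(pat, 0, 1, r).estimate
            kji = ps.cross_k_function(pat, 1, 0, r).estimate
            np.testing.assert_allclose(kij, kji, atol=1e-10)

    def test_matches_naive_oracle(self):
        r = np.linspace(0.02, 0.2, 5)
        for seed in range(5):
            pat = seeded_marked_pattern(seed)
            est = ps.cross_k_function(pat, 0, 2, r, "translation")
            np.testing.assert_allclose(
                est.estimate,
                oracles.naive_cross_k(pat, 0, 2, r, "translation"),
                atol=1e-10,
            )

    def test_independent_components_poisson_cross_structure(self):
        # two independent CSR components: mean K̂_ij(0.1) ≈ π·0.01
        vals = []
        for s in range(300):
            rng = np.random.default_rng(40000 + s)
            a = ps.simulate_csr_n(100, seed=rng)
            b = ps.simulate_csr_n(100, seed=rng)
            pat = ps.MarkedPointPattern(
                np.r_[a.x, b.x], np.r_[a.y, b.y], (0, 1, 0, 1),
                marks=np.r_[np.zeros(100, int), np.ones(100, int)],
            )
            vals.append(ps.cross_k_function(pat, 0, 1, [0.1]).estimate[0])
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - np.pi * 0.01) < 3 * se

    def test_empty_type_rejected(self, csr_marked):
        with pytest.raises(ValidationError):
            ps.cross_k_function(csr_marked, 0, 99, [0.1])


class TestPairCorrelation:
    def test_kernel_mass_unit(self):
        # ∫ k_h = 1 for any h: integrate the implementation numerically
        for h in (0.01, 0.1, 0.5):
            t = np.linspace(-h, h, 20001)
            k = [oracles.epanechnikov(v, h) for v in t]
            assert np.trapezoid(k, t) == pytest.approx(1.0, abs=1e-6)

    def test_matches_naive_oracle(self):
        r = np.linspace(0.05, 0.2, 5)
        for seed in range(5):
            pat = ps.simulate_csr_n(40, seed=seed)
            est = ps.pair_correlation(pat, r, bandwidth=0.05,
                                      correction="translation")
            np.testing.assert_allclose(
                est.estimate, oracles.naive_g(pat, r, 0.05, "translation"),
                atol=1e-10,
            )

    def test_zero_r_dropped_with_warning(self):
        pat = ps.simulate_csr_n(50, seed=1)
        with pytest.warns(UserWarning):
            est = ps.pair_correlation(pat, r=[0.0, 0.05, 0.1])
        assert len(est.r) == 2

    def test_matern_cluster_g_above_one_at_short_range(self):
        vals = [
            ps.pair_correlation(
                ps.simulate_matern_cluster(25, 8, 0.04, seed=s),
                r=[0.03], bandwidth=0.02,
            ).estimate[0]
            for s in range(40)
        ]
        assert np.mean(vals) > 1.2


class TestKernelSums:
    def test_prefix_sum_matches_direct_evaluation(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1, 400)
        w = rng.uniform(0.5, 2.0, 400)
        r = np.linspace(0.05, 0.9, 13)
        h = 0.07
        (got,) = _epanechnikov_sums(d, [w], r, h)
        want = np.array(
            [sum(wi * oracles.epanechnikov(di - ri, h) for di, wi in zip(d, w))
             for ri in r]
        )
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestJFunction:
    def test_csr_near_one(self):
        r = np.linspace(0, 0.04, 9)
        vals = np.array(
            [ps.j_function(ps.simulate_csr_n(200, seed=s), r).estimate
             for s in range(100)]
        )
        mean = np.nanmean(vals, axis=0)
        se = np.nanstd(vals, axis=0) / np.sqrt(len(vals))
        assert (np.abs(mean[1:] - 1.0) < 3 * se[1:] + 1e-3).all()

    def test_inhibited_pattern_j_above_one(self):
        r = np.array([0.0, 0.02, 0.04])
        vals = np.array(
            [ps.j_function(ps.simulate_ssi(150, 0.05, seed=s), r).estimate
             for s in range(20)]
        )
        assert np.nanmean(vals[:, 1:]) > 1.1

    def test_cluster_pattern_j_below_one(self):
        r = np.array([0.0, 0.02, 0.04])
        vals = np.array(
            [
                ps.j_function(
                    ps.simulate_matern_cluster(25, 8, 0.04, seed=s), r
                ).estimate
                for s in range(20)
            ]
        )
        assert np.nanmean(vals[:, 1:]) < 0.9

    def test_undefined_tail_is_nan(self):
        pat = ps.simulate_csr_n(500, seed=1)
        est = ps.j_function(pat, r=np.linspace(0, 0.4, 40))
        assert np.isnan(est.estimate[-1])  # F saturates at 1 well before 0.4


class TestClarkEvans:
    def test_unit_lattice_R_exactly_two(self):
        xx, yy = np.mgrid[0:10, 0:10]
        pat = ps.MarkedPointPattern(xx.ravel() + 0.5, yy.ravel() + 0.5,
                                    (0, 10, 0, 10))
        res = ps.clark_evans_test(pat, metric="toroidal")
        assert res.R == pytest.approx(2.0, abs=1e-12)
        assert res.mean_nn_distance == pytest.approx(1.0, abs=1e-12)

    def test_csr_calibration(self):
        Rs, zs = [], []
        for s in range(200):
            pat = ps.simulate_csr_n(500, seed=s)
            res = ps.clark_evans_test(pat, metric="toroidal")
            Rs.append(res.R)
            zs.append(res.z)
        assert 0.97 < np.mean(Rs) < 1.03
        assert 0.9 < np.mean(np.abs(np.asarray(zs)) < 2) <= 1.0

    def test_matern_cluster_R_below_one(self):
        Rs = [
            ps.clark_evans_test(
                ps.simulate_matern_cluster(25, 8, 0.03, seed=s)
            ).R
            for s in range(30)
        ]
        assert np.mean(np.asarray(Rs) < 1) > 0.9

    def test_summary_renders(self):
        res = ps.clark_evans_test(ps.simulate_csr_n(50, seed=0))
        assert "Clark" in res.summary() and "R =" in res.summary()


class TestMarkConnection:
    def test_degenerate_single_mark(self):
        pat = ps.simulate_csr_n(100, seed=2).with_marks(np.zeros(100, int))
        r = np.linspace(0.02, 0.2, 10)
        est = ps.mark_connection(pat, 0, 0, r)
        np.testing.assert_allclose(est.estimate, 1.0)

    def test_matches_naive_oracle(self):
        r = np.linspace(0.05, 0.2, 4)
        for seed in range(3):
            pat = seeded_marked_pattern(seed)
            est = ps.mark_connection(pat, 0, 1, r, bandwidth=0.06)
            np.testing.assert_allclose(
                est.estimate, oracles.naive_p_lm(pat, 0, 1, r, 0.06),
                atol=1e-10,
            )

    def test_segregated_blocks_zero_cross_connection(self):
        # marks split into two distant blocks: no cross pairs below the gap
        rng = np.random.default_rng(5)
        n = 200
        x = np.r_[rng.uniform(0, 0.2, n), rng.uniform(0.8, 1.0, n)]
        y = rng.uniform(0, 1, 2 * n)
        pat = ps.MarkedPointPattern(
            x, y, (0, 1, 0, 1),
            marks=np.r_[np.ones(n, int), 2 * np.ones(n, int)],
        )
        est = ps.mark_connection(pat, 1, 2, r=np.linspace(0.05, 0.3, 6),
                                 bandwidth=0.03)
        assert np.nanmax(est.estimate) < 1e-12

    def test_unknown_mark_rejected(self, csr_marked):
        with pytest.raises(ValidationError):
            ps.mark_connection(csr_marked, 0, 99, [0.1])


class TestMarkConnectionMatrix:
    def test_mass_conservation(self, csr_marked):
        r = np.linspace(0.02, 0.2, 30)
        mats = ps.mark_connection_matrix(csr_marked, r)
        total = sum(e.estimate for e in mats.values())
        defined = ~np.isnan(total)
        np.testing.assert_allclose(total[defined], 1.0, atol=1e-9)

    def test_matches_single_pair_calls(self):
        pat = seeded_marked_pattern(7, n=80, L=4)
        r = np.linspace(0.05, 0.2, 5)
        mats = ps.mark_connection_matrix(pat, r, bandwidth=0.06)
        assert len(mats) == 16
        for (l, m), est in mats.items():
            single = ps.mark_connection(pat, l, m, r, bandwidth=0.06)
            np.testing.assert_array_equal(est.estimate, single.estimate)

    def test_symmetry_on_seeded_fixtures(self):
        r = np.linspace(0.05, 0.2, 5)
        for seed in range(20):
            pat = seeded_marked_pattern(seed)
            a = ps.mark_connection(pat, 0, 1, r, bandwidth=0.06).estimate
            b = ps.mark_connection(pat, 1, 0, r, bandwidth=0.06).estimate
            np.testing.assert_allclose(a, b, atol=1e-10)


class TestMarkCorrelation:
    def test_constant_marks_exactly_one(self):
        pat = ps.simulate_csr_n(150, seed=8)
        pat = pat.with_marks(None, values=np.full(150, 3.7))
        est = ps.mark_correlation(pat, r=np.linspace(0.02, 0.2, 20))
        np.testing.assert_allclose(est.estimate, 1.0, atol=1e-12)

    def test_matches_naive_oracle(self):
        r = np.linspace(0.05, 0.2, 4)
        for seed in range(3):
            pat = seeded_marked_pattern(seed)
            est = ps.mark_correlation(pat, r, bandwidth=0.06)
            np.testing.assert_allclose(
                est.estimate, oracles.naive_k_mm(pat, r, 0.06), atol=1e-10
            )

    def test_spatially_correlated_marks_above_one(self):
        # mark = smooth function of position + small noise ⇒ k_mm > 1 small r
        vals = []
        for s in range(20):
            pat = ps.simulate_csr_n(300, seed=600 + s)
            rng = np.random.default_rng(700 + s)
            v = 1.0 + np.sin(2 * np.pi * pat.x) * np.sin(2 * np.pi * pat.y) \
                + rng.normal(0, 0.05, pat.n)
            pat = pat.with_marks(None, values=v)
            vals.append(
                ps.mark_correlation(pat, r=[0.03], bandwidth=0.02).estimate[0]
            )
        assert np.mean(vals) > 1.02

    def test_missing_values_rejected(self, csr_marked):
        with pytest.raises(ValidationError):
            ps.mark_correlation(csr_marked, [0.1])


class TestEnvelope:
    def test_csr_envelope_covers_csr_observation(self):
        fracs = []
        for s in range(5):
            pat = ps.simulate_csr_n(100, seed=50 + s)
            env = ps.envelope(pat, "K", "CSR", n_sim=99, rank=5, seed=s,
                              r=np.linspace(0.01, 0.2, 30))
            fracs.append(env.fraction_inside())
        assert np.mean(fracs) > 0.8

    def test_random_labeling_preserves_coordinates(self, csr_marked):
        seen = []

        def probe(pat):
            seen.append((pat.x, pat.y))
            return ps.mark_connection(pat, 0, 1, r=np.linspace(0.05, 0.2, 5))

        ps.envelope(csr_marked, probe, "random_labeling", n_sim=10, rank=2,
                    seed=1)
        for x, y in seen[1:]:  # first entry is the observed pattern
            np.testing.assert_array_equal(x, csr_marked.x)
            np.testing.assert_array_equal(y, csr_marked.y)

    def test_same_seed_identical_envelopes(self):
        pat = ps.simulate_csr_n(80, seed=9)
        kw = dict(n_sim=29, rank=3, seed=42, r=np.linspace(0.01, 0.15, 12))
        a = ps.envelope(pat, "K", "CSR", **kw)
        b = ps.envelope(pat, "K", "CSR", **kw)
        np.testing.assert_array_equal(a.lo, b.lo)
        np.testing.assert_array_equal(a.hi, b.hi)

    def test_statistic_null_mismatch_rejected(self, csr_marked):
        with pytest.raises(ValidationError):
            ps.envelope(csr_marked, "p_lm", "CSR", n_sim=19, rank=2, l=0, m=1)

    def test_rank_precondition(self):
        pat = ps.simulate_csr_n(50, seed=0)
        with pytest.raises(ValidationError):
            ps.envelope(pat, "K", "CSR", n_sim=5, rank=5)


def test_lattice_artefact_documented_behavior():
    """A pure patch-centre lattice shows R ≈ 2 and a K step at r = w."""
    cmap = np.zeros((12, 12), dtype=int)
    pat = ps.pattern_from_labels(cmap, 10)
    res = ps.clark_evans_test(pat, metric="toroidal")
    assert res.R == pytest.approx(2.0, rel=1e-9)
    est = ps.k_function(pat, r=[9.0, 10.0], correction="toroidal")
    assert est.estimate[0] == 0.0 and est.estimate[1] > 0.0
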