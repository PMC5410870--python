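"""Correction learning: Express, Knight-Ruiz, Probability, Binning, Armijo."""

import numpy as np
import pytest

from ccnorm.distance import PROB_EPS
from ccnorm.interactions import InteractionSet, neutral_filter
from ccnorm.normalize import (
    CorrectionSet, ExpectedModel, NormalizationError, _kr_core,
    _prepare_pairs, armijo_backtrack, binning_normalize, expected_5c,
    expected_hic, express_normalize, express_update_5c, express_update_hic,
    kr_balance, neutral_corrections, probability_normalize_5c,
    probability_normalize_hic,
)
from ccnorm.partition import Fragment, Partition


def sinkhorn_symmetric(M, tol=1e-15, max_iter=200_000):
    """Slow symmetric Sinkhorn oracle: x with x*(Mx) = 1."""
    x = np.ones(M.shape[0])
    for _ in range(max_iter):
        x_new = np.sqrt(x / (M @ x))
        if np.abs(x_new - x).max() < tol:
            return x_new
        x = x_new
    return x


class TestExpectedValues:
    def test_hic_neutral_elements(self, two_fragment_partition):
        model = ExpectedModel(two_fragment_partition,
                              neutral_corrections(two_fragment_partition))
        assert expected_hic(0, 2, model) == pytest.approx(1.0)

    def test_hic_arithmetic(self, two_fragment_partition):
        cs = neutral_corrections(two_fragment_partition)
        cs.f = np.array([2.0, 1.0, 3.0, 1.0])

        class ConstD:
            def evaluate(self, d, variant="counts"):
                return np.full_like(np.asarray(d, dtype=float), np.log(4.0))

        model = ExpectedModel(two_fragment_partition, cs, ConstD())
        assert expected_hic(0, 2, model) == pytest.approx(24.0)

    def test_5c_arithmetic(self, fivec_partition):
        cs = neutral_corrections(fivec_partition)
        cs.f = np.zeros(6)
        model = ExpectedModel(fivec_partition, cs)
        assert expected_5c(0, 1, model) == pytest.approx(0.0)
        cs.f[0], cs.f[1] = 0.5, -0.2

        class ConstD:
            def evaluate(self, d):
                return np.full_like(np.asarray(d, dtype=float), 3.0)

        model = ExpectedModel(fivec_partition, cs, ConstD())
        assert expected_5c(0, 1, model) == pytest.approx(3.3)


class TestExpressHiC:
    def test_fixed_point_when_counts_equal_expected(self, hic_exact):
        part, exact, b, filt, df = hic_exact
        pairs = _prepare_pairs(exact, filt)
        D = np.asarray(df.evaluate(pairs.d))
        # at f = b the ratios c/E are exactly 1 -> update is the identity
        f_new, theta = express_update_hic(b.copy(), pairs, D, 0.0)
        assert np.allclose(f_new, b, rtol=1e-12)
        assert theta == pytest.approx(0.0, abs=1e-12)

    def test_doubled_counts_shift_scale_not_corrections(self, hic_exact):
        """Doubling every count from the fixed point multiplies each f by
        sqrt(2) before regauging; the regauge moves that factor into theta."""
        part, exact, b, filt, df = hic_exact
        doubled = InteractionSet(part)
        for k, c in exact.pairs.items():
            doubled.pairs[k] = 2.0 * c
        pairs = _prepare_pairs(doubled, filt)
        D = np.asarray(df.evaluate(pairs.d))
        f_new, theta = express_update_hic(b.copy(), pairs, D, 0.0)
        assert np.allclose(f_new, b, rtol=1e-12)
        assert theta == pytest.approx(np.log(2.0), abs=1e-10)

    def test_noise_free_bias_recovery_is_exact(self, hic_exact):
        part, exact, b, filt, df = hic_exact
        cs = express_normalize(exact, filt, df, tol=1e-13)
        assert cs.converged
        assert np.abs(np.log(cs.f) - np.log(b)).max() < 1e-10
        r = np.corrcoef(np.log(cs.f), np.log(b))[0, 1]
        assert r > 0.999

    def test_balance_condition_at_convergence(self, hic_sim_filtered):
        part, ints, truth, filt, df = hic_sim_filtered
        cs = express_normalize(ints, filt, df, tol=1e-12)
        pairs = _prepare_pairs(ints, filt)
        E = np.exp(np.asarray(df.evaluate(pairs.d)) + cs.theta) \
            * cs.f[pairs.i] * cs.f[pairs.j]
        ratio_sum = pairs.row_sum(pairs.c / E)
        n_a = pairs.row_counts()
        ok = n_a > 0
        assert np.abs(ratio_sum[ok] / n_a[ok] - 1.0).max() < 1e-4

    def test_gauge_geometric_mean_one(self, hic_sim_filtered):
        part, ints, truth, filt, df = hic_sim_filtered
        cs = express_normalize(ints, filt, df)
        assert np.exp(np.log(cs.f[filt.valid]).mean()) == pytest.approx(1.0)

    def test_weighted_equals_standard_when_row_counts_uniform(
            self, hic_sim_filtered):
        """With |A_i| constant, weighted balancing and Knight-Ruiz solve the
        same problem; corrections agree up to the shared gauge."""
        part, ints, truth, filt, df = hic_sim_filtered
        pairs = _prepare_pairs(ints, filt)
        n_a = pairs.row_counts()[filt.valid]
        assert n_a.min() == n_a.max()  # uniform by construction (dense cis)
        ex = express_normalize(ints, filt, df, tol=1e-12)
        kr = kr_balance(ints, filt, df, remove_distance=True)
        assert np.allclose(np.log(ex.f[filt.valid]),
                           np.log(kr.f[filt.valid]), atol=1e-5)


class TestExpress5C:
    def test_zero_residuals_leave_f_unchanged(self, fivec_sim):
        part, ints, truth = fivec_sim
        filt = neutral_filter(part)
        pairs = _prepare_pairs(ints, filt, nonzero_only=True,
                               opposite_orientation_only=True)
        D = np.log(pairs.c) - truth.biases[pairs.i] - truth.biases[pairs.j]
        f_new, theta = express_update_5c(truth.biases.copy(), pairs, D, 0.0)
        assert np.allclose(f_new, truth.biases, atol=1e-12)

    def test_single_partner_residual_half(self):
        frags = [
            Fragment(0, "chr1", 0, 1000, region=0,
                     primer_orientation="forward"),
            Fragment(1, "chr1", 2000, 3000, region=0,
                     primer_orientation="reverse"),
        ]
        part = Partition(frags, assay="fivec", regions=[("chr1", 0, 3000)])
        ints = InteractionSet(part)
        ints.pairs[(0, 1)] = float(np.e)  # ln c = 1, E = 0 -> residual 1
        pairs = _prepare_pairs(ints, neutral_filter(part),
                               nonzero_only=True,
                               opposite_orientation_only=True)
        f_new, theta = express_update_5c(np.zeros(2), pairs,
                                        np.zeros(1), 0.0)
        # each f rises by residual / 2 = 0.5; the shared 0.5 is regauged
        # into theta, leaving E unchanged
        assert theta == pytest.approx(1.0)
        assert np.allclose(f_new, 0.0, atol=1e-12)

    def test_additive_bias_recovery_up_to_gauge(self):
        """Noise-free 5C data: alternating distance/correction fits reach
        the joint least-squares optimum, recovering gamma exactly and f up
        to the model's gauge freedoms.

        The 5C pair graph is bipartite (opposite primer orientations only),
        so besides the overall mean (absorbed by theta) a forward/reverse
        offset +a/-a leaves every E_ij unchanged; comparison removes the
        per-orientation means.
        """
        from ccnorm import simdata
        from ccnorm.distance import fit_5c_distance
        part, ints, truth = simdata.simulate_5c(
            n_regions=2, frags_per_region=20, noise_sigma=0.0, seed=4,
            round_counts=False)
        filt = neutral_filter(part)
        f_adj = np.zeros(part.n_elements)
        for _ in range(30):
            adj = InteractionSet(part)
            for (i, j), c in ints.pairs.items():
                adj.pairs[(i, j)] = float(np.exp(np.log(c)
                                                 - f_adj[i] - f_adj[j]))
            fit = fit_5c_distance(adj, part, filt)
            cs = express_normalize(ints, filt, fit, tol=1e-13,
                                   max_iters=3000)
            f_adj = cs.f
        assert abs(fit.gamma - truth.gamma) < 1e-6

        # each region is a separate connected component with its own
        # forward/reverse offset freedom: demean per region x orientation
        fwd = part.orientations()
        groups = part.element_regions()
        est, tru = cs.f.copy(), truth.biases.copy()
        for r in np.unique(groups):
            for om in (fwd, ~fwd):
                mask = (groups == r) & om
                est[mask] -= est[mask].mean()
                tru[mask] -= tru[mask].mean()
        assert np.abs(est - tru).max() < 1e-6


class TestKnightRuiz:
    def test_uniform_offdiagonal_matrix(self):
        M = np.ones((5, 5)) - np.eye(5)
        x = _kr_core(M)
        assert np.allclose(x, x[0])

    def test_two_by_two_closed_form(self):
        M = np.array([[0.0, 2.0], [2.0, 0.0]])
        x = _kr_core(M)
        assert np.allclose(x, 1.0 / np.sqrt(2.0), rtol=1e-10)
        assert np.allclose(x * (M @ x), 1.0, rtol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sinkhorn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = rng.uniform(0.5, 2.0, (20, 20))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        x = _kr_core(M, tol=1e-14)
        y = sinkhorn_symmetric(M)
        assert np.abs(x - y).max() / np.abs(y).max() < 1e-6

    def test_row_sum_cv_small(self):
        rng = np.random.default_rng(9)
        M = rng.uniform(0.1, 3.0, (50, 50))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0.0)
        x = _kr_core(M, tol=1e-14)
        rows = x * (M @ x)
        assert np.std(rows) / np.mean(rows) < 1e-6

    def test_zero_support_row_raises(self, hic_sim_filtered):
        part, ints, truth, filt, df = hic_sim_filtered
        starved = InteractionSet(part)
        # only pairs among the first 10 elements: the rest have no support
        for (i, j), c in ints.pairs.items():
            if i < 10 and j < 10:
                starved.pairs[(i, j)] = c
        with pytest.raises(NormalizationError, match="zero-support"):
            kr_balance(starved, filt)


class TestProbabilityHiC:
    def test_unbiased_data_neutral_corrections(self):
        # per-fend shot noise on ln f is ~1/sqrt(reads per fend), so deep
        # coverage is needed before the 0.05 neutrality band is visible
        from ccnorm import simdata
        from ccnorm.distance import fit_hic_distance
        part, ints, truth = simdata.simulate_hic(
            n_fragments=100, bias_sigma=0.0, depth=10_000, seed=6)
        filt = neutral_filter(part)
        df = fit_hic_distance(ints, part, filt, n_bins=25,
                              smallest_bin_upper=50_000)
        cs = probability_normalize_hic(ints, filt, df, dist="poisson")
        assert np.abs(np.log(cs.f)).max() < 0.05

    def test_poisson_bias_recovery(self, hic_sim_filtered):
        part, ints, truth, filt, df = hic_sim_filtered
        cs = probability_normalize_hic(ints, filt, df, dist="poisson")
        lb = np.log(truth.biases[filt.valid])
        assert np.corrcoef(np.log(cs.f[filt.valid]), lb)[0, 1] > 0.95

    def test_monotone_descent(self, hic_sim_filtered):
        part, ints, truth, filt, df = hic_sim_filtered
        short = probability_normalize_hic(ints, filt, df, max_iters=2)
        full = probability_normalize_hic(ints, filt, df)
        assert full.cost <= short.cost + 1e-12

    def test_poisson_matches_express_on_exact_data(self, hic_exact):
        part, exact, b, filt, df = hic_exact
        ex = express_normalize(exact, filt, df, tol=1e-13)
        pb = probability_normalize_hic(exact, filt, df, dist="poisson",
                                       max_iters=5000, tol=0.0, gtol=1e-13)
        assert np.corrcoef(np.log(ex.f), np.log(pb.f))[0, 1] > 0.999
        assert np.abs(np.log(pb.f) - np.log(b)).max() < 1e-6

    def test_binomial_runs_and_respects_gauge(self, hic_sim_filtered):
        part, ints, truth, filt, df = hic_sim_filtered
        cs = probability_normalize_hic(ints, filt, df, dist="binomial")
        assert np.exp(np.log(cs.f[filt.valid]).mean()) == pytest.approx(1.0)
        lb = np.log(truth.biases[filt.valid])
        assert np.corrcoef(np.log(cs.f[filt.valid]), lb)[0, 1] > 0.5


class TestProbability5C:
    def test_noise_free_residuals_vanish(self):
        from ccnorm import simdata
        from ccnorm.distance import fit_5c_distance
        part, ints, truth = simdata.simulate_5c(
            n_regions=2, frags_per_region=20, bias_sigma=0.0,
            noise_sigma=0.0, seed=8, round_counts=False)
        filt = neutral_filter(part)
        fit = fit_5c_distance(ints, part, filt)
        cs = probability_normalize_5c(ints, filt, fit)
        assert cs.sigma < 1e-8
        assert np.abs(cs.f).max() < 1e-8

    def test_lognormal_bias_recovery(self, fivec_sim):
        part, ints, truth = fivec_sim
        from ccnorm.distance import fit_5c_distance
        filt = neutral_filter(part)
        fit = fit_5c_distance(ints, part, filt)
        cs = probability_normalize_5c(ints, filt, fit)
        assert np.corrcoef(cs.f, truth.biases)[0, 1] > 0.95

    def test_doubling_counts_is_a_gauge_shift(self, fivec_sim):
        part, ints, truth = fivec_sim
        from ccnorm.distance import fit_5c_distance
        filt = neutral_filter(part)
        fit = fit_5c_distance(ints, part, filt)
        base = probability_normalize_5c(ints, filt, fit)
        doubled = InteractionSet(part)
        for k, c in ints.pairs.items():
            doubled.pairs[k] = 2.0 * c
        d2 = probability_normalize_5c(doubled, filt, fit)
        assert np.allclose(d2.f, base.f, atol=1e-8)
        assert d2.theta - base.theta == pytest.approx(np.log(2.0), abs=1e-8)
        assert d2.sigma == pytest.approx(base.sigma, abs=1e-9)


def binning_toy(seed=0, odds=(1.0, 0.5, 0.25), base_p=0.6, n=60):
    """Single alternating feature with known combination odds."""
    rng = np.random.default_rng(seed)
    frags = [Fragment(k, "chr1", k * 1000, (k + 1) * 1000)
             for k in range(n // 2)]
    part = Partition(frags, assay="hic")
    feat = np.arange(n) % 2
    ints = InteractionSet(part)
    frag_of = np.array([f.fragment_index for f in part.fends])
    iu, ju = np.triu_indices(n, k=1)
    keep = frag_of[iu] != frag_of[ju]
    for i, j in zip(iu[keep], ju[keep]):
        a, b = sorted((feat[i], feat[j]))
        if rng.random() < base_p * odds[a + b]:
            ints.add(int(i), int(j), 1)
    return part, ints, feat.astype(float)


class TestBinning:
    def test_no_bias_grids_near_one(self):
        part, ints, feat = binning_toy(seed=3, odds=(1.0, 1.0, 1.0))
        bm = binning_normalize(ints, {"x": feat}, n_ranges=2, rounds=5)
        assert np.abs(bm.grids["x"] - 1.0).max() < 0.15

    def test_matches_bruteforce_grid_search(self):
        """BFGS grid agrees with a per-combination likelihood search.

        With one feature and a flat prior the Bernoulli likelihood
        separates by range combination, so an independent 1-D grid search
        per cell is an exact oracle for the joint MLE.
        """
        part, ints, feat = binning_toy(seed=0)
        bm = binning_normalize(ints, {"x": feat}, n_ranges=2, rounds=5)
        pairs = _prepare_pairs(ints, neutral_filter(part))
        o = (pairs.c > 0).astype(float)
        prior = np.clip(o.mean(), PROB_EPS, 1 - PROB_EPS)
        assign = bm.assignments["x"]
        combo = assign[pairs.i] + assign[pairs.j]
        gs = np.linspace(0.01, 3.0, 60_000)
        expect = {}
        for cmb, key in ((0, (0, 0)), (1, (0, 1)), (2, (1, 1))):
            sel = combo == cmb
            O, N = o[sel].sum(), sel.sum()
            p = np.clip(prior * gs, PROB_EPS, 1 - PROB_EPS)
            ll = O * np.log(p) + (N - O) * np.log1p(-p)
            expect[key] = gs[ll.argmax()]
        for (a, b), val in expect.items():
            assert abs(bm.grids["x"][a, b] - val) / val < 0.01

    def test_huge_pseudo_count_forces_grids_to_one(self):
        part, ints, feat = binning_toy(seed=0)
        bm = binning_normalize(ints, {"x": feat}, n_ranges=2,
                               pseudo_count=1e7, rounds=3)
        assert np.abs(bm.grids["x"] - 1.0).max() < 1e-3


class TestArmijo:
    def test_quadratic_full_step_accepted(self):
        cost = lambda v: 0.5 * float(v @ v)
        f = np.array([1.0, 1.0])
        f_new, r, ok = armijo_backtrack(cost, f, f, r0=1.0)
        assert ok and r == 1.0
        assert np.allclose(f_new, 0.0)

    def test_zero_gradient_no_move(self):
        cost = lambda v: 0.5 * float(v @ v)
        f = np.array([1.0, 1.0])
        f_new, r, ok = armijo_backtrack(cost, f, np.zeros(2), r0=1.0)
        assert ok and r == 1.0
        assert np.array_equal(f_new, f)

    def test_pathological_rate_halved_until_acceptable(self):
        """r0 = 1e6 on the quadratic: hand iteration accepts the first
        r = 1e6 * 0.5^k with (1-r)^2 <= 1 - 1e-4 * r, i.e. k = 19."""
        cost = lambda v: 0.5 * float(v @ v)
        f = np.array([1.0, 1.0])
        f_new, r, ok = armijo_backtrack(cost, f, f, r0=1e6)
        assert ok
        assert r == pytest.approx(1e6 * 0.5 ** 19)

    def test_exhausted_halvings_flagged(self):
        # a cost that increases for every step triggers the failure path
        cost = lambda v: -float(np.sum(np.minimum(v, 0.0)))
        f = np.array([0.0])
        grad = np.array([1.0])
        f_new, r, ok = armijo_backtrack(cost, f, grad, r0=1.0,
                                        max_halvings=5)
        assert not ok


class TestCrossAlgorithmConsistency:
    def test_all_algorithms_neutral_on_unbiased_data(self):
        from ccnorm import simdata
        from ccnorm.distance import fit_hic_distance
        part, ints, truth = simdata.simulate_hic(
            n_fragments=80, bias_sigma=0.0, depth=10_000, seed=12)
        filt = neutral_filter(part)
        df = fit_hic_distance(ints, part, filt, n_bins=20,
                              smallest_bin_upper=50_000)
        for cs in (express_normalize(ints, filt, df),
                   kr_balance(ints, filt, df, remove_distance=True),
                   probability_normalize_hic(ints, filt, df)):
            assert np.abs(np.log(cs.f)).max() < 0.1, cs.algorithm
        bm = binning_normalize(
            ints, {"len": np.array(
                [part.fragments[fe.fragment_index].stop
                 - part.fragments[fe.fragment_index].start
                 for fe in part.fends], dtype=float)},
            n_ranges=2, rounds=3, distance_function=df, filt=filt)
        assert np.abs(bm.grids["len"] - 1.0).max() < 0.15
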