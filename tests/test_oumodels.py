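import numpy as np
import pytest
from scipy.stats import multivariate_normal

from phyloconv.oumodels import (
    HansenContext,
    RegimePainting,
    _ou_correlation,
    aicc,
    bm_fit,
    bm_loglik,
    hansen_fit,
    hansen_loglik,
    hansen_weight_matrix,
    run_surface,
    summarize_painting,
    surface_backward,
    surface_forward,
)
from phyloconv.shapes import TraitMatrix
from phyloconv.synthetic_data import (
    simulate_bm,
    simulate_hansen,
    simulate_yule_tree,
)
from phyloconv.treeio import parse_newick, patristic_matrix, \
    shared_depth_matrix


def test_aicc_arithmetic():
    assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)
    assert aicc(0.0, 2, 10) == pytest.approx(5.7142857, abs=1e-6)


def test_aicc_blows_up_when_overparameterized():
    assert aicc(0.0, 10, 11) == np.inf


class TestBM:
    def test_two_tip_closed_form(self):
        tree = parse_newick("(A:1,B:1);")
        tm = TraitMatrix(["A", "B"], [[0.0], [2.0]])
        fit = bm_fit(tree, tm)
        assert fit.z0[0] == pytest.approx(1.0)
        assert fit.sigma_sq[0] == pytest.approx(1.0)
        assert fit.n_params == 2

    def test_constant_trait_floors_sigma(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tm = TraitMatrix(["A", "B", "C"], [[5.0], [5.0], [5.0]])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = bm_fit(tree, tm)
        assert fit.sigma_sq[0] <= 1e-11

    @pytest.mark.parametrize("seed", range(5))
    def test_loglik_matches_mvn_density(self, seed):
        tree = simulate_yule_tree(5, seed=seed, depth_rescale=2.0)
        tm = simulate_bm(tree, [0.7], 1.5, seed=seed + 50)
        fit = bm_fit(tree, tm)
        cov = fit.sigma_sq[0] * shared_depth_matrix(tree).to_numpy()
        y = tm.reorder(tree.tip_labels).traits[:, 0]
        expected = multivariate_normal.logpdf(
            y, mean=np.full(5, fit.z0[0]), cov=cov)
        assert fit.loglik == pytest.approx(expected, abs=1e-8)

    def test_bm_loglik_explicit_params(self):
        tree = simulate_yule_tree(6, seed=1, depth_rescale=2.0)
        tm = simulate_bm(tree, [0.5], 0.0, seed=9)
        y = tm.reorder(tree.tip_labels).traits[:, 0]
        cov = 0.8 * shared_depth_matrix(tree).to_numpy()
        expected = multivariate_normal.logpdf(y, mean=np.full(6, 0.3),
                                              cov=cov)
        assert bm_loglik(tree, tm, 0.8, 0.3) == pytest.approx(expected,
                                                              abs=1e-8)


class TestPainting:
    def test_from_shifts_propagates(self, yule_tree_12):
        tree = yule_tree_12
        shift = tree.tip_ids[0]
        p = RegimePainting.from_shifts(tree, {shift: 1})
        assert p.regime_of_branch[shift] == 1
        assert all(p.regime_of_branch[b] == 0
                   for b in tree.branch_ids if b != shift)
        p.validate(tree)

    def test_subtree_inheritance(self, balanced_four_tree):
        tree = balanced_four_tree
        internal = [n for n in tree.branch_ids if not tree.nodes[n].is_tip]
        p = RegimePainting.from_shifts(tree, {internal[0]: 1})
        for cid in tree.subtree_ids(internal[0]):
            if cid != tree.root_id:
                assert p.regime_of_branch[cid] == 1

    def test_validate_rejects_gapped_ids(self, balanced_four_tree):
        tree = balanced_four_tree
        p = RegimePainting.from_shifts(tree, {tree.tip_ids[0]: 2})
        with pytest.raises(ValueError):
            p.validate(tree)

    def test_table1_bookkeeping_contract(self):
        """13 origins into 6 regimes, all multiply occupied: the published
        four-model table's OUc column bookkeeping."""
        tree = simulate_yule_tree(30, seed=0, depth_rescale=10.0)
        branches = tree.branch_ids
        # root origin -> regime 0; 12 shift branches painted so that each
        # of the 6 regimes is reached by >= 2 origins
        shifts = {}
        tips = [b for b in branches if tree.nodes[b].is_tip]
        regimes = [0, 1, 1, 2, 2, 3, 3, 4, 4, 5, 5, 0]
        for b, r in zip(tips[:12], regimes):
            shifts[b] = r
        p = RegimePainting.from_shifts(tree, shifts)
        books = summarize_painting(p)
        assert books == {"k": 13, "k_prime": 6, "delta_k": 7, "c": 13,
                         "k_conv": 6, "k_nonconv": 0}

    def test_single_regime_bookkeeping(self, yule_tree_12):
        p = RegimePainting.from_shifts(yule_tree_12, {})
        books = summarize_painting(p)
        assert books == {"k": 1, "k_prime": 1, "delta_k": 0, "c": 0,
                         "k_conv": 0, "k_nonconv": 1}


class TestHansenLoglik:
    @pytest.mark.parametrize("alpha", [1e-3, 0.1, 1.0, 25.0])
    def test_weight_rows_sum_to_one(self, yule_tree_12, alpha):
        tree = yule_tree_12
        shifts = {tree.tip_ids[0]: 1, tree.branch_ids[5]: 2}
        p = RegimePainting.from_shifts(tree, shifts)
        w = hansen_weight_matrix(tree, p, alpha)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)

    def test_stationary_variance_formula(self):
        # sigma^2 = 2, alpha = 1, T -> inf gives variance 1
        v = 2.0 * _ou_correlation(np.array([[0.0]]), np.array([[60.0]]), 1.0)
        assert v[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_limit_to_bm(self, yule_tree_12):
        tree = yule_tree_12
        tm = simulate_bm(tree, [0.5], 0.3, seed=6)
        single = RegimePainting.from_shifts(tree, {})
        hl = hansen_loglik(tree, tm, single, 1e-8, 0.5, [[0.3]])
        bl = bm_loglik(tree, tm, 0.5, 0.3)
        assert abs(hl - bl) < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_mvn_density_oracle(self, seed):
        tree = simulate_yule_tree(6, seed=seed, depth_rescale=2.0)
        p = RegimePainting.from_shifts(tree, {tree.tip_ids[1]: 1})
        theta = np.array([[0.0], [1.0]])
        alpha, sigma_sq = 0.8, 0.4
        tm = simulate_hansen(tree, p, alpha, sigma_sq, theta, seed=seed + 9)
        got = hansen_loglik(tree, tm, p, alpha, sigma_sq, theta)

        w = hansen_weight_matrix(tree, p, alpha)
        mean = w @ theta[:, 0]
        d = patristic_matrix(tree).to_numpy()
        t = shared_depth_matrix(tree).to_numpy()
        cov = sigma_sq / (2 * alpha) * np.exp(-alpha * d) * \
            (1 - np.exp(-2 * alpha * t))
        y = tm.reorder(tree.tip_labels).traits[:, 0]
        expected = multivariate_normal.logpdf(y, mean=mean, cov=cov)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_rejects_bad_params(self, yule_tree_12):
        tm = simulate_bm(yule_tree_12, [1.0], 0.0, seed=1)
        p = RegimePainting.from_shifts(yule_tree_12, {})
        with pytest.raises(ValueError):
            hansen_loglik(yule_tree_12, tm, p, -1.0, 1.0, [[0.0]])
        with pytest.raises(ValueError):
            hansen_loglik(yule_tree_12, tm, p, 1.0, 1.0, [[0.0], [1.0]])


class TestHansenFit:
    def test_two_regime_optima_recovered(self):
        tree = simulate_yule_tree(30, seed=4, depth_rescale=10.0)
        # paint a whole clade with regime 1
        internal = [n for n in tree.branch_ids
                    if not tree.nodes[n].is_tip
                    and 5 <= len([x for x in tree.subtree_ids(n)
                                  if tree.nodes[x].is_tip]) <= 12]
        p = RegimePainting.from_shifts(tree, {internal[0]: 1})
        theta = np.array([[0.0], [2.0]])
        tm = simulate_hansen(tree, p, 3.0, 0.05, theta, seed=21)
        fit = hansen_fit(tree, tm, p)
        # stationary sd ~ 0.09; clade tips are correlated so the effective
        # sample is small -- 0.25 is ~3 effective standard errors
        assert fit.theta[0, 0] == pytest.approx(0.0, abs=0.25)
        assert fit.theta[1, 0] == pytest.approx(2.0, abs=0.25)
        assert fit.n_params == 1 * (2 + 2)

    def test_refine_improves_or_matches_grid(self):
        tree = simulate_yule_tree(15, seed=5, depth_rescale=5.0)
        p = RegimePainting.from_shifts(tree, {})
        tm = simulate_hansen(tree, p, 0.7, 0.3, [[0.5]], seed=3)
        ctx = HansenContext(tree, tm)
        grid = ctx.fit(p, refine=False)
        ref = ctx.fit(p, refine=True)
        assert ref.loglik >= grid.loglik - 1e-9

    def test_ou1_rarely_beats_bm_on_bm_data(self):
        """Calibration: on BM data AICc(OU1) should rarely beat BM by > 2."""
        wins = 0
        for seed in range(50):
            tree = simulate_yule_tree(12, seed=seed, depth_rescale=5.0)
            tm = simulate_bm(tree, [1.0], 0.0, seed=1000 + seed)
            bm = bm_fit(tree, tm)
            ou1 = hansen_fit(tree, tm, grid_size=24, refine=False)
            if ou1.aicc < bm.aicc - 2.0:
                wins += 1
        assert wins <= 10  # <= 20% of runs


class TestSurface:
    def test_forward_history_strictly_decreasing(self, small_scenario):
        data = small_scenario
        painting, history, ctx = surface_forward(data.tree, data.traits)
        aiccs = [h["aicc"] for h in history]
        assert all(b < a for a, b in zip(aiccs, aiccs[1:]))

    def test_forward_quiet_on_single_regime_data(self):
        accepted = []
        for seed in range(10):
            tree = simulate_yule_tree(12, seed=seed, depth_rescale=5.0)
            p = RegimePainting.from_shifts(tree, {})
            tm = simulate_hansen(tree, p, 1.0, 0.1, [[0.0], ], seed=seed)
            painting, history, _ = surface_forward(tree, tm)
            accepted.append(len(painting.shift_branches))
        # zero or near-zero spurious shifts (greedy AICc does overfit a
        # little at this sample size, as the stepwise method is known to)
        assert sum(1 for a in accepted if a <= 2) >= 8

    def test_two_planted_shifts_recovered(self):
        hits = 0
        for seed in range(10):
            tree = simulate_yule_tree(24, seed=seed, depth_rescale=8.0)
            internals = [n for n in tree.branch_ids
                         if not tree.nodes[n].is_tip]
            sizes = {n: len([x for x in tree.subtree_ids(n)
                             if tree.nodes[x].is_tip]) for n in internals}
            good = [n for n in internals if 4 <= sizes[n] <= 9]
            if len(good) < 2:
                continue
            # two non-nested clades
            b1 = good[0]
            sub1 = set(tree.subtree_ids(b1))
            b2 = next((n for n in good[1:]
                       if n not in sub1 and b1 not in
                       set(tree.subtree_ids(n))), None)
            if b2 is None:
                continue
            truth = RegimePainting.from_shifts(tree, {b1: 1, b2: 2})
            theta = np.array([[0.0], [1.5], [-1.5]])
            tm = simulate_hansen(tree, truth, 3.0, 0.03, theta, seed=seed)
            painting, _, _ = surface_forward(tree, tm)
            found = painting.shift_branches
            neighborhoods = []
            for b in (b1, b2):
                hood = {b, tree.nodes[b].parent_id}
                hood.update(tree.nodes[b].child_ids)
                neighborhoods.append(hood)
            if all(hood & found for hood in neighborhoods):
                hits += 1
        assert hits >= 8

    def test_backward_merges_planted_convergence(self):
        """Two independent lineages sharing one optimum collapse together."""
        merged_runs = 0
        for seed in range(5):
            tree = simulate_yule_tree(20, seed=100 + seed, depth_rescale=8.0)
            tips = tree.tip_ids
            truth = RegimePainting.from_shifts(
                tree, {tips[0]: 1, tips[10]: 2})
            theta = np.array([[0.0], [2.0], [2.0]])  # shared optimum
            tm = simulate_hansen(tree, truth, 3.0, 0.05, theta, seed=seed,
                                 branch_noise_scale={tips[0]: 0.3,
                                                     tips[10]: 0.3})
            res = run_surface(tree, tm)
            r1 = res.painting.regime_of_branch[tips[0]]
            r2 = res.painting.regime_of_branch[tips[10]]
            if r1 == r2 and res.delta_k >= 1:
                merged_runs += 1
        assert merged_runs >= 4

    def test_backward_never_worse_than_forward(self, small_scenario):
        data = small_scenario
        res = run_surface(data.tree, data.traits)
        assert res.aicc_ouc <= res.aicc_ounc + 1e-9
        assert res.aicc_ounc <= res.aicc_ou1 + 1e-9

    def test_bookkeeping_identities(self, small_scenario):
        res = run_surface(small_scenario.tree, small_scenario.traits)
        assert res.delta_k == res.k - res.k_prime
        assert res.k_prime == res.k_conv + res.k_nonconv
        assert res.k == len(res.painting.shift_branches) + 1

    def test_requires_enough_tips(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        tm = TraitMatrix(["A", "B", "C"], [[0.0], [1.0], [2.0]])
        with pytest.raises(ValueError):
            surface_forward(tree, tm)

    def test_result_to_dict_keys(self, small_scenario):
        res = run_surface(small_scenario.tree, small_scenario.traits)
        d = res.to_dict()
        assert set(d) == {"k", "k_prime", "delta_k", "c", "k_conv",
                          "k_nonconv", "aicc"}
        assert set(d["aicc"]) == {"ouc", "ounc", "ou1", "bm"}


class TestContextCache:
    def test_relabeled_paintings_share_cache_and_theta_maps_back(self):
        tree = simulate_yule_tree(10, seed=2, depth_rescale=4.0)
        tm = simulate_bm(tree, [1.0], 0.0, seed=2)
        ctx = HansenContext(tree, tm)
        tip = tree.tip_ids[0]
        p1 = RegimePainting.from_shifts(tree, {tip: 1})
        # same structure, labels swapped
        regime = {b: (0 if b == tip else 1) for b in tree.branch_ids}
        p2 = RegimePainting(regime_of_branch=regime, root_regime=1,
                            shift_branches=frozenset({tip}))
        f1 = ctx.fit(p1)
        f2 = ctx.fit(p2)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-12)
        np.testing.assert_allclose(f1.theta[0], f2.theta[1], atol=1e-12)
        np.testing.assert_allclose(f1.theta[1], f2.theta[0], atol=1e-12)
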