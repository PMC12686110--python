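"""Parametric branch-mixture models: likelihood, fitting, DN test, weights."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from mptrt import (
    Condition,
    DEFAULT_PROB_PARAMS,
    GptModel,
    IncrementSet,
    ProbParams,
    akaike_weights,
    build_model,
    category_probabilities,
    generate_dataset,
    get_family,
    lrt,
)
from mptrt.trees import MptBranch, MptStructure

BASE = np.array([100.0, 150.0, 200.0])


class TestLikelihood:
    def test_single_branch_category_contribution(self):
        """PCRM black-gun 'tool' is reached by one branch: the per-trial
        contribution is log[(1-C)(1-A)] + log f_fast(t)."""
        df = pd.DataFrame(
            {"tree": ["black_gun"] * 2, "response": ["tool"] * 2, "rt": [260.0, 320.0]}
        )
        model = GptModel(df, "PCRM", "shifted_wald", "EQ")
        th = DEFAULT_PROB_PARAMS
        inc = IncrementSet(scheme="EQ")
        ll = model.loglike(th, BASE, inc)
        fam = get_family("shifted_wald")
        expected = sum(
            np.log((1 - th.C_b) * (1 - th.A_b)) + fam.logpdf(t, BASE)
            for t in (260.0, 320.0)
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("structure", ["PCRM", "DIM"])
    def test_marginalizing_rt_recovers_category_probability(self, structure):
        """Integrating the joint (category, RT) density over t gives back the
        category probability from the base MPT model."""
        df = pd.DataFrame({"tree": ["black_gun"], "response": ["gun"], "rt": [300.0]})
        model = GptModel(df, structure, "shifted_wald", "R2")
        th = DEFAULT_PROB_PARAMS
        inc = IncrementSet(d1=25, d2=50, scheme="R2")
        total, _ = integrate.quad(
            lambda t: model.category_rt_density("black_gun", "gun", t, th, BASE, inc),
            200.0, np.inf, limit=200,
        )
        expected = category_probabilities(structure, th).loc["black_gun", "gun"]
        assert total == pytest.approx(expected, abs=1e-6)

    def test_joint_density_normalizes_per_tree(self):
        df = pd.DataFrame({"tree": ["white_tool"], "response": ["tool"], "rt": [300.0]})
        model = GptModel(df, "DIM", "shifted_wald", "R1")
        th = DEFAULT_PROB_PARAMS
        inc = IncrementSet(d1=25, d2=50, s1=50, s2=50, scheme="R1")
        total = 0.0
        for resp in ("gun", "tool"):
            v, _ = integrate.quad(
                lambda t: model.category_rt_density("white_tool", resp, t, th, BASE, inc),
                200.0, np.inf, limit=200,
            )
            total += v
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_rt_below_shift_scores_minus_inf(self):
        df = pd.DataFrame({"tree": ["black_gun"], "response": ["gun"], "rt": [150.0]})
        model = GptModel(df, "DIM", "shifted_wald", "EQ")
        ll = model.loglike(DEFAULT_PROB_PARAMS, BASE, IncrementSet(scheme="EQ"))
        assert ll == -np.inf


class TestFitting:
    def test_free_parameter_counts(self, null_dataset):
        for scheme, k in (("R1", 11), ("R2", 9), ("R3", 9), ("EQ", 7)):
            assert GptModel(null_dataset, "DIM", "shifted_wald", scheme).n_free_params == k
        for scheme, k in (("R1", 10), ("EQ", 6)):
            assert GptModel(null_dataset, "DIM", "normal", scheme).n_free_params == k

    def test_mle_dominates_generating_parameters(self, null_dataset):
        model = GptModel(null_dataset, "DIM", "shifted_wald", "EQ")
        res = model.fit(n_starts=3, seed=1)
        ll_truth = model.loglike(
            DEFAULT_PROB_PARAMS, BASE, IncrementSet(scheme="EQ")
        )
        assert res.llf >= ll_truth
        assert res.aic == pytest.approx(-2 * res.llf + 2 * 7)

    def test_nesting_and_lrt_df(self, null_dataset):
        full = GptModel(null_dataset, "DIM", "shifted_wald", "R1").fit(n_starts=2, seed=2)
        eq = GptModel(null_dataset, "DIM", "shifted_wald", "EQ").fit(n_starts=2, seed=2)
        assert full.llf >= eq.llf - 1e-6
        test = lrt(full, eq)
        assert test.df == 4
        assert test.statistic == pytest.approx(
            (-2 * eq.llf) - (-2 * full.llf), abs=1e-8
        )
        with pytest.raises(ValueError):
            lrt(eq, full)

    def test_fit_determinism(self, null_dataset):
        m = GptModel(null_dataset, "DIM", "shifted_wald", "R2")
        r1 = m.fit(n_starts=2, seed=5)
        r2 = m.fit(n_starts=2, seed=5)
        assert r1.llf == r2.llf
        assert np.array_equal(r1.base, r2.base)

    def test_parameter_recovery_large_n(self):
        """DIM, delta-mu = 75, n=10,000/tree: R1 recovers the probabilities
        within .02 and the location increments (75, 150) within 10%."""
        ds = generate_dataset(Condition("DIM", "delta_mu", 75, 10_000), seed=31)
        res = GptModel(ds, "DIM", "shifted_wald", "R1").fit(n_starts=3, seed=32)
        for name, truth in DEFAULT_PROB_PARAMS.as_dict().items():
            assert getattr(res.prob_params, name) == pytest.approx(truth, abs=0.02)
        assert res.increments.d1 == pytest.approx(75.0, rel=0.10)
        assert res.increments.d2 == pytest.approx(150.0, rel=0.10)

    def test_grid_search_oracle_two_branch_mixture(self):
        """One-tree, two-branch RT mixture: the fitted (A, d1) must sit at the
        argmax of a dense profile grid of the log-likelihood."""
        toy = MptStructure(
            "toy",
            (
                MptBranch("black_gun", (("A_b", False),), "gun", "fast", "A"),
                MptBranch("black_gun", (("A_b", True),), "gun", "slow", "1-A"),
            ),
        )
        rng = np.random.default_rng(8)
        fam = get_family("shifted_wald")
        n = 800
        is_fast = rng.random(n) < 0.6
        rts = np.where(
            is_fast,
            fam.frozen((100, 150, 200)).rvs(size=n, random_state=rng),
            fam.frozen((250, 150, 200)).rvs(size=n, random_state=rng),
        )
        df = pd.DataFrame({"tree": "black_gun", "response": "gun", "rt": rts})
        model = GptModel(df, toy, "shifted_wald", "R2")
        res = model.fit(n_starts=4, seed=9)

        from scipy.special import logit

        x_hat = model._pack(res.prob_params, res.base, res.increments)
        a_hat = res.prob_params.A_b
        a_grid = np.arange(max(a_hat - 0.1, 0.01), min(a_hat + 0.1, 0.99), 0.001)
        best_a, best_ll = None, -np.inf
        for a in a_grid:
            x = x_hat.copy()
            x[0] = logit(a)
            ll = model._loglike_x(x)
            if ll > best_ll:
                best_a, best_ll = a, ll
        assert res.prob_params.A_b == pytest.approx(best_a, abs=1e-2)

        d1_idx = 4 + 3  # first increment slot
        d_grid = np.arange(max(res.increments.d1 - 20, 0.1), res.increments.d1 + 20, 0.1)
        best_d, best_ll = None, -np.inf
        for dv in d_grid:
            x = x_hat.copy()
            x[d1_idx] = dv
            ll = model._loglike_x(x)
            if ll > best_ll:
                best_d, best_ll = dv, ll
        assert res.increments.d1 == pytest.approx(best_d, abs=0.2)

    def test_equivalent_models_match_under_eq_scheme(self, null_dataset):
        """With one shared RT distribution the DIM and PCRM likelihoods are
        the same function, so fitted logL agrees within 1e-4."""
        r_dim = GptModel(null_dataset, "DIM", "shifted_wald", "EQ").fit(n_starts=2, seed=3)
        r_pcrm = GptModel(null_dataset, "PCRM", "shifted_wald", "EQ").fit(n_starts=2, seed=3)
        assert r_dim.llf == pytest.approx(r_pcrm.llf, abs=1e-4)


class TestDnTest:
    def test_dn_statistic_properties(self, null_dataset):
        res = GptModel(null_dataset, "DIM", "shifted_wald", "R2").fit(n_starts=2, seed=4)
        test = res.dn_test()
        assert test.statistic >= 0
        assert 0 <= test.pvalue <= 1
        cells = res._dn_cells(4, 1.0)
        assert test.df == len(cells) - 4 - 9

    def test_dn_invariant_to_cell_reordering(self, null_dataset):
        """The projected quadratic form does not depend on cell order."""
        res = GptModel(null_dataset, "DIM", "shifted_wald", "R2").fit(n_starts=2, seed=4)
        stat = res.dn_test().statistic

        cells = res._dn_cells(4, 1.0)
        groups = {}
        for j, (tree, resp, lo, hi, obs, N) in enumerate(cells):
            groups.setdefault((tree, resp), []).append((j, lo, hi))
        phat = np.empty(len(cells))
        for (tree, resp), items in groups.items():
            edges = np.array([items[0][1]] + [hi for _j, _lo, hi in items])
            for (j, _lo, _hi), m in zip(items, res._cell_masses_x(res._x, tree, resp, edges)):
                phat[j] = m
        phat = np.maximum(phat, 1e-10)
        obs = np.array([c[4] for c in cells], dtype=float)
        N = np.array([c[5] for c in cells], dtype=float)
        v = (obs - N * phat) / np.sqrt(N * phat)
        B = np.empty((len(cells), res.n_free_params))
        for k in range(res.n_free_params):
            h = 1e-5 * max(1.0, abs(res._x[k]))
            xp, xm = res._x.copy(), res._x.copy()
            xp[k] += h
            xm[k] -= h
            pp = np.empty(len(cells))
            pm = np.empty(len(cells))
            for (tree, resp), items in groups.items():
                edges = np.array([items[0][1]] + [hi for _j, _lo, hi in items])
                for (j, _l, _h), a, b in zip(
                    items,
                    res._cell_masses_x(xp, tree, resp, edges),
                    res._cell_masses_x(xm, tree, resp, edges),
                ):
                    pp[j], pm[j] = a, b
            B[:, k] = (pp - pm) / (2 * h) / np.sqrt(phat)

        def quad_form(vv, BB):
            beta, *_ = np.linalg.lstsq(BB, vv, rcond=None)
            r = vv - BB @ beta
            return float(r @ r)

        base_stat = quad_form(v, B)
        assert base_stat == pytest.approx(stat, abs=1e-8)
        perm = np.random.default_rng(0).permutation(len(v))
        assert quad_form(v[perm], B[perm]) == pytest.approx(base_stat, abs=1e-8)

    def test_dn_rejects_with_too_few_cells(self, null_dataset):
        res = GptModel(null_dataset, "DIM", "shifted_wald", "R2").fit(n_starts=2, seed=4)
        with pytest.raises(ValueError, match="increase max_bins"):
            res.dn_test(max_bins=1)


class TestAkaikeWeights:
    def test_hand_examples(self):
        w = akaike_weights([10.0, 12.0])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)
        assert np.allclose(akaike_weights([5.0, 5.0]), [0.5, 0.5])

    def test_shift_invariance_and_normalization(self):
        a = akaike_weights([3.0, 7.0, 4.5])
        b = akaike_weights([103.0, 107.0, 104.5])
        assert np.allclose(a, b)
        assert a.sum() == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            akaike_weights([1.0])
        with pytest.raises(ValueError):
            akaike_weights([1.0, np.inf])


def test_unknown_scheme_and_missing_columns(null_dataset):
    with pytest.raises(ValueError):
        GptModel(null_dataset, "DIM", "shifted_wald", "R9")
    with pytest.raises(ValueError, match="rt"):
        GptModel(pd.DataFrame({"tree": [], "response": []}), "DIM")
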