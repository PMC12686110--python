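"""Two-bin nonparametric extension: binning, fitting, G2, LRT, round trips."""

import numpy as np
import pandas as pd
import pytest

from mptrt import (
    BinnedCounts,
    BinnedMptModel,
    DEFAULT_PROB_PARAMS,
    LatencySet,
    ProbParams,
    bin_dataset,
    extend_with_bins,
    lrt,
)
from mptrt.binned import _empty_counts


def _df(trees, responses, rts):
    return pd.DataFrame({"tree": trees, "response": responses, "rt": rts})


class TestBinning:
    def test_geometric_mean_boundary(self):
        df = _df(["black_gun", "black_gun"], ["gun", "gun"], [100.0, 400.0])
        counts = bin_dataset(df, "geometric_mean")
        assert counts.boundary == pytest.approx(200.0)
        assert counts.counts[("black_gun", "gun", "fast")] == 1
        assert counts.counts[("black_gun", "gun", "slow")] == 1

    def test_fixed_boundary_and_tie_convention(self):
        df = _df(["black_gun"] * 3, ["gun"] * 3, [240.0, 250.0, 260.0])
        counts = bin_dataset(df, 250.0)
        # RT < boundary -> fast; ties go to slow
        assert counts.counts[("black_gun", "gun", "fast")] == 1
        assert counts.counts[("black_gun", "gun", "slow")] == 2

    def test_counts_conserve_trials(self, null_dataset):
        counts = bin_dataset(null_dataset)
        assert counts.counts.sum() == len(null_dataset)
        assert (counts.tree_totals == 100).all()

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bin_dataset(_df([], [], []))
        with pytest.raises(ValueError):
            bin_dataset(_df(["black_gun"], ["gun"], [-1.0]))


class TestBinnedStructure:
    @pytest.mark.parametrize(
        "mode,n_free", [("ordered", 7), ("free", 7), ("all_equal", 5)]
    )
    def test_free_parameter_counts(self, mode, n_free):
        assert extend_with_bins("PCRM", mode).n_free_params == n_free

    @pytest.mark.parametrize("name", ["PCRM", "DIM"])
    def test_cell_probabilities_normalize_per_tree(self, name, rng):
        bs = extend_with_bins(name, "ordered")
        for _ in range(20):
            th = ProbParams(*rng.uniform(0.05, 0.95, 4))
            lat = LatencySet(*np.sort(rng.uniform(0.05, 0.95, 3))[::-1])
            p = bs.cell_probabilities(th, lat)
            sums = p.groupby(level="tree", sort=False).sum()
            assert np.allclose(sums, 1.0, atol=1e-12)


def _counts_from_probs(structure, mode, theta, lat, n):
    bs = extend_with_bins(structure, mode)
    p = bs.cell_probabilities(theta, lat)
    counts = _empty_counts()
    counts.update((p * n).round().astype(int))
    return BinnedCounts(counts, boundary=300.0)


class TestFitting:
    def test_perfect_fit_gives_zero_g2(self):
        """Counts exactly on the model manifold are fitted with G2 ~ 0."""
        theta = ProbParams(0.5, 0.5, 0.5, 0.5)
        lat = LatencySet(0.75, 0.5, 0.25)
        counts = _counts_from_probs("DIM", "free", theta, lat, 1600)
        res = BinnedMptModel(counts, "DIM", "free").fit(seed=0)
        assert res.gof().statistic == pytest.approx(0.0, abs=1e-6)

    def test_df_bookkeeping(self, null_dataset):
        res = BinnedMptModel.from_dataset(null_dataset, "DIM", "free").fit(seed=1)
        assert res.gof().df == 5  # (16 cells - 4 trees) - 7 parameters
        res_eq = BinnedMptModel.from_dataset(null_dataset, "DIM", "all_equal").fit(seed=1)
        assert res_eq.gof().df == 7
        assert res.aic == pytest.approx(-2 * res.llf + 2 * 7)

    def test_nesting_all_equal_fits_worse_on_ordered_data(self):
        """Strongly ordered latencies: the equal-L restriction loses fit."""
        theta = DEFAULT_PROB_PARAMS
        lat = LatencySet(0.85, 0.55, 0.25)
        bs = extend_with_bins("PCRM", "ordered")
        p = bs.cell_probabilities(theta, lat).to_numpy()
        rng = np.random.default_rng(3)
        counts = _empty_counts()
        vals = np.concatenate([rng.multinomial(2000, p[i:i + 4]) for i in range(0, 16, 4)])
        counts.iloc[:] = vals
        bc = BinnedCounts(counts, 300.0)
        full = BinnedMptModel(bc, "PCRM", "ordered").fit(seed=4)
        eq = BinnedMptModel(bc, "PCRM", "all_equal").fit(seed=4)
        assert full.llf >= eq.llf
        assert eq.gof().statistic > full.gof().statistic
        test = lrt(full, eq)
        assert test.df == 2
        assert test.pvalue < 1e-6

    def test_ordered_mode_estimates_are_strictly_ordered(self, effect_dataset):
        res = BinnedMptModel.from_dataset(effect_dataset, "DIM", "ordered").fit(seed=5)
        assert res.latencies.is_ordered

    def test_parameter_recovery_from_model_counts(self):
        """n=10,000/tree multinomial counts from the ordered binned PCRM
        recover the generating probabilities and latencies within .02."""
        theta = DEFAULT_PROB_PARAMS
        lat = LatencySet(0.75, 0.55, 0.35)
        bs = extend_with_bins("PCRM", "ordered")
        p = bs.cell_probabilities(theta, lat).to_numpy()
        rng = np.random.default_rng(11)
        fits = []
        for _ in range(5):  # average out single-draw multinomial noise
            counts = _empty_counts()
            counts.iloc[:] = np.concatenate(
                [rng.multinomial(10_000, p[i:i + 4]) for i in range(0, 16, 4)]
            )
            fits.append(
                BinnedMptModel(BinnedCounts(counts, 300.0), "PCRM", "ordered").fit(seed=12)
            )
        for name, truth in theta.as_dict().items():
            est = np.mean([getattr(r.prob_params, name) for r in fits])
            assert est == pytest.approx(truth, abs=0.02)
        for name in ("L_fast", "L_medium", "L_slow"):
            est = np.mean([getattr(r.latencies, name) for r in fits])
            assert est == pytest.approx(getattr(lat, name), abs=0.02)

    def test_grid_search_oracle_all_equal(self, null_dataset):
        """Brute-force oracle: in the all_equal model the likelihood separates,
        so (A_b, C_b) maximize the black-tree category likelihood and L is the
        overall fast fraction.  The fitter must agree within 1e-2."""
        model = BinnedMptModel.from_dataset(null_dataset, "DIM", "all_equal")
        res = model.fit(seed=2)
        c = model.counts.counts
        n_gun_g = c["black_gun"]["gun"].sum()
        n_tool_g = c["black_gun"]["tool"].sum()
        n_gun_t = c["black_tool"]["gun"].sum()
        n_tool_t = c["black_tool"]["tool"].sum()
        grid = np.arange(0.001, 1.0, 0.001)
        A, C = np.meshgrid(grid, grid, indexing="ij")
        p1 = A + C - A * C  # P(gun | gun tree), shared by both models
        p2 = A * (1 - C)  # P(gun | tool tree)
        ll = (
            n_gun_g * np.log(p1) + n_tool_g * np.log1p(-p1)
            + n_gun_t * np.log(p2) + n_tool_t * np.log1p(-p2)
        )
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert res.prob_params.A_b == pytest.approx(grid[i], abs=1e-2)
        assert res.prob_params.C_b == pytest.approx(grid[j], abs=1e-2)
        fast_frac = c.xs("fast", level="bin").sum() / c.sum()
        assert res.latencies.L_fast == pytest.approx(fast_frac, abs=1e-3)

    def test_fit_determinism(self, null_dataset):
        m = BinnedMptModel.from_dataset(null_dataset, "DIM", "free")
        r1, r2 = m.fit(seed=9), m.fit(seed=9)
        assert r1.llf == r2.llf
        assert r1.prob_params == r2.prob_params


class TestSerialization:
    def test_counts_csv_round_trip(self, null_dataset, tmp_path):
        counts = bin_dataset(null_dataset)
        path = tmp_path / "counts.csv"
        counts.to_csv(path)
        back = BinnedCounts.from_csv(path)
        assert (back.counts == counts.counts).all()
        assert back.boundary == pytest.approx(counts.boundary)

    def test_counts_csv_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("tree,response,count\na,b,1\n")
        with pytest.raises(ValueError, match="bin"):
            BinnedCounts.from_csv(path)

    def test_results_json(self, null_dataset, tmp_path):
        import json

        res = BinnedMptModel.from_dataset(null_dataset, "DIM", "free").fit(seed=1)
        payload = json.loads(res.to_json(tmp_path / "fit.json"))
        assert payload["df"] == 5
        assert payload["converged"] is True
        assert payload["aic"] == pytest.approx(res.aic)
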