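"""Nonparametric two-bin RT extension of the MPT models.

Each branch of the base MPT model is split into a "fast" and a "slow"
sub-branch.  The probability that a response produced by a latent RT
component lands in the fast bin is a latency parameter L, one per component.
Three latency modes are supported: "free" (three unconstrained L
parameters; the theoretical ordering L_fast > L_medium > L_slow is a
prediction checked on the estimates, and the chi-square reference for the
G-squared test is exact even when the true latencies are equal), "ordered"
(the ordering imposed strictly during estimation via a cascading logistic
reparameterization; note that at an equal-latency truth the constrained
G-squared is stochastically larger than chi-square), and "all_equal" (a
single shared L: the nested "no RT differences" model).

RTs are discretized at a per-dataset boundary - by default the geometric
mean of all RTs - and the resulting (tree, response, bin) counts are fitted
by product-multinomial maximum likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .inference import TestResult, chi2_test
from .trees import (
    COMPONENTS,
    PARAM_NAMES,
    RESPONSES,
    TREES,
    MptStructure,
    ProbParams,
    build_model,
    moment_prob_params,
)

BINS = ("fast", "slow")

_PROB_EPS = 1e-12
_LOGIT_BOUND = 15.0


@dataclass(frozen=True)
class LatencySet:
    """Fast-bin probabilities, one per latent RT component."""

    L_fast: float
    L_medium: float
    L_slow: float

    def __post_init__(self) -> None:
        for name in ("L_fast", "L_medium", "L_slow"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v!r} must lie strictly in (0, 1)")

    def for_component(self, component: str) -> float:
        return {"fast": self.L_fast, "medium": self.L_medium, "slow": self.L_slow}[
            component
        ]

    @property
    def is_ordered(self) -> bool:
        return self.L_fast > self.L_medium > self.L_slow


@dataclass(frozen=True)
class BinnedCounts:
    """Counts over (tree, response, bin) cells plus the boundary used (ms)."""

    counts: pd.Series  # MultiIndex (tree, response, bin)
    boundary: float

    @property
    def tree_totals(self) -> pd.Series:
        return self.counts.groupby(level="tree", sort=False).sum()

    def to_csv(self, path: str | Path) -> None:
        df = self.counts.rename("count").reset_index()
        df.attrs = {}
        df.to_csv(path, index=False)
        Path(str(path) + ".meta.json").write_text(
            json.dumps({"boundary": self.boundary})
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinnedCounts":
        df = pd.read_csv(path)
        for col in ("tree", "response", "bin", "count"):
            if col not in df.columns:
                raise ValueError(f"binned-counts file {path} is missing column {col!r}")
        counts = df.set_index(["tree", "response", "bin"])["count"]
        meta = Path(str(path) + ".meta.json")
        boundary = json.loads(meta.read_text())["boundary"] if meta.exists() else np.nan
        full = _empty_counts()
        full.update(counts)
        return cls(full, float(boundary))


def _cell_index() -> pd.MultiIndex:
    return pd.MultiIndex.from_product(
        [list(TREES), list(RESPONSES), list(BINS)], names=["tree", "response", "bin"]
    )


def _empty_counts() -> pd.Series:
    return pd.Series(0, index=_cell_index(), dtype=int)


def geometric_mean(rts: np.ndarray) -> float:
    rts = np.asarray(rts, dtype=float)
    if np.any(rts <= 0):
        raise ValueError("geometric mean requires strictly positive RTs")
    return float(np.exp(np.mean(np.log(rts))))


def bin_dataset(data, boundary="geometric_mean") -> BinnedCounts:
    """Discretize trial RTs into fast/slow counts per (tree, response).

    ``boundary`` is either the string "geometric_mean" (resolved over all RTs
    of the dataset) or a fixed value in ms.  Trials with RT strictly below
    the boundary are "fast"; ties go to "slow".
    """
    df = getattr(data, "df", data)
    if len(df) == 0:
        raise ValueError("cannot bin an empty dataset")
    rts = df["rt"].to_numpy(dtype=float)
    if np.any(rts <= 0):
        raise ValueError("all RTs must be strictly positive")
    b = geometric_mean(rts) if boundary == "geometric_mean" else float(boundary)
    out = _empty_counts()
    binned = np.where(rts < b, "fast", "slow")
    grouped = (
        pd.DataFrame({"tree": df["tree"], "response": df["response"], "bin": binned})
        .groupby(["tree", "response", "bin"], sort=False)
        .size()
    )
    out.update(grouped)
    return BinnedCounts(out, b)


class BinnedStructure:
    """An MPT structure with every branch split into fast/slow sub-branches.

    Cell probabilities over (tree, response, bin) are sums over matching
    branches of p_branch * L_component (fast) or p_branch * (1 - L_component)
    (slow).  ``mode`` is "free" (three latency parameters), "ordered" (three,
    strictly ordered) or "all_equal" (a single shared latency parameter).
    """

    def __init__(self, structure: MptStructure | str, mode: str = "free"):
        if isinstance(structure, str):
            structure = build_model(structure)
        if mode not in ("ordered", "free", "all_equal"):
            raise ValueError(
                f"mode must be 'ordered', 'free' or 'all_equal', got {mode!r}"
            )
        self.structure = structure
        self.mode = mode
        self.cells = _cell_index()
        cell_pos = {cell: i for i, cell in enumerate(self.cells)}
        comp_pos = {c: i for i, c in enumerate(COMPONENTS)}
        # Per branch: factor encoding, component index, fast/slow cell rows.
        self._factors = []
        self._comp_idx = []
        self._fast_cell = []
        self._slow_cell = []
        pidx = {name: i for i, name in enumerate(PARAM_NAMES)}
        for b in structure.branches:
            self._factors.append([(pidx[n], comp) for n, comp in b.factors])
            self._comp_idx.append(comp_pos[b.rt_component])
            self._fast_cell.append(cell_pos[(b.tree, b.response, "fast")])
            self._slow_cell.append(cell_pos[(b.tree, b.response, "slow")])

    @property
    def n_free_params(self) -> int:
        return 4 + (1 if self.mode == "all_equal" else 3)

    def _latency_vector(self, latencies: LatencySet | float) -> np.ndarray:
        if isinstance(latencies, LatencySet):
            return np.array([latencies.L_fast, latencies.L_medium, latencies.L_slow])
        return np.full(3, float(latencies))

    def cell_probabilities(
        self, prob_params: ProbParams | np.ndarray, latencies: LatencySet | float
    ) -> pd.Series:
        """P(response, bin | tree) over the 16 cells; sums to 1 per tree."""
        theta = (
            prob_params.as_array()
            if isinstance(prob_params, ProbParams)
            else np.asarray(prob_params, dtype=float)
        )
        L = self._latency_vector(latencies)
        out = np.zeros(len(self.cells))
        for factors, ci, fc, sc in zip(
            self._factors, self._comp_idx, self._fast_cell, self._slow_cell
        ):
            p = 1.0
            for j, comp in factors:
                p *= (1.0 - theta[j]) if comp else theta[j]
            out[fc] += p * L[ci]
            out[sc] += p * (1.0 - L[ci])
        return pd.Series(out, index=self.cells)


def extend_with_bins(structure: MptStructure | str, mode: str = "free") -> BinnedStructure:
    """Two-bin RT extension of a base MPT structure."""
    return BinnedStructure(structure, mode)


class BinnedMptModel:
    """Nonparametric binned-RT MPT model bound to observed cell counts.

    Parameters
    ----------
    counts : BinnedCounts
        Fast/slow counts per (tree, response), e.g. from :func:`bin_dataset`.
    structure : str or MptStructure
        "PCRM" or "DIM" (or a prebuilt structure).
    latency : str
        "free" (default), "ordered" (strict L_fast > L_medium > L_slow) or
        "all_equal".
    """

    def __init__(self, counts: BinnedCounts, structure="PCRM", latency="free"):
        self.binned = (
            structure
            if isinstance(structure, BinnedStructure)
            else extend_with_bins(structure, latency)
        )
        self.counts = counts
        self._n = counts.counts.reindex(self.binned.cells).to_numpy(dtype=float)
        tree_of_cell = self.binned.cells.get_level_values("tree")
        totals = counts.tree_totals
        self._tree_total = totals.reindex(tree_of_cell).to_numpy(dtype=float)
        if np.any(self._n < 0) or np.any(self._n != np.round(self._n)):
            raise ValueError("counts must be non-negative integers")

    @classmethod
    def from_dataset(cls, data, structure="PCRM", latency="free",
                     boundary="geometric_mean") -> "BinnedMptModel":
        return cls(bin_dataset(data, boundary), structure, latency)

    # -- parameterization ------------------------------------------------

    @property
    def n_free_params(self) -> int:
        return self.binned.n_free_params

    def _unpack(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta = expit(x[:4])
        if self.binned.mode == "ordered":
            # Cascading logistic map guarantees strict ordering.
            L_fast = expit(x[4])
            L_medium = L_fast * expit(x[5])
            L_slow = L_medium * expit(x[6])
            L = np.array([L_fast, L_medium, L_slow])
        elif self.binned.mode == "free":
            L = expit(x[4:7])
        else:
            L = np.full(3, expit(x[4]))
        return theta, L

    def _pack(self, prob_params: ProbParams, latencies: LatencySet | float) -> np.ndarray:
        x = list(logit(prob_params.as_array()))
        if self.binned.mode == "ordered":
            lf, lm, ls = latencies.L_fast, latencies.L_medium, latencies.L_slow
            x += [logit(lf), logit(lm / lf), logit(ls / lm)]
        elif self.binned.mode == "free":
            x += [logit(latencies.L_fast), logit(latencies.L_medium),
                  logit(latencies.L_slow)]
        else:
            L = latencies if isinstance(latencies, float) else latencies.L_fast
            x += [logit(L)]
        return np.clip(x, -_LOGIT_BOUND, _LOGIT_BOUND)

    def _cell_probs(self, x: np.ndarray) -> np.ndarray:
        theta, L = self._unpack(x)
        return self._cell_probs_fast(theta, L)

    def _cell_probs_fast(self, theta: np.ndarray, L: np.ndarray) -> np.ndarray:
        out = np.zeros(len(self.binned.cells))
        for factors, ci, fc, sc in zip(
            self.binned._factors,
            self.binned._comp_idx,
            self.binned._fast_cell,
            self.binned._slow_cell,
        ):
            p = 1.0
            for j, comp in factors:
                p *= (1.0 - theta[j]) if comp else theta[j]
            out[fc] += p * L[ci]
            out[sc] += p * (1.0 - L[ci])
        return out

    def loglike(self, x: np.ndarray) -> float:
        """Product-multinomial log-likelihood (kernel, no multinomial constant)."""
        p = np.maximum(self._cell_probs(np.asarray(x, dtype=float)), _PROB_EPS)
        return float(np.sum(self._n * np.log(p)))

    def _start_points(self, n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
        # Moment start: invert the category probabilities shared by both
        # models (P(gun|gun tree) = A + C - AC, P(gun|tool tree) = A(1-C)),
        # then seed latencies from the overall fast fraction.
        counts = self.counts.counts
        starts = []
        cat = counts.groupby(level=["tree", "response"], sort=False).sum()
        theta0 = moment_prob_params({k: float(v) for k, v in cat.items()})
        f = np.clip(
            counts.xs("fast", level="bin").sum() / counts.sum(), 0.05, 0.95
        )
        if self.binned.mode in ("ordered", "free"):
            lat0 = LatencySet(min(f + 0.15, 0.97), f, max(f - 0.15, 0.03))
        else:
            lat0 = float(f)
        x0 = self._pack(theta0, lat0)
        starts.append(x0)
        for _ in range(max(0, n_starts - 1)):
            starts.append(
                np.clip(x0 + rng.normal(0.0, 1.0, size=x0.size), -_LOGIT_BOUND, _LOGIT_BOUND)
            )
        return starts

    def fit(self, n_starts: int = 5, seed: int | None = None,
            maxiter: int = 500) -> "BinnedMptResults":
        """Maximum-likelihood fit; best of ``n_starts`` starting points."""
        rng = np.random.default_rng(seed)
        bounds = [(-_LOGIT_BOUND, _LOGIT_BOUND)] * self.n_free_params

        def nll(x):
            return -self.loglike(x)

        best = None
        any_success = False
        for x0 in self._start_points(n_starts, rng):
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-10},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        theta, L = self._unpack(best.x)
        return BinnedMptResults(self, best.x, theta, L, -best.fun, any_success, n_starts)


class BinnedMptResults:
    """MLE of a :class:`BinnedMptModel` with goodness-of-fit diagnostics."""

    def __init__(self, model, x, theta, L, llf, converged, n_starts_used):
        self.model = model
        self._x = np.asarray(x, dtype=float)
        self.prob_params = ProbParams(*theta)
        self.latencies = LatencySet(*L)
        self._L = np.asarray(L, dtype=float)
        self.llf = float(llf)
        self.n_free_params = model.n_free_params
        self.aic = -2.0 * self.llf + 2.0 * self.n_free_params
        self.converged = bool(converged)
        self.n_starts_used = int(n_starts_used)

    @property
    def fitted_cell_probabilities(self) -> pd.Series:
        return pd.Series(
            self.model._cell_probs(self._x), index=self.model.binned.cells
        )

    def gof(self) -> TestResult:
        """G-squared against the saturated per-tree cell frequencies.

        df = (cells - trees) - free parameters = 12 - k; zero observed counts
        contribute nothing to the statistic.
        """
        n = self.model._n
        N = self.model._tree_total
        p = np.maximum(self.model._cell_probs(self._x), _PROB_EPS)
        expected = N * p
        mask = n > 0
        g2 = 2.0 * np.sum(n[mask] * np.log(n[mask] / expected[mask]))
        df = (len(n) - len(TREES)) - self.n_free_params
        return chi2_test(g2, df, "G2")

    def summary(self) -> str:
        g = self.gof()
        lines = [
            f"Nonparametric binned MPT ({self.model.binned.structure.name}, "
            f"{self.model.binned.mode})",
            f"  boundary (ms): {self.model.counts.boundary:.2f}",
            f"  logL {self.llf:.3f}   AIC {self.aic:.3f}   "
            f"G2({g.df}) = {g.statistic:.3f}, p = {g.pvalue:.4f}",
            f"  converged: {self.converged} (starts: {self.n_starts_used})",
            "  estimates:",
        ]
        for k, v in self.prob_params.as_dict().items():
            lines.append(f"    {k:9s} {v: .4f}")
        if self.model.binned.mode == "all_equal":
            lines.append(f"    L         {self._L[0]: .4f}")
        else:
            for k, v in zip(("L_fast", "L_medium", "L_slow"), self._L):
                lines.append(f"    {k:9s} {v: .4f}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        g = self.gof()
        payload = {
            "model": self.model.binned.structure.name,
            "mode": self.model.binned.mode,
            "boundary": self.model.counts.boundary,
            "estimates": {
                **self.prob_params.as_dict(),
                "L_fast": self._L[0], "L_medium": self._L[1], "L_slow": self._L[2],
            },
            "logL": self.llf,
            "G2": g.statistic,
            "df": g.df,
            "p": g.pvalue,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
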