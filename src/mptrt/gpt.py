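"""Parametric RT-extended MPT ("generalized processing tree") models.

The joint likelihood of a trial's (response category, RT) pair is a finite
mixture over the MPT branches that reach the observed category: each branch
contributes its branch probability times the density of its latent RT
component (fast/medium/slow).  Component densities come from one of the
families in :mod:`mptrt.distributions` under the additive-increment
parameterization; the non-decision shift is a single parameter shared by all
branches.

Maximum likelihood is computed by box-constrained quasi-Newton optimization
(L-BFGS-B with finite-difference gradients) from several starting points:
one method-of-moments start plus seeded random perturbations.  Process
probabilities are optimized on the logit scale; distribution parameters and
increments live in the box [0.001, 1000], with the shift additionally capped
below the smallest observed RT for families whose support starts at the
shift.  Increment positivity enforces RT_fast < RT_medium < RT_slow.

Goodness of fit uses the Dzhaparidze-Nikulin statistic: standardized cell
residuals over data-driven (tree, response, RT-bin) cells, projected off the
column space of the scaled Jacobian of cell probabilities.  It remains
chi-square distributed when parameters are estimated from the raw
(ungrouped) data, unlike a naive Pearson statistic.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, logsumexp

from .distributions import (
    PARAM_BOUNDS,
    Family,
    IncrementSet,
    component_params,
    default_increment_start,
    get_family,
    moment_start,
)
from .inference import TestResult, chi2_test
from .trees import (
    COMPONENTS,
    PARAM_NAMES,
    RESPONSES,
    MptStructure,
    ProbParams,
    build_model,
    moment_prob_params,
)

_LOGIT_BOUND = 15.0
_BIG = 1e300

#: Families whose density is zero at or below the shift parameter.
_SHIFT_SUPPORT = {"shifted_wald", "shifted_lognormal", "shifted_gamma"}

_SCHEME_INCREMENTS = {
    "R1": ("d1", "d2", "s1", "s2"),
    "R2": ("d1", "d2"),
    "R3": ("s1", "s2"),
    "EQ": (),
}


class GptModel:
    """Parametric RT-extended MPT model bound to trial-level data.

    Parameters
    ----------
    data : Dataset or DataFrame
        Trial records with columns ``tree``, ``response``, ``rt`` (ms).
    structure : str or MptStructure
        "PCRM" or "DIM" (or any prebuilt MPT structure).
    family : str
        RT distribution family for the latent components.
    scheme : str
        "R1" (location and shape increments free), "R2" (location only),
        "R3" (shape only) or "EQ" (one shared RT distribution).
    """

    def __init__(self, data, structure="DIM", family="shifted_wald", scheme="R1"):
        df = getattr(data, "df", data)
        for col in ("tree", "response", "rt"):
            if col not in df.columns:
                raise ValueError(f"data is missing required column {col!r}")
        if scheme not in _SCHEME_INCREMENTS:
            raise ValueError(f"unknown scheme {scheme!r}")
        self.structure: MptStructure = (
            build_model(structure) if isinstance(structure, str) else structure
        )
        self.family: Family = get_family(family)
        self.scheme = scheme
        self.data = df.reset_index(drop=True)
        self._rts = self.data["rt"].to_numpy(dtype=float)
        if not np.all(np.isfinite(self._rts)):
            raise ValueError("all RTs must be finite")
        self.min_rt = float(np.min(self._rts))

        # Precompute per-(tree, response) groups: trial indices plus, for
        # every branch reaching that category, its probability factors and
        # latent component index.
        pidx = {name: i for i, name in enumerate(PARAM_NAMES)}
        cidx = {c: i for i, c in enumerate(COMPONENTS)}
        trees = self.structure.trees
        key = pd.MultiIndex.from_frame(self.data[["tree", "response"]])
        self._groups = []
        for tree in trees:
            for resp in RESPONSES:
                branches = self.structure.branches_for(tree, resp)
                if not branches:
                    continue
                idx = np.flatnonzero((key.get_level_values(0) == tree)
                                     & (key.get_level_values(1) == resp))
                factors = [[(pidx[n], c) for n, c in b.factors] for b in branches]
                comps = np.array([cidx[b.rt_component] for b in branches])
                self._groups.append((tree, resp, idx, factors, comps))
        covered = sum(len(g[2]) for g in self._groups)
        if covered != len(self.data):
            bad = set(map(tuple, self.data[["tree", "response"]].drop_duplicates()
                          .itertuples(index=False))) - {
                (g[0], g[1]) for g in self._groups}
            raise ValueError(f"data contains categories unknown to the model: {sorted(bad)}")

    # -- parameter bookkeeping ------------------------------------------

    @property
    def n_base_params(self) -> int:
        return self.family.n_params

    @property
    def free_increments(self) -> tuple[str, ...]:
        return _SCHEME_INCREMENTS[self.scheme]

    @property
    def n_free_params(self) -> int:
        return 4 + self.n_base_params + len(self.free_increments)

    def _bounds(self) -> list[tuple[float, float]]:
        lo, hi = PARAM_BOUNDS
        bounds = [(-_LOGIT_BOUND, _LOGIT_BOUND)] * 4
        for i in range(self.n_base_params):
            if i == self.family.shift_index and self.family.name in _SHIFT_SUPPORT:
                # keep every trial inside the support of the shifted density
                bounds.append((lo, min(hi, self.min_rt - 1.0)))
            else:
                bounds.append((lo, hi))
        bounds += [(lo, hi)] * len(self.free_increments)
        return bounds

    def _increments(self, x: np.ndarray) -> IncrementSet:
        vals = dict(d1=0.0, d2=0.0, s1=0.0, s2=0.0)
        for name, v in zip(self.free_increments, x[4 + self.n_base_params:]):
            vals[name] = float(v)
        return IncrementSet(scheme=self.scheme, **vals)

    def _unpack(self, x: np.ndarray):
        theta = expit(x[:4])
        base = np.asarray(x[4:4 + self.n_base_params], dtype=float)
        return theta, base, self._increments(x)

    def _pack(self, prob_params: ProbParams, base, increments: IncrementSet) -> np.ndarray:
        x = list(np.clip(logit(prob_params.as_array()), -_LOGIT_BOUND, _LOGIT_BOUND))
        x += list(np.asarray(base, dtype=float))
        x += [getattr(increments, name) for name in self.free_increments]
        return np.array(x)

    # -- likelihood ------------------------------------------------------

    def _component_param_table(self, base, increments) -> list[np.ndarray]:
        return [
            component_params(self.family, base, increments, c, check_bounds=False)
            for c in COMPONENTS
        ]

    def _component_matrix(self, X: np.ndarray) -> np.ndarray:
        """Component parameters for a batch: (m, 3, n_base) from (m, k)."""
        nb = self.n_base_params
        base = X[:, 4:4 + nb]
        out = np.repeat(base[:, None, :], 3, axis=1)
        inc = np.zeros((X.shape[0], 4))  # d1, d2, s1, s2
        pos = {"d1": 0, "d2": 1, "s1": 2, "s2": 3}
        for name, col in zip(self.free_increments, range(4 + nb, X.shape[1])):
            inc[:, pos[name]] = X[:, col]
        fam = self.family
        out[:, 1, fam.d_index] += inc[:, 0]
        out[:, 2, fam.d_index] += inc[:, 0] + inc[:, 1]
        out[:, 1, fam.s_index] += inc[:, 2]
        out[:, 2, fam.s_index] += inc[:, 2] + inc[:, 3]
        return out

    def _loglike_batch(self, X: np.ndarray) -> np.ndarray:
        """Log-likelihood for a batch of parameter vectors (m, k) -> (m,).

        One vectorized pass evaluates all rows at once, which makes
        finite-difference gradients cheap.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = X.shape[0]
        theta = expit(X[:, :4])
        comp = self._component_matrix(X)  # (m, 3, nb)
        # (m, 3, N) log-densities: the family formulas broadcast over the
        # leading batch/component axes when fed parameter slices.
        params = [comp[:, :, i, None] for i in range(self.n_base_params)]
        logf = self.family.logpdf(self._rts, params)
        total = np.zeros(m)
        for _tree, _resp, idx, factors, comps in self._groups:
            if idx.size == 0:
                continue
            logp = np.empty((m, len(factors)))
            for k, fac in enumerate(factors):
                p = np.ones(m)
                for j, compl in fac:
                    p = p * ((1.0 - theta[:, j]) if compl else theta[:, j])
                logp[:, k] = np.log(np.maximum(p, 1e-300))
            mix = logf[:, comps][:, :, idx] + logp[:, :, None]
            total += logsumexp(mix, axis=1).sum(axis=1)
        return total

    def _loglike_x(self, x: np.ndarray) -> float:
        return float(self._loglike_batch(np.asarray(x, dtype=float)[None, :])[0])

    def loglike(self, prob_params: ProbParams, base, increments: IncrementSet) -> float:
        """Joint (category, RT) log-likelihood at natural-scale parameters.

        A parameter vector giving some trial zero likelihood scores -inf.
        """
        ll = self._loglike_x(self._pack(prob_params, base, increments))
        return ll if np.isfinite(ll) else -np.inf

    def category_rt_density(self, tree: str, response: str, t,
                            prob_params: ProbParams, base,
                            increments: IncrementSet) -> np.ndarray:
        """Joint density p(response, t | tree): branch mixture at RT t."""
        comp = self._component_param_table(np.asarray(base, float), increments)
        out = np.zeros_like(np.asarray(t, dtype=float))
        for b in self.structure.branches_for(tree, response):
            ci = COMPONENTS.index(b.rt_component)
            out = out + b.probability(prob_params) * self.family.pdf(t, comp[ci])
        return out

    # -- fitting ---------------------------------------------------------

    def _start_points(self, n_starts: int, rng: np.random.Generator) -> list[np.ndarray]:
        cat = self.data.groupby(["tree", "response"]).size()
        theta0 = moment_prob_params({k: float(v) for k, v in cat.items()})
        base0 = moment_start(self.family, self._rts)
        d0, s0 = default_increment_start(self.family)
        inc0 = IncrementSet(
            scheme=self.scheme,
            **{
                name: {"d1": d0, "d2": d0, "s1": s0, "s2": s0}[name]
                for name in self.free_increments
            },
        )
        x0 = self._pack(theta0, base0, inc0)
        bounds = self._bounds()
        starts = [x0]
        nb = self.n_base_params
        for _ in range(max(0, n_starts - 1)):
            x = x0.copy()
            x[:4] += rng.normal(0.0, 1.0, size=4)
            x[4:4 + nb] *= np.exp(rng.normal(0.0, 0.25, size=nb))
            x[4 + nb:] *= np.exp(rng.normal(0.0, 1.0, size=len(x) - 4 - nb))
            for i, (lo, hi) in enumerate(bounds):
                x[i] = min(max(x[i], lo), hi)
            starts.append(x)
        return starts

    def fit(self, n_starts: int = 5, seed: int | None = None,
            maxiter: int = 1000) -> "GptResults":
        """Maximum-likelihood fit; returns the best of ``n_starts`` starts."""
        rng = np.random.default_rng(seed)
        bounds = self._bounds()
        hi = np.array([b[1] for b in bounds])
        k = len(bounds)
        rows = np.arange(1, k + 1)

        def fun_and_grad(x):
            # one batched pass: the point itself plus k forward-difference
            # perturbations (flipped backward at the upper box edge)
            h = 1e-5 * np.maximum(1.0, np.abs(x))
            step = np.where(x + h > hi, -h, h)
            X = np.tile(x, (k + 1, 1))
            X[rows, rows - 1] += step
            ll = self._loglike_batch(X)
            if not np.isfinite(ll[0]):
                return _BIG, np.zeros_like(x)
            g = (ll[1:] - ll[0]) / step
            g = np.where(np.isfinite(g), g, 0.0)
            return -ll[0], -g

        best = None
        any_success = False
        for x0 in self._start_points(n_starts, rng):
            res = optimize.minimize(
                fun_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-9},
            )
            any_success = any_success or (bool(res.success) and res.fun < _BIG)
            if best is None or res.fun < best.fun:
                best = res
        return GptResults(self, best.x, -best.fun, any_success, n_starts)


class GptResults:
    """MLE of a :class:`GptModel`: estimates, fit indices, GOF test."""

    def __init__(self, model: GptModel, x, llf, converged, n_starts_used):
        self.model = model
        self._x = np.asarray(x, dtype=float)
        theta, base, inc = model._unpack(self._x)
        self.prob_params = ProbParams(*theta)
        self.base = base
        self.increments = inc
        self.llf = float(llf)
        self.n_free_params = model.n_free_params
        self.aic = -2.0 * self.llf + 2.0 * self.n_free_params
        self.converged = bool(converged)
        self.n_starts_used = int(n_starts_used)

    def component_parameters(self) -> dict[str, np.ndarray]:
        """Concrete fast/medium/slow parameter vectors at the MLE."""
        return {
            c: component_params(self.model.family, self.base, self.increments, c,
                                check_bounds=False)
            for c in COMPONENTS
        }

    # -- Dzhaparidze-Nikulin goodness of fit -----------------------------

    def _dn_cells(self, max_bins: int, min_expected: float):
        """Data-driven (tree, response, RT-bin) cells with observed counts.

        Within each category, RT bins sit at empirical quantiles
        (K = clamp(n/10, 1, max_bins)) and are merged upward until every
        expected count reaches ``min_expected``.
        """
        model = self.model
        df = model.data
        tree_totals = df.groupby("tree").size()
        cells = []  # (tree, response, lo, hi, observed, N_tree)
        for tree in model.structure.trees:
            N_t = int(tree_totals.get(tree, 0))
            for resp in RESPONSES:
                if not model.structure.branches_for(tree, resp):
                    continue
                rts = df.loc[(df["tree"] == tree) & (df["response"] == resp), "rt"]
                rts = rts.to_numpy(dtype=float)
                n_cat = rts.size
                K = int(np.clip(n_cat // 10, 1, max_bins))
                inner = (
                    np.quantile(rts, np.arange(1, K) / K) if K > 1 else np.empty(0)
                )
                edges = np.concatenate(([-np.inf], inner, [np.inf]))
                obs = np.histogram(rts, bins=np.concatenate(
                    ([-1e308], inner, [1e308])))[0] if n_cat else np.zeros(K, dtype=int)
                probs = self._cell_masses_x(self._x, tree, resp, edges)
                # merge upward until expected counts are not too small
                while len(probs) > 1 and np.any(N_t * probs < min_expected):
                    j = int(np.argmin(N_t * probs))
                    k = j + 1 if j + 1 < len(probs) else j - 1
                    lo, hi = min(j, k), max(j, k)
                    probs = np.concatenate(
                        [probs[:lo], [probs[lo] + probs[hi]], probs[hi + 1:]]
                    )
                    obs = np.concatenate([obs[:lo], [obs[lo] + obs[hi]], obs[hi + 1:]])
                    edges = np.delete(edges, hi)
                for j in range(len(probs)):
                    cells.append((tree, resp, edges[j], edges[j + 1], int(obs[j]), N_t))
        return cells

    def _cell_masses_x(self, x: np.ndarray, tree: str, resp: str,
                       edges: np.ndarray) -> np.ndarray:
        """Model-implied P(resp, RT-bin | tree) for bins defined by edges."""
        model = self.model
        theta, base, inc = model._unpack(x)
        comp = model._component_param_table(base, inc)
        theta_map = dict(zip(PARAM_NAMES, theta))
        masses = np.zeros(len(edges) - 1)
        finite = np.clip(edges, -1e308, 1e308)
        for b in model.structure.branches_for(tree, resp):
            ci = COMPONENTS.index(b.rt_component)
            cdf = model.family.cdf(finite, comp[ci])
            cdf[edges == -np.inf] = 0.0
            cdf[edges == np.inf] = 1.0
            masses += b.probability(theta_map) * np.diff(cdf)
        return masses

    def dn_test(self, max_bins: int = 4, min_expected: float = 1.0) -> TestResult:
        """Dzhaparidze-Nikulin goodness-of-fit test at the raw-data MLE.

        statistic = v' (I - B (B'B)^- B') v with v the standardized cell
        residuals and B the p^{-1/2}-scaled numerical Jacobian of cell
        probabilities in the free parameters; df = cells - trees - free
        parameters, referred to the upper chi-square tail.
        """
        cells = self._dn_cells(max_bins, min_expected)
        df_total = len(cells) - len(self.model.structure.trees) - self.n_free_params
        if df_total <= 0:
            raise ValueError(
                f"only {len(cells)} cells for {self.n_free_params} free parameters; "
                "increase max_bins to obtain positive degrees of freedom"
            )
        # Recompute cell probabilities at the MLE and numerically
        # differentiate in the free-parameter vector (central differences).
        def all_masses(x):
            groups: dict[tuple[str, str], list[tuple[int, float, float]]] = {}
            for j, (tree, resp, lo, hi, _obs, _N) in enumerate(cells):
                groups.setdefault((tree, resp), []).append((j, lo, hi))
            vals = np.empty(len(cells))
            for (tree, resp), items in groups.items():
                edges = np.array([items[0][1]] + [hi for _j, _lo, hi in items])
                masses = self._cell_masses_x(x, tree, resp, edges)
                for (j, _lo, _hi), m in zip(items, masses):
                    vals[j] = m
            return vals

        phat = np.maximum(all_masses(self._x), 1e-10)
        obs = np.array([c[4] for c in cells], dtype=float)
        N = np.array([c[5] for c in cells], dtype=float)
        v = (obs - N * phat) / np.sqrt(N * phat)

        B = np.empty((len(cells), self.n_free_params))
        for k in range(self.n_free_params):
            h = 1e-5 * max(1.0, abs(self._x[k]))
            xp, xm = self._x.copy(), self._x.copy()
            xp[k] += h
            xm[k] -= h
            B[:, k] = (all_masses(xp) - all_masses(xm)) / (2.0 * h) / np.sqrt(phat)

        beta, *_ = np.linalg.lstsq(B, v, rcond=None)
        resid = v - B @ beta
        return chi2_test(float(resid @ resid), df_total, "DN")

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        fam = self.model.family
        lines = [
            f"GPT model ({self.model.structure.name}, {fam.name}, {self.model.scheme})",
            f"  n trials: {len(self.model.data)}   free parameters: {self.n_free_params}",
            f"  logL {self.llf:.3f}   AIC {self.aic:.3f}   "
            f"converged: {self.converged} (starts: {self.n_starts_used})",
            "  process probabilities:",
        ]
        for k, v in self.prob_params.as_dict().items():
            lines.append(f"    {k:7s} {v: .4f}")
        lines.append("  fast-component base parameters:")
        for name, v in zip(fam.param_names, self.base):
            lines.append(f"    {name:7s} {v: .4f}")
        inc = self.increments
        lines.append(
            f"  increments ({inc.scheme}): d1={inc.d1:.4f} d2={inc.d2:.4f} "
            f"s1={inc.s1:.4f} s2={inc.s2:.4f}"
        )
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": self.model.structure.name,
            "family": self.model.family.name,
            "scheme": self.model.scheme,
            "estimates": {
                **self.prob_params.as_dict(),
                **dict(zip(self.model.family.param_names, map(float, self.base))),
                **{k: v for k, v in self.increments.as_dict().items() if k != "scheme"},
            },
            "logL": self.llf,
            "n_free_params": self.n_free_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text
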