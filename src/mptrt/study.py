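"""Monte Carlo simulation studies for RT-extended MPT models.

Three study designs are orchestrated over the generating grid:

1. **Goodness-of-fit calibration/power** - per replication, fit parametric
   models (family x constraint scheme) and/or the nonparametric binned
   model, and record the Dzhaparidze-Nikulin or G-squared p-value.
2. **Nested comparisons** - fit the full model and its equal-RT-distribution
   restriction and record the likelihood-ratio p-value (type-I error at zero
   effect, power otherwise).
3. **Non-nested model recovery** - fit both the DIM and the PCRM variant to
   the same data and record the Akaike weight in favor of the DIM.

Rejection rates are the relative frequency of p-values below alpha; mean
Akaike weights are averaged over replications.  Replications are fully
seeded (root seed x condition index x replication index) and independent,
so results are invariant to evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binned import BinnedMptModel
from .gpt import GptModel
from .inference import akaike_weights, lrt
from .simulate import Condition, dataset_seed_sequence, generate_dataset, generating_grid
from .trees import DEFAULT_PROB_PARAMS, ProbParams

logger = logging.getLogger(__name__)

_CONDITION_COLS = ["model", "manipulation", "effect", "n_per_tree"]

_FAMILY_SHORT = {
    "shifted_wald": "wald",
    "ex_gaussian": "exgauss",
    "shifted_lognormal": "lognormal",
    "normal": "normal",
    "shifted_gamma": "gamma",
}


@dataclass
class StudyConfig:
    """Configuration of one simulation study run."""

    sim: int
    conditions: Sequence[Condition] | None = None  # None: the full grid
    reps: int = 100
    alpha: float = 0.05
    families: Sequence[str] = ("shifted_wald",)
    schemes: Sequence[str] = ("R2",)  # fitted constraint schemes (study 1 only)
    fit_nonparametric: bool = True
    nonparametric_mode: str = "free"  # latency mode of the full binned model
    prob_params: ProbParams = DEFAULT_PROB_PARAMS
    seed: int = 0
    n_starts: int = 3
    max_bins: int = 4
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.sim not in (1, 2, 3):
            raise ValueError("sim must be 1, 2 or 3")
        if self.reps < 1:
            raise ValueError("reps must be at least 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    def resolved_conditions(self) -> list[Condition]:
        return list(self.conditions) if self.conditions is not None else generating_grid()


def rejection_rate(p_values, alpha: float = 0.05) -> float:
    """Relative frequency of significant results: mean of 1(p < alpha)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.mean(p < alpha))


def _fit_seed(cfg: StudyConfig, cond_idx: int, rep: int, salt: int):
    return np.random.SeedSequence([cfg.seed, cond_idx, rep, 7919 + salt])


def _fit_gpt(ds, structure, family, scheme, cfg, cond_idx, rep, salt) -> "GptModel.fit":
    """Fit with one retry from fresh starts if the first attempt fails."""
    model = GptModel(ds, structure=structure, family=family, scheme=scheme)
    res = model.fit(n_starts=cfg.n_starts, seed=_fit_seed(cfg, cond_idx, rep, salt))
    if not res.converged:
        retry = model.fit(n_starts=cfg.n_starts,
                          seed=_fit_seed(cfg, cond_idx, rep, salt + 5000))
        if retry.converged or retry.llf > res.llf:
            res = retry
    return res


def _row(cond: Condition, rep: int, fit_label: str, **extra) -> dict:
    row = {
        "model": cond.model,
        "manipulation": cond.manipulation,
        "effect": cond.effect,
        "n_per_tree": cond.n_per_tree,
        "rep": rep,
        "fit": fit_label,
    }
    row.update(extra)
    return row


def run_sim1(cfg: StudyConfig) -> pd.DataFrame:
    """Goodness-of-fit study: DN test (parametric) and G2 (nonparametric)."""
    rows = []
    for ci, cond in enumerate(cfg.resolved_conditions()):
        logger.info("study 1: condition %s", cond.label())
        for rep in range(cfg.reps):
            ds = generate_dataset(cond, cfg.prob_params,
                                  dataset_seed_sequence(cfg.seed, ci, rep), rep)
            for fi, family in enumerate(cfg.families):
                for si, scheme in enumerate(cfg.schemes):
                    res = _fit_gpt(ds, cond.model, family, scheme, cfg, ci, rep,
                                   10 * fi + si)
                    label = f"{_FAMILY_SHORT[res.model.family.name]}:{scheme}"
                    try:
                        test = res.dn_test(max_bins=cfg.max_bins)
                        rows.append(_row(cond, rep, label,
                                         statistic=test.statistic, df=test.df,
                                         p=test.pvalue, aic=res.aic, logL=res.llf,
                                         converged=res.converged))
                    except (ValueError, np.linalg.LinAlgError) as err:
                        logger.warning("DN test failed (%s): %s", label, err)
                        rows.append(_row(cond, rep, label, statistic=np.nan,
                                         df=np.nan, p=np.nan, aic=res.aic,
                                         logL=res.llf, converged=False))
            if cfg.fit_nonparametric:
                bres = BinnedMptModel.from_dataset(
                    ds, cond.model, cfg.nonparametric_mode
                ).fit(
                    n_starts=cfg.n_starts,
                    seed=_fit_seed(cfg, ci, rep, 999).generate_state(1)[0] % (2**31),
                )
                gof = bres.gof()
                rows.append(_row(cond, rep, "nonparametric",
                                 statistic=gof.statistic, df=gof.df, p=gof.pvalue,
                                 aic=bres.aic, logL=bres.llf,
                                 converged=bres.converged))
    return pd.DataFrame(rows)


def run_sim2(cfg: StudyConfig) -> pd.DataFrame:
    """Nested LRT study: full (three RT components) vs equal-RT restriction."""
    rows = []
    for ci, cond in enumerate(cfg.resolved_conditions()):
        logger.info("study 2: condition %s", cond.label())
        for rep in range(cfg.reps):
            ds = generate_dataset(cond, cfg.prob_params,
                                  dataset_seed_sequence(cfg.seed, ci, rep), rep)
            for fi, family in enumerate(cfg.families):
                full = _fit_gpt(ds, cond.model, family, "R1", cfg, ci, rep, 10 * fi)
                eq = _fit_gpt(ds, cond.model, family, "EQ", cfg, ci, rep, 10 * fi + 1)
                test = lrt(full, eq)
                rows.append(_row(cond, rep, f"{_FAMILY_SHORT[full.model.family.name]}:LRT",
                                 statistic=test.statistic, df=test.df, p=test.pvalue,
                                 aic=full.aic, logL=full.llf,
                                 converged=full.converged and eq.converged))
            if cfg.fit_nonparametric:
                seed = _fit_seed(cfg, ci, rep, 999).generate_state(1)[0] % (2**31)
                bm_full = BinnedMptModel.from_dataset(ds, cond.model,
                                                      cfg.nonparametric_mode)
                bm_eq = BinnedMptModel(bm_full.counts, cond.model, "all_equal")
                bfull = bm_full.fit(n_starts=cfg.n_starts, seed=seed)
                beq = bm_eq.fit(n_starts=cfg.n_starts, seed=seed + 1)
                test = lrt(bfull, beq)
                rows.append(_row(cond, rep, "nonparametric:LRT",
                                 statistic=test.statistic, df=test.df, p=test.pvalue,
                                 aic=bfull.aic, logL=bfull.llf,
                                 converged=bfull.converged and beq.converged))
    return pd.DataFrame(rows)


def run_sim3(cfg: StudyConfig) -> pd.DataFrame:
    """Non-nested recovery study: Akaike weight for the DIM vs the PCRM."""
    rows = []
    for ci, cond in enumerate(cfg.resolved_conditions()):
        logger.info("study 3: condition %s", cond.label())
        for rep in range(cfg.reps):
            ds = generate_dataset(cond, cfg.prob_params,
                                  dataset_seed_sequence(cfg.seed, ci, rep), rep)
            for fi, family in enumerate(cfg.families):
                fit_dim = _fit_gpt(ds, "DIM", family, "R1", cfg, ci, rep, 10 * fi)
                fit_pcrm = _fit_gpt(ds, "PCRM", family, "R1", cfg, ci, rep, 10 * fi + 1)
                w = akaike_weights([fit_dim.aic, fit_pcrm.aic])
                rows.append(_row(cond, rep, f"{_FAMILY_SHORT[fit_dim.model.family.name]}:R1",
                                 aic_dim=fit_dim.aic, aic_pcrm=fit_pcrm.aic,
                                 waic_dim=float(w[0]),
                                 converged=fit_dim.converged and fit_pcrm.converged))
            if cfg.fit_nonparametric:
                seed = _fit_seed(cfg, ci, rep, 999).generate_state(1)[0] % (2**31)
                counts = BinnedMptModel.from_dataset(ds, "DIM",
                                                     cfg.nonparametric_mode).counts
                bdim = BinnedMptModel(counts, "DIM", cfg.nonparametric_mode).fit(
                    n_starts=cfg.n_starts, seed=seed)
                bpcrm = BinnedMptModel(counts, "PCRM", cfg.nonparametric_mode).fit(
                    n_starts=cfg.n_starts, seed=seed + 1)
                w = akaike_weights([bdim.aic, bpcrm.aic])
                rows.append(_row(cond, rep, "nonparametric",
                                 aic_dim=bdim.aic, aic_pcrm=bpcrm.aic,
                                 waic_dim=float(w[0]),
                                 converged=bdim.converged and bpcrm.converged))
    return pd.DataFrame(rows)


def run_study(cfg: StudyConfig) -> pd.DataFrame:
    runner = {1: run_sim1, 2: run_sim2, 3: run_sim3}[cfg.sim]
    results = runner(cfg)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        summarize(results, cfg.alpha).to_csv(out / "summary.csv", index=False)
        from .simulate import grid_to_csv

        grid_to_csv(out / "conditions.csv", cfg.resolved_conditions())
    return results


def summarize(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Condition-level rejection rates or mean Akaike weights.

    Non-converged replications are excluded from the aggregate (their count
    is reported); a cell with no converged replications yields NaN, not 0.
    """
    if len(results) == 0:
        raise ValueError("empty result table")
    is_recovery = "waic_dim" in results.columns
    out_rows = []
    for keys, grp in results.groupby(_CONDITION_COLS + ["fit"], sort=False):
        ok = grp[grp["converged"].astype(bool)]
        row = dict(zip(_CONDITION_COLS + ["fit"], keys))
        row["n_reps"] = len(grp)
        row["n_converged"] = len(ok)
        row["n_excluded"] = len(grp) - len(ok)
        if is_recovery:
            if len(ok):
                m = float(ok["waic_dim"].mean())
                row["mean_waic_dim"] = m
                row["mc_se"] = float(ok["waic_dim"].std(ddof=1) / np.sqrt(len(ok))) \
                    if len(ok) > 1 else np.nan
            else:
                row["mean_waic_dim"] = np.nan
                row["mc_se"] = np.nan
        else:
            if len(ok):
                r = rejection_rate(ok["p"], alpha)
                row["rrate"] = r
                row["mc_se"] = float(np.sqrt(r * (1.0 - r) / len(ok)))
            else:
                row["rrate"] = np.nan
                row["mc_se"] = np.nan
        out_rows.append(row)
    return pd.DataFrame(out_rows)
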