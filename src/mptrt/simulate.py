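"""Synthetic trial-level data for the weapon-identification simulation studies.

Datasets are generated from the PCRM or DIM with shifted-Wald RT components:
for each of the four trees, a branch is drawn from the model's branch
probabilities and an RT from the branch's latent component distribution.
The condition grid crosses the generating model with a location/scale
manipulation (delta-mu in {0, 25, 50, 75}: medium adds delta-mu, slow adds
3*delta-mu) or a shape manipulation (delta-lambda in {0, 100, 200, 300}:
medium adds delta-lambda, slow adds 2*delta-lambda), at 100 or 300 trials
per tree.  The fast-branch base parameters are mu = 100, lambda = 150,
shift = 200 ms; process probabilities default to A_b = .80, A_w = .20,
C_b = .70, C_w = .65.

Seeding is hierarchical: a root seed plus (condition index, replication
index) deterministically derives each dataset's random stream, so any single
replication is reproducible in isolation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import IncrementSet, component_params, get_family
from .trees import COMPONENTS, DEFAULT_PROB_PARAMS, ProbParams, build_model

logger = logging.getLogger(__name__)

#: Fast-branch shifted-Wald base parameters (mu, lambda, shift) in ms units.
BASE_WALD = (100.0, 150.0, 200.0)

DELTA_MU_LEVELS = (0.0, 25.0, 50.0, 75.0)
DELTA_LAMBDA_LEVELS = (0.0, 100.0, 200.0, 300.0)
N_LEVELS = (100, 300)

_DATA_COLUMNS = ("tree", "response", "rt", "branch")


@dataclass(frozen=True)
class Condition:
    """One cell of the generating design."""

    model: str  # "PCRM" or "DIM"
    manipulation: str  # "delta_mu" or "delta_lambda"
    effect: float
    n_per_tree: int
    family: str = "shifted_wald"
    base: tuple[float, ...] = BASE_WALD

    def __post_init__(self) -> None:
        if self.manipulation not in ("delta_mu", "delta_lambda"):
            raise ValueError(f"unknown manipulation {self.manipulation!r}")
        if self.effect < 0:
            raise ValueError("effect size must be non-negative")
        if self.n_per_tree < 1:
            raise ValueError("n_per_tree must be at least 1")

    @property
    def increments(self) -> IncrementSet:
        """Generating increments: medium/slow offsets relative to the fast branch."""
        if self.manipulation == "delta_mu":
            # mu_medium = mu + delta, mu_slow = mu + 3*delta
            return IncrementSet(d1=self.effect, d2=2.0 * self.effect, scheme="R2")
        # lambda_medium = lambda + delta, lambda_slow = lambda + 2*delta
        return IncrementSet(s1=self.effect, s2=self.effect, scheme="R3")

    def component_params_for(self, component: str) -> np.ndarray:
        return component_params(self.family, self.base, self.increments, component)

    def label(self) -> str:
        return (
            f"{self.model}_{self.manipulation}{self.effect:g}_n{self.n_per_tree}"
        )

    def as_dict(self) -> dict:
        fam = get_family(self.family)
        d = {
            "model": self.model,
            "manipulation": self.manipulation,
            "effect": self.effect,
            "n_per_tree": self.n_per_tree,
            "family": self.family,
        }
        for comp in COMPONENTS:
            for name, v in zip(fam.param_names, self.component_params_for(comp)):
                d[f"{comp}_{name}"] = float(v)
        return d


@dataclass
class Dataset:
    """Trial records plus generating metadata.

    ``df`` has columns tree, response, rt (ms), branch (generating-branch
    label); metadata is empty for externally loaded files.
    """

    df: pd.DataFrame
    condition: Condition | None = None
    seed: int | None = None
    replication: int | None = None
    prob_params: ProbParams | None = None

    def __len__(self) -> int:
        return len(self.df)


def generating_grid(models=("PCRM", "DIM"), n_levels=N_LEVELS) -> list[Condition]:
    """The full generating design: 2 models x 8 effect cells x 2 sample sizes."""
    grid = []
    for model in models:
        for manipulation, levels in (
            ("delta_lambda", DELTA_LAMBDA_LEVELS),
            ("delta_mu", DELTA_MU_LEVELS),
        ):
            for effect in levels:
                for n in n_levels:
                    grid.append(Condition(model, manipulation, effect, n))
    return grid


def grid_to_csv(path: str | Path, grid: Sequence[Condition] | None = None) -> None:
    """One row per condition with all generating parameters explicit."""
    grid = generating_grid() if grid is None else grid
    pd.DataFrame([c.as_dict() for c in grid]).to_csv(path, index=False)


def generate_dataset(
    condition: Condition,
    prob_params: ProbParams = DEFAULT_PROB_PARAMS,
    seed: int | np.random.SeedSequence | None = None,
    replication: int | None = None,
) -> Dataset:
    """Simulate one balanced dataset (n_per_tree trials in each of 4 trees).

    Per trial: draw a branch from the model's branch probabilities, record
    its response, then draw an RT from the branch's latent component
    distribution.  The generating branch label is recorded.
    """
    if not isinstance(prob_params, ProbParams):
        raise ValueError("prob_params must be a ProbParams instance")
    structure = build_model(condition.model)
    fam = get_family(condition.family)
    rng = np.random.default_rng(seed)
    comp_par = {c: condition.component_params_for(c) for c in COMPONENTS}
    records = {col: [] for col in _DATA_COLUMNS}
    for tree in structure.trees:
        branches = structure.branches_for(tree)
        probs = np.array([b.probability(prob_params) for b in branches])
        draws = rng.choice(len(branches), size=condition.n_per_tree, p=probs)
        rts = np.empty(condition.n_per_tree)
        for b_i, b in enumerate(branches):
            idx = np.flatnonzero(draws == b_i)
            if idx.size:
                rts[idx] = fam.frozen(comp_par[b.rt_component]).rvs(
                    size=idx.size, random_state=rng
                )
        records["tree"].extend([tree] * condition.n_per_tree)
        records["response"].extend(branches[i].response for i in draws)
        records["rt"].extend(rts.tolist())
        records["branch"].extend(branches[i].label for i in draws)
    df = pd.DataFrame(records)
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return Dataset(df, condition, seed_val, replication, prob_params)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """CSV of trial records plus a JSON metadata sidecar (<path>.meta.json)."""
    dataset.df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "condition": dataset.condition.as_dict() if dataset.condition else None,
        "seed": dataset.seed,
        "replication": dataset.replication,
        "prob_params": dataset.prob_params.as_dict() if dataset.prob_params else None,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> Dataset:
    """Load a dataset CSV (and its metadata sidecar, when present)."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("tree", "response", "rt"):
        if col not in df.columns:
            raise ValueError(
                f"dataset file {path} is missing required column {col!r} "
                f"(line 1 header: {list(df.columns)})"
            )
    if "branch" not in df.columns:
        df["branch"] = ""
    bad = df.index[~(df["rt"] > 0)]
    if len(bad):
        raise ValueError(
            f"dataset file {path}: non-positive RT at data line {bad[0] + 2}"
        )
    meta_path = Path(str(path) + ".meta.json")
    condition = seed = replication = prob_params = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("condition"):
            c = meta["condition"]
            condition = Condition(
                c["model"], c["manipulation"], c["effect"], c["n_per_tree"],
                c.get("family", "shifted_wald"),
            )
        seed = meta.get("seed")
        replication = meta.get("replication")
        if meta.get("prob_params"):
            prob_params = ProbParams(**meta["prob_params"])
    else:
        warnings.warn(f"no metadata sidecar found for {path}; loading records only")
        logger.warning("no metadata sidecar found for %s", path)
    return Dataset(df, condition, seed, replication, prob_params)


def dataset_seed_sequence(root_seed: int, condition_index: int,
                          replication: int) -> np.random.SeedSequence:
    """Deterministic per-replication stream derivation."""
    return np.random.SeedSequence([int(root_seed), int(condition_index), int(replication)])
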