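"""Multinomial processing tree (MPT) structures for the weapon identification task.

The weapon identification task crosses a racial prime (black/white face) with
a target image (gun/tool), giving four product-multinomial trees:
``black_gun``, ``black_tool``, ``white_gun``, ``white_tool``.  Each tree emits
a "gun" or "tool" response through latent branches built from two kinds of
process parameters:

* ``A_p`` - probability that the automatic process triggers a "gun" response
  (p in {b, w} indexes the racial prime),
* ``C_p`` - probability that the controlled process operates successfully.

Two theories order these processes differently:

* **PCRM** (preemptive-conflict-resolution model): control comes first; only
  when it fails (prob ``1-C``) does the automatic process drive the response.
* **DIM** (default-interventionist model): the automatic association fires
  first ("gun" with prob ``A``); control may subsequently intervene (prob
  ``C``) and force the correct response.

The two models are statistically equivalent on response frequencies alone
(identical category probabilities for every parameter vector); they can only
be told apart once each branch is tagged with a latent response-time
component ("fast", "medium", "slow"), which is what the rest of this package
does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TREES = ("black_gun", "black_tool", "white_gun", "white_tool")
RESPONSES = ("gun", "tool")
COMPONENTS = ("fast", "medium", "slow")

PARAM_NAMES = ("A_b", "A_w", "C_b", "C_w")


class UnknownModelError(ValueError):
    """Raised for MPT model names other than PCRM/DIM."""


@dataclass(frozen=True)
class ProbParams:
    """Process probabilities of the weapon-identification MPT models.

    All four values must lie strictly inside (0, 1).
    """

    A_b: float
    A_w: float
    C_b: float
    C_w: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v!r} must lie strictly in (0, 1)")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])

    @classmethod
    def from_array(cls, values: Iterable[float]) -> "ProbParams":
        return cls(*values)


#: Process probabilities used throughout the simulation studies.
DEFAULT_PROB_PARAMS = ProbParams(A_b=0.80, A_w=0.20, C_b=0.70, C_w=0.65)


@dataclass(frozen=True)
class MptBranch:
    """One root-to-leaf path of an MPT tree.

    ``factors`` lists (parameter name, use-complement) pairs whose product is
    the branch probability.  ``rt_component`` names the latent RT component
    the branch emits; ``label`` is the conventional process label (e.g. "Cg",
    "C+", "A").
    """

    tree: str
    factors: tuple[tuple[str, bool], ...]
    response: str
    rt_component: str
    label: str

    def probability(self, params: Mapping[str, float] | ProbParams) -> float:
        if isinstance(params, ProbParams):
            params = params.as_dict()
        p = 1.0
        for name, complement in self.factors:
            v = params[name]
            p *= (1.0 - v) if complement else v
        return p


@dataclass(frozen=True)
class MptStructure:
    """A named MPT model: a flat list of branches grouped by tree."""

    name: str
    branches: tuple[MptBranch, ...]

    @property
    def trees(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.branches:
            if b.tree not in seen:
                seen.append(b.tree)
        return tuple(seen)

    def branches_for(self, tree: str, response: str | None = None) -> tuple[MptBranch, ...]:
        return tuple(
            b
            for b in self.branches
            if b.tree == tree and (response is None or b.response == response)
        )

    def category_probabilities(self, params: ProbParams | Mapping[str, float]) -> pd.DataFrame:
        """P(response | tree) as a (trees x responses) table.

        Each entry is the sum over matching branches of the product of the
        branch's factor probabilities; rows sum to one by construction.
        """
        if not isinstance(params, ProbParams):
            params = ProbParams(**dict(params))
        pdict = params.as_dict()
        trees = self.trees
        pos = {t: i for i, t in enumerate(trees)}
        rpos = {r: i for i, r in enumerate(RESPONSES)}
        out = np.zeros((len(trees), len(RESPONSES)))
        for b in self.branches:
            out[pos[b.tree], rpos[b.response]] += b.probability(pdict)
        return pd.DataFrame(out, index=list(trees), columns=list(RESPONSES))


def _prime(tree: str) -> str:
    return "b" if tree.startswith("black") else "w"


def _pcrm_branches() -> tuple[MptBranch, ...]:
    branches: list[MptBranch] = []
    for tree in TREES:
        p = _prime(tree)
        A, C = f"A_{p}", f"C_{p}"
        if tree.endswith("gun"):
            # Successful control on a gun target: slow controlled response.
            branches.append(MptBranch(tree, ((C, False),), "gun", "slow", "Cg"))
        else:
            branches.append(MptBranch(tree, ((C, False),), "tool", "medium", "Ct"))
        # Control fails -> automatic process decides; A and 1-A sub-branches
        # share a single latency component (L_A = L_{1-A}).
        branches.append(MptBranch(tree, ((C, True), (A, False)), "gun", "fast", "A"))
        branches.append(MptBranch(tree, ((C, True), (A, True)), "tool", "fast", "1-A"))
    return tuple(branches)


def _dim_branches() -> tuple[MptBranch, ...]:
    branches: list[MptBranch] = []
    for tree in TREES:
        p = _prime(tree)
        A, C = f"A_{p}", f"C_{p}"
        target = "gun" if tree.endswith("gun") else "tool"
        # Automatic default "gun" (prob A) then controlled intervention (C)
        # forcing the correct response; congruent corrections (default equals
        # the target) are "medium", incongruent ones "slow".
        for default, a_comp in (("gun", False), ("tool", True)):
            congruent = default == target
            branches.append(
                MptBranch(
                    tree,
                    ((A, a_comp), (C, False)),
                    target,
                    "medium" if congruent else "slow",
                    "C+" if congruent else "C-",
                )
            )
            branches.append(
                MptBranch(tree, ((A, a_comp), (C, True)), default, "fast", "1-C")
            )
    return tuple(branches)


def build_model(name: str) -> MptStructure:
    """Return the PCRM or DIM tree structure.

    Raises :class:`UnknownModelError` for any other name.
    """
    key = name.upper()
    if key == "PCRM":
        return MptStructure("PCRM", _pcrm_branches())
    if key == "DIM":
        return MptStructure("DIM", _dim_branches())
    raise UnknownModelError(f"unknown MPT model {name!r}; expected 'PCRM' or 'DIM'")


def moment_prob_params(category_counts: Mapping[tuple[str, str], float]) -> ProbParams:
    """Crude closed-form starting values for the process probabilities.

    Both models share the category probabilities P(gun | gun tree) =
    A + C - AC and P(gun | tool tree) = A(1 - C), which invert to
    C = g1 - g2 and A = g2 / (1 - C).  Estimates are clipped away from the
    boundary; intended as an optimizer starting point, not an estimator.
    """
    theta: dict[str, float] = {}
    for p, (gt, tt) in {"b": ("black_gun", "black_tool"),
                        "w": ("white_gun", "white_tool")}.items():
        ng_g = category_counts.get((gt, "gun"), 0.0)
        nt_g = category_counts.get((gt, "tool"), 0.0)
        ng_t = category_counts.get((tt, "gun"), 0.0)
        nt_t = category_counts.get((tt, "tool"), 0.0)
        g1 = (ng_g + 0.5) / (ng_g + nt_g + 1.0)
        g2 = (ng_t + 0.5) / (ng_t + nt_t + 1.0)
        C = float(np.clip(g1 - g2, 0.02, 0.95))
        A = float(np.clip(g2 / (1.0 - C), 0.02, 0.98))
        theta[f"A_{p}"], theta[f"C_{p}"] = A, C
    return ProbParams(**theta)


def category_probabilities(
    model: MptStructure | str, params: ProbParams | Mapping[str, float]
) -> pd.DataFrame:
    """Convenience wrapper: P(response | tree) for a model name or structure."""
    if isinstance(model, str):
        model = build_model(model)
    return model.category_probabilities(params)
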