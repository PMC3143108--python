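"""Selection-scenario models and interval log-ratio scores.

A scenario (s, u, rho) rescales branch lengths of the neutral model:

* gain -- every branch inside the clade tau_u AND its parent edge (u_p, u)
  is multiplied by rho (the clade came under purifying selection);
* loss -- every branch outside tau_u and its parent edge is multiplied by
  rho (the clade and the branch into it drift while the rest is conserved);
* acceleration -- the parent edge (u_p, u) is divided by rho (faster than
  neutral substitution into the clade);
* conserved_all -- every branch is multiplied by rho (whole-tree
  conservation; its own type because the root has no parent edge).

The interval score S(i, j, s, u) is the sum over columns k = i..j of
log p(k; psi_{s,u,rho}) - log p(k; psi_neutral), maximized over a fixed rho
grid; smaller rho means stronger selection and ties break toward it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import CollapsedAlignment, PhyloModel

__all__ = [
    "GAIN",
    "LOSS",
    "ACC",
    "CONSERVED_ALL",
    "SELECTION_TYPES",
    "DEFAULT_RHO_GRID",
    "SelectionScenario",
    "build_scaled_model",
    "ScoreProfile",
    "interval_score",
]

GAIN = "gain"
LOSS = "loss"
ACC = "acc"
CONSERVED_ALL = "conserved_all"
SELECTION_TYPES = (GAIN, LOSS, ACC)

#: the fixed set of rho values the score is maximized over (user-overridable)
DEFAULT_RHO_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class SelectionScenario:
    """Selection type plus target clade; ``node_label`` is None for
    conserved_all (whole tree)."""

    stype: str
    node_label: str | None = None

    def __post_init__(self):
        if self.stype not in SELECTION_TYPES + (CONSERVED_ALL,):
            raise ValueError(f"unknown selection type {self.stype!r}")
        if self.stype == CONSERVED_ALL:
            object.__setattr__(self, "node_label", None)
        elif self.node_label is None:
            raise ValueError(f"{self.stype} scenario requires a target node")

    def __str__(self):
        return f"{self.stype}@{self.node_label or 'all'}"


def branch_scale_factors(
    tree, scenario: SelectionScenario, rho: float
) -> np.ndarray:
    """Per-node parent-edge multipliers realizing the scenario at ``rho``."""
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    factors = np.ones(tree.n_nodes)
    if scenario.stype == CONSERVED_ALL:
        factors[:] = rho
        factors[tree.root] = 1.0
        return factors
    u = tree.node_id(scenario.node_label)
    if u == tree.root:
        raise ValueError(f"{scenario.stype} target node may not be the root")
    sub = tree.subtree_nodes(u)
    if scenario.stype == GAIN:
        factors[sub] = rho
    elif scenario.stype == LOSS:
        # the clade AND its parent edge drift; only the remainder of the
        # tree is conserved (scaling the parent edge too would make loss at
        # a leaf indistinguishable from whole-tree conservation)
        factors[:] = rho
        factors[sub] = 1.0
        factors[tree.root] = 1.0
    elif scenario.stype == ACC:
        factors[u] = 1.0 / rho
        # At a degree-2 root the two root edges form a single unrooted
        # branch: acceleration on either root child rescales the whole
        # branch, which is what makes the two scenarios indistinguishable.
        p = int(tree.parent[u])
        if p == tree.root and len(tree.children[p]) == 2:
            for c in tree.children[p]:
                factors[c] = 1.0 / rho
    return factors


def build_scaled_model(
    neutral: PhyloModel, scenario: SelectionScenario, rho: float
) -> PhyloModel:
    """The scenario model psi_{s,u,rho}: rescaled branch lengths, Q and pi
    unchanged."""
    factors = branch_scale_factors(neutral.tree, scenario, rho)
    return neutral.with_tree(neutral.tree.scale_branches(factors))


class ScoreProfile:
    """Per-column log-ratio vectors for one scenario over the rho grid.

    ``ratios[r, k] = log p(k; psi_{s,u,rho_r}) - log p(k; psi_neutral)``.
    Prefix sums give O(1) interval sums.  All-missing columns contribute
    exactly 0 (log 1 - log 1).
    """

    def __init__(
        self,
        scenario: SelectionScenario,
        rho_grid,
        ratios: np.ndarray,
    ):
        self.scenario = scenario
        self.rho_grid = np.asarray(sorted(rho_grid), dtype=np.float64)
        self.ratios = np.asarray(ratios, dtype=np.float64)
        if self.ratios.shape[0] != len(self.rho_grid):
            raise ValueError("one ratio row per rho grid value required")
        self._csum: np.ndarray | None = None

    @classmethod
    def compute(
        cls,
        collapsed: CollapsedAlignment,
        neutral: PhyloModel,
        scenario: SelectionScenario,
        rho_grid=DEFAULT_RHO_GRID,
        neutral_pattern_ll: np.ndarray | None = None,
    ) -> "ScoreProfile":
        grid = sorted(rho_grid)
        if neutral_pattern_ll is None:
            neutral_pattern_ll = collapsed.pattern_log_likelihoods(neutral)
        ratios = np.empty((len(grid), collapsed.L))
        for r, rho in enumerate(grid):
            model = build_scaled_model(neutral, scenario, rho)
            pr = collapsed.pattern_log_likelihoods(model) - neutral_pattern_ll
            ratios[r] = pr[collapsed.inverse]
        return cls(scenario, grid, ratios)

    @property
    def L(self) -> int:
        return self.ratios.shape[1]

    @property
    def csum(self) -> np.ndarray:
        """(n_rho, L+1) prefix sums; computed lazily."""
        if self._csum is None:
            self._csum = np.concatenate(
                [np.zeros((self.ratios.shape[0], 1)), np.cumsum(self.ratios, axis=1)],
                axis=1,
            )
        return self._csum

    def interval_sums(self, start: int, end: int) -> np.ndarray:
        """Per-rho sums over the half-open column interval [start, end)."""
        return self.csum[:, end] - self.csum[:, start]

    def best_interval_score(self, start: int, end: int) -> tuple[float, float]:
        """(max-over-rho score, arg-max rho) for [start, end); rho ties break
        toward the smallest rho (strongest selection)."""
        sums = self.interval_sums(start, end)
        k = int(np.argmax(sums))  # grid ascending -> first max is smallest rho
        return float(sums[k]), float(self.rho_grid[k])


def interval_score(profile: ScoreProfile, i: int, j: int) -> tuple[float, float]:
    """S(i, j, s, u) over the inclusive column range i..j (0 <= i <= j < L),
    maximized over the rho grid; returns (score, best rho)."""
    if not 0 <= i <= j < profile.L:
        raise ValueError(f"need 0 <= i <= j < L, got i={i}, j={j}, L={profile.L}")
    return profile.best_interval_score(i, j + 1)
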