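"""Sequence-evolution simulator and the benchmark-grid generator.

Sites evolve independently under the substitution model (no indel process);
the root sequence is drawn from the equilibrium frequencies and each branch
applies its transition matrix.  Selected elements are simulated under the
scenario-scaled model and embedded at a uniform random offset inside a
neutral stretch twice the element length, flanked by 1000 further neutral
columns on each side.  Deletion (missing-data) structure of real alignments
can be copied onto simulated blocks from a template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import MISSING
from .model_io import AlignmentBlock
from .phylo import PhyloModel
from .scoring import (
    ACC,
    CONSERVED_ALL,
    SELECTION_TYPES,
    SelectionScenario,
    build_scaled_model,
)

__all__ = [
    "DEFAULT_FLANK",
    "SimulatedRegion",
    "SimulationGridSpec",
    "simulate_alignment",
    "simulate_block",
    "simulate_region",
    "apply_deletion_template",
]

#: neutral columns appended on each side of the embedding region
DEFAULT_FLANK = 1000

#: element lengths and scaling parameters of the benchmark grid
GRID_LENGTHS = (50, 100, 200, 500, 1000)
GRID_RHOS = (0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_alignment(model: PhyloModel, length: int, seed) -> np.ndarray:
    """Leaf sequences, (n_leaves, length) uint8 codes in tree leaf order.

    Fully reproducible: the same seed gives byte-identical output.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    tree = model.tree
    cum_pi = np.cumsum(model.pi)
    P = model.edge_transition_matrices()
    cumP = np.cumsum(P, axis=2)
    seqs = np.empty((tree.n_nodes, length), dtype=np.uint8)
    seqs[tree.root] = np.searchsorted(cum_pi, rng.random(length)).astype(np.uint8)
    for v in tree.postorder[::-1]:  # preorder: parents before children
        v = int(v)
        p = int(tree.parent[v])
        if p < 0:
            continue
        u = rng.random(length)
        seqs[v] = (u[:, None] > cumP[v][seqs[p]]).sum(axis=1).astype(np.uint8)
    return seqs[tree.leaf_ids]


def simulate_block(model: PhyloModel, length: int, seed, **kw) -> AlignmentBlock:
    codes = simulate_alignment(model, length, seed)
    return AlignmentBlock(model.tree.leaf_labels, codes, **kw)


@dataclass
class SimulatedRegion:
    """A simulated alignment with one embedded selected element."""

    block: AlignmentBlock
    truth_start: int
    truth_end: int
    scenario: SelectionScenario
    rho_star: float
    seed: int | None = None

    @property
    def truth_interval(self) -> tuple[int, int]:
        return (self.truth_start, self.truth_end)


def simulate_region(
    neutral: PhyloModel,
    scenario: SelectionScenario,
    rho_star: float,
    element_length: int,
    seed,
    flank: int = DEFAULT_FLANK,
    subtree_rho: float | None = None,
) -> SimulatedRegion:
    """One benchmark region: an element of ``element_length`` columns evolved
    under the scenario model at rho_star, placed uniformly at random inside a
    neutral region twice as long, with ``flank`` neutral columns on each
    side (total 2*m + 2*flank columns).

    ``subtree_rho`` additionally multiplies the branch lengths INSIDE the
    target clade (acceleration only): an accelerated element whose clade is
    internally conserved, the positive-selection signature.
    """
    if element_length < 1:
        raise ValueError("element_length must be >= 1")
    if not 0.0 < rho_star <= 1.0:
        raise ValueError(f"rho_star must be in (0, 1], got {rho_star}")
    rng = _rng(seed)
    m = element_length
    selected = build_scaled_model(neutral, scenario, rho_star)
    if subtree_rho is not None:
        if scenario.stype != ACC:
            raise ValueError("subtree_rho only applies to acceleration scenarios")
        tree = selected.tree
        u = tree.node_id(scenario.node_label)
        factors = np.ones(tree.n_nodes)
        interior = [v for v in tree.subtree_nodes(u) if v != u]
        factors[interior] = subtree_rho
        selected = selected.with_tree(tree.scale_branches(factors))
    total = 2 * m + 2 * flank
    codes = simulate_alignment(neutral, total, rng)
    element = simulate_alignment(selected, m, rng)
    offset = int(rng.integers(0, m + 1))
    start = flank + offset
    codes[:, start : start + m] = element
    block = AlignmentBlock(neutral.tree.leaf_labels, codes)
    return SimulatedRegion(
        block, start, start + m, scenario, rho_star,
        seed if isinstance(seed, int) else None,
    )


def apply_deletion_template(
    block: AlignmentBlock, template: AlignmentBlock, seed
) -> AlignmentBlock:
    """Copy the missing-data mask of ``template`` onto ``block``.

    The mask is read column-block-wise starting at a random template offset
    (wrapping around), so long simulated blocks inherit the template's
    per-species deletion structure and coverage fractions.
    """
    if set(block.species) != set(template.species):
        raise ValueError("template species set differs from block species set")
    rng = _rng(seed)
    order = [template.species.index(sp) for sp in block.species]
    mask = template.codes[order] == MISSING
    off = int(rng.integers(0, template.L))
    idx = (off + np.arange(block.L)) % template.L
    out = block.codes.copy()
    out[mask[:, idx]] = MISSING
    return AlignmentBlock(
        block.species, out, ref_name=block.ref_name,
        ref_start=block.ref_start, strand=block.strand, ref_row=block.ref_row,
    )


@dataclass
class SimulationGridSpec:
    """The benchmark grid: which (type, node, length, rho) cells to simulate
    and how many replicate regions per cell."""

    lengths: tuple = GRID_LENGTHS
    rhos: tuple = GRID_RHOS
    replicates: int = 100
    types: tuple = SELECTION_TYPES
    node_labels: tuple | None = None  # None -> all non-root nodes
    include_conserved_all: bool = True
    flank: int = DEFAULT_FLANK

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for r in self.rhos:
            if not 0.0 < r < 1.0:
                raise ValueError(f"grid rho must be in (0, 1), got {r}")

    def scenarios(self, tree) -> list[SelectionScenario]:
        if self.node_labels is None:
            labels = [tree.labels[v] for v in range(tree.n_nodes) if v != tree.root]
        else:
            labels = list(self.node_labels)
        out = [SelectionScenario(s, lab) for s in self.types for lab in labels]
        if self.include_conserved_all:
            out.append(SelectionScenario(CONSERVED_ALL))
        return out

    def cells(self, tree):
        """Iterate (scenario, length, rho) cells of the grid."""
        for sc in self.scenarios(tree):
            for m in self.lengths:
                for rho in self.rhos:
                    yield sc, m, rho
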