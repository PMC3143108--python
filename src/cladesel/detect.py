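"""The greedy detector: maximal-scoring regions per (selection type, clade).

For every scenario the per-column log-ratio profile is scanned once per rho
(linear time); maximal positive segments above the calibrated threshold
become candidates; candidates containing a sub-region that significantly
deviates from the selection model are split (the anti-clustering rule);
overlaps across scenarios are resolved greedily by score; acceleration at
either child of a degree-2 root is reported once as an ambiguous pair; and
accelerated elements whose clade is internally conserved are flagged as
positive-selection candidates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._segments import greedy_nonoverlap, maximal_segments
from .phylo import CollapsedAlignment, PhyloModel, PhyloTree
from .scoring import (
    ACC,
    CONSERVED_ALL,
    DEFAULT_RHO_GRID,
    GAIN,
    LOSS,
    SELECTION_TYPES,
    ScoreProfile,
    SelectionScenario,
)

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MIN_LENGTH",
    "PredictedElement",
    "ThresholdTable",
    "enumerate_scenarios",
    "find_candidate_regions",
    "resolve_overlaps",
    "collapse_root_symmetry",
    "flag_ps_candidates",
    "detect_elements",
]

#: smallest reported element, in alignment columns (user-overridable)
DEFAULT_MIN_LENGTH = 50

_TYPE_ORDER = {GAIN: 0, LOSS: 1, ACC: 2, CONSERVED_ALL: 3}


@dataclass
class PredictedElement:
    """Half-open column interval predicted under a scenario."""

    start: int
    end: int
    scenario: SelectionScenario
    rho: float
    score: float
    suppressed_by_overlap: bool = False
    ambiguous_root_pair: bool = False
    clades: tuple[str, ...] = ()
    ps_candidate: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "PredictedElement") -> bool:
        return self.start < other.end and other.start < self.end


class ThresholdTable:
    """Per-(selection type, node) score thresholds plus the sub-region
    deviation thresholds used by the anti-clustering rule."""

    def __init__(
        self,
        thresholds: dict[tuple[str, str | None], float],
        dev_factor: float = 1.0,
        min_sub_length: int = DEFAULT_MIN_LENGTH,
        metadata: dict | None = None,
    ):
        for v in thresholds.values():
            if not v > 0:
                raise ValueError("thresholds must be positive")
        self.thresholds = dict(thresholds)
        self.dev_factor = float(dev_factor)
        self.min_sub_length = int(min_sub_length)
        self.metadata = dict(metadata or {})

    def get(self, scenario: SelectionScenario) -> float:
        return self.thresholds[(scenario.stype, scenario.node_label)]

    def deviation(self, scenario: SelectionScenario) -> float:
        """Sub-region 'significant deviation from selection' threshold."""
        return self.dev_factor * self.get(scenario)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "thresholds": [
                {"type": s, "node": u, "threshold": t}
                for (s, u), t in sorted(self.thresholds.items(), key=str)
            ],
            "dev_factor": self.dev_factor,
            "min_sub_length": self.min_sub_length,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdTable":
        obj = json.loads(Path(path).read_text())
        thr = {(d["type"], d["node"]): d["threshold"] for d in obj["thresholds"]}
        return cls(thr, obj["dev_factor"], obj["min_sub_length"], obj["metadata"])


def enumerate_scenarios(
    tree: PhyloTree,
    types=SELECTION_TYPES,
    include_conserved_all: bool = True,
) -> list[SelectionScenario]:
    """All (type, node) scenarios: every non-root node for each lineage-
    specific type, plus whole-tree conservation."""
    out = []
    for stype in types:
        for v in range(tree.n_nodes):
            if v != tree.root:
                out.append(SelectionScenario(stype, tree.labels[v]))
    if include_conserved_all:
        out.append(SelectionScenario(CONSERVED_ALL))
    return out


def merged_segments(
    profile: ScoreProfile, min_len: int, min_score: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Maximal segments of one scenario merged across the rho grid.

    Each rho row is scanned once; overlapping segments from different rho
    values collapse to the best-scoring one; survivors are re-scored over
    the whole grid (arg-max rho, ties toward the smallest).  Returns
    (starts, ends, scores, rhos) sorted by start.
    """
    sts, ens, scs = [], [], []
    for r in range(len(profile.rho_grid)):
        st, en, sc = maximal_segments(profile.ratios[r], min_len, min_score)
        sts.append(st)
        ens.append(en)
        scs.append(sc)
    st = np.concatenate(sts)
    en = np.concatenate(ens)
    sc = np.concatenate(scs)
    if len(st) == 0:
        return st, en, sc, sc
    keep = greedy_nonoverlap(st, en, sc, profile.L)
    st, en = st[keep], en[keep]
    sums = profile.csum[:, en] - profile.csum[:, st]  # (n_rho, K)
    best = np.argmax(sums, axis=0)  # first max = smallest rho
    scores = sums[best, np.arange(len(st))]
    rhos = profile.rho_grid[best]
    order = np.argsort(st)
    return st[order], en[order], scores[order], rhos[order]


def find_candidate_regions(
    profile: ScoreProfile,
    thresholds: ThresholdTable | None = None,
    min_len: int = DEFAULT_MIN_LENGTH,
    anti_clustering: bool = True,
) -> list[PredictedElement]:
    """Maximal-scoring candidate intervals for one scenario.

    One linear scan per rho grid value finds maximal positive segments;
    overlapping segments from different rho values are merged keeping the
    best; each survivor is re-scored over the whole grid (arg-max rho, ties
    toward the smallest) and, when ``anti_clustering`` is set, recursively
    split wherever it contains a sub-region of length >= min_sub whose
    NEGATED score (evidence of neutrality or of selection of another type)
    exceeds the deviation threshold.
    """
    profile_threshold = 0.0
    min_sub = min_len
    if thresholds is not None:
        profile_threshold = thresholds.get(profile.scenario)
        min_sub = thresholds.min_sub_length

    st, en, _sc, _rho = merged_segments(profile, min_len, profile_threshold)

    out: list[PredictedElement] = []
    stack = sorted(zip(st.tolist(), en.tolist()))
    while stack:
        s, e = stack.pop()
        if e - s < min_len:
            continue
        score, rho = profile.best_interval_score(s, e)
        if score <= profile_threshold:
            continue
        if anti_clustering and thresholds is not None:
            r_idx = int(np.searchsorted(profile.rho_grid, rho))
            neg = -profile.ratios[r_idx, s:e]
            dst, den, dsc = maximal_segments(neg, min_sub, 0.0)
            if len(dsc) and dsc.max() > thresholds.deviation(profile.scenario):
                k = int(np.argmax(dsc))
                a, b = s + int(dst[k]), s + int(den[k])
                # discard the deviating core, re-examine the flanks
                if a - s >= min_len:
                    stack.append((s, a))
                if e - b >= min_len:
                    stack.append((b, e))
                continue
        out.append(PredictedElement(s, e, profile.scenario, rho, score))
    out.sort(key=lambda el: el.start)
    return out


def resolve_overlaps(candidates: list[PredictedElement]) -> list[PredictedElement]:
    """Greedy overlap resolution: accept candidates in order of descending
    score (ties: longer interval, smaller start, type order gain < loss <
    acc < conserved_all); a candidate overlapping an accepted element is
    retained but flagged ``suppressed_by_overlap``."""
    order = sorted(
        candidates,
        key=lambda el: (
            -el.score,
            -(el.end - el.start),
            el.start,
            _TYPE_ORDER[el.scenario.stype],
            el.scenario.node_label or "",
        ),
    )
    accepted: list[PredictedElement] = []
    out = []
    for el in order:
        el = replace(el)
        el.suppressed_by_overlap = any(el.overlaps(a) for a in accepted)
        if not el.suppressed_by_overlap:
            accepted.append(el)
        out.append(el)
    out.sort(key=lambda el: (el.start, el.end))
    return out


def collapse_root_symmetry(
    elements: list[PredictedElement], tree: PhyloTree, tol: float = 1e-6
) -> list[PredictedElement]:
    """Report acceleration at either child of a degree-2 root once, flagged
    with both clade labels (the two parent edges form a single unrooted
    branch, so the scores are identical)."""
    root_children = [tree.labels[c] for c in tree.children[tree.root]]
    if len(root_children) != 2:
        log.info("root degree != 2; root-symmetry collapse is a no-op")
        return elements
    pair = tuple(sorted(root_children))
    by_key: dict[tuple[int, int], PredictedElement] = {}
    out: list[PredictedElement] = []
    for el in elements:
        amb = el.scenario.stype == ACC and el.scenario.node_label in root_children
        if not amb:
            out.append(el)
            continue
        key = (el.start, el.end)
        prev = by_key.get(key)
        if prev is not None:
            if abs(prev.score - el.score) > tol:
                raise AssertionError(
                    f"root-child acceleration scores differ: {prev.score} vs {el.score}"
                )
            # drop the duplicate; keep the suppressed twin out of the output
            continue
        el = replace(el, ambiguous_root_pair=True, clades=pair)
        by_key[key] = el
        out.append(el)
    out.sort(key=lambda el: (el.start, el.end))
    return out


def flag_ps_candidates(
    elements: list[PredictedElement],
    collapsed: CollapsedAlignment,
    neutral: PhyloModel,
    thresholds: ThresholdTable,
    rho_grid=DEFAULT_RHO_GRID,
) -> list[PredictedElement]:
    """Flag accelerated elements whose clade is internally conserved.

    The likelihood is recomputed on the element's columns with every species
    outside the clade masked as missing; if the whole-tree conservation
    score of that masked alignment exceeds the conserved_all threshold the
    element is a positive-selection candidate.  For a single-leaf clade
    internal conservation is undefined; instead the element must NOT look
    like a loss at that leaf (loss score below its threshold).
    """
    from .alphabet import MISSING

    tree = neutral.tree
    ca_thr = thresholds.thresholds.get((CONSERVED_ALL, None))
    out = []
    for el in elements:
        if el.scenario.stype != ACC or el.suppressed_by_overlap:
            out.append(el)
            continue
        el = replace(el)
        targets = el.clades if el.ambiguous_root_pair else (el.scenario.node_label,)
        flag = False
        for lab in targets:
            u = tree.node_id(lab)
            leaves = set(tree.leaves_under(u).tolist())
            codes = collapsed.patterns[collapsed.inverse[el.start : el.end]].T.copy()
            if len(leaves) == 1:
                prof = ScoreProfile.compute(
                    CollapsedAlignment(codes), neutral,
                    SelectionScenario(LOSS, lab), rho_grid,
                )
                s, _ = prof.best_interval_score(0, prof.L)
                flag |= s < thresholds.thresholds[(LOSS, lab)]
            else:
                if ca_thr is None:
                    continue
                mask = np.array(
                    [int(v) not in leaves for v in tree.leaf_ids], dtype=bool
                )
                codes[mask, :] = MISSING
                prof = ScoreProfile.compute(
                    CollapsedAlignment(codes), neutral,
                    SelectionScenario(CONSERVED_ALL), rho_grid,
                )
                s, _ = prof.best_interval_score(0, prof.L)
                flag |= s > ca_thr
        el.ps_candidate = flag
        out.append(el)
    return out


def detect_elements(
    codes: np.ndarray,
    neutral: PhyloModel,
    thresholds: ThresholdTable,
    rho_grid=DEFAULT_RHO_GRID,
    min_len: int = DEFAULT_MIN_LENGTH,
    scenarios: list[SelectionScenario] | None = None,
    flag_ps: bool = True,
) -> list[PredictedElement]:
    """End-to-end detection on an alignment (codes in tree leaf order)."""
    collapsed = CollapsedAlignment(codes)
    neutral_ll = collapsed.pattern_log_likelihoods(neutral)
    if scenarios is None:
        scenarios = enumerate_scenarios(neutral.tree)
    candidates: list[PredictedElement] = []
    for sc in scenarios:
        if (sc.stype, sc.node_label) not in thresholds.thresholds:
            continue
        profile = ScoreProfile.compute(
            collapsed, neutral, sc, rho_grid, neutral_pattern_ll=neutral_ll
        )
        candidates.extend(
            find_candidate_regions(profile, thresholds, min_len=min_len)
        )
    elements = resolve_overlaps(candidates)
    elements = collapse_root_symmetry(elements, neutral.tree)
    if flag_ps:
        elements = flag_ps_candidates(
            elements, collapsed, neutral, thresholds, rho_grid
        )
    return elements
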