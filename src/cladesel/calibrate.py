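"""Threshold calibration on neutral simulations and site-level evaluation.

Thresholds are set so that detection applied back to neutral data covers
fewer than the target fraction of columns (the false-positive rate, measured
per column).  The global column budget is shared equally across scenarios
and each per-(type, node) threshold is placed by an exponential tail fit to
that scenario's maximal-segment scores on the calibration data -- segment
score tails are asymptotically exponential (Karlin-Altschul), so the fit
extrapolates a little beyond the observed maximum instead of sitting exactly
on it.  Half the nominal budget is targeted, absorbing tail-estimation error.

Evaluation uses the site-level accuracy metric: the arithmetic mean of
precision (predicted columns that are truly selected, with matching type and
clade) and recall (truly selected columns recovered).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import (
    DEFAULT_MIN_LENGTH,
    PredictedElement,
    ThresholdTable,
    detect_elements,
    enumerate_scenarios,
    merged_segments,
)
from .phylo import CollapsedAlignment, PhyloModel
from .scoring import ACC, DEFAULT_RHO_GRID, ScoreProfile, SelectionScenario
from .simulate import SimulationGridSpec, simulate_alignment, simulate_region

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TARGET_FPR",
    "EvaluationResult",
    "calibrate_thresholds",
    "measure_neutral_fpr",
    "evaluate_sites",
    "run_benchmark",
    "benchmark_table",
]

#: the calibration target: fraction of neutral columns inside called elements
DEFAULT_TARGET_FPR = 1e-3

#: share of the nominal column budget actually targeted (tail-fit safety)
_BUDGET_SAFETY = 0.5


def _scenario_segments(profile: ScoreProfile, min_len: int):
    """Merged-across-rho maximal segments of a neutral profile, with
    best-over-grid scores; short segments are kept too (they feed the tail
    fit even though only length >= min_len segments are ever called)."""
    st, en, scores, _rhos = merged_segments(profile, 1, 0.0)
    return scores, en - st


def _tail_threshold(
    scores: np.ndarray,
    lengths: np.ndarray,
    min_len: int,
    budget_cols: float,
) -> float:
    """Smallest threshold whose expected neutral coverage on independent
    data of the same size stays within ``budget_cols`` columns.

    Each observed segment is treated as an exchangeable draw whose held-out
    counterpart exceeds a threshold t with probability exp(-lambda (t - s))
    (exponential score tail); its own length weights the coverage it would
    cost.  Weak scenarios produce few but very LONG maximal segments, so a
    count-based budget would under-protect exactly there."""
    callable_ = lengths >= min_len
    called = scores[callable_]
    clens = lengths[callable_].astype(float)
    all_sorted = np.sort(scores)[::-1]

    def lam_of(vals_desc: np.ndarray) -> float:
        m = min(len(vals_desc), 200)
        top = vals_desc[:m]
        return 1.0 / max(float(np.mean(top - top[-1])), 1e-9)

    if len(called) >= 10:
        lam = lam_of(np.sort(called)[::-1])

        def expected_coverage(t: float) -> float:
            return float(np.sum(clens * np.exp(-lam * np.maximum(t - called, 0.0))))

        lo = float(called.max())
        hi = lo + 80.0 / lam
        if expected_coverage(lo) <= budget_cols:
            # even calling every observed-level segment is within budget;
            # still never place the threshold below the observed maximum
            return lo
        if expected_coverage(hi) > budget_cols:  # pragma: no cover
            return hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if expected_coverage(mid) > budget_cols:
                lo = mid
            else:
                hi = mid
        return hi
    if len(all_sorted) >= 5:
        # scenario with (almost) no callable neutral segments: require any
        # future call to beat every segment of any length, with a margin
        lam = lam_of(all_sorted)
        base = float(all_sorted[0]) if len(called) == 0 else float(called.max())
        return max(base, float(all_sorted[0])) + 3.0 / lam
    if len(all_sorted):
        return float(all_sorted[0]) * 2.0 + 1.0
    return 1.0


def calibrate_thresholds(
    neutral_codes: np.ndarray,
    model: PhyloModel,
    target_fpr: float = DEFAULT_TARGET_FPR,
    scenarios: list[SelectionScenario] | None = None,
    rho_grid=DEFAULT_RHO_GRID,
    min_len: int = DEFAULT_MIN_LENGTH,
    metadata: dict | None = None,
) -> ThresholdTable:
    """Per-(type, node) thresholds targeting a global column-level FPR.

    ``neutral_codes`` is a neutral simulation (or concatenation of neutral
    blocks) in tree leaf order.  The deviation thresholds of the
    anti-clustering rule reuse the main thresholds (calibration itself runs
    without anti-clustering, which is the conservative direction).
    """
    L = neutral_codes.shape[1]
    if L < 10.0 / target_fpr:
        raise ValueError(
            f"neutral simulation too short for target_fpr={target_fpr}: "
            f"need >= {int(10.0 / target_fpr)} columns, got {L}"
        )
    if scenarios is None:
        scenarios = enumerate_scenarios(model.tree)
    collapsed = CollapsedAlignment(neutral_codes)
    neutral_ll = collapsed.pattern_log_likelihoods(model)
    budget = _BUDGET_SAFETY * target_fpr * L / len(scenarios)
    thresholds: dict[tuple[str, str | None], float] = {}
    for sc in scenarios:
        profile = ScoreProfile.compute(
            collapsed, model, sc, rho_grid, neutral_pattern_ll=neutral_ll
        )
        scores, lens = _scenario_segments(profile, min_len)
        thresholds[(sc.stype, sc.node_label)] = _tail_threshold(
            scores, lens, min_len, budget
        )
    meta = {
        "neutral_columns": int(L),
        "target_fpr": float(target_fpr),
        "rho_grid": list(rho_grid),
        "min_length": int(min_len),
        "tree": model.tree.to_newick(),
        **(metadata or {}),
    }
    return ThresholdTable(thresholds, dev_factor=1.0, min_sub_length=min_len, metadata=meta)


def measure_neutral_fpr(
    neutral_codes: np.ndarray,
    model: PhyloModel,
    thresholds: ThresholdTable,
    rho_grid=DEFAULT_RHO_GRID,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> float:
    """Column-level FPR: fraction of neutral columns covered by predicted
    (primary) elements of the full detector."""
    elements = detect_elements(
        neutral_codes, model, thresholds, rho_grid, min_len, flag_ps=False
    )
    L = neutral_codes.shape[1]
    covered = np.zeros(L, dtype=bool)
    for el in elements:
        if not el.suppressed_by_overlap:
            covered[el.start : el.end] = True
    return float(covered.mean())


def neutral_fpr_experiment(
    model: PhyloModel,
    n_columns: int,
    seed: int,
    target_fpr: float = DEFAULT_TARGET_FPR,
    rho_grid=DEFAULT_RHO_GRID,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> tuple[float, ThresholdTable]:
    """The calibration protocol end to end: simulate two independent neutral
    alignments of ``n_columns``, calibrate thresholds on the first, run full
    detection on the second, and return (held-out column FPR, thresholds)."""
    ss = np.random.SeedSequence(seed)
    s_cal, s_test = ss.spawn(2)
    codes_cal = simulate_alignment(model, n_columns, np.random.default_rng(s_cal))
    thresholds = calibrate_thresholds(
        codes_cal, model, target_fpr, rho_grid=rho_grid, min_len=min_len,
        metadata={"seed": int(seed)},
    )
    del codes_cal
    codes_test = simulate_alignment(model, n_columns, np.random.default_rng(s_test))
    fpr = measure_neutral_fpr(
        codes_test, model, thresholds, rho_grid=rho_grid, min_len=min_len
    )
    return fpr, thresholds


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvaluationResult:
    """Site counts and the derived precision/recall/accuracy."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def accuracy(self) -> float:
        return 0.5 * (self.precision + self.recall)


def _scenario_matches(pred: SelectionScenario, truth: SelectionScenario, tree) -> bool:
    if pred.stype != truth.stype:
        return False
    if pred.node_label == truth.node_label:
        return True
    if pred.stype == ACC:
        # accelerations at the two children of a degree-2 root are one and
        # the same unrooted event; either label matches
        rc = tree.children[tree.root]
        if len(rc) == 2:
            labels = {tree.labels[c] for c in rc}
            return pred.node_label in labels and truth.node_label in labels
    return False


def evaluate_sites(
    predicted: list[PredictedElement],
    truths: list[tuple[int, int, SelectionScenario]],
    L: int,
    tree,
) -> EvaluationResult:
    """Site-level confusion counts for one alignment.

    A truth column is TP when covered by a primary prediction whose type and
    clade match; every other predicted column is FP and every other truth
    column FN.
    """
    pred_any = np.zeros(L, dtype=bool)
    matched = np.zeros(L, dtype=bool)
    truth_mask = np.zeros(L, dtype=bool)
    for ts, te, _sc in truths:
        truth_mask[ts:te] = True
    for el in predicted:
        if el.suppressed_by_overlap:
            continue
        pred_any[el.start : el.end] = True
        for ts, te, tsc in truths:
            if _scenario_matches(el.scenario, tsc, tree):
                a, b = max(el.start, ts), min(el.end, te)
                if a < b:
                    matched[a:b] = True
    tp = int((matched & truth_mask).sum())
    fp = int(pred_any.sum() - (pred_any & matched & truth_mask).sum())
    fn = int(truth_mask.sum() - tp)
    return EvaluationResult(tp, fp, fn)


def run_benchmark(
    grid: SimulationGridSpec,
    model: PhyloModel,
    thresholds: ThresholdTable,
    seed: int,
    rho_grid=DEFAULT_RHO_GRID,
    min_len: int = DEFAULT_MIN_LENGTH,
) -> pd.DataFrame:
    """Simulate every grid cell, run full detection, and tabulate pooled
    site-level precision/recall/accuracy per (type, node, length, rho)."""
    if thresholds.metadata.get("tree") not in (None, model.tree.to_newick()):
        raise ValueError("thresholds were calibrated against a different tree")
    ss = np.random.SeedSequence(seed)
    rows = []
    scenarios = enumerate_scenarios(model.tree)
    for sc, m, rho in grid.cells(model.tree):
        cell_key = zlib.crc32(
            f"{sc.stype}|{sc.node_label}|{m}|{rho}".encode()
        ) & 0x7FFFFFFF
        cell_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=ss.entropy, spawn_key=(cell_key,))
        )
        tp = fp = fn = 0
        for _rep in range(grid.replicates):
            region = simulate_region(model, sc, rho, m, cell_rng, flank=grid.flank)
            codes = region.block.codes
            elements = detect_elements(
                codes, model, thresholds, rho_grid, min_len,
                scenarios=scenarios, flag_ps=False,
            )
            res = evaluate_sites(
                elements,
                [(region.truth_start, region.truth_end, sc)],
                codes.shape[1],
                model.tree,
            )
            tp += res.tp
            fp += res.fp
            fn += res.fn
        res = EvaluationResult(tp, fp, fn)
        rows.append(
            {
                "type": sc.stype,
                "node": sc.node_label or "all",
                "length": m,
                "rho": rho,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "precision": res.precision,
                "recall": res.recall,
                "accuracy": res.accuracy,
            }
        )
    return pd.DataFrame(rows)


def benchmark_table(results: pd.DataFrame) -> pd.DataFrame:
    """Clade-averaged accuracy table: rows = (type, rho), columns = element
    lengths, accuracies as percentages (whole-tree conservation reported as
    its own section)."""
    df = results.copy()
    avg = (
        df.groupby(["type", "rho", "length"])["accuracy"].mean().reset_index()
    )
    table = avg.pivot(index=["type", "rho"], columns="length", values="accuracy")
    return (100.0 * table).round(1)
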