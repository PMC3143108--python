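"""Detector behavior: candidate search, anti-clustering, overlap
resolution, root symmetry, positive-selection flagging."""

import numpy as np
import pytest

import cladesel as cs
from cladesel.detect import (
    PredictedElement,
    ThresholdTable,
    collapse_root_symmetry,
    find_candidate_regions,
    flag_ps_candidates,
    resolve_overlaps,
)
from cladesel.phylo import CollapsedAlignment
from cladesel.scoring import ACC, GAIN, LOSS, ScoreProfile, SelectionScenario


def _el(start, end, stype="gain", node="apes", score=5.0):
    return PredictedElement(start, end, SelectionScenario(stype, node), 0.1, score)


# ---------------------------------------------------------------- candidates


def test_neutral_block_yields_no_elements(primate_model, thresholds_200k):
    codes = cs.simulate_alignment(primate_model, 30_000, seed=77)
    elements = cs.detect_elements(
        codes, primate_model, thresholds_200k, flag_ps=False
    )
    primary = [e for e in elements if not e.suppressed_by_overlap]
    covered = sum(e.length for e in primary)
    assert covered <= 0.002 * 30_000


def test_embedded_element_recovered(primate_model, thresholds_200k):
    """A 200-column clade-conservation element in neutral flanks is found
    by a matching-type primary prediction covering most of the truth."""
    sc = SelectionScenario(GAIN, "simians")
    hits = 0
    for rep in range(20):
        reg = cs.simulate_region(primate_model, sc, 0.1, 200, seed=300 + rep)
        elements = cs.detect_elements(
            reg.block.codes, primate_model, thresholds_200k, flag_ps=False
        )
        for el in elements:
            if el.suppressed_by_overlap or el.scenario.stype != GAIN:
                continue
            ov = min(el.end, reg.truth_end) - max(el.start, reg.truth_start)
            if ov >= 0.9 * 200:
                hits += 1
                break
    assert hits >= 14


def test_primary_elements_pairwise_disjoint_and_above_threshold(
    primate_model, thresholds_200k
):
    reg = cs.simulate_region(
        primate_model, SelectionScenario(LOSS, "catarrhini"), 0.2, 500, seed=31
    )
    elements = cs.detect_elements(
        reg.block.codes, primate_model, thresholds_200k, flag_ps=False
    )
    primary = sorted(
        (e for e in elements if not e.suppressed_by_overlap), key=lambda e: e.start
    )
    assert primary, "expected at least one detection"
    for a, b in zip(primary[:-1], primary[1:]):
        assert a.end <= b.start
    for el in primary:
        assert el.length >= 50
        assert el.score > thresholds_200k.get(el.scenario)


def test_anti_clustering_splits_on_deviating_subregion():
    """A candidate containing a long stretch of strong contrary evidence is
    split rather than reported as one merged element."""
    ratios = np.concatenate(
        [np.full(200, 0.5), np.full(300, -1.0 / 6), np.full(200, 0.5)]
    )[None, :]
    prof = ScoreProfile(SelectionScenario(GAIN, "apes"), (0.1,), ratios)
    thr = ThresholdTable({(GAIN, "apes"): 20.0}, min_sub_length=50)
    got = find_candidate_regions(prof, thr, min_len=50)
    assert [(e.start, e.end) for e in got] == [(0, 200), (500, 700)]
    # without the rule, the single merged segment would win
    free = find_candidate_regions(prof, None, min_len=50)
    assert [(e.start, e.end) for e in free] == [(0, 700)]


def test_two_conserved_elements_never_merge_across_accelerated_gap(
    primate_model, thresholds_200k
):
    """Simulated: conserved - strongly accelerated - conserved, same clade."""
    sc_g = SelectionScenario(GAIN, "catarrhini")
    sc_a = SelectionScenario(ACC, "catarrhini")
    rng = np.random.default_rng(55)
    g1 = cs.simulate_alignment(cs.build_scaled_model(primate_model, sc_g, 0.05), 400, rng)
    mid = cs.simulate_alignment(cs.build_scaled_model(primate_model, sc_a, 0.05), 300, rng)
    g2 = cs.simulate_alignment(cs.build_scaled_model(primate_model, sc_g, 0.05), 400, rng)
    flank = cs.simulate_alignment(primate_model, 1000, rng)
    flank2 = cs.simulate_alignment(primate_model, 1000, rng)
    codes = np.concatenate([flank, g1, mid, g2, flank2], axis=1)
    elements = cs.detect_elements(
        codes, primate_model, thresholds_200k, flag_ps=False
    )
    gains = [
        e for e in elements
        if not e.suppressed_by_overlap and e.scenario == sc_g
    ]
    assert len(gains) >= 2, "expected both gain elements detected"
    for el in gains:
        # no gain element spans the accelerated stretch [1400, 1700)
        ov = min(el.end, 1700) - max(el.start, 1400)
        assert ov < 150


# ------------------------------------------------------------------ overlaps


def test_overlap_keeps_maximum_scoring_region():
    a, b = _el(10, 60, score=10.0), _el(10, 60, "loss", "owm", score=7.0)
    out = resolve_overlaps([a, b])
    primary = [e for e in out if not e.suppressed_by_overlap]
    assert len(primary) == 1 and primary[0].score == 10.0
    assert sum(e.suppressed_by_overlap for e in out) == 1


def test_disjoint_candidates_all_primary():
    out = resolve_overlaps([_el(0, 60), _el(60, 120), _el(200, 260)])
    assert not any(e.suppressed_by_overlap for e in out)


def test_overlap_chain_resolved_greedily():
    a = _el(0, 100, score=9.0)
    b = _el(50, 150, score=8.0)
    c = _el(140, 240, score=7.0)
    out = resolve_overlaps([a, b, c])
    by_start = {e.start: e.suppressed_by_overlap for e in out}
    assert by_start == {0: False, 50: True, 140: False}


def test_overlap_ties_prefer_longer_then_earlier():
    short = _el(100, 160, score=5.0)
    long_ = _el(90, 170, "loss", "owm", score=5.0)
    out = resolve_overlaps([short, long_])
    primary = [e for e in out if not e.suppressed_by_overlap][0]
    assert (primary.start, primary.end) == (90, 170)
    e1 = _el(0, 60, score=5.0)
    e2 = _el(30, 90, score=5.0)
    out = resolve_overlaps([e1, e2])
    primary = [e for e in out if not e.suppressed_by_overlap][0]
    assert primary.start == 0


# ------------------------------------------------------------- root symmetry


def test_acceleration_profiles_identical_at_root_children(primate_model):
    codes = cs.simulate_alignment(primate_model, 3000, seed=21)
    ca = CollapsedAlignment(codes)
    p1 = ScoreProfile.compute(ca, primate_model, SelectionScenario(ACC, "simians"))
    p2 = ScoreProfile.compute(ca, primate_model, SelectionScenario(ACC, "prosimians"))
    np.testing.assert_allclose(p1.ratios, p2.ratios, atol=1e-6)


def test_root_symmetry_collapse(primate_model):
    tree = primate_model.tree
    a = _el(0, 100, ACC, "simians", score=12.0)
    b = _el(0, 100, ACC, "prosimians", score=12.0)
    other = _el(200, 300, ACC, "owm", score=8.0)
    out = collapse_root_symmetry([a, b, other], tree)
    assert len(out) == 2
    amb = [e for e in out if e.ambiguous_root_pair]
    assert len(amb) == 1
    assert amb[0].clades == ("prosimians", "simians")
    assert not [e for e in out if e.scenario.node_label == "owm"][0].ambiguous_root_pair
    # score mismatch between the twins is a bug worth failing loudly on
    b_bad = _el(0, 100, ACC, "prosimians", score=11.0)
    with pytest.raises(AssertionError):
        collapse_root_symmetry([a, b_bad], tree)


def test_root_symmetry_noop_for_nonbinary_root(caplog):
    mod = cs.load_default_model()
    tree = cs.PhyloTree.from_newick("(A:0.1,B:0.1,C:0.1);")
    els = [_el(0, 100, ACC, "A", score=3.0)]
    out = collapse_root_symmetry(els, tree)
    assert out == els


# ------------------------------------------------------------------ PS flags


def test_ps_flag_set_for_internally_conserved_acceleration(
    primate_model, thresholds_200k
):
    """Acceleration with a conserved clade interior is flagged; plain
    acceleration over a neutral interior is not (statistical, matched
    replicates)."""
    sc = SelectionScenario(ACC, "catarrhini")
    counts = {True: [0, 0], False: [0, 0]}  # is_conserved -> [found, flagged]
    for rep in range(12):
        for subtree_rho, is_cons in ((0.1, True), (None, False)):
            reg = cs.simulate_region(
                primate_model, sc, 0.05, 800, seed=700 + rep, subtree_rho=subtree_rho
            )
            elements = cs.detect_elements(
                reg.block.codes, primate_model, thresholds_200k
            )
            for el in elements:
                if el.suppressed_by_overlap or el.scenario.stype != ACC:
                    continue
                if min(el.end, reg.truth_end) - max(el.start, reg.truth_start) > 400:
                    counts[is_cons][0] += 1
                    counts[is_cons][1] += el.ps_candidate
                    break
    assert counts[True][0] >= 8 and counts[False][0] >= 8
    assert counts[True][1] >= 0.7 * counts[True][0]
    assert counts[False][1] <= 0.3 * counts[False][0]


def test_ps_flag_single_leaf_uses_loss_rule(primate_model, thresholds_200k):
    """For a one-leaf clade the flag requires the element NOT to look like
    simple drift of that leaf (loss score below its threshold)."""
    acc_h = SelectionScenario(ACC, "human")
    # genuine acceleration of the human branch in a neutral background
    reg = cs.simulate_region(primate_model, acc_h, 0.05, 600, seed=901)
    ca = CollapsedAlignment(reg.block.codes)
    el = PredictedElement(reg.truth_start, reg.truth_end, acc_h, 0.05, 50.0)
    out = flag_ps_candidates([el], ca, primate_model, thresholds_200k)
    assert out[0].ps_candidate
    # the loss scenario itself: human drifts while everything else is
    # conserved -> high loss score -> not a positive-selection candidate
    reg2 = cs.simulate_region(
        primate_model, SelectionScenario(LOSS, "human"), 0.05, 600, seed=902
    )
    ca2 = CollapsedAlignment(reg2.block.codes)
    el2 = PredictedElement(reg2.truth_start, reg2.truth_end, acc_h, 0.05, 50.0)
    out2 = flag_ps_candidates([el2], ca2, primate_model, thresholds_200k)
    assert not out2[0].ps_candidate


# ---------------------------------------------------------------- thresholds


def test_threshold_table_json_roundtrip(tmp_path, thresholds_200k):
    p = tmp_path / "thr.json"
    thresholds_200k.to_json(p)
    back = ThresholdTable.from_json(p)
    assert back.thresholds == thresholds_200k.thresholds
    assert back.min_sub_length == thresholds_200k.min_sub_length
    assert back.metadata["target_fpr"] == pytest.approx(1e-3)


def test_thresholds_must_be_positive():
    with pytest.raises(ValueError):
        ThresholdTable({(GAIN, "apes"): 0.0})
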