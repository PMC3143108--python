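"""All maximal-scoring segments of a score vector (Ruzzo-Tompa scan).

This is the single left-to-right pass underlying the detector: every
disjoint, maximal positive-sum run of columns is returned in one O(L) sweep,
so candidate search costs linear time per (scenario, rho) rather than the
quadratic all-pairs interval search.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["maximal_segments", "greedy_nonoverlap"]


@njit(cache=True)
def _rt_scan(x):
    n = x.shape[0]
    cap = n // 2 + 2
    st = np.empty(cap, np.int64)
    en = np.empty(cap, np.int64)
    Lv = np.empty(cap, np.float64)
    Rv = np.empty(cap, np.float64)
    # skip pointer: nearest earlier stack entry with smaller left value,
    # giving the amortized-linear left scan of Ruzzo & Tompa
    pt = np.empty(cap, np.int64)
    top = 0
    cum = 0.0
    for i in range(n):
        v = x[i]
        cum += v
        if v > 0.0:
            s_ = i
            e_ = i + 1
            l_ = cum - v
            r_ = cum
            while True:
                j = top - 1
                while j >= 0 and Lv[j] >= l_:
                    j = pt[j]
                if j < 0 or Rv[j] >= r_:
                    st[top] = s_
                    en[top] = e_
                    Lv[top] = l_
                    Rv[top] = r_
                    pt[top] = j
                    top += 1
                    break
                # extend segment j rightward and reconsider
                s_ = st[j]
                l_ = Lv[j]
                top = j
    return st[:top], en[:top], Rv[:top] - Lv[:top]


def maximal_segments(
    x: np.ndarray, min_len: int = 1, min_score: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All maximal-scoring segments of ``x`` with length >= min_len and
    score > min_score.

    Returns (starts, ends, scores) with half-open [start, end) intervals,
    in left-to-right order.  Segments are pairwise disjoint and each has no
    prefix or suffix with non-positive partial sum (Ruzzo-Tompa maximality).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    st, en, sc = _rt_scan(x)
    keep = (en - st >= min_len) & (sc > min_score)
    return st[keep], en[keep], sc[keep]


@njit(cache=True)
def _greedy_keep(st, en, L):
    covered = np.zeros(L, np.uint8)
    keep = np.zeros(st.shape[0], np.bool_)
    for k in range(st.shape[0]):
        s, e = st[k], en[k]
        free = True
        for i in range(s, e):
            if covered[i]:
                free = False
                break
        if free:
            keep[k] = True
            for i in range(s, e):
                covered[i] = 1
    return keep


def greedy_nonoverlap(
    st: np.ndarray, en: np.ndarray, priority: np.ndarray, L: int
) -> np.ndarray:
    """Boolean mask keeping, in descending ``priority`` order, every segment
    that overlaps no previously kept one."""
    order = np.argsort(-priority, kind="stable")
    keep = np.zeros(st.shape[0], dtype=bool)
    kept = _greedy_keep(
        np.ascontiguousarray(st[order]), np.ascontiguousarray(en[order]), L
    )
    keep[order[kept]] = True
    return keep
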