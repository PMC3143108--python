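"""Independent reference implementations used only to check the package.

These deliberately avoid the package's pruning/prefix-sum/scan code paths:
likelihoods are brute-force sums over ancestral state assignments, matrix
exponentials come from a Taylor series, and interval maxima from explicit
double loops.
"""

from itertools import product

import numpy as np
import scipy.linalg

from cladesel.alphabet import MISSING


def taylor_expm(Q: np.ndarray, t: float, terms: int = 40, squarings: int = 20) -> np.ndarray:
    """exp(Qt) by scaled-and-squared truncated Taylor series."""
    A = np.asarray(Q, dtype=float) * (t / 2.0**squarings)
    P = np.eye(4)
    term = np.eye(4)
    for k in range(1, terms):
        term = term @ A / k
        P = P + term
    for _ in range(squarings):
        P = P @ P
    return P


def brute_force_column_prob(model, leaf_codes: dict[str, int]) -> float:
    """p(column) by explicit summation over every assignment of states to
    every internal node (no dynamic programming)."""
    tree = model.tree
    P = {
        v: scipy.linalg.expm(model.Q * float(tree.branch_length[v]))
        for v in range(tree.n_nodes)
        if tree.parent[v] >= 0
    }
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    total = 0.0
    for assign in product(range(4), repeat=len(internal)):
        state = dict(zip(internal, assign))
        p = model.pi[state[tree.root]]
        for v in range(tree.n_nodes):
            par = int(tree.parent[v])
            if par < 0:
                continue
            sp = state[par]
            if tree.children[v]:
                p *= P[v][sp, state[v]]
            else:
                c = leaf_codes[tree.labels[v]]
                if c != MISSING:
                    p *= P[v][sp, c]
        total += p
    return total


def brute_force_best_interval(ratios: np.ndarray, rho_grid) -> tuple[float, int, int, float]:
    """argmax over all (i, j, rho) of the interval sum, by explicit loops.

    Returns (score, start, end_exclusive, rho); ties broken toward smaller
    rho, then smaller start, then shorter interval (first hit wins).
    """
    best = (-np.inf, -1, -1, np.nan)
    R, L = ratios.shape
    for r in range(R):
        for i in range(L):
            run = 0.0
            for j in range(i, L):
                run += ratios[r, j]
                if run > best[0] + 1e-12:
                    best = (run, i, j + 1, rho_grid[r])
    return best
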