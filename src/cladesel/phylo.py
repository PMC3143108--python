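"""Phylogenetic model and per-column likelihoods.

A model is the 4-tuple (Q, tau, beta, pi): a time-reversible substitution
rate matrix Q (normalized to one expected substitution per unit branch
length), a rooted tree topology tau with branch lengths beta in expected
substitutions per site, and equilibrium base frequencies pi.  Per-column
probabilities p(k; psi) are computed with Felsenstein's pruning algorithm,
vectorized over the distinct column patterns of an alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import scipy.linalg

from .alphabet import MISSING, N_STATES, encode

log = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "PhyloModel",
    "ColumnLikelihoodCache",
    "transition_matrix",
    "column_log_prob",
    "CollapsedAlignment",
]


class PhyloTree:
    """Rooted tree stored as flat arrays; node ids are postorder-stable.

    Every non-root node carries the length of its parent edge in expected
    substitutions per site.  Internal nodes without a label in the source
    Newick get a deterministic auto-label ``n<i>`` which is omitted again on
    output.
    """

    def __init__(
        self,
        labels: list[str],
        parent: np.ndarray,
        branch_length: np.ndarray,
        auto_labeled: set[int] | None = None,
    ):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_length = np.asarray(branch_length, dtype=np.float64)
        self.auto_labeled = set(auto_labeled or ())
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("node labels are not unique")
        if np.any(self.branch_length < 0):
            raise ValueError("negative branch length")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            p = int(self.parent[v])
            if p >= 0:
                self.children[p].append(v)
        # postorder via iterative DFS
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = np.array(order[::-1], dtype=np.int64)
        self.leaf_ids = np.array(
            [v for v in self.postorder if not self.children[v]], dtype=np.int64
        )
        self._label_to_id = {lab: i for i, lab in enumerate(self.labels)}

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        nodes = list(dt.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        labels: list[str] = []
        auto: set[int] = set()
        parent = np.empty(len(nodes), dtype=np.int64)
        blen = np.zeros(len(nodes), dtype=np.float64)
        for i, nd in enumerate(nodes):
            if nd.taxon is not None and nd.taxon.label:
                lab = nd.taxon.label
            elif nd.label:
                lab = nd.label
            else:
                lab = f"n{i}"
                auto.add(i)
            labels.append(lab.replace(" ", "_"))
            parent[i] = idx[id(nd.parent_node)] if nd.parent_node is not None else -1
            if nd.parent_node is not None:
                blen[i] = float(nd.edge.length or 0.0)
        return cls(labels, parent, blen, auto)

    def to_newick(self, include_auto_labels: bool = False) -> str:
        def fmt(v: int) -> str:
            lab = "" if (v in self.auto_labeled and not include_auto_labels) else self.labels[v]
            if self.children[v]:
                inner = ",".join(fmt(c) for c in self.children[v])
                s = f"({inner}){lab}"
            else:
                s = lab
            if self.parent[v] >= 0:
                s += f":{self.branch_length[v]:.12g}"
            return s

        return fmt(self.root) + ";"

    # -- queries --------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def is_leaf(self, v: int) -> bool:
        return not self.children[v]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[v] for v in self.leaf_ids]

    def node_id(self, label: str) -> int:
        try:
            return self._label_to_id[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} in tree") from None

    def subtree_nodes(self, u: int) -> np.ndarray:
        """Node ids of the clade rooted at u (u included), preorder."""
        out = []
        stack = [u]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return np.array(out, dtype=np.int64)

    def leaves_under(self, u: int) -> np.ndarray:
        sub = self.subtree_nodes(u)
        return np.array([v for v in sub if self.is_leaf(v)], dtype=np.int64)

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.labels, self.parent.copy(), self.branch_length.copy(), self.auto_labeled
        )

    def scale_branches(self, factors: np.ndarray) -> "PhyloTree":
        """New tree with per-node parent-edge lengths multiplied by ``factors``."""
        t = self.copy()
        t.branch_length = self.branch_length * np.asarray(factors, dtype=np.float64)
        return t


def transition_matrix(
    Q: np.ndarray, t: float, pi: np.ndarray | None = None
) -> np.ndarray:
    """P(t) = exp(Qt) for a rate matrix Q and branch length t >= 0.

    When the equilibrium frequencies ``pi`` of a reversible Q are supplied the
    exponential is taken through the eigendecomposition of the pi-symmetrized
    matrix (real spectrum); otherwise, or if that is ill-conditioned, a dense
    ``scipy.linalg.expm`` is used.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    Q = np.asarray(Q, dtype=np.float64)
    if pi is not None:
        try:
            w, U, Uinv = _rev_eig(Q, np.asarray(pi, dtype=np.float64))
            P = (U * np.exp(w * t)) @ Uinv
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate pi
            P = scipy.linalg.expm(Q * t)
    else:
        P = scipy.linalg.expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _rev_eig(Q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a reversible Q via pi-symmetrization."""
    s = np.sqrt(pi)
    S = (Q * s[:, None]) / s[None, :]
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    U = V / s[:, None]
    Uinv = V.T * s[None, :]
    return w, U, Uinv


@dataclass
class PhyloModel:
    """The 4-tuple (Q, tau, beta, pi); immutable after construction.

    Q is rescaled on construction so that the expected substitution rate at
    stationarity is 1, keeping branch lengths in units of expected
    substitutions per site.
    """

    tree: PhyloTree
    Q: np.ndarray
    pi: np.ndarray
    _eig: tuple = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=np.float64)
        Q = np.asarray(self.Q, dtype=np.float64).copy()
        if Q.shape != (N_STATES, N_STATES):
            raise ValueError(f"rate matrix must be 4x4, got {Q.shape}")
        if abs(self.pi.sum() - 1.0) > 1e-6:
            raise ValueError(f"base frequencies sum to {self.pi.sum():.6f}, not 1")
        # enforce zero row sums, then normalize to 1 expected substitution/site
        np.fill_diagonal(Q, 0.0)
        scale = Q.max() if Q.max() > 0 else 1.0
        flux = self.pi[:, None] * Q
        asym = float(np.max(np.abs(flux - flux.T))) / scale
        if asym > 1e-3:
            log.warning("rate matrix is not time-reversible (detailed balance violated)")
        else:
            # absorb finite input precision by projecting onto the
            # reversible manifold: symmetrize the probability flux
            Q = (flux + flux.T) / (2.0 * self.pi[:, None])
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -float(np.dot(self.pi, np.diag(Q)))
        if rate <= 0:
            raise ValueError("rate matrix has non-positive total rate")
        self.Q = Q / rate
        stat = self.pi @ self.Q
        if np.max(np.abs(stat)) > 1e-8:
            raise ValueError("pi is not stationary for Q")
        self._eig = _rev_eig(self.Q, self.pi)
        self._edge_P: np.ndarray | None = None

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        w, U, Uinv = self._eig
        P = (U * np.exp(w * t)) @ Uinv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def edge_transition_matrices(self) -> np.ndarray:
        """(n_nodes, 4, 4) array; entry v is P(branch_length[v]) of v's parent edge."""
        if self._edge_P is None:
            w, U, Uinv = self._eig
            ewt = np.exp(np.outer(self.tree.branch_length, w))  # (n, 4)
            P = np.einsum("ij,nj,jk->nik", U, ewt, Uinv, optimize=True)
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=2, keepdims=True)
            self._edge_P = P
        return self._edge_P

    def with_tree(self, tree: PhyloTree) -> "PhyloModel":
        """Same Q and pi on a different (e.g. rescaled) tree."""
        return PhyloModel(tree, self.Q, self.pi)


# one-hot rows for codes 0-3, all-ones for missing data
_LEAF_PARTIALS = np.vstack([np.eye(N_STATES), np.ones((1, N_STATES))])


def pattern_log_likelihoods(model: PhyloModel, patterns: np.ndarray) -> np.ndarray:
    """log p(pattern; psi) for each row of ``patterns``.

    ``patterns`` is (n_patterns, n_leaves) uint8 with columns in the order of
    ``model.tree.leaf_ids``; code 4 marks missing data (all-ones partials).
    """
    tree = model.tree
    patterns = np.atleast_2d(patterns)
    if patterns.shape[1] != len(tree.leaf_ids):
        raise ValueError(
            f"pattern width {patterns.shape[1]} != number of leaves {len(tree.leaf_ids)}"
        )
    P = model.edge_transition_matrices()
    leaf_pos = {int(v): j for j, v in enumerate(tree.leaf_ids)}
    partial: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        v = int(v)
        if tree.is_leaf(v):
            part = _LEAF_PARTIALS[patterns[:, leaf_pos[v]]]
        else:
            part = None
            for c in tree.children[v]:
                contrib = partial.pop(c) @ P[c].T
                part = contrib if part is None else part * contrib
        partial[v] = part
    lik = partial[tree.root] @ model.pi
    with np.errstate(divide="ignore"):
        return np.log(lik)


class ColumnLikelihoodCache:
    """Memo of per-(model, column pattern) log-probabilities.

    Models are treated as immutable after construction; entries are keyed on
    the model's object identity.
    """

    def __init__(self):
        self._memo: dict[tuple[int, bytes], float] = {}

    def log_prob(self, model: PhyloModel, pattern: np.ndarray) -> float:
        key = (id(model), pattern.tobytes())
        if key not in self._memo:
            self._memo[key] = float(pattern_log_likelihoods(model, pattern[None, :])[0])
        return self._memo[key]


def column_log_prob(
    column, model: PhyloModel, cache: ColumnLikelihoodCache | None = None
) -> float:
    """log p(k; psi) for one alignment column.

    ``column`` maps leaf labels to single characters (unlisted leaves are
    missing), or is a uint8 code vector already in tree leaf order.
    """
    if isinstance(column, dict):
        codes = np.full(len(model.tree.leaf_ids), MISSING, dtype=np.uint8)
        pos = {lab: j for j, lab in enumerate(model.tree.leaf_labels)}
        for lab, base in column.items():
            if lab not in pos:
                raise KeyError(f"unknown leaf label {lab!r}")
            codes[pos[lab]] = encode(base)[0]
    else:
        codes = np.asarray(column, dtype=np.uint8)
    if cache is not None:
        return cache.log_prob(model, codes)
    return float(pattern_log_likelihoods(model, codes[None, :])[0])


class CollapsedAlignment:
    """Alignment columns collapsed to unique patterns for fast re-scoring.

    Built once per alignment block; every model scored against the block then
    pays per-pattern rather than per-column cost.  Codes are (n_leaves, L) in
    tree leaf order.
    """

    def __init__(self, codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2:
            raise ValueError("codes must be (n_leaves, L)")
        self.n_leaves, self.L = codes.shape
        # encode each column in base 5 (4 bases + missing) into a uint64 key
        powers = (5 ** np.arange(self.n_leaves, dtype=np.uint64))[:, None]
        keys = (codes.astype(np.uint64) * powers).sum(axis=0)
        _, first, inverse = np.unique(keys, return_index=True, return_inverse=True)
        self.patterns = codes[:, first].T.copy()  # (n_patterns, n_leaves)
        self.inverse = inverse.astype(np.int64)
        #: columns where every species is missing contribute 0 to every score
        self.all_missing = (self.patterns == MISSING).all(axis=1)[self.inverse]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def pattern_log_likelihoods(self, model: PhyloModel) -> np.ndarray:
        return pattern_log_likelihoods(model, self.patterns)

    def column_log_likelihoods(self, model: PhyloModel) -> np.ndarray:
        return self.pattern_log_likelihoods(model)[self.inverse]
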