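"""Accuracy metrics for benchmarking inferred solutions against ground truth.

Clone labels are arbitrary, so matrix metrics first compute a minimum-cost
bipartite matching between inferred and true clone profiles (L1 distance,
Hungarian algorithm); RMSEs of C and U, and the rooted Robinson-Foulds
distance, are then taken over matched clones. Variant deconvolution is
scored by the average precision of the co-clustering indicator over variant
pairs, and the clone-number estimate by the signed relative distance
(k_true - k_est) / k_true.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import CloneTree

__all__ = [
    "CloneMatching",
    "match_clones",
    "rmse_matrices",
    "normalized_rf",
    "coclustering_average_precision",
    "clone_number_distance",
]


@dataclass
class CloneMatching:
    """Injective map inferred-clone -> true-clone with its total L1 cost."""

    est_to_true: dict[int, int]
    cost: float
    rows: np.ndarray  # matched inferred indices
    cols: np.ndarray  # matched true indices


def _restrict(idx_n: int, n_leaves: int | None):
    if n_leaves is None:
        return np.arange(idx_n)
    return np.concatenate([np.arange(n_leaves), [idx_n - 1]])  # leaves + root


def match_clones(
    C_true: np.ndarray, C_est: np.ndarray, leaf_only: bool = False,
    n_leaves: int | None = None,
) -> CloneMatching:
    """Minimum-cost bipartite matching of clone rows under L1 profile distance.

    In leaf-only mode (requires ``n_leaves``) only leaves and the root of
    each matrix participate.
    """
    C_true = np.asarray(C_true, dtype=float)
    C_est = np.asarray(C_est, dtype=float)
    if C_true.shape[1] != C_est.shape[1]:
        raise ValueError(
            f"column universes differ: {C_true.shape[1]} vs {C_est.shape[1]}"
        )
    rt = _restrict(C_true.shape[0], n_leaves if leaf_only else None)
    re_ = _restrict(C_est.shape[0], n_leaves if leaf_only else None)
    cost = np.abs(C_est[re_][:, None, :] - C_true[rt][None, :, :]).sum(axis=2)
    ri, ci = linear_sum_assignment(cost)
    mapping = {int(re_[a]): int(rt[b]) for a, b in zip(ri, ci)}
    return CloneMatching(
        est_to_true=mapping, cost=float(cost[ri, ci].sum()),
        rows=re_[ri], cols=rt[ci],
    )


def rmse_matrices(
    C_true, C_est, U_true, U_est, matching: CloneMatching
) -> tuple[float, float]:
    """Element-wise RMSE of C over matched clone rows and U over matched columns."""
    C_true, C_est = np.asarray(C_true, float), np.asarray(C_est, float)
    U_true, U_est = np.asarray(U_true, float), np.asarray(U_est, float)
    dc = C_est[matching.rows] - C_true[matching.cols]
    du = U_est[:, matching.rows] - U_true[:, matching.cols]
    return float(np.sqrt(np.mean(dc**2))), float(np.sqrt(np.mean(du**2)))


def _clusters(tree: CloneTree, labels: dict[int, object]) -> set[frozenset]:
    """Nontrivial rooted clusters: leaf-label sets of internal non-root nodes."""
    A = tree.ancestry().astype(bool)
    out = set()
    for i in range(tree.n, tree.N - 1):
        leaves = [k for k in range(tree.n) if A[i, k]]
        cl = frozenset(labels[k] for k in leaves)
        if len(cl) >= 2:
            out.add(cl)
    return out


def normalized_rf(
    tree_true: CloneTree, tree_est: CloneTree, matching: CloneMatching
) -> float:
    """Rooted Robinson-Foulds distance normalized to [0, 1].

    Leaves of the estimated tree are relabeled through the clone matching
    (unmatched leaves receive fresh labels); the distance is the size of the
    symmetric difference of the two nontrivial-cluster sets divided by the
    total number of nontrivial clusters.
    """
    if tree_true.n < 2 or tree_est.n < 2:
        raise ValueError("trees need at least 2 leaves")
    true_labels = {k: k for k in range(tree_true.n)}
    est_labels = {}
    fresh = tree_true.N
    matched_leaves = 0
    for k in range(tree_est.n):
        t = matching.est_to_true.get(k)
        if t is not None and t < tree_true.n:
            est_labels[k] = t
            matched_leaves += 1
        else:
            est_labels[k] = f"unmatched{fresh}"
            fresh += 1
    if matched_leaves < 2:
        raise ValueError("fewer than 2 matched leaves: RF undefined")
    c1 = _clusters(tree_true, true_labels)
    c2 = _clusters(tree_est, est_labels)
    denom = len(c1) + len(c2)
    if denom == 0:
        return 0.0
    return len(c1 ^ c2) / denom


def coclustering_average_precision(
    assign_true: np.ndarray, assign_est: np.ndarray, block: str,
    n_breakpoints: int | None = None,
) -> float:
    """Average precision of the co-clustering indicator over variant pairs.

    ``assign_true``/``assign_est`` give each variant's clone of origin.
    ``block`` selects the pair population: ``"bp-bp"`` (both variants among
    the first ``n_breakpoints``), ``"snv-snv"``, or ``"bp-snv"`` (one of
    each). Pairs are unordered and off-diagonal. Estimated indicators serve
    as scores against true indicators as labels, with the standard
    step-interpolated precision-recall definition. Returns NaN when the
    truth has no co-clustered pair (undefined), raises on blocks with fewer
    than two variants.
    """
    at = np.asarray(assign_true)
    ae = np.asarray(assign_est)
    if at.shape != ae.shape:
        raise ValueError("assignment vectors differ in length")
    nv = len(at)
    if block not in ("bp-bp", "snv-snv", "bp-snv", "all"):
        raise ValueError(f"unknown block {block!r}")
    l = nv if n_breakpoints is None else n_breakpoints
    ii, jj = np.triu_indices(nv, k=1)
    if block == "bp-bp":
        mask = (ii < l) & (jj < l)
    elif block == "snv-snv":
        mask = (ii >= l) & (jj >= l)
    elif block == "bp-snv":
        mask = (ii < l) != (jj < l)
    else:
        mask = np.ones_like(ii, dtype=bool)
    ii, jj = ii[mask], jj[mask]
    if len(ii) < 1:
        raise ValueError(f"block {block!r} has fewer than 2 variants")
    y = (at[ii] == at[jj]).astype(int)
    s = (ae[ii] == ae[jj]).astype(int)
    n_pos = int(y.sum())
    if n_pos == 0:
        return float("nan")
    # binary scores: thresholds 1 then 0
    tp1 = int((y & s).sum())
    p1 = int(s.sum())
    ap = 0.0
    r_prev = 0.0
    if p1 > 0:
        prec1 = tp1 / p1
        rec1 = tp1 / n_pos
        ap += (rec1 - r_prev) * prec1
        r_prev = rec1
    prec_all = n_pos / len(y)
    ap += (1.0 - r_prev) * prec_all
    return float(ap)


def clone_number_distance(k_true: int, k_est: int) -> float:
    """Signed relative clone-number distance (k_true - k_est) / k_true."""
    if k_true <= 0:
        raise ValueError("k_true must be positive")
    return (k_true - k_est) / k_true
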