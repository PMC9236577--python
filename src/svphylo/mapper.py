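"""Variant subsampling and post-hoc assignment of unsampled variants to tree edges.

The joint MILP scales poorly with the number of variants, so phylogeny
inference can run on a uniform subsample of breakpoint pairs and SNVs (all
CNA segments are always kept). The remaining variants are then mapped to the
most plausible edge of the solved tree by comparing their observed mean copy
numbers against the copy number implied by each candidate (node, allele)
under two scenarios: the variant was acquired before any copy-number change
on that edge (its copy equals its allele's segment copy), or after (its copy
in the introducing clone is one, and the expectation over allele copies in
descendant clones).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CloneProfiles, CloneTree, VariantPanel
from .solver import SolveResult

__all__ = [
    "SubsamplePlan",
    "subsample",
    "assign_unsampled",
    "merge_assignment",
]


class MappingError(ValueError):
    pass


@dataclass
class SubsamplePlan:
    """Which variants enter the MILP and which are held out for mapping."""

    max_breakpoints: int
    max_total: int
    seed: int | None = None
    kept: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    held_out: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def subsample(
    panel: VariantPanel, F: np.ndarray, plan: SubsamplePlan
) -> tuple[VariantPanel, np.ndarray, SubsamplePlan]:
    """Uniformly subsample breakpoint pairs, then SNVs, up to the plan's limits.

    Mate pairs are kept or held out together; every segment is kept. Limits
    exceeding availability keep everything. Deterministic under the plan seed.
    The returned plan records kept/held-out variant indices into ``panel``.
    """
    if plan.max_breakpoints < 0 or plan.max_total < 0:
        raise MappingError("subsample limits must be >= 0")
    rng = np.random.default_rng(plan.seed)
    l, g = panel.l, panel.g
    mate = panel.mate_of
    pairs = [(b, int(mate[b])) for b in range(l) if b < mate[b]]
    n_pairs = min(len(pairs), plan.max_breakpoints // 2)
    chosen = rng.choice(len(pairs), size=n_pairs, replace=False) if pairs else []
    kept_bp = sorted(b for i in chosen for b in pairs[i])
    budget = max(0, plan.max_total - len(kept_bp))
    n_snv = min(g, budget)
    chosen_snv = rng.choice(g, size=n_snv, replace=False) if g else []
    kept_snv = sorted(l + int(s) for s in chosen_snv)
    kept = np.array(kept_bp + kept_snv, dtype=int)
    held = np.setdiff1d(np.arange(l + g), kept)

    bp_keep = [b for b in kept_bp]
    snv_keep = [s - l for s in kept_snv]
    sub_bps = panel.breakpoints.iloc[bp_keep].reset_index(drop=True)
    sub_snvs = panel.snvs.iloc[snv_keep].reset_index(drop=True)
    subQ = panel.Q[kept] if len(kept) else panel.Q[:0]
    subG = panel.G[np.ix_(bp_keep, bp_keep)]
    sub_panel = VariantPanel(
        breakpoints=sub_bps, snvs=sub_snvs, segments=panel.segments, Q=subQ, G=subG
    )
    sub_panel.validate()
    F = np.asarray(F, dtype=float)
    cols = np.concatenate([kept, panel.n_variants + np.arange(2 * panel.r)])
    F_sub = F[:, cols]
    out_plan = SubsamplePlan(plan.max_breakpoints, plan.max_total, plan.seed,
                             kept=kept, held_out=held)
    return sub_panel, F_sub, out_plan


def assign_unsampled(
    F_heldout: np.ndarray,
    seg_heldout: np.ndarray,
    tree: CloneTree,
    U: np.ndarray,
    C: np.ndarray,
    panel_solved: VariantPanel,
    variant_ids: list[str] | None = None,
    mate_pairs: list[tuple[int, int]] | None = None,
    admissibility: str = "gt1",
) -> pd.DataFrame:
    """Map each held-out variant to its best (node, allele, scenario).

    ``F_heldout`` is (m, n_held) observed mean copies; ``seg_heldout`` gives
    each held-out variant's segment index in the solved panel. For candidate
    node i (non-root), allele d and scenario:

    * scenario 1 (acquired before the edge's copy change): predicted mixed
      copy = U[:, i] * chat_i + sum over descendants k of U[:, k] * chat_k,
      admissible iff chat_i == 1 or chat_i - chat_parent(i) > 1 (the printed
      pseudocode rule; ``admissibility="ge1"`` relaxes the second clause to
      >= 1);
    * scenario 2 (acquired after): U[:, i] * 1 + sum_k U[:, k] * chat_k /
      chat_i, admissible iff chat_i >= 1;

    where chat is the allele-d segment copy of the variant's segment. The
    distance is the L1 norm across samples between prediction and
    observation; ties break to the smallest node index, then d = 1, then
    scenario 1. Mate pairs (indices into the held-out set) are assigned
    jointly with summed distance.
    """
    F_heldout = np.atleast_2d(np.asarray(F_heldout, dtype=float))
    n_held = F_heldout.shape[1]
    if len(seg_heldout) != n_held:
        raise MappingError("seg_heldout length mismatch")
    V, r = panel_solved.n_variants, panel_solved.r
    if np.any(np.asarray(seg_heldout) < 0) or np.any(np.asarray(seg_heldout) >= r):
        raise MappingError("held-out variant maps outside the solved panel's segments")
    N = tree.N
    A = tree.ancestry().astype(bool)
    parents = tree.parents()

    def candidate_distances(j: int) -> np.ndarray:
        """(N-1, 2, 2) distances for variant j; inf = inadmissible.

        Axis 1 indexes d in order (1, 0); axis 2 scenario (1, 2).
        """
        s = int(seg_heldout[j])
        obs = F_heldout[:, j]
        out = np.full((N - 1, 2, 2), np.inf)
        for di, d in enumerate((1, 0)):
            col = V + s if d == 1 else V + r + s
            chat = C[:, col].astype(float)
            for i in range(N - 1):
                desc = np.nonzero(A[i])[0]
                cpar = chat[parents[i]]
                ok1 = chat[i] == 1 or (
                    chat[i] - cpar > 1 if admissibility == "gt1" else chat[i] - cpar >= 1
                )
                if ok1:
                    pred = U[:, i] * chat[i] + U[:, desc] @ chat[desc]
                    out[i, di, 0] = np.abs(pred - obs).sum()
                if chat[i] >= 1:
                    pred = U[:, i] * 1.0 + U[:, desc] @ (chat[desc] / chat[i])
                    out[i, di, 1] = np.abs(pred - obs).sum()
        return out

    mate_pairs = mate_pairs or []
    paired = {a for p in mate_pairs for a in p}
    dist_cache = {j: candidate_distances(j) for j in range(n_held)}

    rows = []
    ids = variant_ids or [f"heldout{j}" for j in range(n_held)]

    def best_of(dist: np.ndarray) -> tuple[int, int, int, float]:
        flat_best = None
        for i in range(N - 1):
            for di in range(2):
                for sc in range(2):
                    v = dist[i, di, sc]
                    if flat_best is None or v < flat_best[3] - 1e-15:
                        if np.isfinite(v):
                            flat_best = (i, 1 - di, sc + 1, float(v))
        if flat_best is None:
            raise MappingError("no admissible assignment (degenerate profiles)")
        return flat_best

    done = set()
    for j in range(n_held):
        if j in done:
            continue
        if j in paired:
            k = next(b if a == j else a for a, b in mate_pairs if j in (a, b))
            i, d, sc, dv = best_of(dist_cache[j] + dist_cache[k])
            for jj in (j, k):
                rows.append(dict(variant=ids[jj], node=i, d=d, scenario=sc, distance=dv))
                done.add(jj)
        else:
            i, d, sc, dv = best_of(dist_cache[j])
            rows.append(dict(variant=ids[j], node=i, d=d, scenario=sc, distance=dv))
            done.add(j)
    order = {ids[j]: j for j in range(n_held)}
    return pd.DataFrame(rows).sort_values("variant", key=lambda s: s.map(order)).reset_index(drop=True)


def merge_assignment(
    result: SolveResult,
    assignment: pd.DataFrame,
    panel_solved: VariantPanel,
    panel_full: VariantPanel,
    plan: SubsamplePlan,
) -> tuple[SolveResult, VariantPanel]:
    """Fold mapped held-out variants back into the clone profiles.

    The solved subsample plus the held-out set reconstitute ``panel_full``
    (same segments), so the merged profiles use the full panel's column
    layout. A held-out variant assigned to node i under scenario 1 takes its
    allele's segment copy throughout i's subtree; under scenario 2 it takes
    copy 1 in clone i and the half-up-rounded expectation chat_k / chat_i in
    descendants (pre-rounding values are recorded in the returned result's
    trace). Rounded-to-zero clones propagate zero to their descendants so the
    merged solution keeps the Dollo life cycle.
    """
    if len(assignment) == 0:
        return result, panel_solved
    tree = result.tree
    C_sub, D_sub = result.profiles.C, result.profiles.D
    Vf, r, N = panel_full.n_variants, panel_full.r, tree.N
    if panel_solved.r != r:
        raise MappingError("solved and full panels disagree on segments")
    A = tree.ancestry().astype(bool)
    parents = tree.parents()
    full_ids = panel_full.variant_ids()
    id_to_full = {vid: b for b, vid in enumerate(full_ids)}

    C = np.zeros((N, Vf + 2 * r), dtype=int)
    C[:, Vf:] = C_sub[:, panel_solved.n_variants :]
    D = np.zeros(Vf, dtype=np.int8)
    W = np.zeros((N, N, Vf), dtype=np.int8)
    for b_sub, vid in enumerate(panel_solved.variant_ids()):
        b = id_to_full[vid]
        C[:, b] = C_sub[:, b_sub]
        D[b] = D_sub[b_sub]
        if tree.W is not None:
            W[:, :, b] = tree.W[:, :, b_sub]

    seg_of_full = panel_full.segment_of
    prerounding = []
    for row in assignment.itertuples():
        b = id_to_full[row.variant]
        s = int(seg_of_full[b])
        col = Vf + s if row.d == 1 else Vf + r + s
        chat = C[:, col].astype(float)
        i = int(row.node)
        D[b] = row.d
        W[parents[i], i, b] = 1
        inside = A[i] | (np.arange(N) == i)
        if row.scenario == 1:
            vals = np.where(inside, chat, 0.0)
        else:
            denom = max(chat[i], 1.0)
            vals = np.where(inside, np.floor(chat / denom + 0.5), 0.0)
            vals[i] = 1.0
            prerounding.append(dict(variant=row.variant,
                                    expectation=list(np.round(chat / denom, 6))))
        # Dollo: once zero, zero below
        for k in sorted(np.nonzero(inside)[0], key=lambda k: A[:, k].sum()):
            if k != i and vals[parents[k]] == 0:
                vals[k] = 0.0
        C[:, b] = np.minimum(vals, chat).astype(int)

    profiles = CloneProfiles(C=C, D=D, c_max=result.profiles.c_max)
    new_tree = CloneTree(n=tree.n, E=tree.E.copy(), W=W, rho=tree.rho)
    merged = SolveResult(
        tree=new_tree, profiles=profiles, freqs=result.freqs,
        objective=result.objective, data_term=result.data_term,
        R=result.R, S=result.S,
        trace=result.trace + [{"merged_prerounding": prerounding}],
        optimal=result.optimal, restart_seeds=result.restart_seeds,
    )
    return merged, panel_full
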