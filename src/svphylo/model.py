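"""Core data model for joint clonal deconvolution of SNVs, CNAs and SV breakpoints.

The shared matrix conventions used across the package:

* ``F`` (samples x columns) holds mean copy numbers observed in bulk samples,
  ``C`` (clones x columns) integer copy numbers per clone, with the fixed
  column layout ``[breakpoints 0..l-1 | SNVs l..l+g-1 | allele-1 segments |
  allele-2 segments]``.
* ``Q`` maps each breakpoint/SNV to the single copy-number segment containing
  it; ``G`` pairs SV breakpoints into mates.
* Clone trees are rooted binary trees on ``N = 2n - 1`` nodes; leaves are
  nodes ``0..n-1``, internal nodes ``n..N-2`` and the root (the normal,
  diploid clone) is the last node ``N-1``.
* Genomic coordinates are 1-based inclusive (VCF convention); breakpoint
  directions are ``"left"``/``"right"`` (which side of the position joins the
  mate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantPanel",
    "BulkObservation",
    "CloneTree",
    "CloneProfiles",
    "FrequencyMatrix",
    "ValidationReport",
    "build_panel",
    "order_alleles",
    "compute_vaf",
    "validate_solution",
]

DIRECTIONS = ("left", "right")


class PanelError(ValueError):
    """Raised for malformed variant panels (unmatched mates, unmappable loci)."""


# ---------------------------------------------------------------------------
# Variant panel
# ---------------------------------------------------------------------------

@dataclass
class VariantPanel:
    """Indexed universe of l breakpoints, g SNVs and r segments.

    Attributes
    ----------
    breakpoints : DataFrame with columns ``id, chrom, pos, direction, mate_id``
        sorted by (chrom, pos, direction); one row per breakpoint.
    snvs : DataFrame with columns ``id, chrom, pos`` (+ optional ref/alt).
    segments : DataFrame with columns ``chrom, start, end`` sorted by
        (chrom, start); non-overlapping within a chromosome, 1-based inclusive.
    Q : (l+g, r) binary array; row b has a single 1 marking b's segment.
    G : (l, l) binary symmetric pairing matrix; each row has a single 1.
    """

    breakpoints: pd.DataFrame
    snvs: pd.DataFrame
    segments: pd.DataFrame
    Q: np.ndarray
    G: np.ndarray

    @property
    def l(self) -> int:
        return len(self.breakpoints)

    @property
    def g(self) -> int:
        return len(self.snvs)

    @property
    def r(self) -> int:
        return len(self.segments)

    @property
    def n_variants(self) -> int:
        return self.l + self.g

    @property
    def n_cols(self) -> int:
        """Number of columns of F/C: l + g + 2r."""
        return self.l + self.g + 2 * self.r

    @property
    def segment_of(self) -> np.ndarray:
        """Index of the segment containing each variant (length l+g)."""
        return np.argmax(self.Q, axis=1)

    @property
    def mate_of(self) -> np.ndarray:
        """Index of each breakpoint's mate (length l)."""
        return np.argmax(self.G, axis=1) if self.l else np.zeros(0, dtype=int)

    def variant_ids(self) -> list[str]:
        return list(self.breakpoints["id"]) + list(self.snvs["id"])

    def column_ids(self) -> list[str]:
        seg = [
            f"{row.chrom}:{row.start}-{row.end}"
            for row in self.segments.itertuples()
        ]
        return (
            self.variant_ids()
            + [s + "|a1" for s in seg]
            + [s + "|a2" for s in seg]
        )

    def validate(self) -> None:
        l, g, r = self.l, self.g, self.r
        if self.Q.shape != (l + g, r):
            raise PanelError(f"Q has shape {self.Q.shape}, expected {(l + g, r)}")
        if not np.array_equal(self.Q.sum(axis=1), np.ones(l + g)):
            raise PanelError("every breakpoint/SNV must lie in exactly one segment")
        if self.G.shape != (l, l):
            raise PanelError(f"G has shape {self.G.shape}, expected {(l, l)}")
        if l:
            if not np.array_equal(self.G, self.G.T):
                raise PanelError("G must be symmetric")
            if np.any(np.diag(self.G) != 0):
                raise PanelError("G diagonal must be zero")
            if not np.array_equal(self.G.sum(axis=1), np.ones(l)):
                raise PanelError("every breakpoint must have exactly one mate")
        for chrom, grp in self.segments.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if np.any(starts > ends):
                raise PanelError(f"segment with start > end on {chrom}")
            if np.any(starts[1:] <= ends[:-1]):
                raise PanelError(f"overlapping or unsorted segments on {chrom}")


def _map_to_segments(
    chroms: Sequence, positions: Sequence[int], segments: pd.DataFrame, labels: Sequence[str]
) -> np.ndarray:
    """Return the segment index containing each (chrom, pos) locus."""
    idx = np.full(len(chroms), -1, dtype=int)
    seg_by_chrom = {
        chrom: (grp.index.to_numpy(), grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in segments.groupby("chrom", sort=False)
    }
    for i, (chrom, pos) in enumerate(zip(chroms, positions)):
        if chrom not in seg_by_chrom:
            raise PanelError(f"variant {labels[i]} on unknown chromosome {chrom}")
        rows, starts, ends = seg_by_chrom[chrom]
        j = np.searchsorted(starts, pos, side="right") - 1
        if j < 0 or pos > ends[j]:
            raise PanelError(f"variant {labels[i]} at {chrom}:{pos} falls outside all segments")
        idx[i] = rows[j]
    return idx


def build_panel(
    breakpoint_records: Iterable[Mapping],
    snv_records: Iterable[Mapping],
    segment_records: Iterable[Mapping],
) -> VariantPanel:
    """Assemble a validated :class:`VariantPanel` from plain records.

    Breakpoint records need ``chrom, pos, direction, mate_id, id``; SNV records
    ``chrom, pos`` (+ optional ``id``); segment records ``chrom, start, end``.
    Ordering is deterministic regardless of input order: breakpoints by
    (chrom, pos, direction), SNVs by (chrom, pos), segments by (chrom, start).
    """
    segs = pd.DataFrame(list(segment_records))
    if len(segs) == 0:
        raise PanelError("at least one segment is required")
    segs = segs.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)

    bps = pd.DataFrame(list(breakpoint_records), columns=["id", "chrom", "pos", "direction", "mate_id"])
    if len(bps):
        bad = ~bps["direction"].isin(DIRECTIONS)
        if bad.any():
            raise PanelError(f"invalid breakpoint direction: {bps.loc[bad, 'direction'].iloc[0]!r}")
        bps = bps.sort_values(["chrom", "pos", "direction", "id"], kind="stable").reset_index(drop=True)
    snvs = pd.DataFrame(list(snv_records))
    if len(snvs):
        if "id" not in snvs.columns:
            snvs["id"] = [f"snv_{c}_{p}" for c, p in zip(snvs["chrom"], snvs["pos"])]
        snvs = snvs.sort_values(["chrom", "pos", "id"], kind="stable").reset_index(drop=True)
    else:
        snvs = pd.DataFrame(columns=["id", "chrom", "pos"])

    l, g, r = len(bps), len(snvs), len(segs)
    # mate pairing
    G = np.zeros((l, l), dtype=np.int8)
    if l:
        by_id = {bid: i for i, bid in enumerate(bps["id"])}
        for i, mate in enumerate(bps["mate_id"]):
            j = by_id.get(mate)
            if j is None or j == i:
                raise PanelError(f"breakpoint {bps['id'].iloc[i]} has unresolvable mate id {mate!r}")
            G[i, j] = 1
        if not np.array_equal(G, G.T):
            raise PanelError("breakpoint mate pairing is not reciprocal")

    Q = np.zeros((l + g, r), dtype=np.int8)
    if l:
        si = _map_to_segments(bps["chrom"], bps["pos"], segs, list(bps["id"]))
        Q[np.arange(l), si] = 1
    if g:
        si = _map_to_segments(snvs["chrom"], snvs["pos"], segs, list(snvs["id"]))
        Q[l + np.arange(g), si] = 1

    panel = VariantPanel(breakpoints=bps, snvs=snvs, segments=segs, Q=Q, G=G)
    panel.validate()
    return panel


# ---------------------------------------------------------------------------
# Bulk observation (F, psi, pi)
# ---------------------------------------------------------------------------

@dataclass
class BulkObservation:
    """Observed per-sample mean copy numbers plus derived quantities.

    ``psi[p, b]`` is the mixed (both-allele) copy number of variant b's
    segment in sample p; ``pi[p, b] = F[p, b] / psi[p, b]`` is the VAF.
    """

    F: np.ndarray
    psi: np.ndarray
    pi: np.ndarray
    n_clamped: int = 0
    n_zero_psi: int = 0
    swapped_segments: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    @property
    def m(self) -> int:
        return self.F.shape[0]


def compute_vaf(F: np.ndarray, panel: VariantPanel) -> np.ndarray:
    """Variant allele frequencies pi[p, b] = F[p, b] / psi[p, b] (0 where psi=0)."""
    psi = _compute_psi(F, panel)
    v = panel.n_variants
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(psi > 0, F[:, :v] / np.where(psi > 0, psi, 1.0), 0.0)
    return pi


def _compute_psi(F: np.ndarray, panel: VariantPanel) -> np.ndarray:
    v, r = panel.n_variants, panel.r
    seg_tot = F[:, v : v + r] + F[:, v + r : v + 2 * r]
    return seg_tot[:, panel.segment_of]


def order_alleles(F_raw: np.ndarray, panel: VariantPanel) -> BulkObservation:
    """Order allele columns so allele-1 carries the larger copy number.

    The swap decision is made once per segment by majority vote across
    samples of (allele-A >= allele-B); ties keep the input order. The chosen
    orientation is applied to every sample so that each segment keeps a
    common first allele across the cohort.
    """
    F = np.asarray(F_raw, dtype=float).copy()
    if F.ndim != 2 or F.shape[1] != panel.n_cols:
        raise ValueError(f"F has shape {F.shape}, expected (m, {panel.n_cols})")
    if np.any(F < 0):
        raise ValueError("negative copy numbers in F")
    v, r = panel.n_variants, panel.r
    a1 = F[:, v : v + r]
    a2 = F[:, v + r : v + 2 * r]
    votes_swap = (a1 < a2).sum(axis=0)
    votes_keep = (a1 >= a2).sum(axis=0)
    swap = votes_swap > votes_keep
    a1s, a2s = a1.copy(), a2.copy()
    a1s[:, swap], a2s[:, swap] = a2[:, swap], a1[:, swap]
    F[:, v : v + r] = a1s
    F[:, v + r : v + 2 * r] = a2s

    psi = _compute_psi(F, panel)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(psi > 0, F[:, :v] / np.where(psi > 0, psi, 1.0), 0.0)
    n_zero = int(np.sum((psi <= 0) & (F[:, :v] >= 0))) if v else 0
    n_clamped = int(np.sum(pi > 1.0))
    pi = np.clip(pi, 0.0, 1.0)
    return BulkObservation(
        F=F, psi=psi, pi=pi, n_clamped=n_clamped,
        n_zero_psi=int(np.sum(psi == 0)), swapped_segments=swap,
    )


# ---------------------------------------------------------------------------
# Clone tree
# ---------------------------------------------------------------------------

@dataclass
class CloneTree:
    """Rooted binary clone tree on N = 2n - 1 nodes (root = node N-1).

    ``E[i, j] = 1`` iff i is the parent of j; ``W[i, j, b] = 1`` iff variant b
    is introduced on edge (i, j); ``rho[i, j]`` is the copy-number
    evolutionary length of edge (i, j).
    """

    n: int
    E: np.ndarray
    W: np.ndarray | None = None
    rho: np.ndarray | None = None

    @property
    def N(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return self.N - 1

    @classmethod
    def from_parents(cls, n: int, parents: Sequence[int], **kw) -> "CloneTree":
        """Build from a parent vector (parents[root] = -1)."""
        N = 2 * n - 1
        E = np.zeros((N, N), dtype=np.int8)
        for j, i in enumerate(parents):
            if i >= 0:
                E[i, j] = 1
        return cls(n=n, E=E, **kw)

    def parents(self) -> np.ndarray:
        p = np.full(self.N, -1, dtype=int)
        src, dst = np.nonzero(self.E)
        p[dst] = src
        return p

    def children(self, i: int) -> np.ndarray:
        return np.nonzero(self.E[i])[0]

    def ancestry(self) -> np.ndarray:
        """Strict transitive closure A of E (A[i, j]=1 iff i is a proper ancestor of j)."""
        N = self.E.shape[0]
        A = self.E.astype(bool).copy()
        # Repeated squaring of the reachability relation.
        while True:
            A2 = A | (A @ A)
            if np.array_equal(A2, A):
                break
            A = A2
        return A.astype(np.int8)

    def topo_order(self) -> list[int]:
        """Nodes in root-first topological order."""
        order, stack = [], [self.root]
        while stack:
            i = stack.pop()
            order.append(i)
            stack.extend(self.children(i))
        return order

    def newick(self, labels: Sequence[str] | None = None) -> str:
        labels = labels or [f"clone{i}" for i in range(self.N)]

        def rec(i: int) -> str:
            ch = self.children(i)
            if len(ch) == 0:
                return labels[i]
            return "(" + ",".join(rec(int(c)) for c in ch) + ")" + labels[i]

        return rec(self.root) + ";"

    def validate(self, n_variants: int | None = None) -> list[str]:
        out = []
        N = self.N
        if self.E.shape != (N, N):
            return [f"E has shape {self.E.shape}, expected {(N, N)}"]
        indeg = self.E.sum(axis=0)
        outdeg = self.E.sum(axis=1)
        if indeg[self.root] != 0:
            out.append("root has a parent")
        for j in range(N):
            if j != self.root and indeg[j] != 1:
                out.append(f"node {j} has in-degree {indeg[j]}")
        for i in range(N):
            expect = 0 if i < self.n else 2
            if outdeg[i] != expect:
                out.append(f"node {i} has out-degree {outdeg[i]}, expected {expect}")
        A = self.ancestry()
        if np.any(np.diag(A)):
            out.append("cycle detected (node is its own ancestor)")
        if np.any(A + A.T > 1):
            out.append("mutual ancestry between two nodes")
        if self.W is not None and n_variants is not None:
            if self.W.shape != (N, N, n_variants):
                out.append(f"W has shape {self.W.shape}")
            else:
                per_var = self.W.sum(axis=(0, 1))
                for b in np.nonzero(per_var > 1)[0]:
                    out.append(f"variant {b} introduced on {per_var[b]} edges (Dollo violation)")
                if np.any(self.W > self.E[:, :, None]):
                    out.append("W set on a non-edge")
        return out


# ---------------------------------------------------------------------------
# Clone profiles & frequencies
# ---------------------------------------------------------------------------

@dataclass
class CloneProfiles:
    """Integer copy-number profiles C per clone, allele assignment D.

    ``C`` shares F's column layout. ``D[b] = 1`` places variant b on the
    first allele, 0 on the second. ``gamma`` (derived) gives each variant's
    allele-specific segment copy number per clone.
    """

    C: np.ndarray
    D: np.ndarray
    c_max: int

    @property
    def N(self) -> int:
        return self.C.shape[0]

    def gamma(self, panel: VariantPanel) -> np.ndarray:
        """(N, l+g, 2) allele-specific segment copies at each variant locus."""
        v, r = panel.n_variants, panel.r
        seg = panel.segment_of
        g0 = self.C[:, v + seg]
        g1 = self.C[:, v + r + seg]
        return np.stack([g0, g1], axis=2)


@dataclass
class FrequencyMatrix:
    """Per-sample clone fractions U (rows on the simplex)."""

    U: np.ndarray
    leaf_only: bool = False

    @property
    def m(self) -> int:
        return self.U.shape[0]


# ---------------------------------------------------------------------------
# Whole-solution validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str]
    counters: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "solution valid (no violations)"
        return f"{len(self.violations)} violation(s):\n" + "\n".join(
            "  - " + v for v in self.violations
        )


def validate_solution(
    panel: VariantPanel,
    tree: CloneTree,
    profiles: CloneProfiles,
    freqs: FrequencyMatrix,
    atol: float = 1e-6,
) -> ValidationReport:
    """Check every structural invariant of a (tree, C, U) solution.

    All violations are collected and reported, never raised: tree shape,
    copy-number bounds and root normality, variant-vs-allele-segment bounds,
    simplex rows of U, and the Dollo life cycle of each variant (one gain,
    persistence until loss, no reappearance after loss).
    """
    out: list[str] = []
    v = panel.n_variants
    N = tree.N
    out.extend(tree.validate(n_variants=v))

    C, D = profiles.C, profiles.D
    if C.shape != (N, panel.n_cols):
        out.append(f"C has shape {C.shape}, expected {(N, panel.n_cols)}")
        return ValidationReport(out)
    if np.any(C < 0) or np.any(C > profiles.c_max):
        out.append("C outside [0, c_max]")
    root = tree.root
    if np.any(C[root, :v] != 0):
        out.append("root carries breakpoints/SNVs")
    if np.any(C[root, v:] != 1):
        out.append("root segment copies differ from 1 per allele")

    gam = profiles.gamma(panel)
    allele = np.where(D == 1, 0, 1)  # d_b = 1 -> first allele
    lim = gam[:, np.arange(v), allele] if v else np.zeros((N, 0))
    over = C[:, :v] > lim
    for k, b in zip(*np.nonzero(over)):
        out.append(f"clone {k}: variant {b} copy {C[k, b]} exceeds its allele segment copy {lim[k, b]}")

    U = freqs.U
    if U.shape[1] != N:
        out.append(f"U has {U.shape[1]} columns, expected {N}")
    else:
        if np.any(U < -atol):
            out.append("negative clone frequencies")
        bad = np.abs(U.sum(axis=1) - 1.0) > max(atol, 1e-9)
        for p in np.nonzero(bad)[0]:
            out.append(f"sample {p}: clone frequencies sum to {U[p].sum():.6g}")
        if freqs.leaf_only:
            internal = np.arange(tree.n, N - 1)
            if internal.size and np.any(U[:, internal] > atol):
                out.append("leaf-only mode but internal clones have mass")

    # Dollo life cycle per variant.
    if tree.W is not None and not tree.validate(n_variants=v):
        A = tree.ancestry().astype(bool)
        parents = tree.parents()
        present = C[:, :v] > 0
        for b in range(v):
            intro = np.argwhere(tree.W[:, :, b] == 1)
            if len(intro) > 1:
                continue  # already flagged by tree.validate
            if len(intro) == 0:
                if present[:, b].any():
                    out.append(f"variant {b} present but never introduced (no W edge)")
                continue
            i, j = intro[0]
            if present[i, b]:
                out.append(f"variant {b} introduced on edge ({i},{j}) but present in parent {i}")
            if not present[j, b]:
                out.append(f"variant {b} introduced on edge ({i},{j}) but absent in child {j}")
            inside = A[j] | (np.arange(N) == j)
            if np.any(present[~inside, b]):
                out.append(f"variant {b} present outside the subtree of its introduction")
            # no reappearance: a present node's parent (within the subtree,
            # excluding the introduction child) must be present
            for k in np.nonzero(present[:, b] & inside)[0]:
                if k != j and not present[parents[k], b]:
                    out.append(f"variant {b} reappears at clone {k} after loss (Dollo violation)")
    counters = {"n_violations": len(out)}
    return ValidationReport(out, counters)
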