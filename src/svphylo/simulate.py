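"""Clonal-evolution simulator: random clone trees, SV/SNV events, mixtures, noise.

The generator emulates multi-region bulk sequencing of a tumor: a uniformly
random rooted binary clone tree, structural variants (tandem duplications,
deletions, reciprocal translocations, inversions, relative rates 2:2:1:1)
and SNVs placed on random branches and alleles, allele-specific copy-number
tracking per clone, clonal mixing with per-sample frequencies drawn uniformly
from the simplex, and read-count noise (Poisson segment coverage, binomial
variant reads at the theoretical VAF / BAF).

Copy-number alterations arise only as consequences of duplication and
deletion events; translocations and inversions are copy-neutral and
contribute breakpoints only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import (
    BulkObservation,
    CloneProfiles,
    CloneTree,
    FrequencyMatrix,
    VariantPanel,
    build_panel,
    order_alleles,
)

__all__ = [
    "SimConfig",
    "Event",
    "GroundTruth",
    "simulate_tree",
    "simulate_events",
    "realize_profiles",
    "simulate_mixture",
    "add_read_noise",
    "simulate_cohort",
]

# hg38 autosome lengths (bp); SV densities in the 20-40 events range only
# make sense against a whole-genome coordinate space.
HUMAN_AUTOSOMES: tuple[int, ...] = (
    248_956_422, 242_193_529, 198_295_559, 190_214_555, 181_538_259,
    170_805_979, 159_345_973, 145_138_636, 138_394_717, 133_797_422,
    135_086_622, 133_275_309, 114_364_328, 107_043_718, 101_991_189,
    90_338_345, 83_257_441, 80_373_285, 58_617_616, 64_444_167,
    46_709_983, 50_818_468,
)


class ConfigError(ValueError):
    pass


def chrom_name(c: int) -> str:
    """Simulator chromosome index -> VCF contig name."""
    return f"chr{c + 1}"


class PlacementError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    ``lambda_total`` is the Poisson mean of the total SV count across the
    tree; ``lambda_branch``, if set, switches to per-branch Poisson counts.
    ``snv_rate`` defaults to 100x the total SV rate. SV span lengths are
    Poisson with mean ``sv_length_mean`` (empirical TCGA-BRCA average);
    duplication multiplicities are uniform integers in
    ``dup_multiplicity_range``; event types duplication:deletion:
    translocation:inversion are drawn with weights ``event_type_weights``.
    """

    n_leaves: int = 4
    m_samples: int = 5
    lambda_total: float = 20.0
    lambda_branch: float | None = None
    snv_rate: float | None = None  # default: 100 * lambda_total
    sv_length_mean: float = 5_745_000.0
    event_type_weights: tuple[float, float, float, float] = (2.0, 2.0, 1.0, 1.0)
    dup_multiplicity_range: tuple[int, int] = (2, 6)
    read_depth: float = 100.0
    c_max: int = 10
    genome: tuple[int, ...] = HUMAN_AUTOSOMES
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ConfigError("n_leaves must be >= 2")
        if self.m_samples < 1:
            raise ConfigError("m_samples must be >= 1")
        if any(w <= 0 for w in self.event_type_weights):
            raise ConfigError("event type weights must be positive")
        lo, hi = self.dup_multiplicity_range
        if lo < 2 or hi > self.c_max or lo > hi:
            raise ConfigError("dup multiplicity range must lie within [2, c_max]")
        if self.read_depth <= 0:
            raise ConfigError("read_depth must be positive")
        if self.sv_length_mean + 3 > max(self.genome):
            raise ConfigError("mean SV length does not fit in any chromosome")

    @property
    def snv_count_param(self) -> float:
        return 100.0 * self.lambda_total if self.snv_rate is None else self.snv_rate

    @classmethod
    def toy(cls, **kw) -> "SimConfig":
        """Desk-scale configuration: 2x50 Mb genome, 500 kb SVs."""
        kw.setdefault("genome", (50_000_000, 50_000_000))
        kw.setdefault("sv_length_mean", 500_000.0)
        return cls(**kw)


EVENT_KINDS = ("dup", "del", "tra", "inv")


@dataclass
class Event:
    """One mutational event on a tree edge (coordinates 1-based inclusive)."""

    seq: int                # draw order; defines within-edge application order
    kind: str               # dup | del | tra | inv | snv
    edge: tuple[int, int]   # (parent, child)
    allele: int             # 0 = first allele, 1 = second
    chrom: int
    start: int
    end: int                # == start for snv/tra anchors
    mult: int = 0           # duplication multiplicity
    chrom2: int = -1        # translocation partner
    pos2: int = -1
    applied: bool = True    # set by realize_profiles


# ---------------------------------------------------------------------------
# Random tree
# ---------------------------------------------------------------------------

def simulate_tree(n_leaves: int, seed=None) -> CloneTree:
    """Uniformly random rooted binary labeled tree topology on n leaves.

    Uses sequential leaf insertion: a tree with k leaves offers 2k-1
    attachment positions (every edge plus a new root), which reproduces the
    uniform distribution over the (2n-3)!! labeled topologies.
    """
    if n_leaves < 2:
        raise ConfigError("a clone tree needs at least 2 leaves")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # temp ids; leaves 0..n-1 in creation order, internals negative
    next_internal = [-1]

    def new_internal():
        i = next_internal[0]
        next_internal[0] -= 1
        return i

    root = new_internal()
    children: dict[int, list[int]] = {root: [0, 1]}
    parent: dict[int, int] = {0: root, 1: root}
    for leaf in range(2, n_leaves):
        edges = [(u, v) for u, ch in children.items() for v in ch]
        k = rng.integers(0, len(edges) + 1)
        w = new_internal()
        if k == len(edges):  # new root above the old one
            children[w] = [root, leaf]
            parent[root] = w
            parent[leaf] = w
            root = w
        else:
            u, v = edges[k]
            children[u][children[u].index(v)] = w
            children[w] = [v, leaf]
            parent[v] = w
            parent[w] = u
            parent[leaf] = w

    # relabel: leaves keep 0..n-1, root -> N-1, other internals n..N-2 (BFS)
    N = 2 * n_leaves - 1
    label = {root: N - 1}
    nxt = n_leaves
    queue = [root]
    while queue:
        u = queue.pop(0)
        for v in children.get(u, []):
            if v < 0:
                label[v] = nxt
                nxt += 1
                queue.append(v)
    parents_arr = np.full(N, -1, dtype=int)
    for v, u in parent.items():
        child = label[v] if v < 0 else v
        parents_arr[child] = label[u]
    return CloneTree.from_parents(n_leaves, parents_arr)


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def simulate_events(tree: CloneTree, config: SimConfig, seed=None) -> list[Event]:
    """Draw the SV and SNV event log for a tree under the configured rates."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    edges = [(int(i), int(j)) for i, j in zip(*np.nonzero(tree.E))]
    genome = config.genome
    n_chrom = len(genome)
    weights = np.asarray(config.event_type_weights, dtype=float)
    weights = weights / weights.sum()
    lo, hi = config.dup_multiplicity_range

    events: list[Event] = []
    seq = 0

    def draw_span(kind: str) -> tuple[int, int, int]:
        """Uniform chromosome, interior span with Poisson length."""
        for _ in range(50):
            chrom = int(rng.integers(n_chrom))
            L = genome[chrom]
            length = max(1, int(rng.poisson(config.sv_length_mean)))
            if length + 3 > L:
                continue
            start = int(rng.integers(2, L - length))  # keep 1-bp flanks
            return chrom, start, start + length - 1
        raise PlacementError(f"could not place a {kind} event after 50 attempts")

    def make_sv(edge: tuple[int, int]) -> Event:
        nonlocal seq
        kind = EVENT_KINDS[int(rng.choice(4, p=weights))]
        allele = int(rng.integers(2))
        if kind == "tra":
            for _ in range(50):
                c1 = int(rng.integers(n_chrom))
                c2 = int(rng.integers(n_chrom))
                p1 = int(rng.integers(2, genome[c1] - 1))
                p2 = int(rng.integers(2, genome[c2] - 1))
                if c1 != c2 or abs(p1 - p2) > 1:
                    break
            else:  # pragma: no cover
                raise PlacementError("could not place a translocation")
            ev = Event(seq, "tra", edge, allele, c1, p1, p1, chrom2=c2, pos2=p2)
        else:
            chrom, a, b = draw_span(kind)
            mult = int(rng.integers(lo, hi + 1)) if kind == "dup" else 0
            ev = Event(seq, kind, edge, allele, chrom, a, b, mult=mult)
        seq += 1
        return ev

    if config.lambda_branch is not None:
        for edge in edges:
            for _ in range(rng.poisson(config.lambda_branch)):
                events.append(make_sv(edge))
    else:
        for _ in range(rng.poisson(config.lambda_total)):
            edge = edges[int(rng.integers(len(edges)))]
            events.append(make_sv(edge))

    n_snv = rng.poisson(config.snv_count_param)
    lens = np.asarray(genome, dtype=float)
    chrom_p = lens / lens.sum()  # SNV positions uniform over the genome
    for _ in range(n_snv):
        chrom = int(rng.choice(n_chrom, p=chrom_p))
        pos = int(rng.integers(1, genome[chrom] + 1))
        edge = edges[int(rng.integers(len(edges)))]
        allele = int(rng.integers(2))
        events.append(Event(seq, "snv", edge, allele, chrom, pos, pos))
        seq += 1
    return events


# ---------------------------------------------------------------------------
# Profile realization
# ---------------------------------------------------------------------------

@dataclass
class _PointVar:
    """A point-tracked variant (breakpoint end or SNV)."""

    vid: str
    kind: str          # "bp" | "snv"
    chrom: int
    pos: int
    direction: str     # bp only
    mate: str          # bp only
    allele: int
    event_seq: int
    edge: tuple[int, int]
    init_copy: int


def _event_points(ev: Event) -> list[_PointVar]:
    """Breakpoint/SNV loci generated by one event (positions fixed a priori)."""
    e, al, s = ev.edge, ev.allele, ev.seq
    out = []
    if ev.kind == "snv":
        out.append(_PointVar(f"snv{s}", "snv", ev.chrom, ev.start, "", "", al, s, e, 1))
    elif ev.kind == "dup":
        k = ev.mult - 1
        out.append(_PointVar(f"bp{s}a", "bp", ev.chrom, ev.end, "right", f"bp{s}b", al, s, e, k))
        out.append(_PointVar(f"bp{s}b", "bp", ev.chrom, ev.start, "left", f"bp{s}a", al, s, e, k))
    elif ev.kind == "del":
        out.append(_PointVar(f"bp{s}a", "bp", ev.chrom, ev.start - 1, "right", f"bp{s}b", al, s, e, 1))
        out.append(_PointVar(f"bp{s}b", "bp", ev.chrom, ev.end + 1, "left", f"bp{s}a", al, s, e, 1))
    elif ev.kind == "inv":
        a, b = ev.start, ev.end
        out.append(_PointVar(f"bp{s}a", "bp", ev.chrom, a - 1, "right", f"bp{s}b", al, s, e, 1))
        out.append(_PointVar(f"bp{s}b", "bp", ev.chrom, b, "right", f"bp{s}a", al, s, e, 1))
        out.append(_PointVar(f"bp{s}c", "bp", ev.chrom, a, "left", f"bp{s}d", al, s, e, 1))
        out.append(_PointVar(f"bp{s}d", "bp", ev.chrom, b + 1, "left", f"bp{s}c", al, s, e, 1))
    elif ev.kind == "tra":
        p1, c1, p2, c2 = ev.start, ev.chrom, ev.pos2, ev.chrom2
        out.append(_PointVar(f"bp{s}a", "bp", c1, p1, "right", f"bp{s}b", al, s, e, 1))
        out.append(_PointVar(f"bp{s}b", "bp", c2, p2 + 1, "left", f"bp{s}a", al, s, e, 1))
        out.append(_PointVar(f"bp{s}c", "bp", c2, p2, "right", f"bp{s}d", al, s, e, 1))
        out.append(_PointVar(f"bp{s}d", "bp", c1, p1 + 1, "left", f"bp{s}c", al, s, e, 1))
    return out


def realize_profiles(
    tree: CloneTree, events: Sequence[Event], config: SimConfig, seed=None
) -> tuple[CloneProfiles, VariantPanel, CloneTree, dict]:
    """Replay events along the tree into integer allele-specific profiles.

    Segment boundaries are the union of all event endpoints across the
    cohort. Duplication multiplies one copy of its span (variants ride the
    chosen copy), deletion removes one copy (a variant is lost with
    probability copy/segment-copy), translocations and inversions are
    copy-neutral. Copies are capped at ``c_max`` (cap events counted in the
    returned info dict). Events that cannot apply (zero-copy span) are
    dropped and flagged ``applied=False``.

    Returns (profiles, panel, tree-with-W-and-rho, info).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    genome = config.genome
    n_chrom = len(genome)

    # ---- segmentation: cut points from event endpoints
    cuts: list[set[int]] = [set([1, L + 1]) for L in genome]
    for ev in events:
        if ev.kind in ("dup", "del", "inv"):
            cuts[ev.chrom].update((ev.start, ev.end + 1))
        elif ev.kind == "tra":
            cuts[ev.chrom].add(ev.start + 1)
            cuts[ev.chrom2].add(ev.pos2 + 1)
    seg_start, seg_end, seg_chrom = [], [], []
    chrom_first = []  # first global segment index of each chromosome
    for c in range(n_chrom):
        pts = sorted(cuts[c])
        chrom_first.append(len(seg_start))
        for a, b in zip(pts[:-1], pts[1:]):
            seg_chrom.append(c)
            seg_start.append(a)
            seg_end.append(b - 1)
    seg_start_a = np.asarray(seg_start)
    seg_chrom_a = np.asarray(seg_chrom)
    n_seg = len(seg_start)

    def seg_index(chrom: int, pos: int) -> int:
        lo = chrom_first[chrom]
        hi = chrom_first[chrom + 1] if chrom + 1 < n_chrom else n_seg
        return lo + int(np.searchsorted(seg_start_a[lo:hi], pos, side="right")) - 1

    # ---- point-variant registry (all candidates; applied subset kept)
    points: list[_PointVar] = []
    ev_points: dict[int, list[int]] = {}
    for ev in events:
        idxs = []
        for pv in _event_points(ev):
            idxs.append(len(points))
            points.append(pv)
        ev_points[ev.seq] = idxs
        ev._point_idx = idxs  # type: ignore[attr-defined]
    n_pts = len(points)
    pt_seg = np.array([seg_index(p.chrom, p.pos) for p in points], dtype=int) if n_pts else np.zeros(0, int)
    pt_allele = np.array([p.allele for p in points], dtype=int) if n_pts else np.zeros(0, int)

    # ---- replay
    N = tree.N
    cmax = config.c_max
    seg_copy = np.zeros((N, 2, n_seg), dtype=int)
    var_copy = np.zeros((N, n_pts), dtype=int)
    seg_copy[tree.root] = 1
    applied: dict[int, bool] = {}
    n_caps = 0

    events_by_edge: dict[tuple[int, int], list[Event]] = {}
    for ev in events:
        events_by_edge.setdefault(ev.edge, []).append(ev)
    for lst in events_by_edge.values():
        lst.sort(key=lambda e: e.seq)

    for node in tree.topo_order():
        if node != tree.root:
            par = int(tree.parents()[node])
            seg_copy[node] = seg_copy[par]
            var_copy[node] = var_copy[par]
            sc = seg_copy[node].copy()
            vc = var_copy[node].copy()
            for ev in events_by_edge.get((par, node), []):
                ok = _apply_event(ev, sc, vc, seg_index, pt_seg, pt_allele, cmax, rng)
                applied[ev.seq] = ok
                if ok:
                    n_caps += int(np.sum(sc > cmax))
                    np.minimum(sc, cmax, out=sc)
                    # variant copies never exceed their allele's segment copy
                    if n_pts:
                        np.minimum(vc, sc[pt_allele, pt_seg], out=vc)
            seg_copy[node] = sc
            var_copy[node] = vc
    for ev in events:
        ev.applied = applied.get(ev.seq, False)

    # ---- assemble panel from applied variants (chromosomes named chr1..chrK)
    keep = [i for ev in events if ev.applied for i in ev_points[ev.seq]]
    keep_set = set(keep)
    bp_records, snv_records = [], []
    for i in keep:
        p = points[i]
        if p.kind == "bp":
            bp_records.append(dict(id=p.vid, chrom=chrom_name(p.chrom), pos=p.pos,
                                   direction=p.direction, mate_id=p.mate))
        else:
            snv_records.append(dict(id=p.vid, chrom=chrom_name(p.chrom), pos=p.pos))
    seg_records = [dict(chrom=chrom_name(c), start=int(a), end=int(b))
                   for c, a, b in zip(seg_chrom, seg_start, seg_end)]
    panel = build_panel(bp_records, snv_records, seg_records)

    # map registry -> panel columns (build_panel re-sorts rows and segments)
    vid_to_pt = {points[i].vid: i for i in keep_set}
    order = [vid_to_pt[v] for v in panel.variant_ids()]
    seg_key = {(chrom_name(c), int(a)): i for i, (c, a) in enumerate(zip(seg_chrom, seg_start))}
    seg_perm = [seg_key[(row.chrom, int(row.start))] for row in panel.segments.itertuples()]
    v = panel.n_variants
    C = np.zeros((N, panel.n_cols), dtype=int)
    C[:, :v] = var_copy[:, order]
    C[:, v : v + n_seg] = seg_copy[:, 0, :][:, seg_perm]
    C[:, v + n_seg :] = seg_copy[:, 1, :][:, seg_perm]
    D = np.array([1 if points[i].allele == 0 else 0 for i in order], dtype=np.int8)

    W = np.zeros((N, N, v), dtype=np.int8)
    var_edge = np.zeros(v, dtype=int)  # introduction child node per variant
    for b, i in enumerate(order):
        pi, pj = points[i].edge
        W[pi, pj, b] = 1
        var_edge[b] = pj

    # branch lengths from allele-specific segment copy changes
    rho = np.zeros((N, N), dtype=float)
    for i, j in zip(*np.nonzero(tree.E)):
        rho[i, j] = np.abs(C[j, v:] - C[i, v:]).sum()

    out_tree = CloneTree(n=tree.n, E=tree.E.copy(), W=W, rho=rho)
    profiles = CloneProfiles(C=C, D=D, c_max=cmax)
    info = {"n_caps": n_caps,
            "n_dropped_events": sum(1 for e in events if not e.applied),
            "variant_intro_node": var_edge}
    return profiles, panel, out_tree, info


def _apply_event(ev, sc, vc, seg_index, pt_seg, pt_allele, cmax, rng) -> bool:
    """Mutate (sc, vc) in place; return False if the event cannot apply."""
    al = ev.allele
    if ev.kind == "snv":
        s = seg_index(ev.chrom, ev.start)
        if sc[al, s] < 1:
            return False
        i = _own_point(ev, pt_seg)  # single point
        vc[i] = 1
        return True
    if ev.kind in ("dup", "del", "inv"):
        s0 = seg_index(ev.chrom, ev.start)
        s1 = seg_index(ev.chrom, ev.end)
        span = slice(s0, s1 + 1)
        if np.any(sc[al, span] < 1):
            return False
    if ev.kind == "dup":
        k = ev.mult - 1
        riders = _span_variants(ev.chrom, ev.start, ev.end, al, pt_seg, pt_allele, vc, sc, seg_index, rng)
        sc[al, span] += k
        for i in riders:
            vc[i] += k
        for i in _own_points(ev):
            vc[i] = min(k, int(sc[pt_allele[i], pt_seg[i]]))
        return True
    if ev.kind == "del":
        fl = seg_index(ev.chrom, ev.start - 1)
        fr = seg_index(ev.chrom, ev.end + 1)
        if sc[al, fl] < 1 or sc[al, fr] < 1:
            return False
        riders = _span_variants(ev.chrom, ev.start, ev.end, al, pt_seg, pt_allele, vc, sc, seg_index, rng)
        sc[al, span] -= 1
        for i in riders:
            vc[i] -= 1
        for i in _own_points(ev):
            vc[i] = 1
        return True
    if ev.kind == "inv":
        need = [seg_index(ev.chrom, p) for p in (ev.start - 1, ev.end + 1)]
        if any(sc[al, s] < 1 for s in need):
            return False
        for i in _own_points(ev):
            vc[i] = 1
        return True
    if ev.kind == "tra":
        need = [seg_index(ev.chrom, ev.start), seg_index(ev.chrom, ev.start + 1),
                seg_index(ev.chrom2, ev.pos2), seg_index(ev.chrom2, ev.pos2 + 1)]
        if any(sc[al, s] < 1 for s in need):
            return False
        for i in _own_points(ev):
            vc[i] = 1
        return True
    raise ValueError(f"unknown event kind {ev.kind!r}")  # pragma: no cover


def _own_points(ev: Event) -> list[int]:
    return ev._point_idx  # type: ignore[attr-defined]


def _own_point(ev: Event, pt_seg) -> int:
    return ev._point_idx[0]  # type: ignore[attr-defined]


def _span_variants(chrom, start, end, allele, pt_seg, pt_allele, vc, sc, seg_index, rng):
    """Indices of existing variants that ride the affected copy (Bernoulli v/c)."""
    if len(pt_seg) == 0:
        return []
    s0 = seg_index(chrom, start)
    s1 = seg_index(chrom, end)
    mask = (pt_seg >= s0) & (pt_seg <= s1) & (pt_allele == allele) & (vc > 0)
    idx = np.nonzero(mask)[0]
    out = []
    for i in idx:
        c = sc[allele, pt_seg[i]]
        p = min(1.0, vc[i] / c) if c > 0 else 0.0
        if rng.random() < p:
            out.append(int(i))
    return out


# ---------------------------------------------------------------------------
# Mixture & noise
# ---------------------------------------------------------------------------

def simulate_mixture(
    profiles: CloneProfiles, m_samples: int, seed=None
) -> tuple[FrequencyMatrix, np.ndarray]:
    """Per-sample clone fractions uniform on the simplex; noiseless F = U C."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    N = profiles.N
    U = rng.dirichlet(np.ones(N), size=m_samples)
    F = U @ profiles.C
    return FrequencyMatrix(U=U), F


def add_read_noise(
    F_noiseless: np.ndarray, panel: VariantPanel, config: SimConfig, seed=None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Perturb noiseless mean copy numbers with read-count noise.

    Per sample and segment, coverage rc ~ Poisson(read_depth). Each variant in
    the segment draws alt reads ~ Binomial(rc, theoretical VAF) giving the
    noisy mean copy (alt/rc) * psi. Each segment draws allele-informative
    reads ~ Binomial(rc, theoretical BAF) splitting the theoretical total
    copy into noisy allele-specific copies. Segments with rc = 0 fall back to
    their theoretical values (count returned).

    Returns (noisy F, rc matrix of shape (m, r), n_zero_rc).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    F = np.asarray(F_noiseless, dtype=float)
    m = F.shape[0]
    v, r = panel.n_variants, panel.r
    a1 = F[:, v : v + r]
    a2 = F[:, v + r :]
    tot = a1 + a2
    with np.errstate(divide="ignore", invalid="ignore"):
        baf = np.where(tot > 0, a2 / np.where(tot > 0, tot, 1.0), 0.0)
    psi = tot[:, panel.segment_of] if v else np.zeros((m, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(psi > 0, F[:, :v] / np.where(psi > 0, psi, 1.0), 0.0)
    vaf = np.clip(vaf, 0.0, 1.0)

    rc = rng.poisson(config.read_depth, size=(m, r))
    Fn = F.copy()
    nz = rc[:, panel.segment_of] if v else np.zeros((m, 0), int)
    alt = rng.binomial(nz, vaf)
    with np.errstate(divide="ignore", invalid="ignore"):
        Fn[:, :v] = np.where(nz > 0, alt / np.where(nz > 0, nz, 1) * psi, F[:, :v])
    k2 = rng.binomial(rc, np.clip(baf, 0.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        noisy_a2 = np.where(rc > 0, k2 / np.where(rc > 0, rc, 1) * tot, a2)
    Fn[:, v + r :] = noisy_a2
    Fn[:, v : v + r] = np.where(rc > 0, tot - noisy_a2, a1)
    return Fn, rc, int(np.sum(rc == 0))


# ---------------------------------------------------------------------------
# End-to-end cohort
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the simulator knows about one synthetic cohort."""

    config: SimConfig
    panel: VariantPanel
    tree: CloneTree
    profiles: CloneProfiles
    freqs: FrequencyMatrix
    F_true: np.ndarray              # noiseless, allele-ordered
    obs: BulkObservation            # noisy, allele-ordered
    events: list[Event] = field(default_factory=list)
    rc: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    @property
    def variant_intro_node(self) -> np.ndarray:
        return self.info["variant_intro_node"]


def simulate_cohort(config: SimConfig, seed=None) -> GroundTruth:
    """Full simulation pipeline: tree -> events -> profiles -> mixture -> noise.

    The ground truth is reported in the same allele-ordering convention the
    solver sees: per segment, the allele with the (majority-vote) larger
    noiseless mixed copy number is the first allele.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tree = simulate_tree(config.n_leaves, rng)
    events = simulate_events(tree, config, rng)
    profiles, panel, tree, info = realize_profiles(tree, events, config, rng)
    freqs, F_true = simulate_mixture(profiles, config.m_samples, rng)

    # orient truth alleles by majority vote on the noiseless mixture
    v, r = panel.n_variants, panel.r
    a1 = F_true[:, v : v + r]
    a2 = F_true[:, v + r :]
    swap = (a1 < a2).sum(axis=0) > (a1 >= a2).sum(axis=0)
    if np.any(swap):
        _swap_alleles(profiles, panel, swap)
        F_true = freqs.U @ profiles.C
    F_noisy, rc, n_zero_rc = add_read_noise(F_true, panel, config, rng)
    obs = order_alleles(F_noisy, panel)
    info = dict(info, n_zero_rc=n_zero_rc)
    return GroundTruth(
        config=config, panel=panel, tree=tree, profiles=profiles, freqs=freqs,
        F_true=F_true, obs=obs, events=list(events), rc=rc, info=info,
    )


def _swap_alleles(profiles: CloneProfiles, panel: VariantPanel, swap: np.ndarray) -> None:
    """Swap allele-1/allele-2 roles for the flagged segments, in place."""
    v, r = panel.n_variants, panel.r
    C = profiles.C
    a1 = C[:, v : v + r].copy()
    a2 = C[:, v + r :].copy()
    a1[:, swap], a2[:, swap] = a2[:, swap], a1[:, swap].copy()
    C[:, v : v + r] = a1
    C[:, v + r :] = a2
    seg = panel.segment_of
    flip = swap[seg]
    profiles.D[flip] = 1 - profiles.D[flip]
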