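"""Read and write per-sample variant-call files and solver artifacts.

VCF dialect (one single-sample VCF 4.2 file per sample; a cohort is a
directory of them):

* SV breakpoints: ``SVTYPE=BND`` records with bracketed ALT and ``MATEID``;
  the mean adjacency copy number rides in FORMAT field ``BPCN`` (float).
* SNVs: plain substitution records with FORMAT ``SCN`` (mean variant copy
  number, float) or ``VAF`` (converted using the covering CNA record).
* CNAs: ``SVTYPE=CNV`` records with INFO ``END`` and FORMAT ``CN1``/``CN2``
  (allele-specific mean segment copies, floats).

Matrices are written as TSV (tab-separated, UTF-8, '.'-decimal), trees as
Graphviz DOT and Newick.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

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
    "SampleCallSet",
    "read_cohort",
    "write_cohort",
    "filter_segments_to_variant_bearing",
    "write_solution",
    "read_matrix",
]


class CohortError(ValueError):
    pass


# direction pair -> bracketed ALT template; {m} is "chrom:pos" of the mate
_ALT_FORM = {
    ("right", "left"): "N[{m}[",
    ("right", "right"): "N]{m}]",
    ("left", "left"): "[{m}[N",
    ("left", "right"): "]{m}]N",
}


@dataclass
class SampleCallSet:
    """Variant calls of one sample (shared universe enforced at cohort level)."""

    sample: str
    breakpoints: pd.DataFrame  # id, chrom, pos, direction, mate_id, bpcn
    snvs: pd.DataFrame         # id, chrom, pos, scn (mean variant copy)
    cnas: pd.DataFrame         # chrom, start, end, cn1, cn2


# ---------------------------------------------------------------------------
# Writing cohorts
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the segment">
##FORMAT=<ID=BPCN,Number=1,Type=Float,Description="Mean breakpoint adjacency copy number">
##FORMAT=<ID=SCN,Number=1,Type=Float,Description="Mean SNV variant copy number">
##FORMAT=<ID=CN1,Number=1,Type=Float,Description="Mean copy number of allele 1">
##FORMAT=<ID=CN2,Number=1,Type=Float,Description="Mean copy number of allele 2">
"""


def write_cohort(
    panel: VariantPanel, F: np.ndarray, out_dir, sample_names=None
) -> list[Path]:
    """Write one VCF per sample from a panel and raw F matrix (panel layout)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = F.shape[0]
    sample_names = sample_names or [f"sample{p}" for p in range(m)]
    v, l, r = panel.n_variants, panel.l, panel.r
    contigs = sorted(set(panel.segments["chrom"].astype(str)))
    seg_end_by_chrom = panel.segments.groupby("chrom")["end"].max()
    paths = []
    for p in range(m):
        path = out_dir / f"{sample_names[p]}.vcf"
        rows = []
        bp = panel.breakpoints
        for b in range(l):
            rec = bp.iloc[b]
            mate_row = bp.iloc[int(panel.mate_of[b])]
            alt = _ALT_FORM[(rec["direction"], mate_row["direction"])].format(
                m=f"{mate_row['chrom']}:{mate_row['pos']}"
            )
            rows.append((str(rec["chrom"]), int(rec["pos"]), rec["id"], "N", alt,
                         f"SVTYPE=BND;MATEID={rec['mate_id']}", "BPCN", f"{F[p, b]:.6g}"))
        for s in range(panel.g):
            rec = panel.snvs.iloc[s]
            ref = rec.get("ref", "N") if hasattr(rec, "get") else "N"
            alt = rec.get("alt", "A") if hasattr(rec, "get") else "A"
            rows.append((str(rec["chrom"]), int(rec["pos"]), rec["id"],
                         str(ref) if str(ref) != "N" else "A",
                         str(alt) if str(alt) not in ("N", str(ref)) else "T",
                         ".", "SCN", f"{F[p, l + s]:.6g}"))
        for s in range(r):
            rec = panel.segments.iloc[s]
            rows.append((str(rec["chrom"]), int(rec["start"]), f"seg{s}", "N", "<CNV>",
                         f"SVTYPE=CNV;END={int(rec['end'])}", "CN1:CN2",
                         f"{F[p, v + s]:.6g}:{F[p, v + r + s]:.6g}"))
        rows.sort(key=lambda t: (t[0], t[1]))
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for c in contigs:
                fh.write(f"##contig=<ID={c},length={int(seg_end_by_chrom[c])}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + sample_names[p] + "\n")
            for row in rows:
                chrom, pos, vid, ref, alt, info, fmt, val = row
                fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t{info}\t{fmt}\t{val}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Reading cohorts
# ---------------------------------------------------------------------------

def _parse_bnd_alt(alt: str) -> tuple[str, str]:
    """Return (self_direction, mate_direction) from a bracketed BND ALT."""
    if alt.endswith("[") and "[" in alt[:-1]:
        return "right", "left"
    if alt.endswith("]") and "]" in alt[:-1]:
        return "right", "right"
    if alt.startswith("["):
        return "left", "left"
    if alt.startswith("]"):
        return "left", "right"
    raise CohortError(f"unparseable BND ALT {alt!r}")


def read_sample(path) -> SampleCallSet:
    """Parse one single-sample VCF of the package dialect."""
    vf = pysam.VariantFile(os.fspath(path))
    samples = list(vf.header.samples)
    if len(samples) != 1:
        raise CohortError(f"{path}: expected a single-sample VCF, found {samples}")
    sample = samples[0]
    bps, snvs, cnas = [], [], []
    for ln, rec in enumerate(vf):
        svtype = rec.info.get("SVTYPE")
        fmt = rec.samples[sample]
        if svtype == "BND":
            d_self, _ = _parse_bnd_alt(rec.alts[0])
            if rec.info.get("MATEID") is None or fmt.get("BPCN") is None:
                raise CohortError(f"{path}: malformed BND record {rec.id} (line ~{ln})")
            bps.append(dict(id=rec.id, chrom=rec.chrom, pos=rec.pos,
                            direction=d_self, mate_id=rec.info["MATEID"],
                            bpcn=float(fmt["BPCN"])))
        elif svtype == "CNV":
            if fmt.get("CN1") is None or fmt.get("CN2") is None:
                raise CohortError(f"{path}: CNV record without CN1/CN2 (line ~{ln})")
            cnas.append(dict(chrom=rec.chrom, start=rec.pos, end=rec.stop,
                             cn1=float(fmt["CN1"]), cn2=float(fmt["CN2"])))
        else:
            scn = fmt.get("SCN")
            vaf = fmt.get("VAF")
            if scn is None and vaf is None:
                raise CohortError(f"{path}: SNV record {rec.id} lacks SCN and VAF (line ~{ln})")
            snvs.append(dict(id=rec.id, chrom=rec.chrom, pos=rec.pos,
                             scn=None if scn is None else float(scn),
                             vaf=None if vaf is None else float(vaf)))
    return SampleCallSet(
        sample=sample,
        breakpoints=pd.DataFrame(bps, columns=["id", "chrom", "pos", "direction", "mate_id", "bpcn"]),
        snvs=pd.DataFrame(snvs, columns=["id", "chrom", "pos", "scn", "vaf"]),
        cnas=pd.DataFrame(cnas, columns=["chrom", "start", "end", "cn1", "cn2"]),
    )


def read_cohort(paths) -> tuple[VariantPanel, BulkObservation]:
    """Read a cohort (directory or list of VCFs) into a panel and F matrix.

    Sample order follows the input order (directories are read in sorted
    filename order). Segment boundaries are the union of all CNA record
    boundaries across samples; every sample must cover every derived segment
    with exactly one CNA record, and all samples must share the same
    breakpoint/SNV universe.
    """
    if isinstance(paths, (str, Path)) and Path(paths).is_dir():
        paths = sorted(Path(paths).glob("*.vcf"))
    paths = [Path(p) for p in paths]
    if not paths:
        raise CohortError("no VCF files found")
    calls = [read_sample(p) for p in paths]

    # shared variant universe
    ref = calls[0]
    issues = []
    for cs in calls[1:]:
        for attr, key in (("breakpoints", ["id", "chrom", "pos", "direction", "mate_id"]),
                          ("snvs", ["id", "chrom", "pos"])):
            a = getattr(ref, attr)[key].sort_values(key).reset_index(drop=True)
            b = getattr(cs, attr)[key].sort_values(key).reset_index(drop=True)
            if not a.equals(b):
                issues.append(f"{cs.sample}: {attr} differ from {ref.sample}")
    if issues:
        raise CohortError("inconsistent variant universes: " + "; ".join(issues))

    # union re-segmentation
    cuts: dict[str, set[int]] = {}
    for cs in calls:
        for row in cs.cnas.itertuples():
            cuts.setdefault(row.chrom, set()).update((int(row.start), int(row.end) + 1))
    seg_records = []
    for chrom in sorted(cuts):
        pts = sorted(cuts[chrom])
        for a, b in zip(pts[:-1], pts[1:]):
            seg_records.append(dict(chrom=chrom, start=a, end=b - 1))
    # drop gaps not covered by any sample's records
    covered = []
    for rec in seg_records:
        if any(
            ((cs.cnas["chrom"] == rec["chrom"]) & (cs.cnas["start"] <= rec["start"])
             & (cs.cnas["end"] >= rec["end"])).any()
            for cs in calls
        ):
            covered.append(rec)
    panel = build_panel(
        ref.breakpoints[["id", "chrom", "pos", "direction", "mate_id"]].to_dict("records"),
        ref.snvs[["id", "chrom", "pos"]].to_dict("records"),
        covered,
    )

    m = len(calls)
    v, l, r = panel.n_variants, panel.l, panel.r
    F = np.zeros((m, panel.n_cols))
    for p, cs in enumerate(calls):
        # segments: each output segment needs exactly one covering record
        for s, seg in enumerate(panel.segments.itertuples()):
            hit = cs.cnas[(cs.cnas["chrom"] == seg.chrom)
                          & (cs.cnas["start"] <= seg.start)
                          & (cs.cnas["end"] >= seg.end)]
            if len(hit) != 1:
                raise CohortError(
                    f"{cs.sample}: segment {seg.chrom}:{seg.start}-{seg.end} covered by "
                    f"{len(hit)} CNA records (expected 1)"
                )
            F[p, v + s] = hit["cn1"].iloc[0]
            F[p, v + r + s] = hit["cn2"].iloc[0]
        bp_order = {bid: i for i, bid in enumerate(panel.breakpoints["id"])}
        for row in cs.breakpoints.itertuples():
            F[p, bp_order[row.id]] = row.bpcn
        snv_order = {sid: l + i for i, sid in enumerate(panel.snvs["id"])}
        seg_of = panel.segment_of
        for row in cs.snvs.itertuples():
            b = snv_order[row.id]
            if row.scn is not None and not (isinstance(row.scn, float) and np.isnan(row.scn)):
                F[p, b] = row.scn
            else:
                # VAF -> mean copy number via the covering segment's total copy
                s = seg_of[b]
                F[p, b] = float(row.vaf) * (F[p, v + s] + F[p, v + r + s])
    return panel, order_alleles(F, panel)


# ---------------------------------------------------------------------------
# Segment filtering (keep only variant-bearing segments)
# ---------------------------------------------------------------------------

def filter_segments_to_variant_bearing(
    panel: VariantPanel, obs: BulkObservation | np.ndarray
) -> tuple[VariantPanel, BulkObservation]:
    """Drop segments containing no breakpoint or SNV; slice Q and F consistently."""
    F = obs.F if isinstance(obs, BulkObservation) else np.asarray(obs, dtype=float)
    keep = np.asarray(panel.Q.sum(axis=0) > 0)
    if keep.all():
        sub_panel, F2 = panel, F
    else:
        v, r = panel.n_variants, panel.r
        segs = panel.segments.loc[keep].reset_index(drop=True)
        sub_panel = VariantPanel(
            breakpoints=panel.breakpoints, snvs=panel.snvs, segments=segs,
            Q=panel.Q[:, keep], G=panel.G,
        )
        sub_panel.validate()
        cols = np.concatenate([np.ones(v, bool), keep, keep])
        F2 = F[:, cols]
    v = sub_panel.n_variants
    r = sub_panel.r
    seg_tot = F2[:, v : v + r] + F2[:, v + r :]
    psi = seg_tot[:, sub_panel.segment_of]
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(psi > 0, F2[:, :v] / np.where(psi > 0, psi, 1.0), 0.0)
    pi = np.clip(pi, 0.0, 1.0)
    return sub_panel, BulkObservation(F=F2, psi=psi, pi=pi)


# ---------------------------------------------------------------------------
# Solution artifacts
# ---------------------------------------------------------------------------

def write_solution(
    tree: CloneTree,
    profiles: CloneProfiles,
    freqs: FrequencyMatrix,
    panel: VariantPanel,
    out_dir,
    assignment: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write C.tsv, U.tsv, D.tsv, tree.dot, tree.newick (+assignment.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    clone_ids = [f"clone{i}" for i in range(tree.N)]
    col_ids = panel.column_ids()
    out = {}
    cdf = pd.DataFrame(profiles.C, index=clone_ids, columns=col_ids)
    cdf.to_csv(out_dir / "C.tsv", sep="\t")
    out["C"] = out_dir / "C.tsv"
    udf = pd.DataFrame(freqs.U, index=[f"sample{p}" for p in range(freqs.m)], columns=clone_ids)
    udf.to_csv(out_dir / "U.tsv", sep="\t")
    out["U"] = out_dir / "U.tsv"
    ddf = pd.DataFrame({"variant": panel.variant_ids(), "d": profiles.D})
    ddf.to_csv(out_dir / "D.tsv", sep="\t", index=False)
    out["D"] = out_dir / "D.tsv"

    if tree.W is not None:
        intro = np.full(panel.n_variants, -1, dtype=int)
        for i, j in zip(*np.nonzero(tree.E)):
            for b in np.nonzero(tree.W[i, j])[0]:
                intro[b] = j
        vdf = pd.DataFrame({
            "variant": panel.variant_ids(),
            "clone": intro,
            "d": profiles.D,
            "kind": ["bp"] * panel.l + ["snv"] * panel.g,
        })
        vdf.to_csv(out_dir / "variants.tsv", sep="\t", index=False)
        out["variants"] = out_dir / "variants.tsv"

    with open(out_dir / "tree.dot", "w") as fh:
        fh.write("digraph clones {\n")
        for i in range(tree.N):
            fh.write(f'  {i} [label="{clone_ids[i]}"];\n')
        for i, j in zip(*np.nonzero(tree.E)):
            rho = 0.0 if tree.rho is None else float(tree.rho[i, j])
            nvar = 0 if tree.W is None else int(tree.W[i, j].sum())
            fh.write(f'  {i} -> {j} [label="rho={rho:g}, variants={nvar}"];\n')
        fh.write("}\n")
    out["dot"] = out_dir / "tree.dot"
    with open(out_dir / "tree.newick", "w") as fh:
        fh.write(tree.newick(clone_ids) + "\n")
    out["newick"] = out_dir / "tree.newick"
    if assignment is not None:
        assignment.to_csv(out_dir / "assignment.tsv", sep="\t", index=False)
        out["assignment"] = out_dir / "assignment.tsv"
    return out


def read_matrix(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV matrix back as (values, row ids, column ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(), list(df.index), list(df.columns)
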