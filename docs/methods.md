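# Methods

## Problem and notation

A tumor is modeled as `N = 2n − 1` clones on a rooted binary tree whose last
node is the normal diploid root; leaves are nodes `0..n−1`, internal nodes
`n..N−2`. Bulk sample `p` measures mean copy numbers
`F[p, ·]` of `l` SV breakpoints, `g` SNVs and `r` genome segments (two
allele columns per segment, columns ordered `[breakpoints | SNVs |
allele-1 segments | allele-2 segments]`). The binary matrix `Q` places each
breakpoint/SNV in its unique segment, `G` pairs breakpoint mates. The
deconvolution `F ≈ U C` is estimated by minimizing
`|F − UC| + λ₁R + λ₂S` with

* `R = Σ_edges Σ_segments (|Δ allele-1 copy| + |Δ allele-2 copy|)` — the
  copy-number evolutionary distance, expressing that segments gain or lose
  single copies at a uniform rate;
* `S = Σ_{p,b} |π[p,b]·Σ_k u[p,k](γ[k,b,0]+γ[k,b,1]) − Σ_k u[p,k]c[k,b]|`,
  where `π` is the observed VAF and `γ` the allele-specific segment copy at
  the variant's locus — consistency between the variant's observed and
  implied allele frequencies. Entries with zero mixed segment copy
  (`Ψ[p,b] = 0`) carry no VAF information and are excluded.

`λ₁ = (l+g+2r)/(2·2rmN)` and `λ₂ = (l+g+2r)/(2(l+g))` equalize the expected
scales of the three terms; results are not very sensitive to them and both
can be overridden.

## Preprocessing

Allele columns arrive in arbitrary caller order. For each segment the
orientation is decided once for the whole cohort by majority vote across
samples of (allele-A ≥ allele-B), ties keeping input order, so every
segment has a common "first" (larger) allele in all samples. VAFs are
clamped to [0, 1] (clamp counts reported). Segments containing no
breakpoint or SNV can be dropped (`filter_segments_to_variant_bearing`),
which leaves `Ψ` of every retained variant unchanged.

## Coordinate descent

`U` is initialized uniformly at random on the simplex per sample (Dirichlet
(1,…,1)); the C-step and U-step alternate until the relative objective
improvement falls below `convergence_tol` (default 1e-4) or `max_iters`
(default 10). Several restarts (default 5) run with seeds spawned from the
master seed; the best final objective wins. The U-step is a per-sample LP
(auxiliary variables linearize the absolute values) and is solved to global
optimality; in leaf-only mode internal non-root clones are pinned to
frequency zero. The C-step is a MILP over

* integer `C` (bounds `[0, c_max]`; root row fixed to 0 variants / 1 per
  allele segment copy),
* binary tree variables `E`, `A` (in-degree 1 off the root, out-degree 2
  for internal nodes, `A ≥ E`, transitivity `a_ik ≥ a_ij + a_jk − 1`,
  antisymmetry `a_ij + a_ji ≤ 1`, `a_ii = 0`, root ancestral to all),
* a binarization `C̄` of the variant columns (`C̄ ≤ C ≤ c_max·C̄`),
* the introduction tensor `W` with the Dollo life cycle: per variant at
  most one introduction, `W` only on edges, introduction requires absence
  in the parent and presence in the child, and persistence
  `C̄[j,b] ≤ C̄[i,b] + W[i,j,b]` on every edge, so a variant lost by copy
  loss can never reappear;
* mate pairs share introduction edge and allele (`D`);
* per-edge nonnegative `x¹, x², ≥ |Δ allele copy|` deactivated by
  `c_max(1−e_ij)` big-Ms, whose sum is `R`;
* allele-phased coupling between variant copy change and segment copy
  change (below);
* variant ≤ allele segment copy (`c[k,b] ≤ γ[k,b,allele] + big-M` on the
  unused allele);
* VAF slack `z[p,b] ≥ ±(π·Σu(γ₀+γ₁) − Σu c)` whose sum is `S`.

HiGHS (via `scipy.optimize.milp`) solves the MILP single-threaded, which
makes runs reproducible for a fixed seed up to the solver's deterministic
tie-breaking. Internal-node children are required to have a higher-index
parent — pure symmetry breaking over node relabelings that leaves the
topology space intact. Before every solve the all-normal solution is
checked against the assembled constraint system; its infeasibility would
indicate a modeling bug.

### Variant/segment phasing coupling

On an edge (i, j) where variant `b` already exists in parent `i` (it is not
introduced on the edge) and sits on the active allele, the default
(`phasing="strict"`) couples the changes with equality:
`γ[j,b,a] − γ[i,b,a] = c[j,b] − c[i,b]`, realized with big-M coefficients
`(2c_max+1)` / `(2c_max+2)` and a deactivation term that includes the
parent-existence indicator `C̄[i,b]` — without that term any copy-number
change in a segment would constrain even variants absent from it, making
ordinary ground truths infeasible. The alternative reading
(`phasing="relaxed"`) only bounds the magnitude: `|Δc| ≤ x^a` on active
edges — appropriate when a multi-copy segment changes by a copy that may or
may not carry the variant. Both are exposed because the two readings
genuinely differ for multi-copy segments; strict is the default.

## Clone-number heuristic

With a preset maximal node count (default 9, i.e. 5 leaves) the solved tree
is collapsed: (i) zero-total-frequency nodes with exactly one child are
spliced out (the child's branch accumulates the removed branch's length and
variant count, so chained splices do not fabricate zero-length branches);
(ii) a child whose incoming branch has zero copy-number length and
introduces no variant is the same clone as its parent — frequencies are
summed and its children reattach. The surviving node count estimates the
clone number. The procedure is idempotent.

## Subsampling and post-hoc assignment

For large variant sets the MILP runs on a uniform subsample (breakpoint
mate pairs first, up to `max_breakpoints`; SNVs fill up to `max_total`; all
segments kept). Each held-out variant is then assigned the (node `i`,
allele `d`, scenario) minimizing the L1 distance across samples between its
observed mean copy number and the prediction:

* scenario 1 (variant acquired before the edge's copy change): predicted
  copy `u_i·ĉ_i + Σ_{k ∈ desc(i)} u_k·ĉ_k`, admissible iff `ĉ_i = 1` or
  `ĉ_i − ĉ_parent(i) > 1` (a documented flag relaxes the second clause to
  ≥ 1);
* scenario 2 (acquired after): `u_i·1 + Σ_k u_k·ĉ_k/ĉ_i`, admissible iff
  `ĉ_i ≥ 1`,

where `ĉ` is the allele-`d` copy of the variant's segment. Ties break to
the smallest node index, then allele 1, then scenario 1. Held-out mate
pairs are assigned jointly (summed distance, shared node/allele/scenario)
to honor the common-edge rule. Merging writes scenario-1 variants at their
allele's segment copy throughout the subtree and scenario-2 variants at
copy 1 in the assigned clone with half-up-rounded expectations below
(pre-rounding values recorded; zeros propagate to descendants so the merged
profile keeps the Dollo life cycle). The tree is not re-optimized after
mapping.

## Simulator

The generator draws a uniformly random rooted binary labeled topology
(sequential leaf insertion over the `2k−1` attachment positions), then SV
events with total count Poisson(`λ_total`) on uniformly random edges — or
per-branch Poisson(`λ_branch`) counts — typed
duplication:deletion:translocation:inversion at 2:2:1:1, span lengths
Poisson(5,745,000 bp) (the empirical mean SV length in TCGA-BRCA whole
genomes), uniform start positions on a uniformly chosen chromosome,
duplication multiplicities uniform on {2..6}, and a uniformly random allele
per event; SNV counts are Poisson(`snv_rate`, default 100·`λ_total`) at
genome-uniform positions. CNAs arise only as consequences of duplications
and deletions. The default genome is the 22 human autosomes (hg38 lengths,
~2.9 Gb), where these densities are sparse; `SimConfig.toy()` is the
desk-scale variant (2 × 50 Mb, 500 kb spans) used throughout the tests.

Profiles are realized by replaying events root-down on per-allele segment
copy profiles over the union segmentation of all event endpoints.
A duplication multiplies one copy of its span (an existing point variant
rides the chosen copy with probability copy/segment-copy and is multiplied
with it); a deletion removes one copy (variants ride with the same
probability); translocations and inversions are copy-neutral; every event
contributes breakpoint mate pairs tracked as point variants at the junction
flanks, so each breakpoint's copy number evolves with (and never exceeds)
its allele's segment copy. Copies are capped at `c_max` (cap events
counted); events that cannot apply on a zero-copy span are dropped from the
log and the panel. Clone fractions are Dirichlet(1,…,1) per sample;
noiseless `F = U·C` exactly. Read noise per sample and segment draws
coverage `rc ~ Poisson(depth)` (default 100), variant alt reads
`~ Binomial(rc, theoretical VAF)` giving noisy copy `(alt/rc)·Ψ`, and an
allele split of the theoretical total segment copy from
`Binomial(rc, theoretical BAF)`; `rc = 0` falls back to the theoretical
values. The noise model is at the copy-number/VAF summary level — no reads,
no mapping artifacts, no caller-specific biases — so passing tests show
correctness of the inference under the model's own noise assumptions, not
robustness to real-data artifacts. Ground truths are reported in the same
majority-vote allele orientation the solver sees.

## Numerical and design choices

* Coordinates are 1-based inclusive; breakpoint directions are
  `left`/`right` (which side of the position joins the mate), encoded as
  the four bracketed BND ALT forms in VCF.
* `Ψ` and `π` are real-valued (they derive from real `F`); `π` entries with
  `Ψ = 0` are set to 0 and skipped in `S`.
* The U-step LP returns exact simplex rows (HiGHS primal feasibility);
  tiny negative frequencies from the solver are clipped to 0.
* MILP relative gap defaults to 1e-6; the clone-number workflow loosens it
  (1e-3) since only the collapsed structure is consumed.
* `D` is stored as a single binary per variant (`d_b = 1` ⇔ first allele);
  the two-column form is redundant.
* `U` is `m × N`; leaf-only mode zeroes internal non-root columns rather
  than shrinking the matrix.
* Clone matching for evaluation uses Hungarian assignment under L1 profile
  distance; the rooted Robinson-Foulds distance is normalized by the total
  number of nontrivial clusters of both trees (bounded [0, 1]); average
  precision treats the (binary) estimated co-clustering indicators as
  scores with step interpolation over unordered off-diagonal pairs.

## Desk-scale test conditions

The acceptance-style tests run five noiseless two-leaf cohorts on the toy
genome (seeds 101–105; 5 samples; per-branch SV rate 2 so that every branch
carries events and clone profiles are distinct, mirroring the
per-branch-rate regime; SNV rate 6; `c_max = 6` covering the duplication
range). Exact-recovery solves use 10 restarts with a 30 s MILP limit;
max-node-count (9) solves use 3 restarts, 3 iterations, 25 s limits and gap
1e-2. Statistical checks use ≥10,000–50,000 draws. These sizes were chosen
so the whole suite runs on a single CPU well inside half an hour; larger
trees (3+ leaves) recover equally well given proportionally more restarts
and MILP time, but at desk scale the per-restart cost of the 5-node MILP
makes the needed restart counts impractical.

## Known limitations

* Binary trees only; SNV homoplasy is excluded by the Dollo assumption,
  which is better justified for base-resolution breakpoints than for SNVs.
* With a generous node budget the factorization `F = UC` is not always
  unique: a monotone copy gain can be split across chained nodes with
  identical total `R`, and the collapse heuristic keeps such intermediate
  nodes when their branches carry genuine changes, so the clone-number
  estimate can exceed the truth even at a perfect data fit.
* MILP size grows as `N²(l+g)`; beyond ~9 nodes or a few hundred variants
  run times become excessive — hence the subsample-and-map workflow.
* The mapper assigns held-out variants independently (pairs aside) and does
  not re-optimize the tree.
* Mate pairs are constrained to a common allele (`d_b1 = d_b2`), which
  presumes a consistent allele labeling across segments. Because the
  first/second-allele orientation is decided per segment by majority vote,
  a pair whose two breakpoints land in segments with opposite orientations
  cannot satisfy the constraint exactly; the solver then phases the pair
  into one orientation, at a (small) cost in the fit.
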