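# Methods

This note describes the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Clone calling

A clone is a set of T cells expressing identical TCRα and β chains.  Each
cell's productive chains are reduced to canonical key-lists — per locus,
the sorted tuples `(CDR3, V gene, J gene)` — and two cells belong to the
same clone iff their TRA key-lists and TRB key-lists are equal within one
(patient, lineage) repertoire.  Consequences of this strict reading:

- Cells with two productive α chains merge only when *both* α keys match;
  a tolerant single-α-overlap rule was rejected because it breaks
  transitivity of clone equality.
- Cells lacking a productive TRA or TRB are unassigned in `strict` pairing
  and excluded from all repertoire denominators; `beta_fallback` pairing
  additionally groups β-only cells by their β keys into flagged clones.
- CDR3 identity defaults to **nucleotide** resolution — the most stringent
  reading of "identical chains", and the one under which convergent
  recombination is essentially impossible — with amino-acid resolution as
  an option (public-clone matching across patients is typically re-run at
  amino-acid level).  V/J identity is required by default; a CDR3-only
  switch (`use_vj=False`) exists because published clone definitions vary
  on this point.
- Clone ids are deterministic: lexicographic rank of the serialized key
  within (patient, lineage), so identical inputs in any row order produce
  identical tables.

Synovial tissue (ST) and synovial fluid (SF) repertoires are highly
similar, so `pool_joint` merges their counts into a single *joint*
compartment before sharing analysis, increasing power to detect skin–joint
shared clones.

## Sharing, occupancy, clonality

A shared clone for a compartment pair has ≥ 1 cell in each member; for the
skin–joint pair, clones also present in blood are flagged *triple-shared*.
Public clones are keys observed in ≥ 2 patients (β-only clones excluded —
a lone β chain is weak evidence of common ancestry across donors); public
sharing and within-patient sharing are reported independently.

Occupancy of a clone set in a compartment is
`100 × (cells of those clones in the compartment) / (clone-assigned cells
in the compartment)`, per patient, with the cohort median over the
patients that have the compartment.  The denominator is cells, not clones,
matching the repertoire-fraction reading of alluvial block heights; cells
of shared clones residing in *other* compartments do not enter the
numerator (the focal-compartment reading).

Inverse Pielou clonality is `1 − H/ln S` with natural-log Shannon entropy
H of clone-size proportions and S clones; S = 1 is defined as 1 by
continuity with the monoclonal limit, and the all-equal case returns
exactly 0.  The score is permutation- and scale-invariant and is computed
per (patient, lineage, compartment), never pooled across patients.

## Differential expression

Marker tests are two-sample Wilcoxon rank-sum (Mann–Whitney) tests with
midranks.  Cluster-vs-rest and group-vs-group comparisons in single-cell
practice are unpaired, for which the signed-rank variant is undefined, so
the rank-sum test is used throughout.  When both groups have ≤ 8 cells the
p-value is computed by exact enumeration of all C(n, n_a) group
assignments (two-sided, deviation of the rank sum from its null mean);
larger groups use the tie-corrected normal approximation with continuity
correction.  Genes are prefiltered (default: expressed in ≥ 10% of one
group, |log₂ fold change| ≥ 0.25 with pseudocount 1 — common single-cell
conventions) and BH correction runs over the tested genes only.

Per-patient robustness: a gene is *robust* when significantly changed in
the same direction in ≥ k (default 3) patients with none opposing; a
Fisher combined-p mode is provided as the stand-in for conserved-marker
meta-analysis.

## Two-stage Trm classification

Stage one flags *potential Trm* clusters from cluster-vs-rest DE of the
canonical human residency markers (up: ITGAE/CD103, CD69, CXCR6,
ITGA1/CD49a, PDCD1; down: S1PR1, SELL, KLF2): ≥ 3 markers significant in
the expected direction with ≥ 1 up and ≥ 1 down.  Markers absent from the
matrix count as non-hits.  Evidence from a surface-protein matrix can be
folded in by running the same DE pass on it; a marker counts once however
it is detected.

Stage two confirms each potential cluster by preranked GSEA: genes ranked
by the signed rank-sum z statistic of cluster vs the pooled non-potential
cells, tested against a core residency up-signature.  The enrichment score
is the signed maximum deviation of the weighted Kolmogorov–Smirnov running
sum (hits weighted by |stat|^w, w = 1; misses 1/(N − N_hit)); significance
is by gene-label permutation (random same-size hit sets) with +1 smoothing
on the same-sign tail, default 1,000 permutations; NES divides ES by the
mean |permuted ES| of the same sign.  Confirmation requires ES > 0 and
permutation p < α (default 0.05).  The shipped core signature is a
**synthetic stand-in** of plausible residency genes
(`clonebridge.simulate.CORE_TRM_GENES`); substitute a real GMT via
`read_gmt` when available.

## Concordance of shared clones

Fine clusters map to coarse meta-clusters via a user-supplied table (CD8
vocabulary: Trm, GZMK+, CTL, ANXA1+, Tcm, other; CD4: Trm, Trm-like Treg,
Treg, other) — assignment is by inspection of cluster signatures, not
inferred.  A shared clone is *same* when all its cells in both
compartments occupy a single meta-cluster, *similar* when at least one
cell from each compartment shares one, else *different*; precedence
same > similar > different, and clones with one cell per compartment can
only be same or different.  Fractions over classified clones sum to 1.

## Spatial neighborhood testing

Contacts default to Delaunay edges capped at 30 µm — a standard proxy for
membrane contact at single-cell resolution; mutual-kNN and fixed-radius
graphs are offered because vendor neighbor definitions vary.  Edges never
cross fields of view; fovs with < 3 cells or degenerate geometry fall back
to the radius rule.  Enrichment permutes type labels uniformly *within*
each fov (respecting acquisition structure) with the graph fixed, and
reports the upper-tail one-sided `p = (1 + #{perm ≥ obs})/(1 + n_perm)` per
unordered type pair — never zero by construction.  An exhaustive mode
enumerates all distinct labelings for small maps and is tested against a
brute-force oracle.  Composition edges pool neighbor slots over all cells
of the target type (degree-robust) rather than averaging per-cell
fractions; per-cell averaging is available behind a flag.  The ≥ 5%
threshold is inclusive.

## Synthetic generator

The generator emulates the study-like design: 6 patients; skin and blood
for all; ST for patients 1–5 and SF for 2–6 (5 each); a configurable
number of cells per compartment; clone sizes from a Zipf power law with
α = 2.5 (heavy-tailed expansion; log-series and uniform laws available).
CDR3s are random in-frame sense-codon strings of 30–54 nt with V/J calls
from a small fixed allele list.  Planted structure:

- skin–joint shared clones (cohort totals, allocated round-robin over
  patients with both compartments), the first `n_planted_triple` of which
  also get blood cells;
- public clones planted in two patients as amino-acid-level collisions
  with synonymously recoded, distinct nucleotide sequences — so
  nucleotide-resolution calling keeps them separate and amino-acid
  matching finds them;
- per-clone concordance classes sampled at (0.3, 0.3, 0.4) by default and
  realized exactly through meta-cluster assignments of the member cells;
- optionally a target shared-clone occupancy: the planted cells are CD8,
  so the budget solves `P = occ · (P + f·(total − P))` with CD8 fraction
  f, making the realized CD8-repertoire occupancy match the target up to
  rounding.

Expression is per-cluster Gaussian log-scale noise (sd 0.5) around a
baseline mean of 1; true-Trm clusters shift the residency markers and core
signature by ±δ (default 1 log-unit), other clusters get identity shifts
on three background genes; values are clipped at zero.  Spatial maps draw
Poisson counts per type per 510 µm fov and place attracted cells within
15 µm of a random partner.

What the generator does **not** emulate: dropout/zero inflation and
count-depth variation of real scRNA-seq, doublets, ambient RNA, batch
effects, biological V(D)J recombination biases, convergent recombination,
cross-compartment barcode collisions, segmentation errors in spatial data,
or inhomogeneous tissue architecture.  Passing tests therefore demonstrate
correctness of the statistics and detectors under the assumed model, not
robustness to those artifacts.

## Problem sizes and numerics

The test suite runs the statistical checks at deliberate desk scale: 1,000
random repertoires for the clonality oracle; 500 random instances for
exact rank-sum equality; a 6 × 2,000-cells-per-compartment cohort for
planted-structure recovery; 500 planted clones for concordance recovery;
50 seeds × 8 clusters × 200 cells for classifier calibration (199 GSEA
permutations there; 999–1,000 elsewhere); 200 maps × 499 permutations for
spatial calibration.  Tie handling uses midranks everywhere; permutation
p-values use +1 smoothing; the GSEA running sum is clipped to [−1, 1]
against float drift; degenerate DE rows (all values tied) get p = 1.  All
randomness flows through `numpy.random.Generator` objects seeded from a
single root seed.

## Known limitations

- The occupancy "focal-compartment" reading and the pooled-slot
  composition fraction are documented choices among plausible readings;
  both alternatives are exposed (`per_cell=True`, counting across
  compartments can be had by summing per-compartment occupancies).
- The conserved-marker meta-analysis is approximated by Fisher's method.
- Meta-cluster maps must be supplied (or taken from the generator's
  defaults); the package does not cluster or annotate expression data —
  normalization, integration and clustering are upstream inputs by design.
- The spatial contact definition is a documented stand-in, not a claim of
  equivalence to any vendor pipeline.
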