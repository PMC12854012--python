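# clonebridge

Cross-compartment T cell clonal-sharing analysis for paired multi-tissue
single-cell TCR/RNA cohorts, motivated by the question of whether skin and
joint inflammation in psoriatic arthritis is driven by the same T cell
clones.  The package takes single-cell TCR contig tables (AIRR
Rearrangement TSV or the 10x `filtered_contig_annotations` CSV dialect),
per-cell metadata (patient, compartment, lineage, expression cluster), an
upstream-normalized expression matrix, gene sets, and spatial cell tables,
and provides:

- **Clone calling** — a clone is a group of T cells expressing identical
  TCRα and β chains: cells are partitioned by their canonical chain
  key-lists (CDR3 + V/J per chain) within each (patient, lineage), at
  nucleotide or amino-acid resolution; synovial tissue and fluid can be
  pooled into one *joint* compartment.
- **Sharing and clonality** — skin–joint shared clones (cells of one clone
  in both compartments), *triple-shared* clones (also seen in blood),
  *public* clones (same key in ≥ 2 patients), repertoire **occupancy**
  (percent of a compartment's clone-assigned cells in shared clones), and
  the **inverse Pielou** clonality score
  `1 − H/ln S` (H = Shannon entropy of clone-size proportions, S = number
  of clones; 0 = polyclonal, 1 = monoclonal).
- **Trm phenotyping** — Wilcoxon rank-sum differential expression with BH
  correction (exact enumeration for small groups), a two-stage
  tissue-resident-memory classifier (directional marker rule, then
  preranked GSEA confirmation against a core residency signature), robust
  per-patient marker filtering, shared-clone phenotype **concordance**
  (same / similar / different meta-cluster occupancy across compartments),
  and shared-vs-nonshared DE.
- **Spatial neighborhoods** — per-fov cell contact graphs (capped Delaunay,
  mutual kNN, or radius), pairwise cell-type adjacency enrichment by
  within-fov label permutation (upper-tail one-sided p with +1 smoothing),
  and directed neighborhood-composition edges (A → B when A fills ≥ 5% of
  B's pooled neighbor slots).
- **A synthetic cohort generator** — six patients with the study-like
  compartment layout, power-law clone sizes, planted shared / triple /
  public clones and concordance classes, cluster-structured expression
  with directional Trm shifts, and spatial point patterns with planted
  attraction — every planted feature is returned as ground truth so each
  stage can be scored.

## Worked example

```python
import numpy as np
from clonebridge import (build_chain_profiles, call_clones, pool_joint,
                         find_shared_clones, occupancy)
from clonebridge.simulate import SimConfig, simulate_repertoire

cfg = SimConfig(cells_per_compartment=800, n_planted_shared=12,
                n_planted_triple=4, seed=7)
contigs, meta, truth = simulate_repertoire(cfg, np.random.default_rng(7))
table = call_clones(build_chain_profiles(contigs), meta)
cd8 = pool_joint(table).subset(lineage="CD8")
shared = find_shared_clones(cd8, pair=("skin", "joint"), triple_with="blood")
print(len(shared.clones), sum(c.triple for c in shared.clones))
print(occupancy(cd8, shared, "skin").median)
```

prints

```
12 4
1.0684085992857189
```

i.e. the detector recovers exactly the 12 planted skin–joint shared clones
(4 of them also in blood), and those clones occupy a median 1.07% of each
patient's skin CD8 repertoire — small, because the planted clones here are
only a few cells each.  The `examples/` directory holds one short script
per capability (sharing, clonality, Trm classification, concordance,
spatial neighborhoods); each prints its results with a note on what they
mean.

A thin CLI wraps the same functions:

```bash
clonebridge simulate --out sim --seed 7
clonebridge share --contigs sim/contigs.airr.tsv --meta sim/meta.tsv --out out
clonebridge run-all --out out --seed 7
```

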