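# cretam

Cis-regulatory element (CRE) and super-enhancer (SE) analysis of
tumor-associated macrophage (TAM) heterogeneity from paired single-cell
chromatin accessibility (scATAC-seq) and expression (scRNA-seq) data.

Tumor-associated macrophages in hepatocellular carcinoma split into
subtypes (Kupffer-like cells, SPP1+ TAMs, ...) whose identities are written
into chromatin: subtype-specific distal regulatory elements, super-enhancers,
and the transcription factors that bind them. `cretam` implements the
regulatory-genomics computations needed to dissect that heterogeneity as a
tested, reusable library and CLI:

- **candidate CRE linking** — cells are combined into overlapping meta-cell
  aggregates; peak accessibility is correlated with the expression of every
  gene whose TSS lies within ±250 kb, and pairs with Pearson *r* > 0.4
  become candidate CREs;
- **τ specificity index** — for element *i* over *K* cell types with
  min–max-normalized per-type accessibility *P<sub>i,k</sub>*:
  τ<sub>i</sub> = Σ<sub>k</sub> (1 − *P<sub>i,k</sub>*) / (*K* − 1),
  so τ = 1 marks a one-type element and τ = 0 a uniform one;
- **cell-type-specific distal CREs** — bias-matched Wilcoxon marker peaks
  (FDR ≤ 0.05, log2FC ≥ 0.57) intersected with distal candidate CREs;
- **super-enhancer calling** — distal peaks are clustered into accessons
  (coordinated accessibility); ≤500 kb windows significantly enriched for
  one accesson's peaks (binomial test, BH at 0.05) are merged into SEs,
  filtered for subtype specificity (τ > 0.7, normalized accessibility
  > 0.5) and assigned a target gene (nearest gene, kept when SE–gene
  *r* > 0.3 and focal-type expression exceeds the cross-type median);
- **core TFs** — the intersection of a chromatin branch (motif deviation
  z-scores above the per-type median plus z–expression correlation > 0.5)
  and a regulon-activity branch (signed-mean target expression, Wilcoxon
  FDR < 0.05);
- **SE motif enrichment** — hypergeometric upper tail against a
  GC/accessibility-matched background, BH-adjusted;
- **TF–SE–target network** — TF→SE edges weighted by the linkage score
  LS(*s*,*t*) = Σ<sub>p∈SE<sub>s</sub></sub> R²<sub>p,g</sub> ·
  MS<sub>p,t</sub> (kept when LS > 10), SE→gene edges weighted by
  correlation, and target genes screened by univariate Cox proportional
  hazards (kept when HR > 1, *p* < 0.05);
- **pseudotime dynamics** — genes, peaks and motif deviations averaged over
  100 equal-count pseudotime bins and correlated across modalities.

Real accessions are not bundled. A first-class synthetic-data generator
(`cretam.synth`) emits paired count matrices, peak/gene models, motif
scores, regulons, pseudotime and bulk survival cohorts with *planted*,
recorded regulatory structure, so every stage can be validated against
ground truth.

## Worked example

Run the full pipeline on a synthetic dataset (3 cell types × 200 cells,
~1500 peaks, 300 genes, 4 planted SEs, 6 planted TF programs):

```bash
cretam run --outdir run1 --seed 7
# completed 8 stages -> run1/manifest.json
```

Inspecting the stage outputs (all plain TSV/BED/JSON):

```
qc:            600 cells in, 510 kept (48 low gene count, 42 high mito, 3 low TSS)
links.tsv:     248 candidate CRE links over 176 genes (median 1 CRE/gene)
ses_all.tsv:   7 SEs called; 2 specific to the focal type (type2)
  se5  chr2:46398250-46524750  6 constituents  tau=0.949  target=gene2 (r=0.62)
core_tfs.tsv:  type0 -> gene92, gene219 | type1 -> gene285, gene233
               type2 -> gene215, gene269, gene188
cox.tsv:       gene2  HR=1.40  p=1.5e-05  kept
network:       2 TF nodes, 1 SE node, 1 gene node, 3 edges; hub TF = gene215
```

Reading: the pipeline recovered the planted type2-specific super-enhancer
(6 co-accessible distal peaks spanning ~126 kb), assigned its planted
target gene, found the planted core TFs of each subtype (one false
positive in type2), and kept the SE target in the prognostic screen —
its expression was planted with a positive log-hazard in the simulated
survival cohort, and the fitted hazard ratio 1.40 with *p* ≈ 10⁻⁵ retains
it under the HR > 1, *p* < 0.05 rule.

Every stage is also callable as a library function
(`cretam.linking.link_peaks_to_genes`, `cretam.specificity.tau_index`,
`cretam.superenh.call_superenhancers`, `cretam.network.cox_screen`, ...)
or as an individual subcommand (`cretam synth`, `cretam link`, `cretam
tau`, `cretam markers`, `cretam se`, `cretam tf`, `cretam network`,
`cretam trajectory`).

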