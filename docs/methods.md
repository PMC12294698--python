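# Methods

This note documents the models, statistics and numerical choices behind
`cretam`, and what its synthetic benchmarks do and do not establish.

## Scope and data model

The package operates downstream of standard single-cell preprocessing: its
inputs are a peak-by-cell accessibility count matrix with peak intervals,
a gene-by-cell expression count matrix with one-TSS gene models, cell
metadata (type labels, optional pseudotime and QC covariates), a TF-by-peak
motif score matrix, a TF regulon table, and (for the prognostic screen) a
bulk cohort with survival times. Peak calling, dimensionality reduction,
clustering, label transfer, trajectory *inference* and motif *scanning*
are out of scope — pseudotime, labels, motif scores and regulons are
inputs. Coordinates are 0-based half-open everywhere, including the
gene-model TSV; BED is the on-disk interval format, MatrixMarket plus
row/column TSVs the matrix format.

## Quality control

Cells are dropped when they detect fewer than 200 genes, exceed 20%
mitochondrial content (strictly greater; a cell at exactly 0.20 is kept),
carry fewer than 1000 ATAC fragments, or have TSS enrichment below 4.
Filtering is applied consistently to both modalities and is idempotent.
These thresholds are the conventional operating points for this data type
and are configurable (`qc_*` keys); the bundled synthetic panel has 300
genes, so the 200-gene floor retains most but not all cells.

## Genomic annotation

Peaks are classified promoter / exonic / intronic / distal with strict
precedence in that order; a peak overlapping any promoter window is
"promoter" regardless of other overlaps. The promoter window defaults to
−2000/+100 bp around the TSS in transcriptional orientation — common ATAC
practice; there is no universal definition. The distance anchor for a peak
is its midpoint; `tss_distance` is signed in the nearest gene's
orientation (positive = downstream). "Distal" means not promoter, exonic
or intronic; far-upstream peaks are distal. Intron order counts 5′→3′ in
the host gene.

## Meta-cell aggregation and CRE linking

Single-cell counts are too sparse for per-element correlations, so cells
are combined into overlapping aggregates: a seed cell plus its
k_agg − 1 nearest neighbors in a 30-component PCA of log1p
depth-normalized (counts-per-10k) expression. Aggregate profiles are means
of the per-cell normalized vectors; each aggregate is labeled with its
modal cell type. Defaults are k_agg = 50 and n_agg = 500 at atlas scale;
the bundled synthetic pipeline uses k_agg = 20 and n_agg = 50. The reason
for scaling down is statistical, not computational: overlapping aggregates
share members, so the effective number of independent replicates is about
n_cells / k_agg. At 600 cells, k_agg = 50 leaves ~12 effective replicates
and the null distribution of the Pearson r between unrelated peak–gene
pairs becomes wide enough to leak through the r > 0.4 cutoff; k_agg = 20
restores ~30 effective replicates and a false-link rate well under 5%.

Candidate pairs are peaks and genes with |peak midpoint − TSS| ≤ 250 kb;
the link statistic is the Pearson correlation of aggregate profiles, and
links with r > 0.4 are retained. No p-value/FDR filter is applied by
default because the published operating point is the correlation cutoff
alone. Zero-variance features are skipped and logged. The aggregation
scheme itself (seeded k-NN) is this package's explicit construction; the
upstream tooling this emulates does not document its internals, so every
parameter is exposed in config.

## τ specificity

Per-type mean accessibility is min–max normalized across types and
τ = Σ(1 − P_k)/(K − 1). Constant profiles get τ = 0 with a warning —
"least specific" is the only convention that keeps downstream τ > 0.7
filters meaningful for degenerate elements. τ is scale-invariant by
construction and lies in [0, 1]. Category comparisons use Kruskal–Wallis
(omnibus) plus BH-adjusted pairwise Wilcoxon tests.

## Marker peaks

One-vs-rest two-sided Wilcoxon rank-sum per peak, against a *bias-matched*
background: non-group cells are sampled, with replacement where needed, to
match the group's distribution over deciles of per-cell total
accessibility (optionally any covariate); strata without background cells
are dropped with a warning. This guards against depth confounding, the
dominant technical bias in scATAC differential tests. Fold change is
computed on pseudobulk means with a pseudocount of one count unit (the
published rule does not state the unit of fold change; pseudobulk is the
configurable default). A peak is a marker iff FDR ≤ 0.05 and
log2FC ≥ 0.57. Cell-type-specific distal CREs are the intersection of a
type's markers with the distal candidate CREs.

## Super-enhancers

Distal peaks are clustered into accessons by k-means (default 10 at
synthetic scale) on per-peak standardized accessibility profiles —
coordinated accessibility is the defining property, matching the accesson
concept of scATAC SE callers. For each accesson, a window of width
super_range = 500 kb is anchored at every member peak; the count of
same-accesson peaks among the window's distal peaks is tested against
Binomial(n = peaks in window, p = accesson's genome-wide share). All
anchored windows enter one BH family — including windows too sparse to
ever seed an SE. This matters: conditioning the family on windows that
already contain ≥3 same-accesson peaks selects extreme windows and
invalidates the FDR control (measured as spurious SE calls on null
genomes before the family was widened). Significant (FDR < 0.05)
overlapping windows of one accesson are merged; an SE needs ≥3
constituents (configurable) and its interval spans its member peaks,
trimmed to the best window if a merged run exceeds super_range.

SE accessibility per cell is the *sum* (not mean) of constituent counts,
preserving the count model for downstream correlations. Specificity reuses
the τ machinery on summed profiles with τ > 0.7 and focal-type normalized
accessibility > 0.5. The target gene is the nearest gene by SE-edge-to-TSS
distance (0 if the TSS lies inside; ties broken by lower gene start
coordinate), kept only when SE–gene Pearson r across focal-type cells
exceeds 0.3 *and* the gene's focal-type pseudobulk mean exceeds the median
of its per-type pseudobulk means.

## Motif deviations, regulon activity, core TFs

Motif deviation z-scores follow the chromVAR idea: a cell's observed
fraction of counts in motif-bearing peaks, versus the motif set's share of
all counts, normalized by n_background = 50 random peak sets matched on
GC-content and mean-accessibility deciles. z is invariant to global depth
scaling; degenerate background SDs produce NaN with a warning, never
silently. Motifs with fewer than 5 peaks are skipped.

The chromatin branch keeps TFs whose focal-type mean z exceeds the median
of their own per-type mean z values ("above the median across TAMs" read
as a within-TF, across-type comparison; alternatives are config-exposed)
and whose per-type mean z correlates with the TF's per-type pseudobulk
expression at r strictly greater than 0.5. The activity branch scores each
regulon as the mean over targets of mode-sign × z-scored log-normalized
expression — a deliberate simplification of VIPER-style inference
(regulons are inputs; enrichment-weighted scoring adds little at regulon
sizes of tens) — and keeps TFs with a positive focal-vs-rest shift at
Wilcoxon FDR < 0.05. Core TFs are the intersection of the branches.

SE motif enrichment is the hypergeometric upper tail of motif-bearing SE
peaks in a population of SE peaks plus a matched background (10 draws per
SE peak from the same GC × accessibility stratum; all non-SE peaks if
matching is off), BH across TFs at 0.05.

## Network and prognostic screen

TF→SE edges carry the linkage score LS(s,t) = Σ_p R²_{p,g}·MS_{p,t} over
the SE's constituent peaks, where R² is the squared peak-to-target
correlation (looked up from the candidate-pair table; recomputed from
aggregate profiles if the 250 kb window excluded the pair; 0 if
unavailable) and MS the TF's motif score at the peak. Edges with LS > 10
survive; because the cutoff is scale-dependent in MS units, a warning is
emitted when motif scores look binary and the cutoff is configurable.

The prognostic screen fits, per gene, a one-covariate Cox proportional
hazards model on standardized log1p expression: Newton iterations on the
Breslow partial likelihood to |step| < 1e−8 (ties are immaterial with
continuous simulated times; Breslow is the documented choice), Wald p from
the observed information. Genes are kept iff HR > 1 and p < 0.05 — the
one-sided HR gate halves the nominal null rate to ≈2.5%. The
implementation is cross-checked in the test suite against both lifelines
and a grid/golden-section maximization of the partial likelihood.
Non-converged or constant genes are excluded with warnings. The network
keeps gene nodes passing the screen, their SEs, and core TFs with ≥1
surviving edge; assembly is a pure function of its inputs.

## Trajectory dynamics

Pseudotime is consumed, never inferred. Cells are ranked and split into
100 equal-count bins (sizes differ by ≤1), making the binning invariant to
any strictly monotone reparameterization of pseudotime — the reason
equal-count was chosen over equal-width, which is also available. Per-bin
means are z-scaled across the trajectory; empty bins are linearly
interpolated and flagged. Gene profiles are binned on depth-normalized
log1p expression (binning raw counts would fold per-cell depth noise into
the bins). Cross-modality coordination is the Pearson correlation between
scaled profiles of named pairs — TF motif vs TF gene, or peak vs linked
gene via the candidate-CRE table (the pairing rule is this package's
choice; the emulated workflow does not document one).

## Synthetic data: what is emulated, what is not

The generator plants every structure the pipeline is supposed to find and
records it in a `GroundTruth`:

- **K cell types** (default 3 × 200 cells) on a toy genome (2 × 60 Mb),
  peaks of all four genomic categories placed without overlap on a 1 kb
  grid;
- **CRE links**: for a planted (peak, gene) pair, log-rates share a latent
  standard-normal factor with weight √ρ (Gaussian copula), so the latent
  correlation equals `link_effect`; accessibility is Poisson, expression
  negative-binomial (gamma–Poisson, dispersion 0.3). Copula scales (1.3 on
  the peak side, 1.2 on the gene side) were calibrated once so that at
  ρ = 0.9 the realized count-level r exceeds 0.5 for ≥90% of pairs — the
  generator's documented contract;
- **cell-type-specific CREs**: 40% of linked peaks get an 8× accessibility
  fold in one type, their partner genes a 4× expression fold (these
  partners double as the type's "program genes" and regulon targets);
- **super-enhancers**: constituents share a per-cell factor active only in
  the focal type (6× fold), so they co-cluster into one accesson and
  correlate with the planted target gene;
- **TF programs**: two planted TFs per type, motifs on ~85% of the type's
  program peaks plus a 4% genome-wide background, 10× expression fold in
  the driven type (master-regulator-scale enrichment; the log-scale
  trajectory SNR grows with the fold, and 10× leaves clear margin on the
  coordination properties), regulons of ~90% activating targets from the
  own-type program and ~10% repressed targets from another type's;
- **pseudotime**: the first and last types are trajectory endpoints with
  pseudotime U(0, 0.55) and U(0.45, 1); their programs blend along a
  logistic with midpoint 0.5 and scale 0.06 (`smooth_trajectory=False`
  restores a hard type switch for separation-dependent checks);
- **survival cohorts**: per-subject expression log-normal around a gene
  signature; event times exponential with log-hazard
  Σ effect·z(log-expression) over planted hazard genes; independent
  exponential censoring (~1/3 censored);
- **QC covariates** (mito fraction, TSS enrichment) are simulated
  covariates, not derived from reads.

Not modeled: sequencing reads, doublets, batch effects, chromatin
contacts, negative (silencer) links, isoform structure. Passing the
planted-recovery benchmarks therefore shows the algorithms are correct and
calibrated under a clean latent-factor regime with known truth; it does
not certify performance on real tissue, where confounding (depth,
batch, ambient signal) is richer than the biases simulated here.

Benchmark accounting: planted links and SE-constituent→SE-target pairs are
excluded from the false-link denominator — the generator correlates SE
constituents with their target by design, so calling those links is
correct behavior.

## Numerical and reproducibility choices

All randomness flows from explicit seeds through `numpy.random.default_rng`;
a fixed config reproduces bit-identical datasets and, across two full
pipeline runs, identical output checksums (floats are written with a fixed
format; the manifest stores SHA-256 per file and contains no timestamps).
Wilcoxon tests use the asymptotic normal approximation (group sizes are
hundreds); BH adjustment is `scipy.stats.false_discovery_control`.
Undefined statistics (zero-variance features, degenerate backgrounds,
non-converged fits) are always skipped-with-warning or NaN-flagged, never
silent. Synthetic problem sizes (600 cells, ~1.5–4k peaks, 20-seed
Monte-Carlo loops) were chosen so the full test suite and the acceptance
script each complete in minutes on one CPU while keeping the Monte-Carlo
standard errors well below the margins being asserted.

## Known limitations

- The accesson construction (k-means) and the binomial window test are
  this package's explicit stand-ins for an undocumented upstream
  procedure; absolute SE counts depend on `n_accessons`.
- The LS > 10 cutoff is only meaningful on log-odds-like motif-score
  scales; binary motif matrices need a rescaled cutoff.
- One TSS per gene; isoform-level promoters are not resolved.
- The expression–deviation correlation in the chromatin branch uses K
  per-type pseudobulk points; with small K the correlation gate is coarse,
  and the activity branch carries most of the specificity of the
  consensus.
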