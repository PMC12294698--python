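"""Synthetic paired scATAC/scRNA datasets with planted regulatory structure.

The generator emulates the data regime of a tumor-associated-macrophage
(TAM) atlas: K cell types with type-specific accessible distal peaks, peaks
whose accessibility is correlated with the expression of a nearby gene
(planted cis-regulatory links within +/-250 kb), clusters of co-accessible
distal peaks forming planted super-enhancers inside a bounded genomic span,
TF programs in which motif-bearing peaks, TF expression and regulon targets
co-activate in one cell type, a smooth two-endpoint pseudotime transition
between the first and last cell types, and bulk survival cohorts whose
hazard depends on planted gene expression.

Counts follow a latent-factor (Gaussian copula) construction: accessibility
is Poisson around a log-linear latent rate, expression is negative-binomial
(gamma-Poisson). For a planted link, peak and gene log-rates share a
standard-normal cell-level factor with weight ``sqrt(link_effect)`` so the
latent correlation equals ``link_effect`` and the realized count-level
Pearson r maps monotonically onto it. Every planted object is recorded in a
:class:`GroundTruth` so downstream recovery is measurable.

Not modeled: sequencing reads, doublets, batch effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd

PEAK_WIDTH = 500
SLOT = 1000  # placement grid resolution, bp
GENE_BODY = 20_000
GENE_MARGIN = 3_000  # promoter clearance on both sides of a gene body


@dataclass
class SynthConfig:
    """Generator settings. Defaults define the study conditions of the
    synthetic regime: 3 macrophage-like cell types of 200 cells on a
    2 x 60 Mb toy genome."""

    n_cell_types: int = 3
    cells_per_type: int = 200
    n_genes: int = 300
    n_peaks: int = 1500
    genome: tuple[tuple[str, int], ...] = (("chr1", 60_000_000), ("chr2", 60_000_000))
    frac_linked_peaks: float = 0.2     # fraction of distal peaks given a planted gene link
    link_effect: float = 0.8           # latent peak-gene correlation of a planted link
    n_planted_SEs: int = 4
    peaks_per_SE: int = 6
    se_span_bp: int = 200_000
    n_TFs: int = 20
    tfs_per_type: int = 2
    regulon_size: int = 20
    noise_dispersion: float = 0.3      # NB dispersion of expression counts
    survival_n: int = 300
    survival_effect: float = 0.8       # log-hazard per SD of a planted gene's expression
    n_hazard_genes: int = 10
    seed: int = 0

    # secondary effect sizes of the planted regime
    frac_specific: float = 0.4         # fraction of linked peaks made cell-type-specific
    type_fc_acc: float = 8.0           # accessibility fold of a type-specific peak in its type
    type_fc_expr: float = 4.0          # expression fold of a program gene in its type
    tf_fc: float = 10.0                # expression fold of a planted TF in its type
    se_fc: float = 6.0                 # accessibility fold of SE constituents in the focal type
    link_sigma_acc: float = 1.3        # log-rate scale of the shared link factor (peaks)
    link_sigma_expr: float = 1.2       # log-rate scale of the shared link factor (genes)
    se_sigma: float = 0.5              # per-cell spread of the shared SE factor
    smooth_trajectory: bool = True     # logistic blending of the endpoint programs
                                       # along pseudotime; False = hard type switch

    def validate(self) -> None:
        positive = ("n_cell_types", "cells_per_type", "n_genes", "n_peaks",
                    "n_planted_SEs", "peaks_per_SE", "se_span_bp", "n_TFs",
                    "tfs_per_type", "regulon_size")
        for name in positive:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_planted_SEs > 0 and self.peaks_per_SE < 3:
            raise ValueError("peaks_per_SE must be >= 3")
        if not (0.0 <= self.frac_linked_peaks <= 1.0):
            raise ValueError("frac_linked_peaks must lie in [0, 1]")
        if not (0.0 < self.link_effect < 1.0):
            raise ValueError("link_effect must lie in (0, 1)")
        if self.se_span_bp > 500_000:
            raise ValueError("se_span_bp must not exceed the 500 kb super_range")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")
        if self.n_cell_types * self.tfs_per_type > self.n_TFs:
            raise ValueError("not enough TFs for the requested planted programs")


@dataclass
class GroundTruth:
    """Record of every planted object, keyed by emitted ids."""

    planted_links: set[tuple[str, str]] = field(default_factory=set)
    planted_SEs: list[dict] = field(default_factory=list)
    planted_core_tfs: dict[str, list[str]] = field(default_factory=dict)
    planted_hazard_genes: list[tuple[str, float]] = field(default_factory=list)
    specific_peaks: dict[str, list[str]] = field(default_factory=dict)
    program_genes: dict[str, list[str]] = field(default_factory=dict)
    trajectory_start: str = ""
    trajectory_end: str = ""
    gain_tfs: list[str] = field(default_factory=list)
    loss_tfs: list[str] = field(default_factory=list)
    pseudotime_midpoint: float = 0.5

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["planted_links"] = sorted(self.planted_links)
        return d


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`generate_dataset`."""

    acc: ad.AnnData               # cells x peaks accessibility counts
    expr: ad.AnnData              # cells x genes expression counts
    peaks: pd.DataFrame           # peak_id, chrom, start, end, gc
    genes: pd.DataFrame           # gene models (0-based TSV schema)
    cells: pd.DataFrame           # cell_type, pseudotime, QC covariates
    motif_scores: pd.DataFrame    # TF x peak motif scores (0 = no site)
    regulons: pd.DataFrame        # tf, target, mode
    truth: GroundTruth


class _Placer:
    """Non-overlapping placement on a per-chromosome slot grid."""

    def __init__(self, genome, rng: np.random.Generator):
        self.rng = rng
        self.chroms = [c for c, _ in genome]
        self.lengths = {c: int(n) for c, n in genome}
        self.free = {c: np.ones(int(n) // SLOT, dtype=bool) for c, n in genome}

    def take_run(self, n_slots: int, chrom: str | None = None) -> tuple[str, int]:
        """Reserve a contiguous free run of ``n_slots``; returns (chrom, slot)."""
        cand = [chrom] if chrom else list(self.chroms)
        for _ in range(200):
            c = cand[self.rng.integers(len(cand))]
            mask = self.free[c]
            if len(mask) <= n_slots:
                continue
            s = int(self.rng.integers(0, len(mask) - n_slots))
            if mask[s:s + n_slots].all():
                mask[s:s + n_slots] = False
                return c, s
        raise ValueError("genome too small to place the requested elements without overlap")

    def take_slot(self, chrom: str | None = None) -> tuple[str, int]:
        c, s = self.take_run(1, chrom)
        return c, s

    def take_slot_near(self, chrom: str, lo_bp: int, hi_bp: int) -> int | None:
        mask = self.free[chrom]
        lo = max(0, lo_bp // SLOT)
        hi = min(len(mask), hi_bp // SLOT)
        if hi <= lo:
            return None
        idx = np.flatnonzero(mask[lo:hi])
        if len(idx) == 0:
            return None
        s = lo + int(self.rng.choice(idx))
        mask[s] = False
        return s

    def take_slots_in(self, chrom: str, lo_slot: int, hi_slot: int, n: int) -> np.ndarray:
        idx = np.arange(lo_slot, hi_slot)
        picked = self.rng.choice(idx, size=n, replace=False)
        return np.sort(picked)


def _slot_to_peak(slot: int) -> tuple[int, int]:
    start = slot * SLOT + (SLOT - PEAK_WIDTH) // 2
    return start, start + PEAK_WIDTH


def _logistic(x: np.ndarray, mid: float, scale: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - mid) / scale))


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate one paired dataset plus ground truth. Deterministic in
    ``cfg.seed``: rerunning with the same config is bit-identical."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_cell_types
    type_names = [f"type{k}" for k in range(K)]
    placer = _Placer(cfg.genome, rng)

    # ---- genome layout: SE windows first, then genes, then peaks ----
    se_windows = []  # (chrom, start_slot, end_slot)
    span_slots = cfg.se_span_bp // SLOT
    for _ in range(cfg.n_planted_SEs):
        c, s = placer.take_run(span_slots + (GENE_BODY + 2 * GENE_MARGIN) // SLOT + 40)
        se_windows.append((c, s, s + span_slots))

    # gene bodies; the first n_planted_SEs genes are SE target genes placed
    # just downstream of their SE window
    gene_rows = []
    body_slots = (GENE_BODY + 2 * GENE_MARGIN) // SLOT
    for i, (c, s0, s1) in enumerate(se_windows):
        body_start = s1 * SLOT + 30_000
        gene_rows.append((f"gene{i}", c, "+", body_start))
    for i in range(cfg.n_planted_SEs, cfg.n_genes):
        c, s = placer.take_run(body_slots)
        strand = "+" if rng.random() < 0.5 else "-"
        body_start = s * SLOT + GENE_MARGIN
        gene_rows.append((f"gene{i}", c, strand, body_start))

    exon_offsets = [(0, 1000), (9000, 10_000), (19_000, GENE_BODY)]
    genes = pd.DataFrame([
        {
            "gene_id": gid, "chrom": c, "strand": strand,
            "start": start, "end": start + GENE_BODY,
            "tss": start if strand == "+" else start + GENE_BODY - 1,
            "exon_starts": ",".join(str(start + a) for a, _ in exon_offsets),
            "exon_ends": ",".join(str(start + b) for _, b in exon_offsets),
        }
        for gid, c, strand, start in gene_rows
    ])
    tss = genes["tss"].to_numpy()

    # ---- peak placement by category ----
    n_reg = cfg.n_peaks
    n_prom = int(0.15 * n_reg)
    n_exonic = int(0.08 * n_reg)
    n_intronic = int(0.25 * n_reg)
    n_distal = n_reg - n_prom - n_exonic - n_intronic
    if n_prom > cfg.n_genes or n_exonic > cfg.n_genes or n_intronic > 2 * cfg.n_genes:
        raise ValueError("n_peaks too large for n_genes with the fixed category mix")

    peak_rows: list[tuple[str, str, int, int, str]] = []  # id, chrom, start, end, class

    def add_peak(chrom: str, start: int, klass: str) -> str:
        pid = f"peak{len(peak_rows)}"
        peak_rows.append((pid, chrom, start, start + PEAK_WIDTH, klass))
        return pid

    g_chrom = genes["chrom"].to_numpy()
    g_start = genes["start"].to_numpy()
    # promoter peaks straddle the TSS
    for gi in rng.choice(cfg.n_genes, size=n_prom, replace=False):
        add_peak(g_chrom[gi], int(tss[gi]) - PEAK_WIDTH // 2, "promoter")
    # exonic peaks inside the middle exon
    for gi in rng.choice(cfg.n_genes, size=n_exonic, replace=False):
        add_peak(g_chrom[gi], int(g_start[gi]) + 9_200, "exonic")
    # intronic peaks inside the first (genomic) intron, two possible offsets
    combos = [(gi, off) for gi in range(cfg.n_genes) for off in (3_000, 6_000)]
    for ci in rng.choice(len(combos), size=n_intronic, replace=False):
        gi, off = combos[ci]
        add_peak(g_chrom[gi], int(g_start[gi]) + off, "intronic")

    # distal peaks: planted-link peaks near a partner gene, the rest scattered
    n_linked = int(round(cfg.frac_linked_peaks * n_distal))
    eligible = np.arange(cfg.n_planted_SEs, cfg.n_genes)  # not SE targets
    if n_linked > len(eligible):
        raise ValueError("not enough genes to host the requested planted links")
    partner_gi = rng.choice(eligible, size=n_linked, replace=False)
    link_peak_ids: list[str] = []
    for gi in partner_gi:
        c = g_chrom[gi]
        t = int(tss[gi])
        for _ in range(60):
            side = 1 if rng.random() < 0.5 else -1
            off = int(rng.integers(15_000, 240_000))
            pos = t + side * off
            slot = placer.take_slot_near(c, pos - 2 * SLOT, pos + 2 * SLOT)
            if slot is not None:
                start, _ = _slot_to_peak(slot)
                link_peak_ids.append(add_peak(c, start, "distal"))
                break
        else:
            raise ValueError("genome too crowded to place a planted link peak")
    for _ in range(n_distal - n_linked):
        c, s = placer.take_slot()
        start, _ = _slot_to_peak(s)
        add_peak(c, start, "distal")

    # SE constituent peaks inside their reserved windows
    se_constituents: list[list[str]] = []
    for (c, s0, s1) in se_windows:
        slots = placer.take_slots_in(c, s0, s1, cfg.peaks_per_SE)
        ids = []
        for s in slots:
            start, _ = _slot_to_peak(int(s))
            ids.append(add_peak(c, start, "distal"))
        se_constituents.append(ids)

    peaks = pd.DataFrame(peak_rows, columns=["peak_id", "chrom", "start", "end", "klass"])
    peaks["gc"] = np.clip(rng.normal(0.45, 0.08, len(peaks)), 0.2, 0.8)
    n_peaks_total = len(peaks)
    peak_index = {p: i for i, p in enumerate(peaks["peak_id"])}

    # ---- cell-level structure ----
    n_cells = K * cfg.cells_per_type
    labels = np.repeat(type_names, cfg.cells_per_type)
    start_t, end_t = type_names[0], type_names[-1]
    pseudotime = np.full(n_cells, np.nan)
    is_start = labels == start_t
    is_end = labels == end_t
    pseudotime[is_start] = rng.uniform(0.0, 0.55, is_start.sum())
    pseudotime[is_end] = rng.uniform(0.45, 1.0, is_end.sum())

    # per-cell weight of each type's program; smooth along the trajectory
    W = np.zeros((n_cells, K))
    for k, t in enumerate(type_names):
        W[:, k] = (labels == t).astype(float)
    if cfg.smooth_trajectory:
        lam = _logistic(pseudotime[is_start | is_end], 0.5, 0.06)
        traj = is_start | is_end
        W[traj, 0] = 1.0 - lam
        W[traj, K - 1] = lam

    # ---- planted assignments ----
    truth = GroundTruth(trajectory_start=start_t, trajectory_end=end_t)
    gene_ids = genes["gene_id"].to_numpy()
    partner_gene_ids = gene_ids[partner_gi]
    truth.planted_links = set(zip(link_peak_ids, partner_gene_ids))

    n_specific = int(round(cfg.frac_specific * n_linked))
    spec_order = rng.permutation(n_linked)[:n_specific]
    peak_type = np.full(n_peaks_total, -1)      # type index of a specific peak
    gene_type = np.full(cfg.n_genes, -1)        # type index of a program gene
    for j, li in enumerate(spec_order):
        k = j % K
        peak_type[peak_index[link_peak_ids[li]]] = k
        gene_type[partner_gi[li]] = k
    for k, t in enumerate(type_names):
        truth.specific_peaks[t] = [link_peak_ids[li] for j, li in enumerate(spec_order)
                                   if j % K == k]
        truth.program_genes[t] = [str(g) for g in gene_ids[gene_type == k]]

    # SE focal types and target genes
    for s, ids in enumerate(se_constituents):
        focal = type_names[s % K]
        target = f"gene{s}"
        gene_type[s] = s % K  # SE target co-activates in the focal type
        c, s0, s1 = se_windows[s]
        idx = [peak_index[p] for p in ids]
        truth.planted_SEs.append({
            "chrom": c,
            "start": int(peaks["start"].iloc[idx].min()),
            "end": int(peaks["end"].iloc[idx].max()),
            "peak_ids": ids,
            "focal_type": focal,
            "target_gene": target,
        })

    # TF genes: drawn from genes that host no planted link and no SE target
    tf_candidates = [i for i in range(cfg.n_planted_SEs, cfg.n_genes)
                     if gene_type[i] < 0 and i not in set(partner_gi)]
    if len(tf_candidates) < cfg.n_TFs:
        raise ValueError("not enough spare genes to serve as TFs")
    tf_gi = rng.choice(tf_candidates, size=cfg.n_TFs, replace=False)
    tf_ids = [str(g) for g in gene_ids[tf_gi]]
    tf_type = np.full(cfg.n_TFs, -1)
    for k in range(K):
        for j in range(cfg.tfs_per_type):
            tf_type[k * cfg.tfs_per_type + j] = k
    for k, t in enumerate(type_names):
        truth.planted_core_tfs[t] = [tf_ids[i] for i in range(cfg.n_TFs) if tf_type[i] == k]
    truth.gain_tfs = list(truth.planted_core_tfs[end_t])
    truth.loss_tfs = list(truth.planted_core_tfs[start_t])

    # motif scores: planted TFs sit on their type's specific peaks (and the
    # SE constituents of that type), every TF has a sparse background
    MS = np.zeros((cfg.n_TFs, n_peaks_total))
    for i in range(cfg.n_TFs):
        bg = rng.random(n_peaks_total) < 0.04
        MS[i, bg] = rng.uniform(5, 15, bg.sum())
        k = tf_type[i]
        if k >= 0:
            prog = np.flatnonzero(peak_type == k)
            hit = prog[rng.random(len(prog)) < 0.85]
            MS[i, hit] = rng.uniform(8, 18, len(hit))
            for s, ids in enumerate(se_constituents):
                if s % K == k:
                    idx = [peak_index[p] for p in ids]
                    MS[i, idx] = rng.uniform(8, 18, len(idx))
    motif_scores = pd.DataFrame(MS, index=tf_ids, columns=peaks["peak_id"])

    # regulons: planted TFs regulate their type's program genes (mode +) plus
    # a few genes of another type's program as repressed targets (mode -)
    reg_rows = []
    baseline_pool = [str(g) for i, g in enumerate(gene_ids)
                     if gene_type[i] < 0 and str(g) not in tf_ids]
    for i, tf in enumerate(tf_ids):
        k = tf_type[i]
        if k >= 0:
            t = type_names[k]
            pos_pool = truth.program_genes[t]
            other = type_names[(k + 1) % K]
            neg_pool = truth.program_genes[other]
            n_neg = max(1, cfg.regulon_size // 10)
            n_pos = min(cfg.regulon_size - n_neg, len(pos_pool))
            chosen = rng.choice(len(pos_pool), size=n_pos, replace=False)
            for ci in chosen:
                reg_rows.append((tf, pos_pool[ci], "+"))
            chosen = rng.choice(len(neg_pool), size=min(n_neg, len(neg_pool)), replace=False)
            for ci in chosen:
                reg_rows.append((tf, neg_pool[ci], "-"))
        else:
            chosen = rng.choice(len(baseline_pool),
                                size=min(cfg.regulon_size, len(baseline_pool)),
                                replace=False)
            for ci in chosen:
                reg_rows.append((tf, baseline_pool[ci], "+"))
    regulons = pd.DataFrame(reg_rows, columns=["tf", "target", "mode"])

    # hazard genes: SE targets first, then program genes
    hazard_pool = [f"gene{s}" for s in range(cfg.n_planted_SEs)]
    for t in type_names:
        hazard_pool += [g for g in truth.program_genes[t] if g not in hazard_pool]
    hazard_genes = hazard_pool[:cfg.n_hazard_genes]
    truth.planted_hazard_genes = [(g, cfg.survival_effect) for g in hazard_genes]

    # ---- latent rates and counts ----
    log_depth = rng.normal(0.0, 0.25, n_cells)

    base_p = np.exp(rng.normal(np.log(0.8), 0.4, n_peaks_total))
    log_mu_acc = np.log(base_p)[None, :] + log_depth[:, None]

    base_g = np.exp(rng.normal(np.log(2.0), 0.6, cfg.n_genes))
    log_mu_expr = np.log(base_g)[None, :] + log_depth[:, None]

    # type-specific boosts
    for k in range(K):
        pk = peak_type == k
        if pk.any():
            log_mu_acc[:, pk] += np.log(cfg.type_fc_acc) * W[:, [k]]
        gk = gene_type == k
        if gk.any():
            log_mu_expr[:, gk] += np.log(cfg.type_fc_expr) * W[:, [k]]
    for i, gi in enumerate(tf_gi):
        if tf_type[i] >= 0:
            log_mu_expr[:, gi] += np.log(cfg.tf_fc) * W[:, tf_type[i]]

    # shared link factors (Gaussian copula on the log-rate scale)
    rho = cfg.link_effect
    if n_linked:
        U = rng.normal(size=(n_cells, n_linked))
        x_p = np.sqrt(rho) * U + np.sqrt(1 - rho) * rng.normal(size=(n_cells, n_linked))
        x_g = np.sqrt(rho) * U + np.sqrt(1 - rho) * rng.normal(size=(n_cells, n_linked))
        li = [peak_index[p] for p in link_peak_ids]
        log_mu_acc[:, li] += cfg.link_sigma_acc * x_p
        log_mu_expr[:, partner_gi] += cfg.link_sigma_expr * x_g

    # shared SE factors, active only in the focal type
    for s, ids in enumerate(se_constituents):
        k = s % K
        v = rng.normal(size=n_cells)
        act = W[:, k] * (np.log(cfg.se_fc) + cfg.se_sigma * v)
        idx = [peak_index[p] for p in ids]
        log_mu_acc[:, idx] += act[:, None]
        log_mu_expr[:, s] += 0.8 * act  # focal-type target gene tracks its SE

    acc_counts = rng.poisson(np.exp(log_mu_acc)).astype(np.int32)
    shape = 1.0 / cfg.noise_dispersion
    gamma = rng.gamma(shape, 1.0 / shape, size=log_mu_expr.shape)
    expr_counts = rng.poisson(np.exp(log_mu_expr) * gamma).astype(np.int32)

    # ---- tables and AnnData bundles ----
    cell_ids = [f"cell{i}" for i in range(n_cells)]
    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "cell_type": labels,
        "pseudotime": pseudotime,
        "n_genes_detected": (expr_counts > 0).sum(axis=1),
        "mito_frac": rng.beta(2.0, 18.0, n_cells),
        "n_fragments": acc_counts.sum(axis=1),
        "tss_enrichment": np.clip(rng.normal(9.0, 2.0, n_cells), 0.0, None),
    }).set_index("cell_id")
    # keep fragment totals comfortably inside the QC regime of real data
    cells["n_fragments"] = cells["n_fragments"] + 1000

    acc = ad.AnnData(X=acc_counts, obs=cells.copy(),
                     var=peaks.set_index("peak_id", drop=False))
    expr = ad.AnnData(X=expr_counts, obs=cells.copy(),
                      var=genes.set_index("gene_id", drop=False))
    return SyntheticDataset(acc=acc, expr=expr, peaks=peaks, genes=genes,
                            cells=cells, motif_scores=motif_scores,
                            regulons=regulons, truth=truth)


def binarize(acc: ad.AnnData) -> ad.AnnData:
    """Return a copy with accessibility counts thresholded to 0/1."""
    out = acc.copy()
    out.X = (np.asarray(out.X) > 0).astype(np.int8)
    return out


# ---------------------------------------------------------------------------
# survival cohort


def generate_survival_cohort(cfg: SynthConfig, expr_signature: pd.Series,
                             hazard_genes: list[tuple[str, float]] | None = None,
                             seed: int | None = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a bulk cohort whose hazard depends on planted gene expression.

    Per-subject expression is log-normal around ``expr_signature`` (gene-level
    means). Event times are exponential with log-hazard
    ``sum_g effect_g * z_g`` over the planted hazard genes, where ``z_g`` is
    the subject's standardized log-expression of gene ``g``; censoring is
    independent exponential. Returns ``(survival, expr_by_subject)`` with
    survival columns ``subject, time, event``.
    """
    if cfg.survival_n < 50:
        raise ValueError("survival cohort needs at least 50 subjects")
    rng = np.random.default_rng(cfg.seed + 10_000 if seed is None else seed)
    if hazard_genes is None:
        hazard_genes = [(g, cfg.survival_effect)
                        for g in list(expr_signature.index[:cfg.n_hazard_genes])]
    n = cfg.survival_n
    genes = list(expr_signature.index)
    log_sig = np.log(np.maximum(expr_signature.to_numpy(dtype=float), 1e-3))
    X = np.exp(log_sig[None, :] + rng.normal(0.0, 0.6, size=(n, len(genes))))
    expr_df = pd.DataFrame(X, columns=genes,
                           index=[f"subj{i}" for i in range(n)])

    logX = np.log1p(X)
    Z = (logX - logX.mean(axis=0)) / np.where(logX.std(axis=0) > 0, logX.std(axis=0), 1.0)
    eta = np.zeros(n)
    gi = {g: j for j, g in enumerate(genes)}
    for g, effect in hazard_genes:
        if g in gi:
            eta += effect * Z[:, gi[g]]
    t_event = rng.exponential(1.0 / (0.1 * np.exp(eta)))
    t_cens = rng.exponential(1.0 / 0.05, size=n)
    surv = pd.DataFrame({
        "subject": expr_df.index,
        "time": np.minimum(t_event, t_cens),
        "event": (t_event <= t_cens).astype(int),
    })
    return surv, expr_df


# ---------------------------------------------------------------------------
# quality control


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell inclusion rules: at least ``min_genes`` detected genes, at
    most ``max_mito`` mitochondrial fraction (strictly-over fails), at least
    ``min_fragments`` ATAC fragments and TSS enrichment >= ``min_tss``."""

    min_genes: int = 200
    max_mito: float = 0.20
    min_fragments: int = 1000
    min_tss: float = 4.0


def apply_qc(expr: ad.AnnData, acc: ad.AnnData, cells: pd.DataFrame,
             thresholds: QCThresholds = QCThresholds(),
             ) -> tuple[ad.AnnData, ad.AnnData, pd.DataFrame, dict]:
    """Drop cells failing any QC rule, consistently from both modalities.

    Returns the filtered (expr, acc, cells) plus a report of removed counts
    per rule. Idempotent: re-applying to the output removes nothing.
    """
    required = ("n_genes_detected", "mito_frac", "n_fragments", "tss_enrichment")
    for col in required:
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required QC column '{col}'")
    fail_genes = cells["n_genes_detected"] < thresholds.min_genes
    fail_mito = cells["mito_frac"] > thresholds.max_mito
    fail_frag = cells["n_fragments"] < thresholds.min_fragments
    fail_tss = cells["tss_enrichment"] < thresholds.min_tss
    keep = ~(fail_genes | fail_mito | fail_frag | fail_tss)
    report = {
        "n_input": len(cells),
        "n_removed_low_genes": int(fail_genes.sum()),
        "n_removed_high_mito": int(fail_mito.sum()),
        "n_removed_low_fragments": int(fail_frag.sum()),
        "n_removed_low_tss": int(fail_tss.sum()),
        "n_removed_total": int((~keep).sum()),
        "n_kept": int(keep.sum()),
    }
    if report["n_removed_total"] == 0:
        return expr, acc, cells, report
    keep_arr = keep.to_numpy()
    return expr[keep_arr].copy(), acc[keep_arr].copy(), cells.loc[keep], report
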