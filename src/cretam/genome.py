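"""Genomic interval handling: peak annotation, TSS distances, interval overlap.

Coordinates are 0-based, half-open ([start, end)) throughout, matching BED.
Gene models carry a single TSS per gene (no isoform resolution): for a
``+``-strand gene the TSS is ``start``; for a ``-``-strand gene it is
``end - 1``.

Peaks are annotated into four mutually exclusive categories with precedence

    promoter > exonic > intronic > distal

so a peak overlapping a promoter window is "promoter" regardless of any
other overlap. The peak anchor for all distance computations is its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("promoter", "exonic", "intronic", "distal")

#: promoter window (upstream bp, downstream bp) around the TSS, in the gene's
#: transcriptional orientation. -2000/+100 is common ATAC practice.
DEFAULT_PROMOTER_WINDOW = (2000, 100)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """One gene with a single TSS and non-overlapping exons sorted 5'->3'."""

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns: {missing}")


def gene_tss(genes: pd.DataFrame) -> np.ndarray:
    """TSS coordinate per gene row (start for +, end-1 for -)."""
    _require_columns(genes, ("start", "end", "strand"), "gene")
    return np.where(genes["strand"].to_numpy() == "-",
                    genes["end"].to_numpy() - 1,
                    genes["start"].to_numpy())


def _parse_exon_list(field: str) -> list[int]:
    if field is None or (isinstance(field, float) and np.isnan(field)) or field == "":
        return []
    return [int(x) for x in str(field).rstrip(",").split(",")]


def promoter_intervals(genes: pd.DataFrame,
                       window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW) -> pd.DataFrame:
    """Strand-aware promoter windows around each TSS.

    ``window = (up, down)``: the promoter covers ``up`` bp upstream of the
    TSS and ``down`` bp downstream (the TSS base itself counts as downstream).
    """
    up, down = window
    tss = gene_tss(genes)
    minus = genes["strand"].to_numpy() == "-"
    start = np.where(minus, tss - down + 1, tss - up)
    end = np.where(minus, tss + up + 1, tss + down)
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "chrom": genes["chrom"].to_numpy(),
        "start": np.maximum(start, 0),
        "end": end,
    })


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame,
                   promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW,
                   ) -> pd.DataFrame:
    """Annotate each peak as promoter / exonic / intronic / distal.

    Parameters
    ----------
    peaks
        Columns ``peak_id, chrom, start, end``.
    genes
        Columns ``gene_id, chrom, start, end, strand`` and optionally
        ``exon_starts, exon_ends`` (comma-separated coordinate lists).

    Returns
    -------
    DataFrame with one row per peak: ``peak_id, category, nearest_gene,
    tss_distance, intron_order, dist_to_first_intron_5p``. ``tss_distance``
    is the signed midpoint-to-nearest-TSS distance in the nearest gene's
    transcriptional orientation (positive = downstream of the TSS).
    """
    _require_columns(peaks, ("peak_id", "chrom", "start", "end"), "peak")
    _require_columns(genes, ("gene_id", "chrom", "start", "end", "strand"), "gene")

    gene_chroms = set(genes["chrom"].unique())
    bad = sorted(set(peaks["chrom"].unique()) - gene_chroms)
    if bad:
        raise ValueError(f"peaks on chromosomes with no annotated genes: {bad}")

    proms = promoter_intervals(genes, promoter_window)
    has_exons = "exon_starts" in genes.columns and "exon_ends" in genes.columns

    records = []
    for chrom, pk in peaks.groupby("chrom", sort=False):
        gn = genes[genes["chrom"] == chrom]
        pm = proms[proms["chrom"] == chrom]
        tss = gene_tss(gn)
        g_start = gn["start"].to_numpy()
        g_end = gn["end"].to_numpy()
        g_minus = gn["strand"].to_numpy() == "-"
        g_ids = gn["gene_id"].to_numpy()

        exon_bounds: list[tuple[np.ndarray, np.ndarray]] = []
        if has_exons:
            for _, g in gn.iterrows():
                es = np.asarray(_parse_exon_list(g["exon_starts"]), dtype=np.int64)
                ee = np.asarray(_parse_exon_list(g["exon_ends"]), dtype=np.int64)
                exon_bounds.append((es, ee))

        p_start = pk["start"].to_numpy()
        p_end = pk["end"].to_numpy()
        p_mid = (p_start + p_end) // 2

        # promoter overlap: any promoter window intersecting the peak
        pr_s = pm["start"].to_numpy()
        pr_e = pm["end"].to_numpy()
        is_prom = (
            (p_start[:, None] < pr_e[None, :]) & (pr_s[None, :] < p_end[:, None])
        ).any(axis=1) if len(pm) else np.zeros(len(pk), dtype=bool)

        # gene-body containment of the midpoint (used for exonic/intronic)
        in_body = (g_start[None, :] <= p_mid[:, None]) & (p_mid[:, None] < g_end[None, :])

        # signed TSS distance, orientation of each gene
        d_signed = np.where(g_minus[None, :],
                            tss[None, :] - p_mid[:, None],
                            p_mid[:, None] - tss[None, :])
        nearest_j = np.abs(d_signed).argmin(axis=1)

        for i, pid in enumerate(pk["peak_id"].to_numpy()):
            j = int(nearest_j[i])
            category = "distal"
            intron_order = None
            dist_first_intron = None
            if is_prom[i]:
                category = "promoter"
            else:
                body_js = np.flatnonzero(in_body[i])
                exonic = False
                if has_exons:
                    for bj in body_js:
                        es, ee = exon_bounds[bj]
                        if len(es) and np.any(
                            (p_start[i] < ee) & (es < p_end[i])
                        ):
                            exonic = True
                            break
                if exonic:
                    category = "exonic"
                elif len(body_js):
                    category = "intronic"
                    # intron order in the host gene, 5'->3'
                    bj = body_js[0]
                    if has_exons and len(exon_bounds[bj][0]) >= 2:
                        es, ee = exon_bounds[bj]
                        # introns in genomic order are [ee[k], es[k+1])
                        k = int(np.searchsorted(ee, p_mid[i], side="right")) - 1
                        n_introns = len(es) - 1
                        genomic_order = min(max(k, 0), n_introns - 1) + 1
                        if g_minus[bj]:
                            intron_order = n_introns - genomic_order + 1
                            first_5p = es[-1]  # 5' end of intron 1 on - strand
                        else:
                            intron_order = genomic_order
                            first_5p = ee[0]
                        dist_first_intron = int(abs(p_mid[i] - first_5p))
                    else:
                        intron_order = 1
                        dist_first_intron = int(abs(p_mid[i] - g_start[bj]))
            records.append({
                "peak_id": pid,
                "category": category,
                "nearest_gene": g_ids[j],
                "tss_distance": int(d_signed[i, j]),
                "intron_order": intron_order,
                "dist_to_first_intron_5p": dist_first_intron,
            })
    out = pd.DataFrame.from_records(records)
    return out.set_index("peak_id").loc[peaks["peak_id"]].reset_index()


def interval_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame,
                     min_bp: int = 1) -> tuple[pd.DataFrame, dict]:
    """All pairs of intervals from A and B overlapping by at least ``min_bp``.

    Both inputs need ``chrom, start, end`` and an id column (first column
    that is not a coordinate, defaulting to the index). Returns the pair
    table and a symmetric summary with element-wise hit counts and a
    Jaccard-style statistic on elements (|A hit| + |B hit|) / (|A| + |B|).
    """
    def _ids(df: pd.DataFrame) -> np.ndarray:
        for c in df.columns:
            if c not in ("chrom", "start", "end", "strand"):
                return df[c].to_numpy()
        return df.index.to_numpy()

    rows = []
    for chrom in sorted(set(set_a["chrom"]) & set(set_b["chrom"])):
        a = set_a[set_a["chrom"] == chrom]
        b = set_b[set_b["chrom"] == chrom]
        a_s, a_e = a["start"].to_numpy(), a["end"].to_numpy()
        b_s, b_e = b["start"].to_numpy(), b["end"].to_numpy()
        ov = (np.minimum(a_e[:, None], b_e[None, :])
              - np.maximum(a_s[:, None], b_s[None, :]))
        ii, jj = np.nonzero(ov >= min_bp)
        ida, idb = _ids(a), _ids(b)
        for i, j in zip(ii, jj):
            rows.append((ida[i], idb[j], chrom, int(ov[i, j])))
    pairs = pd.DataFrame(rows, columns=["id_a", "id_b", "chrom", "overlap_bp"])
    n_a_hit = pairs["id_a"].nunique()
    n_b_hit = pairs["id_b"].nunique()
    denom = len(set_a) + len(set_b)
    summary = {
        "n_a": len(set_a), "n_b": len(set_b),
        "n_a_with_overlap": n_a_hit, "n_b_with_overlap": n_b_hit,
        "n_pairs": len(pairs),
        "jaccard_elements": (n_a_hit + n_b_hit) / denom if denom else 0.0,
    }
    return pairs, summary
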