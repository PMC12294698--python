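"""Meta-cell aggregation and peak-to-gene correlation linking.

Single cells are too sparse for per-element correlations, so cells are
combined into overlapping k-nearest-neighbor aggregates (meta-cells) in a
PCA embedding of the expression matrix; each aggregate is annotated with
its predominant cell type. Peak accessibility and the expression of every
gene whose TSS lies within a +/-250 kb window of the peak midpoint are then
correlated (Pearson) across aggregate profiles, and pairs with r above the
correlation cutoff (default 0.4) are reported as candidate cis-regulatory
elements.

Profiles are depth-normalized (counts per 10k) and log1p-transformed means
over member cells. An optional BH-adjusted permutation-p filter is
available but off by default; the retained-link rule is the r cutoff alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .genome import gene_tss

logger = logging.getLogger(__name__)


@dataclass
class MetaCellAggregate:
    aggregate_id: str
    member_cells: list[int]
    dominant_type: str


@dataclass
class Aggregates:
    """Aggregate membership plus stacked normalized profiles."""

    aggregates: list[MetaCellAggregate]
    acc_profiles: np.ndarray   # (n_agg, n_peaks)
    expr_profiles: np.ndarray  # (n_agg, n_genes)

    def __len__(self) -> int:
        return self.acc_profiles.shape[0]

    @property
    def dominant_types(self) -> np.ndarray:
        return np.array([a.dominant_type for a in self.aggregates])


def _normalize_log(X: np.ndarray, scale: float = 1e4) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    depth = X.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log1p(X / depth * scale)


def make_aggregates(acc_X: np.ndarray, expr_X: np.ndarray, cell_types,
                    k_agg: int = 50, n_agg: int = 500, seed: int = 0,
                    n_pcs: int = 30) -> Aggregates:
    """Build overlapping k-NN meta-cell aggregates.

    Each aggregate is a seed cell plus its ``k_agg - 1`` nearest neighbors
    in a PCA embedding of the log-normalized expression matrix; seeds are
    sampled with a fixed RNG so membership is deterministic. Profiles are
    means of the log-normalized per-cell vectors. With ``k_agg = 1``
    aggregates degenerate to single cells.
    """
    n_cells = np.asarray(expr_X).shape[0]
    if k_agg > n_cells:
        raise ValueError(f"k_agg={k_agg} exceeds the number of cells ({n_cells})")
    cell_types = np.asarray(cell_types)
    rng = np.random.default_rng(seed)

    logE = _normalize_log(expr_X)
    logA = _normalize_log(acc_X)
    if k_agg == 1:
        members = rng.choice(n_cells, size=min(n_agg, n_cells), replace=n_agg > n_cells)
        nbrs = members[:, None]
    else:
        n_comp = min(n_pcs, n_cells - 1, logE.shape[1])
        emb = PCA(n_components=n_comp, random_state=0).fit_transform(logE)
        nn = NearestNeighbors(n_neighbors=k_agg).fit(emb)
        seeds = rng.choice(n_cells, size=n_agg, replace=n_agg > n_cells)
        nbrs = nn.kneighbors(emb[seeds], return_distance=False)

    aggs, acc_prof, expr_prof = [], [], []
    for i, mem in enumerate(nbrs):
        mem = np.asarray(mem)
        types, counts = np.unique(cell_types[mem], return_counts=True)
        aggs.append(MetaCellAggregate(f"agg{i}", mem.tolist(), str(types[counts.argmax()])))
        acc_prof.append(logA[mem].mean(axis=0))
        expr_prof.append(logE[mem].mean(axis=0))
    return Aggregates(aggs, np.asarray(acc_prof), np.asarray(expr_prof))


def _candidate_pairs(peaks: pd.DataFrame, genes: pd.DataFrame,
                     window_bp: int) -> pd.DataFrame:
    """All (peak, gene) pairs with |peak midpoint - TSS| <= window_bp."""
    tss = gene_tss(genes)
    rows = []
    for chrom, pk in peaks.groupby("chrom", sort=False):
        gsel = genes["chrom"].to_numpy() == chrom
        if not gsel.any():
            continue
        g_idx = np.flatnonzero(gsel)
        t = tss[gsel]
        mid = ((pk["start"] + pk["end"]) // 2).to_numpy()
        d = np.abs(mid[:, None] - t[None, :])
        ii, jj = np.nonzero(d <= window_bp)
        pid = pk["peak_id"].to_numpy()
        p_iloc = pk.index.to_numpy()
        for i, j in zip(ii, jj):
            rows.append((pid[i], int(p_iloc[i]), int(g_idx[j]), int(d[i, j])))
    return pd.DataFrame(rows, columns=["peak_id", "peak_row", "gene_row", "distance_bp"])


def link_peaks_to_genes(aggregates: Aggregates, peaks: pd.DataFrame,
                        genes: pd.DataFrame, window_bp: int = 250_000,
                        cor_cutoff: float = 0.4,
                        annotations: pd.DataFrame | None = None,
                        return_all: bool = False) -> pd.DataFrame:
    """Candidate CRE links: peak-gene Pearson r across aggregate profiles.

    ``peaks`` rows must align with the columns of the aggregate accessibility
    profiles (positional), likewise ``genes`` with expression profiles. Pairs
    are restricted to ``|midpoint - TSS| <= window_bp``. Zero-variance peaks
    or genes yield undefined r and are skipped (logged). With ``return_all``
    every tested pair is returned with a ``retained`` flag; otherwise only
    links with ``r > cor_cutoff``.
    """
    if len(aggregates) < 20:
        raise ValueError("peak-gene correlation needs at least 20 aggregates")
    peaks = peaks.reset_index(drop=True)
    genes = genes.reset_index(drop=True)
    cand = _candidate_pairs(peaks, genes, window_bp)

    A = aggregates.acc_profiles
    E = aggregates.expr_profiles
    As = A - A.mean(axis=0)
    Es = E - E.mean(axis=0)
    a_sd = np.sqrt((As ** 2).sum(axis=0))
    e_sd = np.sqrt((Es ** 2).sum(axis=0))

    pr = cand["peak_row"].to_numpy()
    gr = cand["gene_row"].to_numpy()
    valid = (a_sd[pr] > 0) & (e_sd[gr] > 0)
    n_skip = int((~valid).sum())
    if n_skip:
        logger.info("skipped %d candidate pairs with zero variance", n_skip)
    r = np.full(len(cand), np.nan)
    if valid.any():
        num = np.einsum("ij,ij->j", As[:, pr[valid]], Es[:, gr[valid]])
        r[valid] = num / (a_sd[pr[valid]] * e_sd[gr[valid]])

    out = pd.DataFrame({
        "peak_id": cand["peak_id"],
        "gene_id": genes["gene_id"].to_numpy()[gr],
        "chrom": peaks["chrom"].to_numpy()[pr],
        "peak_start": peaks["start"].to_numpy()[pr],
        "peak_end": peaks["end"].to_numpy()[pr],
        "r": r,
        "distance_bp": cand["distance_bp"],
    })
    if annotations is not None:
        cat = annotations.set_index("peak_id")["category"]
        out["category"] = out["peak_id"].map(cat)
    out["retained"] = valid & (r > cor_cutoff)
    if return_all:
        return out
    return out[out["retained"]].drop(columns="retained").reset_index(drop=True)


def links_per_gene(links: pd.DataFrame) -> tuple[pd.Series, float]:
    """CRE count per linked gene and the median over genes."""
    if links is None or len(links) == 0:
        raise ValueError("no links provided")
    counts = links.groupby("gene_id")["peak_id"].nunique()
    return counts, float(counts.median())
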