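"""Super-enhancer detection from coordinated distal-peak accessibility.

Distal peaks are first clustered into "accessons" -- groups of peaks with
coordinated accessibility across cells (k-means on standardized per-cell
profiles). A super-enhancer (SE) is then a genomic window of width at most
``super_range`` (default 500 kb) significantly enriched for peaks of one
accesson: for each window anchored at a member peak, the count of
same-accesson distal peaks among all distal peaks in the window is tested
against a binomial null whose success probability is the accesson's
genome-wide share of distal peaks; p-values are BH-adjusted across all
tested windows and significant overlapping windows of one accesson are
merged. The SE interval spans its constituent peaks.

Subtype specificity reuses the tau index on summed constituent counts
(tau > 0.7 and focal-type normalized accessibility > 0.5 by default), and
each SE is assigned the nearest gene as target if SE accessibility and gene
expression correlate (r > 0.3) in focal-type cells and the gene's
focal-type pseudobulk expression exceeds the median across types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .genome import GenomicInterval, gene_tss
from .specificity import tau_index

logger = logging.getLogger(__name__)


@dataclass
class Accesson:
    accesson_id: str
    peak_ids: list[str]
    centroid: np.ndarray  # per-cell-type mean of standardized accessibility


@dataclass
class SuperEnhancer:
    se_id: str
    interval: GenomicInterval
    constituent_peaks: list[str]
    accesson_id: str
    enrichment_p: float
    fdr: float
    tau: float = np.nan
    per_type_norm_acc: dict[str, float] = field(default_factory=dict)
    target_gene: str | None = None
    target_r: float | None = None


def build_accessons(acc_X: np.ndarray, peak_ids, cell_types,
                    n_accessons: int = 10, seed: int = 0) -> tuple[list[Accesson], pd.Series]:
    """Cluster distal peaks into accessons by k-means on standardized
    per-cell accessibility profiles. ``acc_X`` is cells-by-peaks restricted
    to distal peaks. Deterministic under ``seed``."""
    if n_accessons < 2:
        raise ValueError("need at least 2 accessons")
    X = np.asarray(acc_X, dtype=float).T  # peaks x cells
    if X.shape[0] < n_accessons:
        raise ValueError("fewer distal peaks than requested accessons")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=n_accessons, random_state=seed, n_init=10)
    labels = km.fit_predict(Z)
    cell_types = np.asarray(cell_types)
    types = sorted(pd.unique(cell_types))
    accessons = []
    peak_ids = list(peak_ids)
    for a in range(n_accessons):
        mem = np.flatnonzero(labels == a)
        prof = Z[mem].mean(axis=0)
        centroid = np.array([prof[cell_types == t].mean() for t in types])
        accessons.append(Accesson(f"accesson{a}", [peak_ids[i] for i in mem], centroid))
    assign = pd.Series([f"accesson{l}" for l in labels], index=peak_ids, name="accesson_id")
    return accessons, assign


def call_superenhancers(assignment: pd.Series, peaks: pd.DataFrame,
                        super_range: int = 500_000, p_cutoff: float = 0.05,
                        min_constituents: int = 3) -> list[SuperEnhancer]:
    """Detect SEs as accesson-enriched windows of width ``super_range``.

    ``assignment`` maps distal peak_id -> accesson_id; ``peaks`` provides
    coordinates. One window is anchored at each member peak's start; the
    binomial test compares the same-accesson count among the window's
    distal peaks with the accesson's genome-wide share; BH across all
    tested windows at ``p_cutoff``; overlapping significant windows of one
    accesson are merged and trimmed to their member peaks.
    """
    pk = peaks.set_index("peak_id").loc[assignment.index]
    chrom = pk["chrom"].to_numpy()
    start = pk["start"].to_numpy()
    end = pk["end"].to_numpy()
    acc = assignment.to_numpy()
    n_total = len(pk)
    share = pd.Series(acc).value_counts() / n_total

    tests = []  # (accesson, chrom, win_start, win_end, k, n, p)
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        order = sel[np.argsort(start[sel])]
        s = start[order]
        a = acc[order]
        for anchor in range(len(order)):
            w0 = s[anchor]
            w1 = w0 + super_range
            in_win = slice(anchor, int(np.searchsorted(s, w1, side="left")))
            n = in_win.stop - in_win.start
            k = int((a[in_win] == a[anchor]).sum())
            # every anchored window enters the BH family; windows too sparse
            # to seed an SE still count toward multiplicity
            p = float(stats.binom.sf(k - 1, n, share[a[anchor]]))
            tests.append((a[anchor], c, int(w0), int(w1), k, n, p))
    if not tests:
        return []
    tdf = pd.DataFrame(tests, columns=["accesson", "chrom", "w0", "w1", "k", "n", "p"])
    tdf["fdr"] = stats.false_discovery_control(tdf["p"], method="bh")
    sig = tdf[(tdf["fdr"] < p_cutoff) & (tdf["k"] >= min_constituents)]

    ses: list[SuperEnhancer] = []
    pid_arr = assignment.index.to_numpy()
    for (a, c), grp in sig.groupby(["accesson", "chrom"]):
        grp = grp.sort_values("w0")
        merged: list[list] = []
        for _, row in grp.iterrows():
            if merged and row["w0"] <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], row["w1"])
                merged[-1][2] = min(merged[-1][2], row["p"])
                merged[-1][3] = min(merged[-1][3], row["fdr"])
            else:
                merged.append([row["w0"], row["w1"], row["p"], row["fdr"]])
        for w0, w1, p_best, fdr_best in merged:
            mem = np.flatnonzero((chrom == c) & (acc == a)
                                 & (start >= w0) & (start < w1))
            if len(mem) < min_constituents:
                continue
            iv = GenomicInterval(c, int(start[mem].min()), int(end[mem].max()))
            if iv.length > super_range:
                # merged run longer than one window: trim to the best window
                keep = mem[(start[mem] >= w0) & (start[mem] < w0 + super_range)]
                if len(keep) < min_constituents:
                    continue
                mem = keep
                iv = GenomicInterval(c, int(start[mem].min()), int(end[mem].max()))
            ses.append(SuperEnhancer(
                se_id=f"se{len(ses)}", interval=iv,
                constituent_peaks=[str(p) for p in pid_arr[mem]],
                accesson_id=str(a), enrichment_p=float(p_best), fdr=float(fdr_best)))
    ses.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    for i, s in enumerate(ses):
        s.se_id = f"se{i}"
    return ses


def se_accessibility(ses: list[SuperEnhancer], acc_X: np.ndarray,
                     peak_ids) -> np.ndarray:
    """Per-cell SE accessibility = summed counts of constituent peaks.
    Returns (n_SEs, n_cells)."""
    idx = {p: i for i, p in enumerate(peak_ids)}
    X = np.asarray(acc_X, dtype=float)
    return np.vstack([X[:, [idx[p] for p in s.constituent_peaks]].sum(axis=1)
                      for s in ses]) if ses else np.empty((0, X.shape[0]))


def se_specificity(ses: list[SuperEnhancer], acc_X: np.ndarray, peak_ids,
                   cell_types, focal_type: str, tau_cut: float = 0.7,
                   acc_cut: float = 0.5) -> list[SuperEnhancer]:
    """Annotate SEs with tau / per-type normalized accessibility and return
    the subset specific to ``focal_type`` (tau > tau_cut and normalized
    focal accessibility > acc_cut)."""
    cell_types = np.asarray(cell_types)
    types = sorted(pd.unique(cell_types))
    if focal_type not in types:
        raise ValueError(f"unknown focal type '{focal_type}'")
    if not ses:
        return []
    S = se_accessibility(ses, acc_X, peak_ids)
    tau_tab = tau_index(S, cell_types, element_ids=[s.se_id for s in ses])
    keep = []
    for s, (_, row) in zip(ses, tau_tab.iterrows()):
        s.tau = float(row["tau"])
        s.per_type_norm_acc = {t: float(row[f"P_{t}"]) for t in types}
        if s.tau > tau_cut and s.per_type_norm_acc[focal_type] > acc_cut:
            keep.append(s)
    return keep


def assign_target_genes(ses: list[SuperEnhancer], genes: pd.DataFrame,
                        expr_X: np.ndarray, acc_X: np.ndarray, peak_ids,
                        cell_types, focal_type: str,
                        r_cut: float = 0.3) -> list[SuperEnhancer]:
    """Assign each SE its nearest gene as target, gated by correlation and
    expression level.

    Candidate = gene minimizing the SE-edge-to-TSS distance (0 if the TSS
    lies inside the SE; ties broken by lower gene start). The candidate is
    kept iff Pearson r between SE accessibility and gene expression across
    focal-type cells exceeds ``r_cut`` AND the gene's focal-type pseudobulk
    mean exceeds the median of its per-type pseudobulk means; otherwise the
    SE's target stays null.
    """
    cell_types = np.asarray(cell_types)
    types = sorted(pd.unique(cell_types))
    if focal_type not in types:
        raise ValueError(f"unknown focal type '{focal_type}'")
    genes = genes.reset_index(drop=True)
    tss = gene_tss(genes)
    E = np.asarray(expr_X, dtype=float)
    focal = cell_types == focal_type
    S = se_accessibility(ses, acc_X, peak_ids)
    pseudo = np.vstack([E[cell_types == t].mean(axis=0) for t in types])
    med = np.median(pseudo, axis=0)
    t_idx = types.index(focal_type)

    for si, s in enumerate(ses):
        on_chrom = np.flatnonzero(genes["chrom"].to_numpy() == s.interval.chrom)
        if len(on_chrom) == 0:
            logger.info("SE %s: no gene on %s; target null", s.se_id, s.interval.chrom)
            s.target_gene = None
            s.target_r = None
            continue
        t = tss[on_chrom]
        d = np.maximum(0, np.maximum(s.interval.start - t, t - (s.interval.end - 1)))
        g_start = genes["start"].to_numpy()[on_chrom]
        best = on_chrom[np.lexsort((g_start, d))[0]]
        gexp = E[focal, best]
        sacc = S[si, focal]
        if gexp.std() == 0 or sacc.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(sacc, gexp)[0, 1])
        if np.isfinite(r) and r > r_cut and pseudo[t_idx, best] > med[best]:
            s.target_gene = str(genes["gene_id"].iloc[best])
            s.target_r = r
        else:
            s.target_gene = None
            s.target_r = None
    return ses


def ses_to_frame(ses: list[SuperEnhancer]) -> pd.DataFrame:
    """Flatten SE objects into the on-disk TSV schema."""
    rows = []
    for s in ses:
        rows.append({
            "se_id": s.se_id, "chrom": s.interval.chrom,
            "start": s.interval.start, "end": s.interval.end,
            "n_constituents": len(s.constituent_peaks),
            "constituent_peaks": ",".join(s.constituent_peaks),
            "accesson_id": s.accesson_id,
            "enrichment_p": s.enrichment_p, "fdr": s.fdr, "tau": s.tau,
            "target_gene": s.target_gene if s.target_gene else "",
            "target_r": s.target_r if s.target_r is not None else np.nan,
        })
    return pd.DataFrame(rows, columns=["se_id", "chrom", "start", "end",
                                       "n_constituents", "constituent_peaks",
                                       "accesson_id", "enrichment_p", "fdr",
                                       "tau", "target_gene", "target_r"])
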