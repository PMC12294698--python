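"""TF motif deviations, regulon activity, core-TF consensus, SE motif
enrichment.

Two independent branches identify candidate regulators of a cell type:

* chromatin branch -- per-cell motif deviation z-scores (observed fraction
  of a cell's accessibility in motif-bearing peaks, normalized against
  GC/accessibility-matched random peak sets), kept if the TF's mean z in the
  focal type exceeds the median of its per-type mean z AND the Pearson
  correlation between per-type mean z and the TF's own expression is > 0.5;
* activity branch -- regulon activity (signed mean of z-scored target
  expression), kept if the focal-vs-rest Wilcoxon shift is positive at
  FDR < 0.05.

Core TFs are the intersection of the two branches. Motif enrichment within
super-enhancer peaks is a hypergeometric upper tail against a matched
background, BH-adjusted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class DeviationResult:
    tf_id: str
    z: np.ndarray                  # per-cell deviation z-score
    mean_z_per_type: pd.Series     # indexed by cell type
    expr_corr: float = np.nan


def _decile_bins(values: np.ndarray, n: int = 10) -> np.ndarray:
    edges = np.quantile(values, np.linspace(0, 1, n + 1))
    return np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n - 1)


def _matched_sample(rng: np.random.Generator, target_idx: np.ndarray,
                    bins: np.ndarray, pool_mask: np.ndarray) -> np.ndarray:
    """One random peak from ``pool_mask`` per target peak, matched on bin."""
    out = np.empty(len(target_idx), dtype=int)
    pool = np.flatnonzero(pool_mask)
    by_bin = {b: pool[bins[pool] == b] for b in np.unique(bins[target_idx])}
    for i, t in enumerate(target_idx):
        cand = by_bin.get(bins[t])
        if cand is None or len(cand) == 0:
            cand = pool
        out[i] = rng.choice(cand)
    return out


def motif_deviation_z(acc_X: np.ndarray, motif_binary: pd.DataFrame,
                      peak_gc: np.ndarray, cell_types,
                      n_background: int = 50, seed: int = 0,
                      min_peaks: int = 5) -> list[DeviationResult]:
    """Per-cell motif deviation z-scores with matched random backgrounds.

    For motif peak set S: observed_c = cell c's count fraction in S,
    expected = S's share of all counts; raw deviation = (obs - exp) / exp.
    z standardizes the raw deviation against ``n_background`` random peak
    sets matched to S on GC and mean-accessibility deciles. Motifs with
    fewer than ``min_peaks`` peaks are skipped with a warning; a degenerate
    background sd yields NaN z (never silent).

    ``acc_X`` is cells-by-peaks; ``motif_binary`` is a TF-by-peak boolean
    frame whose columns align positionally with the peaks.
    """
    X = np.asarray(acc_X, dtype=float)
    cell_types = np.asarray(cell_types)
    types = sorted(pd.unique(cell_types))
    rng = np.random.default_rng(seed)
    totals = X.sum(axis=1)
    totals[totals == 0] = 1.0
    grand = X.sum()
    peak_sums = X.sum(axis=0)
    mean_acc = X.mean(axis=0)
    # composite GC-decile x accessibility-decile stratum per peak
    bins = _decile_bins(np.asarray(peak_gc)) * 10 + _decile_bins(mean_acc)
    all_mask = np.ones(X.shape[1], dtype=bool)

    def raw_dev(idx: np.ndarray) -> np.ndarray:
        exp = peak_sums[idx].sum() / grand
        if exp == 0:
            return np.zeros(X.shape[0])
        obs = X[:, idx].sum(axis=1) / totals
        return (obs - exp) / exp

    results = []
    for tf, row in motif_binary.iterrows():
        idx = np.flatnonzero(row.to_numpy().astype(bool))
        if len(idx) < min_peaks:
            warnings.warn(f"motif {tf}: only {len(idx)} peaks; skipped")
            continue
        dev = raw_dev(idx)
        bg = np.vstack([raw_dev(_matched_sample(rng, idx, bins, all_mask))
                        for _ in range(n_background)])
        sd = bg.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (dev - bg.mean(axis=0)) / sd
        if (sd == 0).any():
            warnings.warn(f"motif {tf}: degenerate background sd; NaN z emitted")
        mean_z = pd.Series({t: float(np.nanmean(z[cell_types == t])) for t in types})
        results.append(DeviationResult(str(tf), z, mean_z))
    return results


def deviations_frame(deviations: list[DeviationResult]) -> pd.DataFrame:
    """Per-type mean z, TFs in rows."""
    return pd.DataFrame({d.tf_id: d.mean_z_per_type for d in deviations}).T


def chromatin_branch_tfs(deviations: list[DeviationResult], expr_X: np.ndarray,
                         gene_ids, cell_types, cell_type: str,
                         r_cut: float = 0.5) -> tuple[set[str], pd.DataFrame]:
    """Candidate positive regulators by the chromatin branch.

    A TF passes iff its mean deviation z in ``cell_type`` exceeds the median
    of its own per-type mean z values AND the Pearson correlation between
    per-type mean z and the TF gene's per-type pseudobulk expression is
    strictly greater than ``r_cut``. TFs absent from the expression matrix
    are excluded and logged.
    """
    E = np.asarray(expr_X, dtype=float)
    cell_types = np.asarray(cell_types)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    types = sorted(pd.unique(cell_types))
    pseudo = np.vstack([E[cell_types == t].mean(axis=0) for t in types])

    rows = []
    chosen: set[str] = set()
    for d in deviations:
        if d.tf_id not in gene_pos:
            logger.info("TF %s absent from expression matrix; excluded", d.tf_id)
            continue
        zs = d.mean_z_per_type.reindex(types).to_numpy()
        ex = pseudo[:, gene_pos[d.tf_id]]
        if np.std(zs) == 0 or np.std(ex) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(zs, ex)[0, 1])
        d.expr_corr = r
        z_gate = d.mean_z_per_type[cell_type] > float(np.median(zs))
        passes = bool(z_gate and np.isfinite(r) and r > r_cut)
        rows.append({"tf_id": d.tf_id, "mean_z_focal": d.mean_z_per_type[cell_type],
                     "z_above_median": z_gate, "expr_corr": r, "passes": passes})
        if passes:
            chosen.add(d.tf_id)
    return chosen, pd.DataFrame(rows)


def regulon_activity(expr_X: np.ndarray, gene_ids, regulons: pd.DataFrame,
                     min_targets: int = 5) -> pd.DataFrame:
    """TF-by-cell regulon activity: mean over targets of mode-sign times
    z-scored (log-normalized) target expression. Regulons smaller than
    ``min_targets`` are skipped with a log message."""
    E = np.asarray(expr_X, dtype=float)
    depth = E.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    L = np.log1p(E / depth * 1e4)
    mu = L.mean(axis=0)
    sd = L.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (L - mu) / sd
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    acts = {}
    for tf, grp in regulons.groupby("tf"):
        idx, signs = [], []
        for _, row in grp.iterrows():
            j = gene_pos.get(row["target"])
            if j is not None:
                idx.append(j)
                signs.append(1.0 if row["mode"] == "+" else -1.0)
        if len(idx) < min_targets:
            logger.info("regulon %s has %d usable targets; skipped", tf, len(idx))
            continue
        acts[str(tf)] = (Z[:, idx] * np.asarray(signs)).mean(axis=1)
    return pd.DataFrame(acts).T  # TF x cells


def activity_branch_tfs(activity: pd.DataFrame, cell_types, cell_type: str,
                        fdr_cut: float = 0.05) -> tuple[set[str], pd.DataFrame]:
    """TFs whose regulon activity is shifted up in ``cell_type`` vs the rest
    (two-sided Wilcoxon rank-sum, BH FDR, positive shift required)."""
    cell_types = np.asarray(cell_types)
    focal = cell_types == cell_type
    rows = []
    for tf, a in activity.iterrows():
        a = a.to_numpy()
        res = stats.mannwhitneyu(a[focal], a[~focal], alternative="two-sided")
        rows.append({"tf_id": tf, "shift": float(a[focal].mean() - a[~focal].mean()),
                     "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
        out["active"] = (out["fdr"] < fdr_cut) & (out["shift"] > 0)
    else:
        out["fdr"] = []
        out["active"] = []
    return set(out.loc[out["active"], "tf_id"]), out


def core_tfs(all_tfs, chromatin_set: set[str], activity_set: set[str],
             cell_type: str) -> pd.DataFrame:
    """Core-TF consensus: flagged iff identified by both branches."""
    rows = []
    for tf in all_tfs:
        pc = tf in chromatin_set
        pa = tf in activity_set
        rows.append({"tf_id": tf, "cell_type": cell_type,
                     "passes_chromatin": pc, "passes_activity": pa,
                     "is_core": pc and pa})
    return pd.DataFrame(rows)


def se_motif_enrichment(motif_binary: pd.DataFrame, se_peak_ids,
                        peaks: pd.DataFrame, mean_acc: np.ndarray,
                        bgd_matched: bool = True, bg_per_peak: int = 10,
                        fdr_cut: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Hypergeometric motif enrichment in SE peaks vs a matched background.

    The population is the SE peaks plus a background of non-SE peaks matched
    to the SE peaks on GC/mean-accessibility deciles (``bg_per_peak`` draws
    per SE peak; all non-SE peaks if ``bgd_matched`` is false). For each TF,
    the upper-tail probability of observing at least the seen number of
    motif-bearing SE peaks, BH-adjusted across TFs.
    """
    peak_ids = list(peaks["peak_id"])
    pos = {p: i for i, p in enumerate(peak_ids)}
    se_idx = np.array([pos[p] for p in se_peak_ids])
    is_se = np.zeros(len(peak_ids), dtype=bool)
    is_se[se_idx] = True

    if bgd_matched:
        rng = np.random.default_rng(seed)
        bins = _decile_bins(peaks["gc"].to_numpy()) * 10 + _decile_bins(np.asarray(mean_acc))
        draws = [
            _matched_sample(rng, se_idx, bins, ~is_se) for _ in range(bg_per_peak)
        ]
        bg_idx = np.unique(np.concatenate(draws))
    else:
        bg_idx = np.flatnonzero(~is_se)

    population = np.concatenate([se_idx, bg_idx])
    M = len(population)
    N = len(se_idx)
    rows = []
    for tf, row in motif_binary.iterrows():
        present = row.to_numpy().astype(bool)
        n = int(present[population].sum())
        k = int(present[se_idx].sum())
        p = float(stats.hypergeom.sf(k - 1, M, n, N))
        rows.append({"tf_id": tf, "n_se_with_motif": k, "n_pop_with_motif": n,
                     "n_se": N, "n_population": M, "p": p})
    out = pd.DataFrame(rows)
    out["fdr"] = stats.false_discovery_control(out["p"], method="bh")
    out["enriched"] = out["fdr"] < fdr_cut
    return out
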