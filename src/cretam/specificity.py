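"""Cell-type specificity of regulatory elements.

Implements the tau specificity index on per-cell-type accessibility,
bias-matched Wilcoxon marker-peak calling, the intersection rule defining
cell-type-specific distal CREs, and the Kruskal-Wallis comparison of tau
across genomic categories.

The tau index of element i over K cell types is

    tau_i = sum_k (1 - P_ik) / (K - 1)

where P_ik is the element's mean accessibility in type k, min-max
normalized across types. tau = 1 for a one-type element, 0 for a uniform
one; a constant profile is assigned tau = 0 by convention (least specific).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _type_means(X: np.ndarray, cell_types: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Per-type mean over cells. X is (n_elements, n_cells)."""
    types = sorted(pd.unique(cell_types))
    M = np.column_stack([X[:, cell_types == t].mean(axis=1) for t in types])
    return M, [str(t) for t in types]


def tau_index(X: np.ndarray, cell_types, element_ids=None) -> pd.DataFrame:
    """Tau specificity per element.

    Parameters
    ----------
    X
        Element-by-cell accessibility, shape ``(n_elements, n_cells)``. For a
        super-enhancer, pass the summed counts of its constituent peaks.
    cell_types
        Per-cell labels, length ``n_cells``; at least 2 distinct types.

    Returns
    -------
    DataFrame with ``element_id``, one ``P_<type>`` column per cell type
    (min-max normalized per-type means) and ``tau``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cell_types = np.asarray(cell_types)
    M, types = _type_means(X, cell_types)
    K = len(types)
    if K < 2:
        raise ValueError("tau index requires at least 2 cell types")
    lo = M.min(axis=1, keepdims=True)
    hi = M.max(axis=1, keepdims=True)
    span = hi - lo
    constant = span[:, 0] <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        P = (M - lo) / span
    P[constant] = 0.0
    tau = (1.0 - P).sum(axis=1) / (K - 1)
    tau[constant] = 0.0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant profiles assigned tau = 0")
    if element_ids is None:
        element_ids = [f"element{i}" for i in range(X.shape[0])]
    out = pd.DataFrame({"element_id": list(element_ids)})
    for j, t in enumerate(types):
        out[f"P_{t}"] = P[:, j]
    out["tau"] = tau
    return out


def marker_peaks(X: np.ndarray, cell_types, group: str,
                 bias_covariates: np.ndarray | None = None,
                 fdr_cut: float = 0.05, log2fc_cut: float = 0.57,
                 n_strata: int = 10, min_group: int = 20,
                 pseudocount: float = 1.0, peak_ids=None,
                 seed: int = 0) -> pd.DataFrame:
    """Differentially accessible peaks of one cell type vs a bias-matched
    background (Wilcoxon rank-sum, BH FDR).

    The background is drawn from cells outside ``group``, stratified on
    deciles of the bias covariate (per-cell total accessibility by default)
    so its covariate distribution matches the group's; strata with no
    background cells are dropped with a warning. ``log2fc`` compares group
    vs background pseudobulk means with a pseudocount. A peak is a marker
    iff ``fdr <= fdr_cut`` and ``log2fc >= log2fc_cut``.

    ``X`` is cells-by-peaks.
    """
    X = np.asarray(X, dtype=float)
    cell_types = np.asarray(cell_types)
    in_group = cell_types == group
    n_g = int(in_group.sum())
    if n_g < min_group:
        raise ValueError(f"group '{group}' has {n_g} cells; need >= {min_group}")
    if bias_covariates is None:
        bias_covariates = X.sum(axis=1)
    bias_covariates = np.asarray(bias_covariates, dtype=float)

    rng = np.random.default_rng(seed)
    edges = np.quantile(bias_covariates, np.linspace(0, 1, n_strata + 1))
    strata = np.clip(np.searchsorted(edges, bias_covariates, side="right") - 1,
                     0, n_strata - 1)
    bg_pool = np.flatnonzero(~in_group)
    bg_idx: list[np.ndarray] = []
    dropped = 0
    for s in range(n_strata):
        want = int((strata[in_group] == s).sum())
        if want == 0:
            continue
        pool = bg_pool[strata[bg_pool] == s]
        if len(pool) == 0:
            dropped += want
            continue
        bg_idx.append(rng.choice(pool, size=want, replace=len(pool) < want))
    if dropped:
        warnings.warn(f"{dropped} group cells fell in strata with no background; dropped")
    if not bg_idx:
        raise ValueError("no background cells available after bias matching")
    bg = np.concatenate(bg_idx)

    Xg, Xb = X[in_group], X[bg]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.mannwhitneyu(Xg, Xb, axis=0, alternative="two-sided",
                                 method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance peaks: no evidence
    fdr = stats.false_discovery_control(p, method="bh")
    mg, mb = Xg.mean(axis=0), Xb.mean(axis=0)
    log2fc = np.log2((mg + pseudocount) / (mb + pseudocount))
    if peak_ids is None:
        peak_ids = [f"peak{i}" for i in range(X.shape[1])]
    return pd.DataFrame({
        "peak_id": list(peak_ids), "cell_type": group,
        "log2fc": log2fc, "p": p, "fdr": fdr,
        "is_marker": (fdr <= fdr_cut) & (log2fc >= log2fc_cut),
    })


def marker_peaks_all_types(X, cell_types, **kwargs) -> pd.DataFrame:
    """Run :func:`marker_peaks` for every cell type and concatenate."""
    frames = [marker_peaks(X, cell_types, t, **kwargs)
              for t in sorted(pd.unique(np.asarray(cell_types)))]
    return pd.concat(frames, ignore_index=True)


def celltype_specific_distal_cres(markers: pd.DataFrame, links: pd.DataFrame,
                                  ) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Per cell type, peaks that are both markers of that type and distal
    candidate CREs (the marker/distal-link intersection)."""
    if "category" not in links.columns:
        raise ValueError("links must carry the genomic 'category' column")
    distal_cres = set(links.loc[links["category"] == "distal", "peak_id"])
    out: dict[str, list[str]] = {}
    rows = []
    for t, sub in markers.groupby("cell_type"):
        hit = sorted(set(sub.loc[sub["is_marker"], "peak_id"]) & distal_cres)
        out[str(t)] = hit
        rows.append({"cell_type": t, "n_markers": int(sub["is_marker"].sum()),
                     "n_specific_distal_cres": len(hit)})
    return out, pd.DataFrame(rows)


def tau_by_category(tau_table: pd.DataFrame, annotations: pd.DataFrame,
                    ) -> tuple[pd.DataFrame, dict]:
    """Compare tau across genomic categories.

    Joins the tau table (``element_id, tau``) with peak annotations
    (``peak_id, category``); returns per-category summaries plus an omnibus
    Kruskal-Wallis p and BH-adjusted pairwise Wilcoxon rank-sum p-values.
    """
    merged = tau_table.merge(annotations[["peak_id", "category"]],
                             left_on="element_id", right_on="peak_id")
    cats = sorted(merged["category"].unique())
    if len(cats) < 2:
        raise ValueError("tau comparison needs at least 2 categories")
    groups = [merged.loc[merged["category"] == c, "tau"].to_numpy() for c in cats]
    kw = stats.kruskal(*groups)
    summary = merged.groupby("category")["tau"].agg(["count", "median", "mean"]).reset_index()
    pair_rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            mw = stats.mannwhitneyu(groups[i], groups[j], alternative="two-sided")
            pair_rows.append((cats[i], cats[j], float(mw.pvalue)))
    pairs = pd.DataFrame(pair_rows, columns=["cat_a", "cat_b", "p"])
    if len(pairs):
        pairs["fdr"] = stats.false_discovery_control(pairs["p"], method="bh")
    return summary, {"kruskal_p": float(kw.pvalue), "pairwise": pairs}
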