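"""TF-SE-target regulatory network with a prognostic gene screen.

Edges between a core TF t and a super-enhancer s with assigned target gene
g are weighted by the linkage score

    LS(s, t) = sum over constituent peaks p of R2(p, g) * MS(p, t)

where R2 is the squared peak-to-gene Pearson correlation and MS the TF's
motif score at the peak; edges with LS above a cutoff (default 10, on the
scale of log-odds-like motif scores) are kept. Target genes are screened by
univariate Cox proportional hazards on standardized expression, retaining
genes associated with poor survival (HR > 1, p < 0.05). The final network
is undirected: TF--SE edges weighted by LS, SE--gene edges weighted by the
SE-target correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .superenh import SuperEnhancer

logger = logging.getLogger(__name__)


@dataclass
class LinkageEdge:
    tf_id: str
    se_id: str
    ls: float
    contributing_peaks: list[tuple[str, float, float]] = field(default_factory=list)


def linkage_scores(ses: list[SuperEnhancer], pair_r: pd.DataFrame,
                   motif_scores: pd.DataFrame, core_tf_ids,
                   ls_cut: float = 10.0,
                   aggregates=None, peaks: pd.DataFrame | None = None,
                   genes: pd.DataFrame | None = None) -> list[LinkageEdge]:
    """Linkage-score edges between core TFs and target-bearing SEs.

    ``pair_r`` holds computed peak-gene correlations (``peak_id, gene_id,
    r``); a constituent peak without a computed r to the SE's target is
    recomputed from aggregate profiles when ``aggregates``/``peaks``/
    ``genes`` are supplied (the 250 kb candidate window may have excluded
    the pair), else contributes R2 = 0. SEs without a target gene yield no
    edges. Edges with ``ls > ls_cut`` are returned.
    """
    if (np.asarray(motif_scores.values) == motif_scores.values.astype(bool)).all():
        warnings.warn("motif scores look binary; the LS cutoff is scale-dependent")
    r_lookup = {(p, g): r for p, g, r in
                zip(pair_r["peak_id"], pair_r["gene_id"], pair_r["r"])}

    def recompute(peak_id: str, gene_id: str) -> float | None:
        if aggregates is None or peaks is None or genes is None:
            return None
        try:
            pi = list(peaks["peak_id"]).index(peak_id)
            gi = list(genes["gene_id"]).index(gene_id)
        except ValueError:
            return None
        a = aggregates.acc_profiles[:, pi]
        e = aggregates.expr_profiles[:, gi]
        if a.std() == 0 or e.std() == 0:
            return None
        return float(np.corrcoef(a, e)[0, 1])

    edges = []
    for se in ses:
        if not se.target_gene:
            logger.info("SE %s has no target gene; no TF edges", se.se_id)
            continue
        g = se.target_gene
        r2_ms = []
        for p in se.constituent_peaks:
            r = r_lookup.get((p, g))
            if r is None or not np.isfinite(r):
                r = recompute(p, g)
            r2 = float(r) ** 2 if r is not None and np.isfinite(r) else 0.0
            r2_ms.append((p, r2))
        for tf in core_tf_ids:
            if tf not in motif_scores.index:
                continue
            ms_row = motif_scores.loc[tf]
            contrib = [(p, r2, float(ms_row[p])) for p, r2 in r2_ms]
            ls = float(sum(r2 * ms for _, r2, ms in contrib))
            if ls > ls_cut:
                edges.append(LinkageEdge(str(tf), se.se_id, ls, contrib))
    return edges


# ---------------------------------------------------------------------------
# univariate Cox proportional hazards


def _cox_newton(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                tol: float = 1e-8, max_iter: int = 50) -> tuple[float, float] | None:
    """Newton maximization of the Breslow partial likelihood for one
    covariate. Returns (beta, se) or None if not converged."""
    order = np.argsort(-time, kind="stable")  # descending: risk set = prefix
    x = x[order]
    t = time[order]
    e = event[order].astype(bool)
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * x)
        s0 = np.cumsum(w)
        s1 = np.cumsum(w * x)
        s2 = np.cumsum(w * x * x)
        # Breslow: risk set of an event at time t_i is {j: t_j >= t_i};
        # with descending sort that is the prefix through the last tied index
        last_tied = np.searchsorted(-t, -t, side="right") - 1
        r0 = s0[last_tied][e]
        r1 = s1[last_tied][e]
        r2 = s2[last_tied][e]
        score = float(x[e].sum() - (r1 / r0).sum())
        info = float((r2 / r0 - (r1 / r0) ** 2).sum())
        if info <= 0:
            return None
        step = score / info
        beta += step
        if abs(step) < tol:
            return beta, 1.0 / np.sqrt(info)
    return None


def cox_screen(survival: pd.DataFrame, expr_by_subject: pd.DataFrame,
               genes=None, p_cut: float = 0.05) -> pd.DataFrame:
    """Univariate proportional-hazards screen per gene.

    Each gene's (log1p, standardized) expression enters a one-covariate Cox
    model (Breslow ties, Newton iterations to |step| < 1e-8); the Wald p and
    hazard ratio decide retention: ``kept`` iff HR > 1 and p < ``p_cut``.
    Genes with constant expression or non-converged fits are excluded with
    a warning. ``survival`` needs columns ``subject, time, event`` aligned
    with the rows of ``expr_by_subject``.
    """
    sv = survival.set_index("subject").loc[expr_by_subject.index]
    time = sv["time"].to_numpy(dtype=float)
    event = sv["event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise ValueError("Cox screen needs at least 2 events")
    if genes is None:
        genes = list(expr_by_subject.columns)
    rows = []
    for g in genes:
        if g not in expr_by_subject.columns:
            continue
        x = np.log1p(expr_by_subject[g].to_numpy(dtype=float))
        if np.ptp(x) == 0:
            warnings.warn(f"gene {g}: constant expression; excluded from Cox screen")
            continue
        x = (x - x.mean()) / x.std()
        fit = _cox_newton(x, time, event)
        if fit is None:
            warnings.warn(f"gene {g}: Cox fit did not converge; excluded")
            continue
        beta, se = fit
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
        hr = float(np.exp(beta))
        rows.append({"gene_id": g, "hr": hr, "beta": beta, "se": se,
                     "p": float(p), "kept": bool(hr > 1.0 and p < p_cut)})
    return pd.DataFrame(rows, columns=["gene_id", "hr", "beta", "se", "p", "kept"])


# ---------------------------------------------------------------------------
# network assembly


def build_network(core_tf_ids, ses: list[SuperEnhancer],
                  cox_results: pd.DataFrame,
                  tf_se_edges: list[LinkageEdge]) -> tuple[nx.Graph, dict]:
    """Assemble the undirected TF-SE-target network.

    Gene nodes are SE targets passing the Cox screen; SE nodes are their
    SEs; TF nodes are core TFs with at least one surviving linkage edge.
    SE--gene edges are weighted by the target correlation, TF--SE edges by
    LS. Pure function of its inputs. Returns the graph and a degree report
    identifying the maximum-connectivity TF.
    """
    kept_genes = set(cox_results.loc[cox_results["kept"], "gene_id"])
    if not kept_genes:
        warnings.warn("no genes survive the Cox screen; network is empty")
    G = nx.Graph()
    kept_ses = {}
    for se in ses:
        if se.target_gene and se.target_gene in kept_genes:
            kept_ses[se.se_id] = se
            G.add_node(se.se_id, kind="se")
            G.add_node(se.target_gene, kind="gene")
            G.add_edge(se.se_id, se.target_gene,
                       weight=float(se.target_r or 0.0), kind="se_gene")
    core = set(core_tf_ids)
    for e in tf_se_edges:
        if e.tf_id in core and e.se_id in kept_ses:
            G.add_node(e.tf_id, kind="tf")
            G.add_edge(e.tf_id, e.se_id, weight=e.ls, kind="tf_se")
    tf_deg = {n: d for n, d in G.degree() if G.nodes[n].get("kind") == "tf"}
    report = {
        "n_tf_nodes": sum(1 for _, a in G.nodes(data=True) if a["kind"] == "tf"),
        "n_se_nodes": sum(1 for _, a in G.nodes(data=True) if a["kind"] == "se"),
        "n_gene_nodes": sum(1 for _, a in G.nodes(data=True) if a["kind"] == "gene"),
        "n_edges": G.number_of_edges(),
        "max_degree_tf": max(tf_deg, key=tf_deg.get) if tf_deg else None,
    }
    return G, report


def edges_frame(G: nx.Graph) -> pd.DataFrame:
    rows = [{"source": u, "target": v, "kind": a["kind"], "weight": a["weight"]}
            for u, v, a in G.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "kind", "weight"])
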