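"""Stage orchestration: synth -> link -> tau -> markers -> se -> tf ->
network -> trajectory, communicating only through declared files in the run
directory, with a checksum manifest for reproducibility."""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, genome, linking, motifs, network, specificity, superenh, trajectory
from .config import PipelineConfig
from .io import (read_bed, read_json, read_matrix, read_tsv, write_bed,
                 write_json, write_matrix, write_tsv)
from .synth import (QCThresholds, SynthConfig, apply_qc, generate_dataset,
                    generate_survival_cohort)

logger = logging.getLogger(__name__)

STAGES = ("synth", "link", "tau", "markers", "se", "tf", "network", "trajectory")


def _dataset_paths(outdir: Path) -> dict[str, Path]:
    d = Path(outdir) / "dataset"
    return {k: d / v for k, v in {
        "dir": "", "peaks_bed": "peaks.bed", "peak_meta": "peak_meta.tsv",
        "genes": "genes.tsv", "cells": "cells.tsv", "acc": "acc",
        "expr": "expr", "motifs": "motifs", "regulons": "regulons.tsv",
        "truth": "ground_truth.json", "survival": "survival.tsv",
        "cohort_expr": "cohort_expr.tsv",
    }.items()}


def _load_dataset(outdir: Path):
    p = _dataset_paths(outdir)
    peaks = read_bed(p["peaks_bed"])[["chrom", "start", "end", "peak_id"]]
    meta = read_tsv(p["peak_meta"])
    peaks = peaks.merge(meta, on="peak_id")[["peak_id", "chrom", "start", "end", "gc"]]
    genes_df = read_tsv(p["genes"])
    cells = read_tsv(p["cells"], index_col=0)
    accX, acc_rows, acc_cols = read_matrix(p["acc"])
    exprX, _, expr_cols = read_matrix(p["expr"])
    peaks = peaks.set_index("peak_id", drop=False).loc[acc_cols].reset_index(drop=True)
    genes_df = genes_df.set_index("gene_id", drop=False).loc[expr_cols].reset_index(drop=True)
    cells = cells.loc[acc_rows]
    return peaks, genes_df, cells, accX, exprX


def _focal_type(cells: pd.DataFrame, pcfg: PipelineConfig) -> str:
    if pcfg.focal_type:
        return pcfg.focal_type
    return sorted(cells["cell_type"].unique())[-1]


def stage_synth(outdir: Path, scfg: SynthConfig,
                qc: QCThresholds = QCThresholds()) -> list[Path]:
    out = _dataset_paths(outdir)
    out["dir"].mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(scfg)
    expr, acc, cells, qc_report = apply_qc(ds.expr, ds.acc, ds.cells, qc)
    if qc_report["n_kept"] == 0:
        raise ValueError("QC removed every cell; check thresholds vs panel size")
    write_bed(ds.peaks, out["peaks_bed"])
    write_tsv(ds.peaks[["peak_id", "gc", "klass"]], out["peak_meta"])
    write_tsv(ds.genes, out["genes"])
    write_tsv(cells.reset_index(), out["cells"])
    write_json(qc_report, out["dir"] / "qc_report.json")
    write_matrix(acc.X, acc.obs_names, acc.var_names, out["acc"])
    write_matrix(expr.X, expr.obs_names, expr.var_names, out["expr"])
    write_matrix(ds.motif_scores.to_numpy(), ds.motif_scores.index,
                 ds.motif_scores.columns, out["motifs"])
    write_tsv(ds.regulons, out["regulons"])
    write_json(ds.truth.to_json_dict(), out["truth"])
    sig = pd.Series(np.asarray(ds.expr.X).mean(axis=0), index=ds.expr.var_names)
    surv, cohort_expr = generate_survival_cohort(
        scfg, sig, hazard_genes=ds.truth.planted_hazard_genes)
    write_tsv(surv, out["survival"])
    write_tsv(cohort_expr.reset_index(names="subject"), out["cohort_expr"])
    files = [out[k] for k in ("peaks_bed", "peak_meta", "genes", "cells",
                              "regulons", "truth", "survival", "cohort_expr")]
    files.append(out["dir"] / "qc_report.json")
    for prefix in (out["acc"], out["expr"], out["motifs"]):
        files += [Path(str(prefix) + s) for s in (".mtx", "_rows.tsv", "_cols.tsv")]
    return files


def stage_link(outdir: Path, pcfg: PipelineConfig) -> list[Path]:
    outdir = Path(outdir)
    peaks, genes_df, cells, accX, exprX = _load_dataset(outdir)
    annotations = genome.annotate_peaks(
        peaks, genes_df, (pcfg.promoter_upstream, pcfg.promoter_downstream))
    aggs = linking.make_aggregates(accX, exprX, cells["cell_type"],
                                   k_agg=pcfg.k_agg, n_agg=pcfg.n_agg,
                                   seed=pcfg.seed)
    pairs = linking.link_peaks_to_genes(aggs, peaks, genes_df,
                                        window_bp=pcfg.window_bp,
                                        cor_cutoff=pcfg.cor_cutoff,
                                        annotations=annotations,
                                        return_all=True)
    links = pairs[pairs["retained"]].drop(columns="retained")
    files = [outdir / "annotations.tsv", outdir / "links.tsv",
             outdir / "pairs_all.tsv", outdir / "links_per_gene.tsv"]
    write_tsv(annotations, files[0])
    write_tsv(links, files[1])
    write_tsv(pairs, files[2])
    counts, median = linking.links_per_gene(links)
    lpg = counts.reset_index(name="n_cres")
    lpg["median_overall"] = median
    write_tsv(lpg, files[3])
    return files


def stage_tau(outdir: Path, pcfg: PipelineConfig) -> list[Path]:
    outdir = Path(outdir)
    peaks, _, cells, accX, _ = _load_dataset(outdir)
    annotations = read_tsv(outdir / "annotations.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tau = specificity.tau_index(accX.T, cells["cell_type"],
                                    element_ids=peaks["peak_id"])
    summary, stats_d = specificity.tau_by_category(tau, annotations)
    files = [outdir / "tau.tsv", outdir / "tau_by_category.tsv",
             outdir / "tau_stats.json"]
    write_tsv(tau, files[0])
    write_tsv(summary, files[1])
    write_json({"kruskal_p": stats_d["kruskal_p"],
                "pairwise": stats_d["pairwise"].to_dict(orient="records")},
               files[2])
    return files


def stage_markers(outdir: Path, pcfg: PipelineConfig) -> list[Path]:
    outdir = Path(outdir)
    peaks, _, cells, accX, _ = _load_dataset(outdir)
    links = read_tsv(outdir / "links.tsv")
    markers = specificity.marker_peaks_all_types(
        accX, cells["cell_type"].to_numpy(), fdr_cut=pcfg.fdr,
        log2fc_cut=pcfg.log2fc, peak_ids=peaks["peak_id"], seed=pcfg.seed)
    specific, counts = specificity.celltype_specific_distal_cres(markers, links)
    files = [outdir / "markers.tsv", outdir / "specific_distal_cres.json",
             outdir / "specific_distal_cre_counts.tsv"]
    write_tsv(markers, files[0])
    write_json(specific, files[1])
    write_tsv(counts, files[2])
    return files


def stage_se(outdir: Path, pcfg: PipelineConfig) -> list[Path]:
    outdir = Path(outdir)
    peaks, genes_df, cells, accX, exprX = _load_dataset(outdir)
    annotations = read_tsv(outdir / "annotations.tsv")
    distal_ids = annotations.loc[annotations["category"] == "distal", "peak_id"]
    dmask = peaks["peak_id"].isin(set(distal_ids)).to_numpy()
    dpeaks = peaks[dmask].reset_index(drop=True)
    _, assign = superenh.build_accessons(accX[:, dmask], dpeaks["peak_id"],
                                         cells["cell_type"],
                                         n_accessons=pcfg.n_accessons,
                                         seed=pcfg.seed)
    ses = superenh.call_superenhancers(assign, dpeaks,
                                       super_range=pcfg.super_range,
                                       p_cutoff=pcfg.p_cutoff)
    focal = _focal_type(cells, pcfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        specific = superenh.se_specificity(ses, accX, peaks["peak_id"],
                                           cells["cell_type"], focal,
                                           tau_cut=pcfg.tau_cut,
                                           acc_cut=pcfg.acc_cut)
        superenh.assign_target_genes(specific, genes_df, exprX, accX,
                                     peaks["peak_id"], cells["cell_type"],
                                     focal, r_cut=pcfg.target_r_cut)
    all_df = superenh.ses_to_frame(ses)
    spec_df = superenh.ses_to_frame(specific)
    files = [outdir / "accessons.tsv", outdir / "ses_all.tsv",
             outdir / "ses_specific.tsv", outdir / "ses.bed"]
    write_tsv(assign.reset_index().set_axis(["peak_id", "accesson_id"], axis=1),
              files[0])
    write_tsv(all_df, files[1])
    write_tsv(spec_df, files[2])
    if len(spec_df):
        bed = spec_df.assign(score=(-np.log10(np.maximum(spec_df["fdr"], 1e-300))).round(3))
        write_bed(bed, files[3], name_col="se_id", score_col="score")
    else:
        files[3].write_text("")
    return files


def stage_tf(outdir: Path, pcfg: PipelineConfig) -> list[Path]:
    outdir = Path(outdir)
    peaks, genes_df, cells, accX, exprX = _load_dataset(outdir)
    p = _dataset_paths(outdir)
    MS, tf_ids, ms_cols = read_matrix(p["motifs"])
    motif_scores = pd.DataFrame(MS, index=tf_ids, columns=ms_cols)[peaks["peak_id"]]
    regulons = read_tsv(p["regulons"])
    focal = _focal_type(cells, pcfg)
    labels = cells["cell_type"].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        devs = motifs.motif_deviation_z(accX, motif_scores > 0,
                                        peaks["gc"].to_numpy(), labels,
                                        n_background=pcfg.n_background,
                                        seed=pcfg.seed)
    activity = motifs.regulon_activity(exprX, list(genes_df["gene_id"]), regulons)

    core_frames = []
    for t in sorted(cells["cell_type"].unique()):
        cset, ctab = motifs.chromatin_branch_tfs(
            devs, exprX, list(genes_df["gene_id"]), labels, t, r_cut=pcfg.tf_r_cut)
        aset, _ = motifs.activity_branch_tfs(activity, labels, t, fdr_cut=pcfg.fdr)
        core_frames.append(motifs.core_tfs(tf_ids, cset, aset, t))
    core = pd.concat(core_frames, ignore_index=True)

    ses_df = read_tsv(outdir / "ses_specific.tsv")
    se_peaks = [pid for cp in ses_df["constituent_peaks"].dropna()
                for pid in str(cp).split(",") if pid]
    if se_peaks:
        enr = motifs.se_motif_enrichment(motif_scores > 0, se_peaks, peaks,
                                         accX.mean(axis=0), fdr_cut=pcfg.fdr,
                                         seed=pcfg.seed)
    else:
        enr = pd.DataFrame(columns=["tf_id", "n_se_with_motif", "n_pop_with_motif",
                                    "n_se", "n_population", "p", "fdr", "enriched"])
    dev_z = pd.DataFrame({d.tf_id: d.z for d in devs}).T
    dev_z.columns = list(cells.index)
    files = [outdir / "core_tfs.tsv", outdir / "tf_deviation_type_means.tsv",
             outdir / "tf_deviation_z.tsv", outdir / "se_motif_enrichment.tsv"]
    write_tsv(core, files[0])
    write_tsv(motifs.deviations_frame(devs).reset_index(names="tf_id"), files[1])
    write_tsv(dev_z.reset_index(names="tf_id"), files[2])
    write_tsv(enr, files[3])
    return files


def stage_network(outdir: Path, pcfg: PipelineConfig) -> list[Path]:
    import networkx as nx

    outdir = Path(outdir)
    peaks, genes_df, cells, accX, exprX = _load_dataset(outdir)
    p = _dataset_paths(outdir)
    MS, tf_ids, ms_cols = read_matrix(p["motifs"])
    motif_scores = pd.DataFrame(MS, index=tf_ids, columns=ms_cols)[peaks["peak_id"]]
    focal = _focal_type(cells, pcfg)

    ses_df = read_tsv(outdir / "ses_specific.tsv")
    ses = _ses_from_frame(ses_df)
    pairs = read_tsv(outdir / "pairs_all.tsv")
    core = read_tsv(outdir / "core_tfs.tsv")
    core_ids = core.loc[(core["cell_type"] == focal) & core["is_core"], "tf_id"]
    edges = network.linkage_scores(ses, pairs, motif_scores, list(core_ids),
                                   ls_cut=pcfg.ls_cut)

    surv = read_tsv(p["survival"])
    cohort = read_tsv(p["cohort_expr"], index_col=0)
    target_genes = sorted({s.target_gene for s in ses if s.target_gene})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cox = network.cox_screen(surv, cohort, genes=target_genes, p_cut=pcfg.cox_p)
        G, report = network.build_network(list(core_ids), ses, cox, edges)

    files = [outdir / "cox.tsv", outdir / "network_edges.tsv",
             outdir / "network.graphml", outdir / "network_report.json"]
    write_tsv(cox, files[0])
    write_tsv(network.edges_frame(G), files[1])
    nx.write_graphml(G, files[2])
    write_json(report, files[3])
    return files


def stage_trajectory(outdir: Path, pcfg: PipelineConfig) -> list[Path]:
    outdir = Path(outdir)
    peaks, genes_df, cells, accX, exprX = _load_dataset(outdir)
    pt = cells["pseudotime"].to_numpy(dtype=float)
    on_traj = np.isfinite(pt)
    if on_traj.sum() < 2:
        raise ValueError("no cells carry pseudotime; trajectory stage needs it")
    dev_z = read_tsv(outdir / "tf_deviation_z.tsv", index_col=0)
    dev_z = dev_z[list(cells.index)]

    gene_ids = list(genes_df["gene_id"])
    tf_on_traj = [tf for tf in dev_z.index if tf in gene_ids]
    # expression binned on depth-normalized log values, like the deviations
    logE = linking._normalize_log(exprX)
    gprofiles = {p_.feature_id: p_ for p_ in trajectory.bin_trajectories(
        logE[on_traj][:, [gene_ids.index(t) for t in tf_on_traj]],
        pt[on_traj], tf_on_traj, "gene", n_bins=pcfg.n_bins)}
    mprofiles = {p_.feature_id: p_ for p_ in trajectory.bin_trajectories(
        dev_z.loc[tf_on_traj].to_numpy().T[on_traj], pt[on_traj],
        tf_on_traj, "motif", n_bins=pcfg.n_bins)}
    paired = trajectory.correlate_trajectories(
        mprofiles, gprofiles, [(t, t) for t in tf_on_traj], r_cut=0.5)
    prof_df = trajectory.profiles_frame(
        list(mprofiles.values()) + list(gprofiles.values()))
    files = [outdir / "trajectory_profiles.tsv", outdir / "trajectory_pairs.tsv"]
    write_tsv(prof_df.reset_index(), files[0])
    write_tsv(paired, files[1])
    return files


def _ses_from_frame(df: pd.DataFrame) -> list[superenh.SuperEnhancer]:
    ses = []
    for _, row in df.iterrows():
        tgt = row.get("target_gene")
        tgt = None if (pd.isna(tgt) or tgt == "") else str(tgt)
        tr = row.get("target_r")
        ses.append(superenh.SuperEnhancer(
            se_id=str(row["se_id"]),
            interval=genome.GenomicInterval(str(row["chrom"]),
                                            int(row["start"]), int(row["end"])),
            constituent_peaks=[x for x in str(row["constituent_peaks"]).split(",") if x],
            accesson_id=str(row["accesson_id"]),
            enrichment_p=float(row["enrichment_p"]), fdr=float(row["fdr"]),
            tau=float(row["tau"]) if pd.notna(row.get("tau")) else np.nan,
            target_gene=tgt,
            target_r=float(tr) if pd.notna(tr) else None))
    return ses


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(outdir: Path, pcfg: PipelineConfig, scfg: SynthConfig) -> dict:
    """Run all stages in dependency order and write a manifest recording the
    package version, seeds, config hash and per-file checksums. Identical
    config + seed reproduce identical checksums."""
    pcfg.validate()
    scfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    qc = QCThresholds(min_genes=pcfg.qc_min_genes, max_mito=pcfg.qc_max_mito,
                      min_fragments=pcfg.qc_min_fragments, min_tss=pcfg.qc_min_tss)
    stage_fns = {
        "synth": lambda: stage_synth(outdir, scfg, qc),
        "link": lambda: stage_link(outdir, pcfg),
        "tau": lambda: stage_tau(outdir, pcfg),
        "markers": lambda: stage_markers(outdir, pcfg),
        "se": lambda: stage_se(outdir, pcfg),
        "tf": lambda: stage_tf(outdir, pcfg),
        "network": lambda: stage_network(outdir, pcfg),
        "trajectory": lambda: stage_trajectory(outdir, pcfg),
    }
    manifest: dict = {
        "version": __version__,
        "seed": pcfg.seed,
        "synth_seed": scfg.seed,
        "config_hash": pcfg.hash(),
        "stages": {},
    }
    for name in STAGES:
        logger.info("running stage %s", name)
        files = stage_fns[name]()
        manifest["stages"][name] = {
            str(f.relative_to(outdir)): _sha256(f) for f in files}
        write_json(manifest, outdir / "manifest.json")
    return manifest
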