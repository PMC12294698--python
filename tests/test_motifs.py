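"""Motif deviations, regulon activity, core-TF consensus, SE enrichment."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from cretam.motifs import (activity_branch_tfs, chromatin_branch_tfs,
                           core_tfs, motif_deviation_z, regulon_activity,
                           se_motif_enrichment)


def exact_hypergeom_tail(k, M, n, N):
    """P(X >= k) for a hypergeometric by direct enumeration."""
    total = 0.0
    for j in range(k, min(n, N) + 1):
        total += math.comb(n, j) * math.comb(M - n, N - j) / math.comb(M, N)
    return total


@pytest.fixture(scope="module")
def dev_setup(ds):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        devs = motif_deviation_z(np.asarray(ds.acc.X), ds.motif_scores > 0,
                                 ds.peaks["gc"].to_numpy(),
                                 ds.cells["cell_type"].to_numpy(), seed=0)
    return devs


class TestMotifDeviation:
    def test_random_motif_has_near_zero_z(self, ds, rng):
        n_peaks = len(ds.peaks)
        row = np.zeros(n_peaks, dtype=bool)
        row[rng.choice(n_peaks, 80, replace=False)] = True
        mb = pd.DataFrame([row], index=["null_tf"], columns=ds.peaks["peak_id"])
        devs = motif_deviation_z(np.asarray(ds.acc.X), mb,
                                 ds.peaks["gc"].to_numpy(),
                                 ds.cells["cell_type"].to_numpy(), seed=1)
        assert abs(np.nanmean(devs[0].z)) < 0.2

    def test_planted_program_elevates_focal_type(self, ds, dev_setup):
        by_tf = {d.tf_id: d for d in dev_setup}
        for t, tfs in ds.truth.planted_core_tfs.items():
            for tf in tfs:
                mz = by_tf[tf].mean_z_per_type
                assert mz.idxmax() == t

    def test_depth_scaling_invariance(self, ds):
        X = np.asarray(ds.acc.X)[:, :400]
        mb = (ds.motif_scores.iloc[:3, :400] > 0)
        gc = ds.peaks["gc"].to_numpy()[:400]
        labels = ds.cells["cell_type"].to_numpy()
        d1 = motif_deviation_z(X, mb, gc, labels, n_background=20, seed=2)
        d2 = motif_deviation_z(X * 3, mb, gc, labels, n_background=20, seed=2)
        for a, b in zip(d1, d2):
            assert np.allclose(a.z, b.z, equal_nan=True)

    def test_sparse_motif_skipped_with_warning(self, ds):
        row = np.zeros(len(ds.peaks), dtype=bool)
        row[:3] = True
        mb = pd.DataFrame([row], index=["tiny"], columns=ds.peaks["peak_id"])
        with pytest.warns(UserWarning, match="skipped"):
            out = motif_deviation_z(np.asarray(ds.acc.X), mb,
                                    ds.peaks["gc"].to_numpy(),
                                    ds.cells["cell_type"].to_numpy())
        assert out == []


class TestChromatinBranch:
    def test_exact_cutoff_is_excluded(self, ds, dev_setup):
        """The expression-correlation gate is strictly greater-than."""
        gene_ids = list(ds.genes["gene_id"])
        E = np.asarray(ds.expr.X)
        labels = ds.cells["cell_type"].to_numpy()
        chosen, tab = chromatin_branch_tfs(dev_setup, E, gene_ids, labels, "type0")
        tab = tab.set_index("tf_id")
        for tf in list(chosen):
            r = tab.loc[tf, "expr_corr"]
            at_cut, _ = chromatin_branch_tfs(dev_setup, E, gene_ids, labels,
                                             "type0", r_cut=r)
            assert tf not in at_cut

    def test_anticorrelated_repressor_excluded(self, ds, dev_setup):
        gene_ids = list(ds.genes["gene_id"])
        E = np.asarray(ds.expr.X)
        labels = ds.cells["cell_type"].to_numpy()
        _, tab = chromatin_branch_tfs(dev_setup, E, gene_ids, labels, "type0")
        neg = tab.loc[tab["expr_corr"] < 0, "tf_id"]
        chosen, _ = chromatin_branch_tfs(dev_setup, E, gene_ids, labels, "type0")
        assert not set(neg) & chosen

    def test_planted_core_tf_included(self, ds, dev_setup):
        gene_ids = list(ds.genes["gene_id"])
        E = np.asarray(ds.expr.X)
        labels = ds.cells["cell_type"].to_numpy()
        for t, tfs in ds.truth.planted_core_tfs.items():
            chosen, _ = chromatin_branch_tfs(dev_setup, E, gene_ids, labels, t)
            assert set(tfs) <= chosen


class TestRegulonActivity:
    def test_single_up_target_equals_zscored_expression(self, rng):
        E = rng.poisson(5.0, size=(40, 6)).astype(float)
        regulons = pd.DataFrame({"tf": ["t"] * 5, "target": [f"g{i}" for i in range(5)],
                                 "mode": ["+"] * 5})
        act = regulon_activity(E, [f"g{i}" for i in range(6)], regulons)
        depth = E.sum(axis=1, keepdims=True)
        L = np.log1p(E / depth * 1e4)
        Z = (L - L.mean(0)) / L.std(0)
        assert np.allclose(act.loc["t"], Z[:, :5].mean(axis=1))

    def test_sign_flip_negates_activity(self, rng):
        E = rng.poisson(5.0, size=(40, 8)).astype(float)
        genes = [f"g{i}" for i in range(8)]
        reg = pd.DataFrame({"tf": "t", "target": genes[:6], "mode": "+"})
        flipped = reg.assign(mode="-")
        a1 = regulon_activity(E, genes, reg)
        a2 = regulon_activity(E, genes, flipped)
        assert np.allclose(a1.loc["t"], -a2.loc["t"])

    def test_small_regulon_skipped(self, rng):
        E = rng.poisson(5.0, size=(20, 4)).astype(float)
        reg = pd.DataFrame({"tf": "t", "target": ["g0", "g1"], "mode": "+"})
        act = regulon_activity(E, [f"g{i}" for i in range(4)], reg)
        assert "t" not in act.index

    def test_planted_regulons_flagged_active(self, ds):
        act = regulon_activity(np.asarray(ds.expr.X), list(ds.genes["gene_id"]),
                               ds.regulons)
        labels = ds.cells["cell_type"].to_numpy()
        for t, tfs in ds.truth.planted_core_tfs.items():
            active, _ = activity_branch_tfs(act, labels, t)
            assert set(tfs) <= active


class TestCoreTfs:
    def test_intersection_rule(self):
        calls = core_tfs(["t1", "t2", "t3"], {"t1", "t2"}, {"t2", "t3"}, "a")
        by = calls.set_index("tf_id")
        assert not by.loc["t1", "is_core"]
        assert by.loc["t2", "is_core"]
        assert not by.loc["t3", "is_core"]

    def test_empty_intersection_is_not_an_error(self):
        calls = core_tfs(["t1"], {"t1"}, set(), "a")
        assert not calls["is_core"].any()


class TestSEMotifEnrichment:
    def _frame(self, rng, n_peaks=600):
        peaks = pd.DataFrame({"peak_id": [f"p{i}" for i in range(n_peaks)],
                              "gc": rng.uniform(0.3, 0.7, n_peaks)})
        mean_acc = rng.gamma(2.0, 1.0, n_peaks)
        return peaks, mean_acc

    def test_matches_exact_enumeration(self, rng):
        """Unmatched-background tail equals direct enumeration."""
        peaks, mean_acc = self._frame(rng)
        present = rng.random(600) < 0.05
        present[:10] = True  # 10 of the 12 SE peaks carry the motif
        present[10:12] = False
        mb = pd.DataFrame([present], index=["tf"], columns=peaks["peak_id"])
        se_ids = [f"p{i}" for i in range(12)]
        out = se_motif_enrichment(mb, se_ids, peaks, mean_acc, bgd_matched=False)
        M, n, N, k = 600, int(present.sum()), 12, 10
        assert out["p"].iloc[0] == pytest.approx(exact_hypergeom_tail(k, M, n, N),
                                                 rel=1e-12)

    def test_saturated_motif_is_not_enriched(self, rng):
        peaks, mean_acc = self._frame(rng, 100)
        mb = pd.DataFrame([np.ones(100, bool)], index=["tf"], columns=peaks["peak_id"])
        out = se_motif_enrichment(mb, [f"p{i}" for i in range(8)], peaks,
                                  mean_acc, bgd_matched=False)
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert not out["enriched"].iloc[0]

    def test_bh_never_flags_more_than_nominal(self, rng):
        peaks, mean_acc = self._frame(rng)
        mb = pd.DataFrame(rng.random((15, 600)) < 0.1,
                          index=[f"tf{i}" for i in range(15)],
                          columns=peaks["peak_id"])
        se_ids = [f"p{i}" for i in rng.choice(600, 20, replace=False)]
        out = se_motif_enrichment(mb, se_ids, peaks, mean_acc, seed=3)
        assert (out["fdr"] < 0.05).sum() <= (out["p"] < 0.05).sum()

    def test_permuted_assignment_flags_nothing(self, ds, rng):
        mb = ds.motif_scores > 0
        peaks = ds.peaks
        mean_acc = np.asarray(ds.acc.X).mean(axis=0)
        flagged = total = 0
        for rep in range(5):
            se_ids = list(rng.choice(peaks["peak_id"], 24, replace=False))
            out = se_motif_enrichment(mb, se_ids, peaks, mean_acc, seed=rep)
            flagged += int(out["enriched"].sum())
            total += len(out)
        assert flagged / total <= 0.01
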