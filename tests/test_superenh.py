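"""Accesson clustering, SE window enrichment, specificity, target genes."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from cretam.superenh import (SuperEnhancer, assign_target_genes,
                             build_accessons, call_superenhancers,
                             se_specificity)
from cretam.genome import GenomicInterval


def exact_binom_tail(k, n, p):
    """P(X >= k) by direct enumeration (oracle for n <= 30)."""
    return sum(math.comb(n, j) * p**j * (1 - p)**(n - j) for j in range(k, n + 1))


def _peaks(positions, chrom="chr1"):
    return pd.DataFrame({
        "peak_id": [f"p{i}" for i in range(len(positions))],
        "chrom": chrom, "start": positions,
        "end": np.asarray(positions) + 500,
    })


class TestAccessons:
    def test_planted_constituents_coassigned(self, ds):
        klass = ds.peaks["klass"].to_numpy()
        distal = ds.peaks[klass == "distal"].reset_index(drop=True)
        X = np.asarray(ds.acc.X)[:, klass == "distal"]
        _, assign = build_accessons(X, distal["peak_id"], ds.cells["cell_type"],
                                    n_accessons=10, seed=0)
        for se in ds.truth.planted_SEs:
            labels = assign.loc[se["peak_ids"]]
            assert labels.nunique() == 1

    def test_duplicate_profiles_identical_assignment(self, rng):
        X = rng.poisson(1.0, size=(50, 20)).astype(float)
        X[:, 5] = X[:, 3]  # duplicate column
        _, assign = build_accessons(X, [f"p{i}" for i in range(20)],
                                    np.array(["a", "b"] * 25), n_accessons=3, seed=1)
        assert assign.iloc[5] == assign.iloc[3]

    def test_too_few_accessons_rejected(self, rng):
        with pytest.raises(ValueError):
            build_accessons(rng.poisson(1, (10, 5)).astype(float),
                            list("abcde"), ["a"] * 10, n_accessons=1)


class TestCallSuperenhancers:
    def test_binomial_tail_matches_enumeration(self):
        from scipy import stats
        for k, n, p in [(3, 8, 0.1), (6, 12, 0.05), (5, 30, 0.2), (1, 1, 0.5)]:
            assert stats.binom.sf(k - 1, n, p) == pytest.approx(
                exact_binom_tail(k, n, p), rel=1e-12)

    def test_dense_cluster_called(self):
        """6 same-accesson peaks within 200 kb against a 1% genome-wide
        share produce a far-below-cutoff binomial tail and an SE."""
        cluster = [1_000_000 + i * 30_000 for i in range(6)]
        scatter = list(range(2_000_000, 2_000_000 + 594 * 100_000, 100_000))
        peaks = _peaks(cluster + scatter)
        assign = pd.Series(["accA"] * 6 + ["accB"] * len(scatter),
                           index=peaks["peak_id"])
        ses = call_superenhancers(assign, peaks)
        assert len(ses) == 1
        se = ses[0]
        assert set(se.constituent_peaks) == {f"p{i}" for i in range(6)}
        share = 6 / len(peaks)
        assert se.enrichment_p <= exact_binom_tail(6, 6, share) + 1e-12
        assert se.enrichment_p < 1e-6

    def test_uniform_scatter_yields_none(self):
        positions = list(range(0, 50 * 10_000_000, 10_000_000))  # 1 per 10 Mb
        peaks = _peaks(positions, chrom="chr1")
        assign = pd.Series(["accA"] * len(positions), index=peaks["peak_id"])
        assert call_superenhancers(assign, peaks) == []

    def test_distant_clusters_not_merged(self):
        c1 = [1_000_000 + i * 20_000 for i in range(6)]
        c2 = [3_500_000 + i * 20_000 for i in range(6)]  # 2 Mb away
        scatter = list(range(10_000_000, 10_000_000 + 600 * 50_000, 50_000))
        peaks = _peaks(c1 + c2 + scatter)
        assign = pd.Series(["accA"] * 12 + ["accB"] * len(scatter),
                           index=peaks["peak_id"])
        ses = call_superenhancers(assign, peaks)
        assert len(ses) == 2
        spans = sorted((s.interval.start, s.interval.end) for s in ses)
        assert spans[0][1] <= 3_500_000 <= spans[1][0]
        for s in ses:
            assert s.interval.length <= 500_000
            assert len(s.constituent_peaks) >= 3


class TestSpecificityAndTargets:
    def _one_type_se(self):
        labels = np.repeat(["a", "b", "c"], 20)
        X = np.zeros((60, 4))
        X[labels == "b", :3] = 5.0  # SE constituents open only in b
        X[:, 3] = 1.0               # unrelated flat peak
        se = SuperEnhancer("se0", GenomicInterval("chr1", 1000, 40_000),
                           ["p0", "p1", "p2"], "accA", 1e-8, 1e-6)
        return labels, X, ["p0", "p1", "p2", "p3"], se

    def test_one_type_se_retained_uniform_rejected(self):
        labels, X, pids, se = self._one_type_se()
        kept = se_specificity([se], X, pids, labels, focal_type="b")
        assert kept == [se] and se.tau == pytest.approx(1.0)
        assert se.per_type_norm_acc["b"] == pytest.approx(1.0)

        uniform = SuperEnhancer("se1", GenomicInterval("chr1", 1000, 40_000),
                                ["p3"], "accB", 1e-8, 1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert se_specificity([uniform], X, pids, labels, "b") == []

    def test_threshold_sweep_matches_brute_filter(self, ds):
        from cretam.specificity import tau_index
        from cretam.superenh import se_accessibility
        labels = ds.cells["cell_type"].to_numpy()
        pids = list(ds.peaks["peak_id"])
        ses = [SuperEnhancer(f"se{i}", GenomicInterval(se["chrom"], se["start"], se["end"]),
                             se["peak_ids"], "acc", 1e-8, 1e-6)
               for i, se in enumerate(ds.truth.planted_SEs)]
        X = np.asarray(ds.acc.X)
        for tau_cut in (0.3, 0.7, 0.95):
            kept = se_specificity([SuperEnhancer(s.se_id, s.interval,
                                                 s.constituent_peaks, "acc", 1e-8, 1e-6)
                                   for s in ses], X, pids, labels, "type1",
                                  tau_cut=tau_cut, acc_cut=0.5)
            tab = tau_index(se_accessibility(ses, X, pids), labels,
                            [s.se_id for s in ses])
            want = set(tab.loc[(tab["tau"] > tau_cut) & (tab["P_type1"] > 0.5),
                               "element_id"])
            assert {s.se_id for s in kept} == want

    def test_unknown_focal_type_rejected(self):
        labels, X, pids, se = self._one_type_se()
        with pytest.raises(ValueError, match="unknown focal type"):
            se_specificity([se], X, pids, labels, "zz")

    def test_planted_targets_recovered(self, ds):
        labels = ds.cells["cell_type"].to_numpy()
        pids = list(ds.peaks["peak_id"])
        X = np.asarray(ds.acc.X)
        E = np.asarray(ds.expr.X)
        for truth_se in ds.truth.planted_SEs:
            se = SuperEnhancer("se", GenomicInterval(truth_se["chrom"],
                                                     truth_se["start"], truth_se["end"]),
                               truth_se["peak_ids"], "acc", 1e-8, 1e-6)
            assign_target_genes([se], ds.genes, E, X, pids, labels,
                                truth_se["focal_type"])
            assert se.target_gene == truth_se["target_gene"]
            assert se.target_r > 0.3

    def test_median_expression_gate_blocks_low_genes(self):
        labels = np.repeat(["a", "b"], 30)
        X = np.zeros((60, 2))
        X[labels == "b"] = np.linspace(1, 5, 60).reshape(-1, 1)[labels == "b"]
        E = np.zeros((60, 1))
        E[labels == "a", 0] = 10.0  # expressed in the other type only
        E[labels == "b", 0] = X[labels == "b", 0]  # correlated but low
        genes = pd.DataFrame({"gene_id": ["g0"], "chrom": ["chr1"], "strand": ["+"],
                              "start": [50_000], "end": [60_000]})
        se = SuperEnhancer("se", GenomicInterval("chr1", 1000, 30_000),
                           ["p0", "p1"], "acc", 1e-8, 1e-6)
        assign_target_genes([se], genes, E, X, ["p0", "p1"], labels, "b")
        assert se.target_gene is None

    def test_equidistant_tie_broken_by_lower_coordinate(self, rng):
        labels = np.repeat(["a", "b"], 30)
        acc = rng.poisson(3.0, size=(60, 2)).astype(float)
        expr = acc.sum(axis=1, keepdims=True) + rng.normal(0, 0.1, (60, 1))
        E = np.hstack([expr, expr])
        # SE spans [10000, 20000); both TSSs 5000 bp from an edge
        genes = pd.DataFrame({"gene_id": ["gR", "gL"], "chrom": "chr1",
                              "strand": "+", "start": [24_999, 5_000],
                              "end": [44_999, 25_000]})
        se = SuperEnhancer("se", GenomicInterval("chr1", 10_000, 20_000),
                           ["p0", "p1"], "acc", 1e-8, 1e-6)
        assign_target_genes([se], genes, E, acc, ["p0", "p1"], labels, "b")
        assert se.target_gene == "gL"  # lower start coordinate wins the tie

    def test_no_gene_on_chromosome_gives_null_target(self):
        labels = np.repeat(["a", "b"], 30)
        X = np.ones((60, 1))
        genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["chr9"], "strand": ["+"],
                              "start": [0], "end": [100]})
        se = SuperEnhancer("se", GenomicInterval("chr1", 0, 10_000),
                           ["p0"], "acc", 1e-8, 1e-6)
        assign_target_genes([se], genes, np.ones((60, 1)), X, ["p0"], labels, "a")
        assert se.target_gene is None
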