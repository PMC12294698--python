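"""Linkage scores, univariate Cox screen, network assembly."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cretam.genome import GenomicInterval
from cretam.network import (LinkageEdge, _cox_newton, build_network,
                            cox_screen, edges_frame, linkage_scores)
from cretam.superenh import SuperEnhancer


def _se(se_id="se0", peaks=("p0", "p1"), target="g0", chrom="chr1"):
    return SuperEnhancer(se_id, GenomicInterval(chrom, 1000, 50_000),
                         list(peaks), "accA", 1e-8, 1e-6,
                         target_gene=target, target_r=0.6)


class TestLinkageScores:
    def test_worked_example(self):
        """R2 = 0.25 at MS 20 plus R2 = 0.16 at MS 30 gives LS = 9.8,
        below the default cutoff of 10."""
        se = _se()
        pair_r = pd.DataFrame({"peak_id": ["p0", "p1"], "gene_id": ["g0", "g0"],
                               "r": [0.5, 0.4]})
        ms = pd.DataFrame([[20.0, 30.0]], index=["tf"], columns=["p0", "p1"])
        edges = linkage_scores([se], pair_r, ms, ["tf"], ls_cut=0.0)
        assert len(edges) == 1
        assert edges[0].ls == pytest.approx(0.25 * 20 + 0.16 * 30) == pytest.approx(9.8)
        assert linkage_scores([se], pair_r, ms, ["tf"], ls_cut=10.0) == []

    def test_matches_brute_force_double_loop(self, rng):
        n_peaks, n_tfs = 6, 4
        pids = [f"p{i}" for i in range(n_peaks)]
        tfs = [f"tf{i}" for i in range(n_tfs)]
        se = _se(peaks=pids)
        rs = rng.uniform(-1, 1, n_peaks)
        pair_r = pd.DataFrame({"peak_id": pids, "gene_id": "g0", "r": rs})
        ms = pd.DataFrame(rng.uniform(0, 20, (n_tfs, n_peaks)), index=tfs,
                          columns=pids)
        edges = {e.tf_id: e.ls for e in linkage_scores([se], pair_r, ms, tfs,
                                                       ls_cut=-1.0)}
        for ti, tf in enumerate(tfs):
            want = sum(rs[pi] ** 2 * ms.iloc[ti, pi] for pi in range(n_peaks))
            assert edges[tf] == pytest.approx(want, rel=1e-12)

    def test_zero_motif_scores_give_zero_ls(self):
        se = _se()
        pair_r = pd.DataFrame({"peak_id": ["p0", "p1"], "gene_id": "g0",
                               "r": [0.9, 0.9]})
        ms = pd.DataFrame([[0.0, 0.0]], index=["tf"], columns=["p0", "p1"])
        edges = linkage_scores([se], pair_r, ms, ["tf"], ls_cut=-1.0)
        assert edges[0].ls == 0.0

    def test_removing_a_peak_never_increases_ls(self, rng):
        pids = [f"p{i}" for i in range(5)]
        pair_r = pd.DataFrame({"peak_id": pids, "gene_id": "g0",
                               "r": rng.uniform(0, 1, 5)})
        ms = pd.DataFrame([rng.uniform(0, 10, 5)], index=["tf"], columns=pids)
        full = linkage_scores([_se(peaks=pids)], pair_r, ms, ["tf"], ls_cut=-1)[0].ls
        part = linkage_scores([_se(peaks=pids[:4])], pair_r, ms, ["tf"], ls_cut=-1)[0].ls
        assert part <= full + 1e-12

    def test_se_without_target_yields_no_edges(self):
        se = _se(target=None)
        ms = pd.DataFrame([[5.0, 5.0]], index=["tf"], columns=["p0", "p1"])
        assert linkage_scores([se], pd.DataFrame(columns=["peak_id", "gene_id", "r"]),
                              ms, ["tf"]) == []

    def test_binary_motif_scores_warn(self):
        se = _se()
        pair_r = pd.DataFrame({"peak_id": ["p0"], "gene_id": ["g0"], "r": [0.5]})
        ms = pd.DataFrame([[1.0, 0.0]], index=["tf"], columns=["p0", "p1"])
        with pytest.warns(UserWarning, match="binary"):
            linkage_scores([se], pair_r, ms, ["tf"])


def _cohort(rng, n=150, beta=0.8):
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
    c = rng.exponential(12.0, n)
    return x, np.minimum(t, c), (t <= c).astype(int)


class TestCoxScreen:
    def test_newton_matches_grid_golden_section_oracle(self, rng):
        """Direct maximization of the Breslow partial log-likelihood on a
        10-subject fixture agrees with the Newton fit."""
        x, time_, event = _cohort(rng, n=10)

        def breslow_loglik(beta):
            ll = 0.0
            for i in np.flatnonzero(event):
                risk = time_ >= time_[i]
                ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
            return ll

        grid = np.linspace(-4, 4, 2001)
        b0 = grid[np.argmax([breslow_loglik(b) for b in grid])]
        lo, hi = b0 - 0.01, b0 + 0.01
        phi = (np.sqrt(5) - 1) / 2
        for _ in range(60):  # golden-section refinement
            m1 = hi - phi * (hi - lo)
            m2 = lo + phi * (hi - lo)
            if breslow_loglik(m1) < breslow_loglik(m2):
                lo = m1
            else:
                hi = m2
        beta_oracle = (lo + hi) / 2
        beta, _ = _cox_newton(x, time_, event)
        assert beta == pytest.approx(beta_oracle, abs=1e-6)

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        x, time_, event = _cohort(rng, n=200)
        beta, se = _cox_newton(x, time_, event)
        cph = lifelines.CoxPHFitter()
        cph.fit(pd.DataFrame({"x": x, "T": time_, "E": event}),
                duration_col="T", event_col="E")
        assert beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
        assert se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)

    def test_keeps_only_hazardous_significant_genes(self, rng):
        n = 400
        x_bad, time_, event = _cohort(rng, n=n, beta=0.9)
        surv = pd.DataFrame({"subject": [f"s{i}" for i in range(n)],
                             "time": time_, "event": event})
        expr = pd.DataFrame({
            "bad": np.expm1(x_bad - x_bad.min() + 0.1),
            "noise": rng.uniform(1, 5, n),
        }, index=surv["subject"])
        res = cox_screen(surv, expr).set_index("gene_id")
        assert res.loc["bad", "kept"]
        assert res.loc["bad", "hr"] > 1
        assert not res.loc["noise", "kept"]

    def test_constant_gene_excluded_with_warning(self, rng):
        x, time_, event = _cohort(rng, n=60)
        surv = pd.DataFrame({"subject": [f"s{i}" for i in range(60)],
                             "time": time_, "event": event})
        expr = pd.DataFrame({"flat": np.ones(60)}, index=surv["subject"])
        with pytest.warns(UserWarning, match="constant"):
            res = cox_screen(surv, expr)
        assert len(res) == 0

    def test_no_events_rejected(self):
        surv = pd.DataFrame({"subject": ["s0", "s1"], "time": [1.0, 2.0],
                             "event": [0, 0]})
        expr = pd.DataFrame({"g": [1.0, 2.0]}, index=surv["subject"])
        with pytest.raises(ValueError, match="events"):
            cox_screen(surv, expr)


class TestBuildNetwork:
    def _inputs(self):
        ses = [_se("se0", target="gKept"), _se("se1", target="gDropped")]
        cox = pd.DataFrame({"gene_id": ["gKept", "gDropped"],
                            "hr": [2.0, 2.0], "p": [0.01, 0.5],
                            "kept": [True, False]})
        edges = [LinkageEdge("tfA", "se0", 15.0), LinkageEdge("tfA", "se1", 20.0),
                 LinkageEdge("tfB", "se0", 12.0)]
        return ses, cox, edges

    def test_failed_cox_target_prunes_se_and_edges(self):
        ses, cox, edges = self._inputs()
        G, report = build_network(["tfA", "tfB"], ses, cox, edges)
        assert "se1" not in G and "gDropped" not in G
        assert report["n_se_nodes"] == 1 and report["n_gene_nodes"] == 1
        # surviving edges: se0-gKept, tfA-se0, tfB-se0
        assert report["n_edges"] == 3

    def test_edge_bookkeeping_and_determinism(self):
        ses, cox, edges = self._inputs()
        G1, _ = build_network(["tfA", "tfB"], ses, cox, edges)
        G2, _ = build_network(["tfA", "tfB"], ses, cox, edges)
        f1, f2 = edges_frame(G1), edges_frame(G2)
        assert f1.equals(f2)
        kept_tf_se = [e for e in edges if e.se_id == "se0"]
        assert len(f1) == len(kept_tf_se) + 1  # + the se-gene edge

    def test_hub_tf_has_max_degree(self):
        ses = [_se(f"se{i}", target=f"g{i}") for i in range(3)]
        cox = pd.DataFrame({"gene_id": [f"g{i}" for i in range(3)],
                            "hr": 2.0, "p": 0.01, "kept": True})
        edges = [LinkageEdge("hub", f"se{i}", 20.0) for i in range(3)]
        edges.append(LinkageEdge("minor", "se0", 11.0))
        _, report = build_network(["hub", "minor"], ses, cox, edges)
        assert report["max_degree_tf"] == "hub"

    def test_empty_gene_set_warns_and_is_empty(self):
        ses, cox, edges = self._inputs()
        cox["kept"] = False
        with pytest.warns(UserWarning, match="no genes"):
            G, report = build_network(["tfA"], ses, cox, edges)
        assert G.number_of_nodes() == 0 and report["max_degree_tf"] is None
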