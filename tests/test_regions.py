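"""DMR statistics, candidate construction and co-methylation windows."""

import numpy as np
import pandas as pd
import pytest

import xwaskit as xk
from xwaskit.regions import comethylation, dmr_stat, find_candidates
from xwaskit.types import ProbeManifest, ValidationError


def _manifest(positions, probes=None, chrom="X"):
    probes = probes or [f"p{i}" for i in range(len(positions))]
    tab = pd.DataFrame({"chromosome": chrom, "position": positions,
                        "design_type": "II"},
                       index=pd.Index(probes, name="probe_id"))
    return ProbeManifest(tab)


def _results(probes, effects, p_adj):
    return pd.DataFrame({"probe_id": probes, "effect": effects,
                         "se": [0.1] * len(probes), "p_adj": p_adj})


class TestDmrStat:
    def test_single_member_reduces_to_input(self):
        B, se_B, z, p = dmr_stat([0.3], [0.1], np.eye(1))
        assert B == pytest.approx(0.3, abs=1e-15)
        assert se_B == pytest.approx(0.1, abs=1e-15)
        assert z == pytest.approx(3.0)

    def test_independent_members_match_meta_analysis(self):
        B, se_B, z, p = dmr_stat([0.2, 0.4], [0.1, 0.1], np.eye(2))
        assert B == pytest.approx(0.3)
        assert se_B == pytest.approx(0.1 / np.sqrt(2), abs=1e-12)
        assert z == pytest.approx(np.sqrt(2) * 3, abs=1e-9)

    def test_perfect_correlation_gives_no_precision_gain(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        B, se_B, z, p = dmr_stat([0.3, 0.3], [0.1, 0.1], R)
        assert B == pytest.approx(0.3)
        assert se_B == pytest.approx(0.1, abs=1e-12)
        assert z == pytest.approx(3.0)

    def test_identity_correlation_equals_closed_form_oracle(self):
        """Against the classical fixed-effect meta-analysis closed form,
        1000 random instances, agreement to 1e-10."""
        rng = np.random.default_rng(5)
        for _ in range(1000):
            k = rng.integers(1, 8)
            b = rng.normal(size=k)
            se = rng.uniform(0.05, 1.0, size=k)
            B, se_B, z, p = dmr_stat(b, se, np.eye(k))
            w = 1.0 / se ** 2
            assert B == pytest.approx(float(np.sum(w * b) / np.sum(w)),
                                      abs=1e-10)
            assert se_B == pytest.approx(float(np.sqrt(1.0 / np.sum(w))),
                                         abs=1e-10)

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(6)
        b = rng.normal(size=5)
        se = rng.uniform(0.05, 0.5, size=5)
        A = rng.normal(size=(5, 5))
        R = np.corrcoef(A @ A.T + 5 * np.eye(5))
        ref = dmr_stat(b, se, R)
        perm = rng.permutation(5)
        out = dmr_stat(b[perm], se[perm], R[np.ix_(perm, perm)])
        np.testing.assert_allclose(out, ref, rtol=1e-12)

    def test_equicorrelated_limit_approaches_member_se(self):
        se = np.full(4, 0.1)
        b = np.full(4, 0.2)
        for rho, expect_gain in [(0.999, False), (0.0, True)]:
            R = np.full((4, 4), rho)
            np.fill_diagonal(R, 1.0)
            _, se_B, _, _ = dmr_stat(b, se, R)
            if expect_gain:
                assert se_B < 0.06
            else:
                assert se_B == pytest.approx(0.1, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            dmr_stat([0.1], [0.0], np.eye(1))
        with pytest.raises(ValidationError):
            dmr_stat([0.1, 0.2], [0.1, 0.1], -np.eye(2))


class TestFindCandidates:
    def test_gap_rule_splits_runs(self):
        man = _manifest([100, 400, 2000])
        res = _results(["p0", "p1", "p2"], [0.3, 0.3, 0.3], [0.01, 0.01, 0.01])
        cands = find_candidates(res, man, maxgap_bp=500)
        assert cands == [["p0", "p1"], ["p2"]]

    def test_sign_flip_splits_runs(self):
        man = _manifest([100, 300, 500])
        res = _results(["p0", "p1", "p2"], [0.3, -0.3, -0.3],
                       [0.01, 0.01, 0.01])
        cands = find_candidates(res, man, maxgap_bp=500)
        assert cands == [["p0"], ["p1", "p2"]]

    def test_nothing_passes_empty(self):
        man = _manifest([100, 300])
        res = _results(["p0", "p1"], [0.3, 0.3], [0.5, 0.9])
        assert find_candidates(res, man) == []


class TestCallDmrs:
    def test_two_cpg_candidate_never_significant(self):
        rng = np.random.default_rng(2)
        man = _manifest([100, 300])
        m = pd.DataFrame(rng.normal(size=(2, 50)), index=["p0", "p1"],
                         columns=[f"s{i}" for i in range(50)])
        res = _results(["p0", "p1"], [2.0, 2.0], [1e-30, 1e-30])
        dmrs = xk.call_dmrs(res, m, man, list(m.columns))
        assert len(dmrs) == 1
        assert dmrs[0].p < 1e-10 and not dmrs[0].significant

    def test_subregion_scan_trims_to_signal_core(self):
        """With one diluting null member appended to a strong run, the
        sub-region scan recovers the strong core; the Bonferroni factor
        makes the full-run p a bound on the scanned p."""
        rng = np.random.default_rng(7)
        man = _manifest([100, 300, 500, 700])
        probes = ["p0", "p1", "p2", "p3"]
        m = pd.DataFrame(rng.normal(size=(4, 60)), index=probes,
                         columns=[f"s{i}" for i in range(60)])
        res = pd.DataFrame({"probe_id": probes,
                            "effect": [0.5, 0.5, 0.5, 0.01],
                            "se": [0.05, 0.05, 0.05, 0.05],
                            "p_adj": [1e-8, 1e-8, 1e-8, 0.04]})
        plain = xk.call_dmrs(res, m, man, list(m.columns),
                             scan_subregions=False)
        scanned = xk.call_dmrs(res, m, man, list(m.columns),
                               scan_subregions=True)
        assert plain[0].n_cpgs == 4
        assert scanned[0].member_probe_ids == ["p0", "p1", "p2"]
        assert scanned[0].p <= plain[0].p * 10  # 10 sub-runs scanned

    def test_spans_and_gaps_respect_candidate_rule(self, dmr_recovery_run):
        out = dmr_recovery_run["result"]
        for d in out.dmrs:
            assert d.start <= d.end
            assert d.n_cpgs == len(d.member_probe_ids)

    def test_null_data_rarely_yields_significant_dmrs(self):
        """On pure-null data the mean number of significant DMRs per run
        stays well below one half."""
        from xwaskit.regions import call_dmrs
        counts = []
        for s in range(300, 310):
            cfg = xk.SyntheticConfig(n_trios_art=150, n_trios_nonart=150,
                                     n_cpgs=600, block_size=4,
                                     include_parents=False, seed=s)
            mat, sheet, man, _ = xk.generate_trio_dataset(cfg)
            _, m_vals, _ = xk.preprocess_pipeline(mat, man, sheet,
                                                  run_gap_scan=False)
            res = xk.run_xwas(m_vals, sheet, model_id="M1", sex="F")
            null = xk.estimate_empirical_null(res["z_raw"].to_numpy(),
                                              seed=s + 1)
            adj = xk.adjust_results(res, null)
            girls = [c for c in sheet.children("F").index
                     if c in m_vals.columns]
            dmrs = call_dmrs(adj, m_vals, man, girls, se_scale=null.sigma0)
            counts.append(sum(d.significant for d in dmrs))
        assert float(np.mean(counts)) < 0.5

    def test_planted_regions_recovered_no_false_calls(self, dmr_recovery_run):
        out = dmr_recovery_run["result"]
        truth = dmr_recovery_run["truth"]
        causal = truth.causal_probes
        sig = [d for d in out.dmrs if d.significant]
        # every planted region found...
        hit = sum(1 for e in truth.entries
                  if any(set(d.member_probe_ids) & set(e["probe_ids"])
                         for d in sig))
        assert hit == len(truth.entries) == 5
        # ...and nothing significant outside the planted spans
        for d in sig:
            assert set(d.member_probe_ids) <= causal


class TestComethylation:
    def test_duplicated_probe_perfectly_correlated(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=40)
        m = pd.DataFrame([v, v, rng.normal(size=40)],
                         index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(40)])
        man = _manifest([1000, 1200, 1400], probes=["a", "b", "c"])
        rep = comethylation(m, man, "a", window_bp=2000)
        assert rep.r.loc["a", "b"] == pytest.approx(1.0)
        assert rep.p_adj.loc["a", "b"] < 0.05

    def test_window_boundary_closed(self):
        m = pd.DataFrame(np.random.default_rng(4).normal(size=(3, 30)),
                         index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(30)])
        # center at 10_000, +/- 25_000 window: 35_000 is exactly on the edge
        man = _manifest([10_000, 35_000, 35_001], probes=["a", "b", "c"])
        rep = comethylation(m, man, "a", window_bp=50_000)
        assert rep.member_probe_ids == ["a", "b"]

    def test_negated_values_anticorrelated(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=40)
        m = pd.DataFrame([v, -v], index=["a", "b"],
                         columns=[f"s{i}" for i in range(40)])
        man = _manifest([100, 200], probes=["a", "b"])
        rep = comethylation(m, man, "a", window_bp=1000)
        assert rep.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matrices_symmetric_unit_diagonal(self, small_dataset):
        mat, _, man, _ = small_dataset
        m = xk.beta_to_m(mat.beta)
        center = list(man.probe_ids)[10]
        rep = comethylation(m, man, center, window_bp=4000)
        r = rep.r.to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        pa = rep.p_adj.to_numpy()
        np.testing.assert_allclose(pa, pa.T, atol=1e-12)

    def test_absent_center_rejected(self, small_dataset):
        mat, _, man, _ = small_dataset
        with pytest.raises(ValidationError, match="center"):
            comethylation(mat.beta, man, "cg_nope")
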