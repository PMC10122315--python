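"""QC chain: exclusions, masking, greedy filtering, gap detection, BMIQ,
logit2 transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

import xwaskit as xk
from xwaskit.types import MethylationMatrix, ProbeManifest, SampleSheet, ValidationError


def _matrix(values, probes=None, samples=None, detp=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    beta = pd.DataFrame(values, index=probes, columns=samples)
    d = None
    if detp is not None:
        d = pd.DataFrame(np.asarray(detp, dtype=float), index=probes,
                         columns=samples)
    return MethylationMatrix(beta, d)


def _manifest(probes, flagged=(), design=None):
    tab = pd.DataFrame({
        "chromosome": "X",
        "position": np.arange(1, len(probes) + 1) * 100,
        "design_type": design or ["II"] * len(probes),
        "cross_reactive": [p in flagged for p in probes],
        "snp_overlap_last3": False,
    }, index=pd.Index(probes, name="probe_id"))
    return ProbeManifest(tab)


class TestExcludeFlagged:
    def test_flagged_removed_order_preserved(self):
        probes = [f"p{i}" for i in range(5)]
        mat = _matrix(np.full((5, 2), 0.5), probes=probes)
        out = xk.exclude_flagged_probes(mat, _manifest(probes, flagged={"p1", "p3"}))
        assert list(out.probes) == ["p0", "p2", "p4"]

    def test_no_flags_identity(self):
        mat = _matrix(np.full((3, 2), 0.5))
        out = xk.exclude_flagged_probes(mat, _manifest(list(mat.probes)))
        assert list(out.probes) == list(mat.probes)

    def test_all_flagged_empty(self):
        mat = _matrix(np.full((2, 2), 0.5))
        out = xk.exclude_flagged_probes(
            mat, _manifest(list(mat.probes), flagged=set(mat.probes)))
        assert out.shape[0] == 0

    def test_probe_missing_from_manifest_rejected(self):
        mat = _matrix(np.full((2, 2), 0.5))
        with pytest.raises(ValidationError, match="absent"):
            xk.exclude_flagged_probes(mat, _manifest(["p0"]))


class TestMaskByDetection:
    def test_single_failing_cell_masked_probe_kept(self):
        mat = _matrix([[0.5, 0.5], [0.5, 0.5]],
                      detp=[[0.0001, 0.5], [0.0001, 0.0001]])
        out = xk.mask_by_detection(mat)
        assert np.isnan(out.beta.iloc[0, 1])
        assert out.shape == (2, 2)

    def test_probe_failing_everywhere_dropped(self):
        mat = _matrix([[0.5, 0.5], [0.5, 0.5]],
                      detp=[[0.9, 0.9], [0.0001, 0.0001]])
        out = xk.mask_by_detection(mat)
        assert list(out.probes) == ["p1"]

    def test_threshold_one_is_identity(self):
        mat = _matrix([[0.5, 0.5]], detp=[[0.9, 0.3]])
        out = xk.mask_by_detection(mat, threshold=1.0)
        assert not out.beta.isna().any().any()

    def test_missing_detection_matrix_instructs(self):
        mat = _matrix([[0.5]])
        with pytest.raises(ValidationError, match="skip"):
            xk.mask_by_detection(mat)


class TestGreedyFilter:
    def test_hand_traced_three_by_three(self):
        """Sample s2 fails all probes, probe p0 additionally fails in s0:
        iteration 1 removes s2 (fraction 1.0), iteration 2 removes p0
        (fraction 1/2), then stop."""
        beta = np.full((3, 3), 0.5)
        beta[0, 0] = np.nan   # p0 fails in s0
        beta[:, 2] = np.nan   # s2 fails everywhere
        mat = _matrix(beta)
        out, rp, rs = xk.greedy_filter(mat, max_unreliable_frac=0.05)
        assert rs == ["s2"]
        assert rp == ["p0"]
        assert list(out.probes) == ["p1", "p2"]
        assert list(out.samples) == ["s0", "s1"]

    def test_no_failures_identity(self):
        mat = _matrix(np.full((3, 3), 0.5))
        out, rp, rs = xk.greedy_filter(mat)
        assert rp == [] and rs == []
        assert out.shape == (3, 3)

    def test_threshold_one_identity(self):
        beta = np.full((2, 2), np.nan)
        out, rp, rs = xk.greedy_filter(_matrix(beta), max_unreliable_frac=1.0)
        assert out.shape == (2, 2)

    def test_permutation_invariance_up_to_tiebreak(self):
        rng = np.random.default_rng(0)
        beta = np.full((6, 6), 0.5)
        beta[rng.random((6, 6)) < 0.3] = np.nan
        mat = _matrix(beta)
        out, rp, rs = xk.greedy_filter(mat)
        perm_p = rng.permutation(6)
        perm_s = rng.permutation(6)
        mat2 = _matrix(beta[np.ix_(perm_p, perm_s)],
                       probes=[f"p{i}" for i in perm_p],
                       samples=[f"s{j}" for j in perm_s])
        out2, rp2, rs2 = xk.greedy_filter(mat2)
        assert set(rp) == set(rp2) and set(rs) == set(rs2)


class TestDetectGaps:
    def test_two_separated_clusters_flagged(self):
        scan = xk.detect_gaps([0.10, 0.11, 0.12, 0.13, 0.75, 0.76])
        assert scan.n_groups == 2
        assert sorted(np.bincount(scan.assignment)) == [2, 4]
        assert scan.flagged

    def test_constant_vector_single_group(self):
        scan = xk.detect_gaps([0.4] * 10)
        assert scan.n_groups == 1 and not scan.flagged

    def test_lone_outlier_not_flagged(self):
        values = [0.10] * 10 + [0.90]
        scan = xk.detect_gaps(values, outlier_frac=0.1)  # cutoff 1.1 samples
        assert scan.n_groups == 2 and not scan.flagged

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_assignment_is_sorted_partition(self, values):
        scan = xk.detect_gaps(values)
        v = np.asarray(values)
        # groups are contiguous in sorted order and labels ordered by value
        order = np.argsort(v, kind="stable")
        labels = scan.assignment[order]
        assert np.all(np.diff(labels) >= 0)
        assert scan.n_groups == labels[-1] + 1


class TestBmiq:
    @pytest.fixture(scope="class")
    def compressed(self):
        cfg = xk.SyntheticConfig(n_trios_art=40, n_trios_nonart=40,
                                 n_cpgs=1200, include_parents=False,
                                 type2_compression=0.5, seed=17)
        mat, sheet, man, _ = xk.generate_trio_dataset(cfg)
        return mat, man, xk.bmiq_normalize(mat, man)

    def test_type_one_probes_unchanged(self, compressed):
        mat, man, out = compressed
        is1 = (man.table["design_type"] == "I").to_numpy()
        np.testing.assert_array_equal(out.beta.to_numpy()[is1],
                                      mat.beta.to_numpy()[is1])

    def test_output_in_unit_interval_and_rank_preserved(self, compressed):
        mat, man, out = compressed
        vals = out.beta.to_numpy()
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
        is2 = (man.table["design_type"] == "II").to_numpy()
        for j in [0, 11, 37]:  # spot-check samples
            before = mat.beta.to_numpy()[is2, j]
            after = vals[is2, j]
            order = np.argsort(before, kind="stable")
            assert np.all(np.diff(after[order]) >= 0)

    def test_ks_distance_between_types_decreases(self, compressed):
        mat, man, out = compressed
        is2 = (man.table["design_type"] == "II").to_numpy()
        before = ks_2samp(mat.beta.to_numpy()[is2].ravel(),
                          mat.beta.to_numpy()[~is2].ravel()).statistic
        after = ks_2samp(out.beta.to_numpy()[is2].ravel(),
                         out.beta.to_numpy()[~is2].ravel()).statistic
        assert after < before

    def test_bulk_idempotence(self, compressed):
        _, man, out = compressed
        again = xk.bmiq_normalize(out, man)
        delta = np.abs(again.beta.to_numpy() - out.beta.to_numpy())
        assert float(np.nanmedian(delta)) < 1e-3


class TestLogit2:
    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, beta, m):
        assert xk.beta_to_m(beta) == pytest.approx(m, abs=1e-12)

    @given(st.floats(min_value=1e-5, max_value=1 - 1e-5))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, b):
        assert xk.m_to_beta(xk.beta_to_m(b)) == pytest.approx(b, abs=1e-12)

    def test_boundary_values_finite(self):
        m = xk.beta_to_m(np.array([0.0, 1.0]))
        assert np.all(np.isfinite(m))


def test_pipeline_runs_and_reports(small_dataset):
    mat, sheet, man, _ = small_dataset
    clean, m_vals, report = xk.preprocess_pipeline(mat, man, sheet,
                                                   run_bmiq=False)
    assert report.n_probes_final == clean.shape[0]
    assert m_vals.shape == clean.shape
    assert report.gap_flags is not None
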