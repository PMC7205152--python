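"""Anomaly scoring, TV denoising, Gamma testing and region merging."""

import numpy as np
import pytest
from scipy.optimize import minimize

from puracn import (
    anomaly_scores,
    build_isolation_forest,
    detect_cnvs,
    gamma_test,
    load_external_calls,
    merge_calls,
    tv_denoise,
)
from puracn.cnv_detect import CNVRegion

from conftest import profile_from_rd


def _avg_path_length(n: int) -> float:
    """Expected path length of an unsuccessful BST search over n points."""
    if n <= 1:
        return 0.0
    if n == 2:
        return 1.0
    return 2.0 * (np.log(n - 1) + np.euler_gamma) - 2.0 * (n - 1) / n


def brute_force_scores(forest, values: np.ndarray) -> np.ndarray:
    """Recompute isolation scores by walking every tree point by point."""
    depths = []
    for est in forest.estimators_:
        t = est.tree_
        per_tree = []
        for x in values:
            node, depth = 0, 0
            while t.children_left[node] != -1:
                node = (t.children_left[node] if x <= t.threshold[node]
                        else t.children_right[node])
                depth += 1
            per_tree.append(depth + _avg_path_length(t.n_node_samples[node]))
        depths.append(per_tree)
    mean_depth = np.mean(depths, axis=0)
    return 2.0 ** (-mean_depth / _avg_path_length(forest.max_samples_))


class TestIsolationForest:
    def test_paper_scale_forest_shape(self):
        rng = np.random.default_rng(0)
        forest = build_isolation_forest(rng.poisson(100, 2000), seed=1)
        assert len(forest.estimators_) == 256
        # 2000 bins < 256 would shrink; here the full 256 subsample is kept
        assert forest.max_samples_ == 256

    def test_subsample_shrinks_to_bin_count(self, caplog):
        forest = build_isolation_forest(np.arange(50.0), subsample=256, seed=0)
        assert forest.max_samples_ == 50

    def test_outlier_scores_above_bulk(self):
        rng = np.random.default_rng(2)
        rd = np.concatenate([rng.normal(100, 5, 500), [1000.0]])
        forest = build_isolation_forest(rd, n_trees=64, subsample=64, seed=3)
        s = anomaly_scores(forest, rd)
        assert s[-1] > np.median(s[:-1])

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        rd = rng.poisson(100, 600).astype(float)
        s1 = anomaly_scores(build_isolation_forest(rd, seed=9), rd)
        s2 = anomaly_scores(build_isolation_forest(rd, seed=9), rd)
        np.testing.assert_array_equal(s1, s2)

    def test_matches_brute_force_tree_walk(self):
        rng = np.random.default_rng(3)
        rd = rng.normal(100, 10, 50)
        forest = build_isolation_forest(rd, n_trees=32, subsample=32, seed=5)
        ours = anomaly_scores(forest, rd)
        brute = brute_force_scores(forest, rd)
        np.testing.assert_allclose(ours, brute, atol=1e-12)
        assert np.all((ours > 0) & (ours < 1))


def tv_objective(u, y, lam):
    return 0.5 * np.sum((u - y) ** 2) + lam * np.sum(np.abs(np.diff(u)))


class TestTVDenoise:
    def test_lam_zero_is_identity(self):
        y = np.random.default_rng(0).normal(size=40)
        np.testing.assert_array_equal(tv_denoise(y, 0.0), y)

    def test_huge_lam_gives_constant_mean(self):
        y = np.random.default_rng(1).normal(size=30)
        out = tv_denoise(y, lam=1e6)
        np.testing.assert_allclose(out, y.mean(), atol=1e-9)

    def test_step_signal_matches_qp_solution(self):
        # two-level step: TV pulls the levels together by lam/3 each
        y = np.array([0.0, 0, 0, 1, 1, 1])
        lam = 0.1
        out = tv_denoise(y, lam)
        np.testing.assert_allclose(
            out, [lam / 3] * 3 + [1 - lam / 3] * 3, atol=1e-12)
        res = minimize(tv_objective, y, args=(y, lam), method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxfev=50000))
        assert tv_objective(out, y, lam) <= tv_objective(res.x, y, lam) + 1e-10

    @pytest.mark.parametrize("trial", range(8))
    def test_objective_beats_numeric_optimizer(self, trial):
        rng = np.random.default_rng(100 + trial)
        y = rng.normal(0, 1, rng.integers(2, 8))
        lam = rng.uniform(0.01, 1.0)
        out = tv_denoise(y, lam)
        res = minimize(tv_objective, y.copy(), args=(y, lam),
                       method="Nelder-Mead",
                       options=dict(xatol=1e-10, fatol=1e-13, maxfev=100000))
        assert tv_objective(out, y, lam) <= tv_objective(res.x, y, lam) + 1e-8

    def test_never_increases_total_variation(self):
        rng = np.random.default_rng(7)
        for lam in (0.0, 0.05, 0.5, 5.0):
            y = rng.normal(0, 1, 200)
            out = tv_denoise(y, lam)
            assert (np.abs(np.diff(out)).sum()
                    <= np.abs(np.diff(y)).sum() + 1e-12)

    def test_negative_lam_rejected(self):
        with pytest.raises(ValueError):
            tv_denoise([1.0, 2.0], -0.1)


class TestGammaTest:
    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(8)
        scores = rng.gamma(5.0, 0.1, 10_000)
        result = gamma_test(scores, level=0.01)
        frac = result.calls.mean()
        # binomial 99% interval around 0.01 over 10^4 bins
        se = np.sqrt(0.01 * 0.99 / 10_000)
        assert abs(frac - 0.01) < 2.58 * se + 0.003  # MoM-fit slack

    def test_level_zero_calls_nothing(self):
        rng = np.random.default_rng(9)
        result = gamma_test(rng.gamma(5.0, 0.1, 1000), level=0.0)
        assert result.calls.sum() == 0

    def test_planted_run_fully_called(self):
        rng = np.random.default_rng(10)
        scores = rng.gamma(5.0, 0.1, 10_000)  # mean 0.5, sd ~0.22
        scores[4000:4020] += 5 * scores.std()  # >= 5 SD shift
        result = gamma_test(scores, level=0.01)
        assert result.calls[4000:4020].all()

    def test_zero_variance_makes_no_calls(self, caplog):
        result = gamma_test(np.full(100, 0.5), level=0.05)
        assert result.calls.sum() == 0

    def test_nonpositive_scores_are_shifted_not_fatal(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(0.0, 1.0, 500)  # contains negatives
        result = gamma_test(scores, level=0.05)
        assert np.all((result.pvalue >= 0) & (result.pvalue <= 1))


class TestMergeCalls:
    def test_runs_become_regions(self):
        prof = profile_from_rd([5.0, 5.0, 10.0, 5.0])
        regions = merge_calls([True, True, False, True], prof, r_bar=10.0)
        assert [(r.start, r.end, r.n_bins) for r in regions] == [
            (0, 2000, 2), (3000, 4000, 1)]
        assert all(r.direction == "loss" for r in regions)

    def test_direction_from_mean_rd(self):
        prof = profile_from_rd([5.0, 15.0])
        regions = merge_calls([True, True], prof, r_bar=10.0)
        # one run whose mean equals r_bar -> dropped with a warning
        assert regions == []
        regions = merge_calls([True, False], prof, r_bar=10.0)
        assert regions[0].direction == "loss"

    def test_runs_do_not_cross_chromosomes(self):
        import pandas as pd
        from puracn import RDProfile
        df = pd.DataFrame(dict(
            chrom=["c1", "c1", "c2", "c2"],
            start=[0, 1000, 0, 1000], end=[1000, 2000, 1000, 2000],
            gc=0.45, n_frac=0.0, rd_raw=5.0, rd=5.0, masked=False))
        prof = RDProfile(df, 1000)
        regions = merge_calls([True, True, True, True], prof, r_bar=10.0)
        assert [(r.chrom, r.start, r.end) for r in regions] == [
            ("c1", 0, 2000), ("c2", 0, 2000)]

    def test_no_flags_no_regions(self):
        prof = profile_from_rd([5.0, 5.0])
        assert merge_calls([False, False], prof, r_bar=10.0) == []


class TestExternalCalls:
    def test_bed_record_to_region(self, tmp_path):
        prof = profile_from_rd([5.0] * 5 + [10.0] * 5)
        bed = tmp_path / "calls.bed"
        bed.write_text("chr21\t1000\t5000\n")
        regions = load_external_calls(bed, prof)
        assert len(regions) == 1
        assert regions[0].direction == "loss"
        assert regions[0].observed_rd == 5.0

    def test_empty_file_empty_list(self, tmp_path):
        prof = profile_from_rd([5.0, 10.0])
        bed = tmp_path / "calls.bed"
        bed.write_text("")
        assert load_external_calls(bed, prof) == []

    def test_masked_gap_excluded_from_observed_rd(self, tmp_path):
        rd = [4.0, 6.0, 99.0, 8.0, 30.0]
        prof = profile_from_rd(rd, masked=[False, False, True, False, False])
        bed = tmp_path / "calls.bed"
        bed.write_text("chr21\t0\t4000\n")
        regions = load_external_calls(bed, prof)
        assert regions[0].observed_rd == pytest.approx((4 + 6 + 8) / 3)
        assert regions[0].n_bins == 3
        assert regions[0].direction == "loss"

    def test_direction_column_respected(self, tmp_path):
        prof = profile_from_rd([9.0, 10.0, 11.0])
        bed = tmp_path / "calls.bed"
        bed.write_text("chr21\t0\t1000\tloss\n")
        regions = load_external_calls(bed, prof)
        assert regions[0].direction == "loss"

    def test_malformed_line_reports_line_number(self, tmp_path):
        prof = profile_from_rd([5.0, 10.0])
        bed = tmp_path / "calls.bed"
        bed.write_text("chr21\t0\t1000\nchr21\tnot_a_number\t2000\n")
        with pytest.raises(ValueError, match=":2"):
            load_external_calls(bed, prof)


class TestDetectEndToEnd:
    def test_planted_segments_found_with_calibrated_false_rate(self):
        # strong (>= 3 SD) planted loss and gain segments
        rng = np.random.default_rng(12)
        n = 10_000
        rd = rng.poisson(100, n).astype(float)  # SD ~ 10
        truth = np.zeros(n, dtype=bool)
        for start, mean in ((2000, 50.0), (5000, 160.0), (8000, 40.0)):
            rd[start:start + 60] = rng.poisson(mean, 60)
            truth[start:start + 60] = True
        prof = profile_from_rd(rd)
        level = 0.01
        regions, scores = detect_cnvs(prof, level=level, seed=13)
        sensitivity = scores.calls[truth].mean()
        false_rate = scores.calls[~truth].mean()
        assert sensitivity >= 0.9
        assert false_rate <= 2 * level
        assert any(r.direction == "gain" for r in regions)
        assert any(r.direction == "loss" for r in regions)

    def test_fixed_seed_reproducible_calls(self):
        rng = np.random.default_rng(14)
        rd = rng.poisson(100, 3000).astype(float)
        rd[1000:1050] = rng.poisson(50, 50)
        prof = profile_from_rd(rd)
        r1, s1 = detect_cnvs(prof, seed=21)
        r2, s2 = detect_cnvs(prof, seed=21)
        np.testing.assert_array_equal(s1.calls, s2.calls)
        assert [(r.start, r.end, r.direction) for r in r1] == \
               [(r.start, r.end, r.direction) for r in r2]

    def test_region_invariants(self):
        with pytest.raises(ValueError):
            CNVRegion("c", 100, 100, "loss", 5.0, 1)
        with pytest.raises(ValueError):
            CNVRegion("c", 0, 100, "sideways", 5.0, 1)
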