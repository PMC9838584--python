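"""Synthetic cohort generation, closure detection, binning and R-fit."""

import numpy as np
import pytest

from ahflow.clinical_cohort import (BinnedIOPStats, CohortParams,
                                    SyntheticEye, bin_and_summarize,
                                    cohort_to_frame, detect_closed_sectors,
                                    detect_cohort, fit_reduction_factor,
                                    generate_cohort, group_extent_quarter_deg,
                                    model_iop_mmhg)
from ahflow.closure_study import LumpedEngine, sweep
from ahflow.lumped_model import LumpedConfig


def small_params(**kw):
    kw.setdefault("n_eyes", 300)
    kw.setdefault("seed", 11)
    return CohortParams(**kw)


class TestGenerateCohort:
    def test_same_seed_reproduces_cohort_exactly(self):
        a = generate_cohort(small_params())
        b = generate_cohort(small_params())
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.aod500_mm, eb.aod500_mm)
            assert ea.iop_mmhg == eb.iop_mmhg
            assert ea.true_closed_sectors == eb.true_closed_sectors

    def test_different_seed_differs(self):
        a = generate_cohort(small_params())
        b = generate_cohort(small_params(seed=12))
        assert any(not np.array_equal(ea.aod500_mm, eb.aod500_mm)
                   for ea, eb in zip(a, b))

    def test_all_open_point_mass_gives_iid_iop(self):
        dist = (1.0,) + (0.0,) * 8
        params = small_params(closed_sector_count_distribution=dist,
                              baseline_mobility_dispersion=0.0,
                              iop_measurement_noise_sd=0.0)
        eyes = generate_cohort(params)
        iops = {e.iop_mmhg for e in eyes}
        assert len(iops) == 1                      # identical up to noise=0
        assert all(len(e.true_closed_sectors) == 0 for e in eyes)

    def test_validation(self):
        with pytest.raises(ValueError):
            small_params(closed_sector_count_distribution=(0.5, 0.5))
        with pytest.raises(ValueError):
            small_params(severity_mean=0.8)

    def test_conditional_mean_follows_generating_curve(self):
        """Eq-12 structure: with (K0, severity) independent of extent,
        the mean IOP conditioned on the closed-sector count reproduces
        the generating model mean within 3 Monte-Carlo SEs."""
        params = CohortParams(seed=5)   # full n = 2395
        eyes = generate_cohort(params)
        counts = np.array([len(e.true_closed_sectors) for e in eyes])
        iops = np.array([e.iop_mmhg for e in eyes])
        # dispersion-aware reference: expectation over the same K0 law
        rng = np.random.default_rng(987654)
        k0 = np.exp(rng.normal(0.0, params.baseline_mobility_dispersion,
                               1500))
        for count in (0, 1, 4, 8):
            sel = counts == count
            if sel.sum() < 8:
                continue
            ref = np.mean([model_iop_mmhg(count, k, params.severity_mean,
                                          params.lumped) for k in k0])
            se = iops[sel].std(ddof=1) / np.sqrt(sel.sum())
            se_ref = np.std([model_iop_mmhg(count, k, params.severity_mean,
                                            params.lumped)
                             for k in k0[:300]]) / np.sqrt(1500)
            tol = 3.0 * np.hypot(se, se_ref)
            assert abs(iops[sel].mean() - ref) < tol, count


class TestDetection:
    def test_boundary_value_counts_as_open(self):
        eye = SyntheticEye(0, [0.01, 0.039, 0.04, 0.05, 0.2, 0.2, 0.2, 0.2],
                           (0, 1), 15.0, 1.0, 1.0)
        assert detect_closed_sectors(eye, 0.04) == 2

    def test_all_open(self):
        eye = SyntheticEye(0, [0.5] * 8, (), 12.0, 1.0, 1.0)
        assert detect_closed_sectors(eye) == 0

    def test_detection_identity_with_separating_threshold(self):
        eyes = generate_cohort(small_params())
        kept, counts = detect_cohort(eyes)
        assert len(kept) == len(eyes)
        true = np.array([len(e.true_closed_sectors) for e in eyes])
        assert np.array_equal(counts, true)

    def test_missing_sector_excludes_eye(self, caplog):
        eyes = generate_cohort(small_params(n_eyes=10))
        eyes[3].aod500_mm[2] = np.nan
        with caplog.at_level("WARNING"):
            kept, counts = detect_cohort(eyes)
        assert len(kept) == 9
        assert "missing AOD500" in caplog.text

    @pytest.mark.parametrize("threshold", [0.02, 0.06])
    def test_sensitivity_thresholds_rerun_pipeline(self, threshold):
        eyes = generate_cohort(small_params())
        kept, counts = detect_cohort(eyes, threshold_mm=threshold)
        stats = bin_and_summarize(kept, counts)
        assert sum(s.n for s in stats) == len(kept)
        # lower threshold detects no more closures than the default
        _, counts_default = detect_cohort(eyes)
        if threshold < 0.04:
            assert counts.sum() <= counts_default.sum()
        else:
            assert counts.sum() >= counts_default.sum()


class TestBinning:
    def test_hand_computed_group_statistics(self):
        eyes = [SyntheticEye(i, [0.5] * 8, (), v, 1.0, 1.0)
                for i, v in enumerate((10.0, 12.0, 14.0, 16.0, 18.0))]
        stats = bin_and_summarize(eyes, np.zeros(5, dtype=int))
        assert len(stats) == 1
        s = stats[0]
        assert s.group == "0" and s.n == 5
        assert s.median == 14.0 and s.mean == 14.0
        assert s.q1 == 12.0 and s.q3 == 16.0       # linear interpolation
        assert s.whisker_lo == 10.0 and s.whisker_hi == 18.0

    def test_extensive_closure_merges_into_one_group(self):
        eyes = [SyntheticEye(i, [0.01] * 8, tuple(range(8)), 20.0, 1.0, 1.0)
                for i in range(6)]
        counts = np.array([7, 8, 7, 8, 8, 7])
        stats = bin_and_summarize(eyes, counts)
        assert [s.group for s in stats] == ["7-8"]
        assert stats[0].n == 6

    def test_empty_groups_are_absent_not_zero_filled(self):
        eyes = [SyntheticEye(i, [0.5] * 8, (), 12.0, 1.0, 1.0)
                for i in range(4)]
        stats = bin_and_summarize(eyes, np.array([0, 0, 3, 3]))
        assert [s.group for s in stats] == ["0", "3"]

    def test_quartile_ordering_invariant(self):
        eyes = generate_cohort(small_params())
        kept, counts = detect_cohort(eyes)
        for s in bin_and_summarize(kept, counts):
            assert s.whisker_lo <= s.q1 <= s.median <= s.q3 <= s.whisker_hi

    def test_group_counts_sum_to_cohort(self):
        eyes = generate_cohort(small_params())
        kept, counts = detect_cohort(eyes)
        stats = bin_and_summarize(kept, counts)
        assert sum(s.n for s in stats) == len(kept)


@pytest.fixture(scope="module")
def curves():
    return sweep(LumpedEngine(LumpedConfig()),
                 factors=(1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 5.0))


class TestFitReductionFactor:
    def test_noise_free_cohort_recovers_exactly(self, curves):
        stats = []
        for label in ("0", "2", "4", "6", "7-8"):
            count = 7.5 if label == "7-8" else int(label)
            iop = model_iop_mmhg(count if count != 7.5 else 7.5, 1.0, 1.6,
                                 LumpedConfig())
            stats.append(BinnedIOPStats(label, 10, iop, iop, iop, iop,
                                        iop, iop))
        assert fit_reduction_factor(stats, curves) == 1.6

    def test_generated_cohort_recovers_generating_factor(self, curves):
        params = small_params(n_eyes=2395, seed=3,
                              iop_measurement_noise_sd=1.0,
                              baseline_mobility_dispersion=0.1)
        eyes = generate_cohort(params)
        kept, counts = detect_cohort(eyes)
        stats = bin_and_summarize(kept, counts)
        assert fit_reduction_factor(stats, stats and curves) == 1.6

    def test_grid_without_truth_returns_nearest(self, curves):
        near = [c for c in curves if c.reduction_factor in (1.4, 1.8)]
        stats = []
        for label in ("0", "4", "7-8"):
            count = 7.5 if label == "7-8" else int(label)
            iop = model_iop_mmhg(count, 1.0, 1.6, LumpedConfig())
            stats.append(BinnedIOPStats(label, 10, iop, iop, iop, iop,
                                        iop, iop))
        assert fit_reduction_factor(stats, near) in (1.4, 1.8)

    def test_degenerate_single_curve_grid_warns(self, curves, caplog):
        stats = [BinnedIOPStats("0", 5, 12.0, 12.0, 11.0, 13.0, 10.0, 14.0)]
        with caplog.at_level("WARNING"):
            best = fit_reduction_factor(stats, curves[:1])
        assert best == curves[0].reduction_factor
        assert "degenerate" in caplog.text


class TestFrames:
    def test_cohort_frame_layout(self):
        eyes = generate_cohort(small_params(n_eyes=20))
        frame = cohort_to_frame(eyes)
        assert list(frame.columns) == (
            ["eye_id"] + [f"aod500_s{i}_mm" for i in range(8)]
            + ["iop_mmhg"])
        assert len(frame) == 20

    def test_group_extent_mapping(self):
        assert group_extent_quarter_deg("0") == 0.0
        assert group_extent_quarter_deg("4") == 45.0
        assert group_extent_quarter_deg("7-8") == pytest.approx(84.375)
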