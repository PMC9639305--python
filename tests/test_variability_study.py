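import dataclasses

import numpy as np
import pandas as pd
import pytest

from nsdremote import myogeometry as geo
from nsdremote import nsd_core
from nsdremote import variability_study as vs
from nsdremote.phantom import CohortTemplate, generate_cohort, generate_slice

from conftest import make_spec


def small_cohort(n=6, seed=21, **base_kw):
    base = dict(noise_model="rician", remote_sd=0.02, infarct_sd=0.05)
    base.update(base_kw)
    tmpl = CohortTemplate(
        base=make_spec(**base),
        infarct_center_angle_range=(0.0, 360.0),
        infarct_extent_range=(60.0, 140.0),
        transmurality_range=(0.5, 1.0),
    )
    return generate_cohort([(tmpl, n)], seed)


class TestSummarize:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=vs.OUTCOME_COLUMNS)

    def _row(self, slice_id, level, measured, reference):
        return {
            "slice_id": slice_id,
            "site_label": "s",
            "factor": "f",
            "factor_level": level,
            "measured_pct": measured,
            "reference_pct": reference,
            "error_pct": measured - reference,
            "threshold": 0.0,
        }

    def test_all_zero_errors(self):
        table = self._table([self._row("a", i, 10.0, 10.0) for i in range(3)])
        s = vs.summarize(table)
        assert s.mean_error == 0.0 and s.error_sd == 0.0
        assert s.cov_mean == 0.0 and s.median_abs_diff == 0.0

    def test_hand_arithmetic_cov(self):
        # errors {+2, -2} on one slice with reference 10%:
        # CoV = SD({2, -2}) / 10 = 2*sqrt(2) / 10 = 28.28%
        table = self._table([self._row("a", 0, 12.0, 10.0), self._row("a", 1, 8.0, 10.0)])
        s = vs.summarize(table)
        assert s.cov_mean == pytest.approx(28.2842712, abs=1e-5)
        assert s.mean_error == pytest.approx(0.0)
        assert s.roi_count == 2 and s.slice_count == 1

    def test_translation_shifts_mean_not_cov(self):
        rng = np.random.default_rng(0)
        rows = []
        for sid in "abc":
            ref = float(rng.uniform(10, 30))
            for i in range(5):
                rows.append(self._row(sid, i, ref + float(rng.normal(0, 3)), ref))
        base = vs.summarize(self._table(rows))
        shifted_rows = [
            dict(r, measured_pct=r["measured_pct"] + 4.0, error_pct=r["error_pct"] + 4.0)
            for r in rows
        ]
        shifted = vs.summarize(self._table(shifted_rows))
        assert shifted.mean_error == pytest.approx(base.mean_error + 4.0)
        assert shifted.cov_mean == pytest.approx(base.cov_mean)
        assert shifted.cov_sd == pytest.approx(base.cov_sd)

    def test_cov_scale_consistency(self):
        rng = np.random.default_rng(1)
        rows = []
        for sid in "abcd":
            ref = float(rng.uniform(10, 30))
            for i in range(4):
                rows.append(self._row(sid, i, ref + float(rng.normal(0, 2)), ref))
        base = vs.summarize(self._table(rows))
        doubled_rows = [
            dict(
                r,
                measured_pct=2 * r["measured_pct"],
                reference_pct=2 * r["reference_pct"],
                error_pct=2 * r["error_pct"],
            )
            for r in rows
        ]
        doubled = vs.summarize(self._table(doubled_rows))
        assert doubled.cov_mean == pytest.approx(base.cov_mean)
        assert doubled.cov_sd == pytest.approx(base.cov_sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vs.summarize(self._table([]))


class TestPositionStudy:
    def test_noiseless_cohort_zero_error_zero_cov(self):
        cohort = small_cohort(4, noise_model="none", remote_sd=0.0, infarct_sd=0.0)
        result = vs.run_position_study(cohort)
        assert np.allclose(result.table["error_pct"], 0.0)
        assert result.summary.cov_mean == 0.0 and result.summary.mean_error == 0.0

    def test_row_bookkeeping(self):
        cohort = small_cohort(5)
        result = vs.run_position_study(cohort)
        # each included slice contributes its own candidate-position count
        for sid, grp in result.table.groupby("slice_id"):
            assert 1 <= len(grp) <= 7
            assert grp["factor_level"].is_unique

    def test_bias_field_raises_cov(self):
        # paired seeds: identical cohorts except for the bias field
        flat = small_cohort(6, seed=33, bias_amplitude=0.0)
        biased = small_cohort(6, seed=33, bias_amplitude=0.4, bias_scale=25.0)
        cov_flat = vs.run_position_study(flat).summary.cov_mean
        cov_biased = vs.run_position_study(biased).summary.cov_mean
        assert cov_biased > cov_flat

    def test_excluded_slices_are_reported(self):
        bad = generate_slice(make_spec(infarct_extent=20.0))  # fails the 10% criterion
        result = vs.run_position_study([bad] + small_cohort(2))
        assert any(reason == "inclusion filter" for _, reason in result.excluded)


class TestSizeStudy:
    def test_noiseless_zero_cov(self):
        cohort = small_cohort(3, noise_model="none", remote_sd=0.0, infarct_sd=0.0)
        result = vs.run_size_study(cohort)
        assert result.summary.cov_mean == 0.0

    def test_included_slice_gets_full_default_grid(self):
        # inclusion guarantees a remote arc >= 180 deg, so every default
        # width (max 105 deg) fits: exactly 7 rows per slice
        cohort = small_cohort(3)
        result = vs.run_size_study(cohort)
        assert (result.table.groupby("slice_id").size() == 7).all()

    def test_narrow_grid_respects_remote_arc(self):
        sl = generate_slice(make_spec(infarct_extent=170.0, noise_model="rician",
                                      remote_sd=0.02, infarct_sd=0.05))
        cfg = vs.StudyConfig(size_grid=(45.0, 120.0, 185.0, 250.0))
        result = vs.run_size_study([sl], cfg)
        widths = sorted(result.table["factor_level"].unique())
        assert widths == [45.0, 120.0, 185.0]  # 250 exceeds the ~190-deg arc


class TestNsdStudy:
    def test_seven_rows_increasing_thresholds(self):
        cohort = small_cohort(4)
        result = vs.run_nsd_study(cohort)
        for sid, grp in result.table.groupby("slice_id"):
            assert len(grp) == 7
            grp = grp.sort_values("factor_level")
            thr = grp["threshold"].to_numpy()
            assert np.all(np.diff(thr) > 0)
            meas = grp["measured_pct"].to_numpy()
            assert np.all(np.diff(meas) <= 0)

    def _spread_over_n(self, result):
        sizes = result.table.groupby("slice_id")["measured_pct"]
        return (sizes.max() - sizes.min()).mean()

    def test_well_separated_contrast_insensitive_to_n(self):
        # crisp contrast: only the n=2 remote false-positive floor moves
        sep = vs.run_nsd_study(small_cohort(3, infarct_mean=0.9, remote_sd=0.01,
                                            infarct_sd=0.01))
        assert self._spread_over_n(sep) < 5.0
        high_n = sep.table[sep.table["factor_level"] >= 3.0]
        assert np.abs(high_n["error_pct"]).max() < 1.5

    def test_overlapping_contrast_steep_in_n(self):
        ovl = vs.run_nsd_study(small_cohort(3, infarct_mean=0.18, remote_sd=0.02,
                                            infarct_sd=0.04))
        sep = vs.run_nsd_study(small_cohort(3, infarct_mean=0.9, remote_sd=0.01,
                                            infarct_sd=0.01))
        assert self._spread_over_n(ovl) > 2 * self._spread_over_n(sep)
        by_n = ovl.table.groupby("factor_level")["measured_pct"].mean()
        assert by_n.loc[2.0] - by_n.loc[8.0] > 5.0


class TestSpuriousComparison:
    def test_no_islands_zero_difference(self):
        cohort = small_cohort(3, noise_model="none", remote_sd=0.0, infarct_sd=0.0)
        cmp = vs.run_spurious_comparison(cohort)
        assert cmp.paired_mean_diff == 0.0

    def test_naive_at_least_no_spurious_everywhere(self):
        cohort = small_cohort(6, remote_sd=0.05, infarct_mean=0.3, infarct_sd=0.08)
        cmp = vs.run_spurious_comparison(cohort)
        naive = cmp.naive_table["measured_pct"].to_numpy()
        clean = cmp.no_spurious_table["measured_pct"].to_numpy()
        assert np.all(naive >= clean)


class TestOptimalN:
    def test_recovers_construction_threshold(self):
        sl = generate_slice(make_spec(grid_size=192, pixel_spacing=1.0, infarct_extent=140,
                                      infarct_mean=0.22, infarct_sd=0.1, remote_sd=0.02,
                                      noise_model="gaussian", seed=5))
        polar = geo.polar_parameterize(sl.endo_contour, sl.epi_contour, sl.myo_mask)
        roi = geo.sector_roi(polar, 250.0, 45.0, 0.15)
        stats = nsd_core.remote_stats(sl.image, roi)
        truth = nsd_core.classify(sl.image, sl.myo_mask, stats.mu + 4.0 * stats.sigma)
        ref = nsd_core.infarct_fraction(truth, sl.myo_mask)
        opt = vs.optimal_n_per_slice(sl.image, sl.myo_mask, roi, ref)
        assert abs(opt.n_star - 4.0) <= 0.1 + 1e-9
        assert not opt.degenerate

    def test_invisible_infarct_degenerate_at_grid_end(self):
        rng = np.random.default_rng(0)
        img = np.clip(0.1 + rng.normal(0, 0.02, (64, 64)), 0, 1)
        myo = np.zeros((64, 64), dtype=bool)
        myo[16:48, 16:48] = True
        roi = np.zeros_like(myo)
        roi[20:30, 20:30] = True
        # reference far above anything noise-only thresholding can reach
        opt = vs.optimal_n_per_slice(img, myo, roi, reference_pct=90.0)
        assert opt.degenerate and opt.n_star == 0.1  # lowest n maximizes measured size

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            vs.optimal_n_per_slice(np.zeros((4, 4)), np.ones((4, 4), bool),
                                   np.ones((4, 4), bool), 0.0)

    def test_site_sigma_shifts_optimal_n(self):
        # higher remote sigma -> lower optimal n at matched contrast
        def site_mean(remote_sd, seed0):
            vals = []
            for seed in range(seed0, seed0 + 8):
                sl = generate_slice(make_spec(infarct_mean=0.3, infarct_sd=0.05,
                                              remote_sd=remote_sd, edge_smooth_px=1.0,
                                              noise_model="gaussian", seed=seed))
                polar = geo.polar_parameterize(sl.endo_contour, sl.epi_contour, sl.myo_mask)
                roi = geo.sector_roi(polar, 180.0, 45.0, 0.15)
                ref = nsd_core.infarct_fraction(sl.truth_infarct_mask, sl.myo_mask)
                vals.append(vs.optimal_n_per_slice(sl.image, sl.myo_mask, roi, ref).n_star)
            return np.mean(vals)

        assert site_mean(0.026, 100) < site_mean(0.013, 100)

    def test_study_aggregation(self):
        cohort = small_cohort(5)
        result = vs.optimal_n_study(cohort)
        assert len(result.table) == 5
        grid_lo, grid_hi = 0.1, 15.0
        assert ((result.table["n_star"] >= grid_lo) & (result.table["n_star"] <= grid_hi)).all()
        assert result.mean == pytest.approx(result.table["n_star"].mean())


class TestSignalVariability:
    def test_noiseless_zero(self):
        cohort = small_cohort(2, noise_model="none", remote_sd=0.0, infarct_sd=0.0)
        rep = vs.signal_variability_report(cohort)
        assert np.allclose(rep.table["remote_sd"], 0.0)

    def test_recovers_injected_sd_with_unit_range(self):
        # gaussian remote noise, image range pinned to [0, 1] by construction
        rng = np.random.default_rng(2)
        slices = []
        for seed in range(10):
            sl = generate_slice(make_spec(infarct_mean=1.0, remote_sd=0.02, infarct_sd=0.0,
                                          noise_model="gaussian", seed=seed))
            slices.append(sl)
        rep = vs.signal_variability_report(slices)
        assert rep.group_stats["mean"].iloc[0] == pytest.approx(0.02, rel=0.1)

    def test_two_group_ordering_and_ratio(self):
        a = small_cohort(8, seed=50, noise_model="gaussian", remote_sd=0.013,
                         infarct_mean=1.0, infarct_sd=0.0, site_label="lo")
        b = small_cohort(8, seed=60, noise_model="gaussian", remote_sd=0.026,
                         infarct_mean=1.0, infarct_sd=0.0, site_label="hi")
        rep = vs.signal_variability_report(a + b)
        stats = rep.group_stats.set_index("site_label")["mean"]
        assert stats["lo"] < stats["hi"]
        assert stats["hi"] / stats["lo"] == pytest.approx(2.0, rel=0.25)

    def test_constant_image_rejected(self):
        sl = generate_slice(make_spec())
        sl2 = dataclasses.replace(sl, image=np.zeros_like(sl.image))
        with pytest.raises(ValueError, match="constant"):
            vs.signal_variability_report([sl2])


class TestDeterminism:
    def test_rerun_tables_bit_identical(self):
        for _ in range(2):
            tables = []
            for run in range(2):
                cohort = small_cohort(4, seed=77)
                result = vs.run_nsd_study(cohort)
                tables.append(result.table)
            pd.testing.assert_frame_equal(tables[0], tables[1])
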