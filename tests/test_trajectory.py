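"""Trajectory assembly, crop rule, correlations and mode classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import shg4d as s
from shg4d.trajectory import FeatureTrajectory, build_trajectory, classify_mode, correlate

from conftest import tiny_spec


def _make_table(t, isum_f, dw_pct, dimean_f_pct=None):
    """Minimal wide table for direct classifier/correlation tests."""
    t = np.asarray(t, dtype=float)
    isum_f = np.asarray(isum_f, dtype=float)
    dw = np.asarray(dw_pct, dtype=float)
    n = len(t)
    df = pd.DataFrame(
        {
            "t_min": t,
            "V_um3": np.full(n, 1e5),
            "w_um": 60 * (1 + dw / 100),
            "h_um": np.full(n, 30.0),
            "imean_f": isum_f / 1e5,
            "imean_epi": 0.5 * isum_f / 1e5,
            "isum_f": isum_f,
            "isum_epi": 0.5 * isum_f,
        }
    )
    for raw, pct in (("V_um3", "dV_pct"), ("w_um", "dw_pct"), ("h_um", "dh_pct"),
                     ("imean_f", "dimean_f_pct"), ("imean_epi", "dimean_epi_pct"),
                     ("isum_f", "disum_f_pct"), ("isum_epi", "disum_epi_pct")):
        df[pct] = 100 * (df[raw] - df[raw].iloc[0]) / df[raw].iloc[0]
    if dimean_f_pct is not None:
        df["dimean_f_pct"] = dimean_f_pct
    return FeatureTrajectory(records=[], table=df, crop_min=50.0)


class TestBuildTrajectory:
    def test_crop_rule_is_exact_at_fifty_minutes(self):
        spec = tiny_spec(timestamps=(3.0, 20.0, 45.0, 50.0, 55.0))
        traj = build_trajectory(s.generate_stack_series(spec))
        assert list(traj.table["t_min"]) == [3.0, 20.0, 45.0, 50.0]
        dropped = [r for r in traj.records if r.flagged]
        assert len(dropped) == 1 and "crop" in dropped[0].reason

    def test_record_just_past_the_limit_is_dropped(self):
        spec = tiny_spec(timestamps=(3.0, 20.0, 50.0 + 1e-6))
        traj = build_trajectory(s.generate_stack_series(spec))
        assert list(traj.table["t_min"]) == [3.0, 20.0]

    def test_baseline_percent_changes_are_zero(self, swelling_trajectory):
        first = swelling_trajectory.table.iloc[0]
        for col in ("dV_pct", "dw_pct", "dh_pct", "dimean_f_pct", "disum_f_pct"):
            assert first[col] == 0.0

    def test_inert_noiseless_phantom_is_flat(self):
        spec = tiny_spec(timestamps=(0.0, 20.0, 40.0))
        traj = build_trajectory(s.generate_stack_series(spec))
        for col in ("dV_pct", "dw_pct", "dh_pct", "dimean_f_pct", "disum_f_pct"):
            assert traj.table[col].abs().max() < 2.0

    def test_swelling_phantom_tracks_the_kinetic_law(self, swelling_spec, swelling_trajectory):
        tab = swelling_trajectory.table
        truth = 100 * swelling_spec.swell_amplitude * (
            1 - np.exp(-tab["t_min"].to_numpy() / swelling_spec.tau_s_min)
        )
        assert np.abs(tab["dw_pct"].to_numpy() - truth).max() < 5.0
        assert tab["dh_pct"].abs().max() < 3.0

    def test_fewer_than_two_usable_records_is_undefined(self):
        spec = tiny_spec(timestamps=(3.0, 55.0, 60.0))
        with pytest.raises(ValueError, match="trajectory undefined"):
            build_trajectory(s.generate_stack_series(spec))

    def test_global_intensity_rescaling_leaves_percent_changes_unchanged(self):
        spec = tiny_spec(timestamps=(0.0, 15.0, 30.0), swell_amplitude=0.3, tau_s_min=10.0)
        series = s.generate_stack_series(spec)
        scaled = s.StackSeries(
            stacks=[
                s.VoxelStack(forward=st.forward * 3.0, epi=st.epi * 3.0,
                             spacing=st.spacing, timestamp_min=st.timestamp_min)
                for st in series
            ]
        )
        a = build_trajectory(series).table
        b = build_trajectory(scaled).table
        # single-precision voxel storage leaves ~1e-7 relative rounding in the
        # rescaled intensities; anything beyond that indicates a real leak
        for col in ("dV_pct", "dw_pct", "dh_pct", "dimean_f_pct", "disum_f_pct"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-4)

    def test_qc_overlap_with_previous_timepoint_reported(self, swelling_trajectory):
        overlaps = swelling_trajectory.table["overlap_prev"].to_numpy()
        assert np.isnan(overlaps[0])
        assert np.all(overlaps[1:] > 0.5)


class TestCorrelate:
    def test_forward_epi_mean_intensities_perfectly_correlated_noiselessly(self):
        spec = tiny_spec(timestamps=(0.0, 10.0, 20.0, 30.0), mode="destruction", tau_d_min=15.0)
        traj = build_trajectory(s.generate_stack_series(spec))
        c = correlate(traj, "imean_f", "imean_epi")
        assert c.pearson_r == pytest.approx(1.0, abs=1e-9)
        assert c.slope_origin == pytest.approx(spec.beta, rel=1e-6)

    def test_dilution_cumulative_signal_slope_near_zero(self, dilution_trajectory):
        c = correlate(dilution_trajectory, "dw_pct", "disum_f_pct")
        assert abs(c.slope_origin) < 0.05

    def test_dilution_mean_signal_follows_conservation_curve(self, dilution_trajectory):
        tab = dilution_trajectory.table
        dw = tab["dw_pct"].to_numpy() / 100
        predicted = -100 * dw / (1 + dw)
        assert np.abs(tab["dimean_f_pct"].to_numpy() - predicted).max() < 5.0

    def test_destruction_without_swelling_hugs_the_intensity_axis(self):
        spec = tiny_spec(timestamps=(0.0, 10.0, 20.0, 30.0), mode="destruction",
                         tau_d_min=10.0, swell_amplitude=0.0)
        traj = build_trajectory(s.generate_stack_series(spec))
        assert traj.table["dw_pct"].abs().max() < 2.0
        assert traj.table["dimean_f_pct"].iloc[-1] < -50.0

    def test_zero_variance_x_rejected(self):
        traj = _make_table([0, 10, 20], [1e7, 1e7, 1e7], [0, 0, 0])
        with pytest.raises(ValueError, match="zero-variance"):
            correlate(traj, "dw_pct", "disum_f_pct")

    def test_too_few_points_rejected(self):
        traj = _make_table([0, 10], [1e7, 9e6], [0, 5])
        with pytest.raises(ValueError, match=">= 3"):
            correlate(traj, "dw_pct", "disum_f_pct")


class TestClassifyMode:
    def test_label_is_pure_function_of_r_and_w(self):
        # conserved signal, large swelling -> bundle drifting
        drifting = _make_table([0, 10, 20, 30], [1e7, 1.0e7, 0.99e7, 1.01e7], [0, 20, 35, 50])
        assert classify_mode(drifting).label == "bundle_drifting"
        # conserved signal, no swelling -> inert
        inert = _make_table([0, 10, 20, 30], [1e7, 1.0e7, 0.99e7, 1.0e7], [0, 1, 2, 1])
        assert classify_mode(inert).label == "inert"
        # lost signal -> destruction regardless of swelling
        lost = _make_table([0, 10, 20, 30], [1e7, 6e6, 4e6, 2e6], [0, 20, 35, 50])
        assert classify_mode(lost).label == "intrinsic_destruction"

    def test_retention_threshold_boundary(self):
        # R slightly above 1 - tau_R stays non-destructive; slightly below flips
        high = _make_table([0, 10, 20], [1e7, 0.87e7, 0.87e7], [0, 15, 20])
        low = _make_table([0, 10, 20], [1e7, 0.83e7, 0.83e7], [0, 15, 20])
        assert classify_mode(high, tau_R=0.15).label == "bundle_drifting"
        assert classify_mode(low, tau_R=0.15).label == "intrinsic_destruction"

    def test_width_threshold_boundary(self):
        narrow = _make_table([0, 10, 20], [1e7, 1e7, 1e7], [0, 4, 9.9])
        wide = _make_table([0, 10, 20], [1e7, 1e7, 1e7], [0, 4, 10.1])
        assert classify_mode(narrow, tau_W_pct=10.0).label == "inert"
        assert classify_mode(wide, tau_W_pct=10.0).label == "bundle_drifting"

    def test_thresholds_recorded_in_result(self):
        res = classify_mode(_make_table([0, 10, 20], [1e7, 1e7, 1e7], [0, 0, 1]),
                            tau_R=0.2, tau_W_pct=12.0)
        assert res.tau_R == 0.2 and res.tau_W_pct == 12.0

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        ratios=st.lists(st.floats(0.05, 2.0), min_size=2, max_size=8),
        w_max=st.floats(-5.0, 80.0),
        tau_R=st.floats(0.05, 0.4),
        tau_W=st.floats(1.0, 30.0),
    )
    def test_label_consistent_with_recomputed_statistics(self, ratios, w_max, tau_R, tau_W):
        """Whatever the trajectory, the label follows from (R, W) alone."""
        isum = [1e7] + [1e7 * r for r in ratios]
        dw = np.linspace(0.0, w_max, len(isum))
        traj = _make_table(np.arange(len(isum)) * 5.0, isum, dw)
        res = classify_mode(traj, tau_R=tau_R, tau_W_pct=tau_W)
        r_stat = float(np.median(ratios))
        w_stat = float(dw.max())
        if r_stat < 1 - tau_R:
            expected = "intrinsic_destruction"
        elif w_stat >= tau_W:
            expected = "bundle_drifting"
        else:
            expected = "inert"
        assert res.label == expected
        assert res.retention_R == pytest.approx(r_stat)
        assert res.width_gain_W_pct == pytest.approx(w_stat)

    def test_phantom_modes_recovered(self, dilution_trajectory, destruction_trajectory):
        assert classify_mode(dilution_trajectory).label == "bundle_drifting"
        assert classify_mode(destruction_trajectory).label == "intrinsic_destruction"
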