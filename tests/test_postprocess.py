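"""Slice averaging, pressure gradients and the remodeling summary."""

import numpy as np
import pandas as pd
import pytest

from archstent.anatomy import AnatomyConfig, build_dissected_aorta
from archstent.lbm import FlowField, voxelize
from archstent.postprocess import (SliceProfile, branch_slices,
                                   phase_samples, pressure_gradient_metric,
                                   remodeling_summary, slice_averages)


@pytest.fixture(scope="module")
def split_tube():
    """Straight tube with a mid-plane flap: distinct TL and FL channels."""
    return build_dissected_aorta(AnatomyConfig(
        arch_radius=float("inf"), ascending_length=50, descending_length=50,
        wall_inner_diameter=20.0, flap_angular_extent_deg=170,
        flap_axial_start=0.0, flap_axial_extent=1.0, flap_taper_fraction=0.0,
        tl_min_diameter=8.0, flap_thickness=1.0, branch_positions=(),
        branch_diameters=(), surface_resolution=2.0))


def _field(model, fill):
    """Synthetic FlowField over a voxelized model; ``fill(pts_mm, region)``
    returns (velocity (n,3) m/s, pressure (n,) Pa)."""
    lat = voxelize(model, 2.0e-3)
    coords = np.argwhere(lat.flags != 0)
    pts = (lat.origin + (coords + 0.5) * lat.dx) * 1000.0
    region = lat.region[tuple(coords.T)]
    vel, pres = fill(pts, region)
    times = np.array([0.0, 0.4])
    return FlowField(lattice=lat, times=times, cycle=np.array([0, 0]),
                     velocity=np.stack([vel, vel]).astype(np.float32),
                     pressure=np.stack([pres, pres]).astype(np.float32),
                     fluid_index=coords)


PHASES = {"systole": 0, "diastole": 1}


class TestSliceAverages:
    def test_uniform_field_recovers_the_value(self, split_tube):
        def fill(pts, region):
            v = np.zeros((len(pts), 3))
            v[:, 2] = 0.37
            return v, np.full(len(pts), 1234.5)
        prof = slice_averages(_field(split_tube, fill), split_tube.centerline,
                              n_slices=10, phases=PHASES)
        assert np.allclose(prof.table.mean_velocity, 0.37, atol=1e-5)
        assert np.allclose(prof.table.mean_pressure, 1234.5, atol=1e-2)

    def test_linear_pressure_is_linear_in_slice_position(self, split_tube):
        G = 50.0   # Pa/mm along z
        def fill(pts, region):
            return np.zeros((len(pts), 3)), G * pts[:, 2]
        prof = slice_averages(_field(split_tube, fill), split_tube.centerline,
                              n_slices=10, phases=PHASES)
        tl = prof.series("TL", "systole", "mean_pressure")
        smid = prof.table[(prof.table.region == "TL")
                          & (prof.table.phase == "systole")].s_mid.values
        fitted = np.polyfit(smid, tl.values, 1)
        assert fitted[0] == pytest.approx(G, rel=0.01)
        resid = tl.values - np.polyval(fitted, smid)
        assert np.abs(resid).max() < 0.01 * np.ptp(tl.values)

    def test_two_channel_values_recovered_exactly(self, split_tube):
        def fill(pts, region):
            v = np.zeros((len(pts), 3))
            v[:, 2] = np.where(region == 1, 0.5, 0.125)
            p = np.where(region == 1, 9000.0, 7000.0)
            return v, p
        prof = slice_averages(_field(split_tube, fill), split_tube.centerline,
                              n_slices=8, phases=PHASES)
        t = prof.table
        assert np.allclose(t[t.region == "TL"].mean_velocity, 0.5, atol=1e-6)
        assert np.allclose(t[t.region == "FL"].mean_velocity, 0.125, atol=1e-6)
        assert np.allclose(t[t.region == "TL"].mean_pressure, 9000.0)
        assert np.allclose(t[t.region == "FL"].mean_pressure, 7000.0)

    def test_empty_slices_are_missing_not_zero(self, split_tube):
        def fill(pts, region):
            return np.zeros((len(pts), 3)), np.zeros(len(pts))
        field = _field(split_tube, fill)
        # restrict to a nonexistent branch: every slice lacks cells
        prof = slice_averages(field, split_tube.centerline, n_slices=5,
                              phases=PHASES, restrict_branch=7)
        assert len(prof.table) == 0


class TestPressureGradient:
    def test_uniform_pressure_gives_zero(self, split_tube):
        def fill(pts, region):
            return np.zeros((len(pts), 3)), np.full(len(pts), 500.0)
        prof = slice_averages(_field(split_tube, fill), split_tube.centerline,
                              n_slices=20, phases=PHASES)
        assert pressure_gradient_metric(prof) == pytest.approx(0.0, abs=1e-2)

    def test_linear_gradient_recovers_group_distance(self, split_tube):
        G = 12.0    # Pa/mm
        L = split_tube.centerline.length
        def fill(pts, region):
            return np.zeros((len(pts), 3)), -G * pts[:, 2]
        prof = slice_averages(_field(split_tube, fill), split_tube.centerline,
                              n_slices=20, phases=PHASES)
        # slice centers sit at (k - 1/2) L/20, so the group centers
        # (slices 1-3 vs 18-20) are 17/20 L apart
        expect = G * L * 17 / 20
        assert pressure_gradient_metric(prof) == pytest.approx(expect, rel=0.02)

    def test_missing_slices_raise(self, split_tube):
        prof = SliceProfile("aorta", 20, pd.DataFrame(
            columns=["slice", "s_mid", "phase", "region", "mean_velocity",
                     "mean_pressure", "n_cells"]))
        with pytest.raises(ValueError):
            pressure_gradient_metric(prof)


class TestBranchSlices:
    def test_zero_flow_gives_zero_branch_means(self, aorta):
        def fill(pts, region):
            return np.zeros((len(pts), 3)), np.zeros(len(pts))
        field = _field(aorta, fill)
        out = branch_slices(field, aorta, PHASES)
        assert set(out) == {b.name for b in aorta.branches}
        for prof in out.values():
            assert np.allclose(prof.table.mean_velocity, 0.0)


class TestRemodelingSummary:
    def test_baseline_change_is_zero_and_gaps_are_explicit(self, aorta):
        table = remodeling_summary(aorta, {0.1: None})
        base = table[table.configuration == "non-stented"].iloc[0]
        assert base.fl_change_pct == 0.0
        gap = table[table.configuration == "stented 1:0.1"].iloc[0]
        assert np.isnan(gap.get("fl_volume_mm3", np.nan))

    def test_summary_tabulates_deployed_metrics(self, aorta, deployed_states):
        table = remodeling_summary(aorta, deployed_states)
        assert len(table) == 4
        stented = table[table.configuration != "non-stented"]
        assert (stented.fl_change_pct < 0).all()
        assert (stented.max_von_mises_MPa > 0).all()


def test_phase_samples_picks_systole_and_diastole(aorta, flow_fields,
                                                  inlet_waveform):
    ph = phase_samples(flow_fields["non-stented"], inlet_waveform)
    f = flow_fields["non-stented"]
    T = inlet_waveform.period
    v_sys = inlet_waveform(np.mod(f.times[ph["systole"]], T))
    v_dia = inlet_waveform(np.mod(f.times[ph["diastole"]], T))
    assert v_sys > v_dia
    assert f.cycle[ph["systole"]] == f.analysis_cycle
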