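"""Monodomain solver: operator structure, quiescence, CV physics, lesions."""

import numpy as np
import pytest

from conftest import make_uniform_substrate
from latwin.myocyte import ConductanceScaling, ModelError
from latwin.tissue import (ConductionBlock, StimulusEvent, apply_lesions,
                           build_grid, build_scaling_field,
                           calibrate_diffusion, lesion_mask_rings,
                           measure_cv, run)


class TestOperator:
    def test_zero_row_sums(self):
        grid = build_grid(make_uniform_substrate(nx=16, ny=16,
                                                 fiber_angle_deg=30.0))
        rowsum = np.abs(np.asarray(grid.laplacian.sum(axis=1))).max()
        assert rowsum < 1e-12  # conservation incl. no-flux boundaries

    def test_lesion_nodes_decoupled(self):
        n = 16 * 16
        lesion = np.zeros(n, dtype=bool)
        lesion[40] = True
        grid = build_grid(make_uniform_substrate(nx=16, ny=16,
                                                 lesion_mask=lesion))
        lap = grid.laplacian.tocsr()
        assert lap[40].nnz == 0
        assert lap[:, 40].nnz == 0

    def test_fiber_rotation_swaps_principal_axes(self):
        g0 = build_grid(make_uniform_substrate(nx=12, ny=12,
                                               fiber_angle_deg=0.0))
        g90 = build_grid(make_uniform_substrate(nx=12, ny=12,
                                                fiber_angle_deg=90.0))
        # coupling of a central node to its x-neighbor under 0 deg equals
        # its coupling to the y-neighbor under 90 deg
        c = 5 * 12 + 5
        assert g0.laplacian[c, c + 1] == pytest.approx(
            g90.laplacian[c, c + 12], rel=1e-12)
        assert g0.laplacian[c, c + 1] > g0.laplacian[c, c + 12]  # anisotropy

    def test_spd_tensor_symmetric_coupling(self):
        grid = build_grid(make_uniform_substrate(nx=10, ny=10,
                                                 fiber_angle_deg=37.0))
        asym = np.abs((grid.laplacian - grid.laplacian.T)).max()
        assert asym < 1e-12


class TestRun:
    def test_quiescence_without_stimulus(self):
        grid = build_grid(make_uniform_substrate(nx=20, ny=20))
        trace = run(grid, t_end_ms=2000.0, dt=0.1, record_dt_ms=20.0)
        drift = np.ptp(trace.frames.astype(float), axis=0).max()
        assert drift < 0.5
        assert trace.act_counts.sum() == 0

    def test_determinism_bit_identical(self):
        grid = build_grid(make_uniform_substrate(nx=16, ny=8))
        stim = [StimulusEvent(np.arange(8), 5.0, 2.0, 40.0)]
        t1 = run(grid, stimuli=stim, t_end_ms=150.0, dt=0.05)
        t2 = run(grid, stimuli=stim, t_end_ms=150.0, dt=0.05)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.act_times, t2.act_times, equal_nan=True)

    def test_dt_beyond_cfl_rejected(self):
        grid = build_grid(make_uniform_substrate(nx=8, ny=8, spacing_mm=0.1))
        with pytest.raises(ModelError, match="CFL"):
            run(grid, t_end_ms=10.0, dt=0.1)

    def test_circular_isochrones_on_isotropic_sheet(self):
        sub = make_uniform_substrate(nx=41, ny=41, spacing_mm=0.25)
        sub.sigma_t = sub.sigma_l.copy()  # isotropic
        grid = build_grid(sub)
        site = grid.disc_nodes(5.0, 5.0, 0.5)
        trace = run(grid, stimuli=[StimulusEvent(site, 2.0, 2.0, 80.0)],
                    t_end_ms=60.0, dt=0.05, record_dt_ms=1e9, max_act=4)
        first = np.where(trace.act_counts > 0, trace.act_times[:, 0], np.nan)
        pts = sub.mesh.points
        d = np.hypot(pts[:, 0] - 5.0, pts[:, 1] - 5.0)
        t_ref = np.nanmedian(first[np.abs(d - 3.0) < 0.2])
        iso = np.isfinite(first) & (np.abs(first - t_ref) < 0.4)
        assert iso.sum() > 20
        # isochrone radius per angular sector; eccentricity = spread of
        # sector radii (per-node max/min would measure band width instead)
        ang = np.arctan2(pts[iso, 1] - 5.0, pts[iso, 0] - 5.0)
        sector = np.floor((ang + np.pi) / (np.pi / 4)).astype(int) % 8
        radii = np.array([d[iso][sector == s].mean() for s in range(8)])
        ecc = radii.max() / radii.min()
        assert ecc < 1.1


@pytest.fixture(scope="module")
def strip():
    return make_uniform_substrate(nx=60, ny=10, spacing_mm=0.25)


class TestConductionVelocity:

    def test_cv_sqrt_d_scaling(self):
        # fine grid so the wavefront stays resolved over the 4x D range
        sub = make_uniform_substrate(nx=100, ny=8, spacing_mm=0.1)
        grid = build_grid(sub)
        cvs = {s: measure_cv(grid.with_scale(s), dt=0.005)
               for s in (1.0, 2.0, 4.0)}
        for s in (1.0, 2.0):
            expected = cvs[4.0] * np.sqrt(s / 4.0)
            assert cvs[s] == pytest.approx(expected, rel=0.05)

    def test_cv_anisotropy(self):
        # along fibers vs across fibers when sigma_l > sigma_t
        sub_l = make_uniform_substrate(nx=60, ny=10, fiber_angle_deg=0.0)
        sub_t = make_uniform_substrate(nx=60, ny=10, fiber_angle_deg=90.0)
        cv_l = measure_cv(build_grid(sub_l), dt=0.05)
        cv_t = measure_cv(build_grid(sub_t), dt=0.05)
        assert cv_l > cv_t

    def test_fibrotic_tissue_conducts_slower(self, strip):
        fib = make_uniform_substrate(nx=60, ny=10, spacing_mm=0.25,
                                     fibrotic=True)
        cv_n = measure_cv(build_grid(strip), dt=0.05)
        cv_f = measure_cv(build_grid(fib), dt=0.05)
        assert cv_f < cv_n

    def test_conduction_block_reported(self, strip):
        grid = build_grid(strip).with_scale(1e-4)
        with pytest.raises(ConductionBlock):
            measure_cv(grid, dt=0.05)


class TestCalibrateDiffusion:
    def test_fixed_point(self):
        grid = build_grid(make_uniform_substrate(nx=60, ny=10))
        cv1 = measure_cv(grid, dt=0.05)
        s = calibrate_diffusion(grid, target_cv_mps=cv1, bracket=(0.3, 3.0),
                                tol=0.02, dt=0.05)
        assert s == pytest.approx(1.0, rel=0.1)
        cv_s = measure_cv(grid.with_scale(s), dt=0.05)
        assert cv_s == pytest.approx(cv1, rel=0.02)

    def test_unreachable_target_reports_extremes(self):
        grid = build_grid(make_uniform_substrate(nx=60, ny=10))
        from latwin.tissue import CalibrationError

        with pytest.raises(CalibrationError, match="achievable range"):
            calibrate_diffusion(grid, target_cv_mps=10.0, bracket=(0.5, 2.0),
                                dt=0.05)


class TestLesions:
    def test_closed_ring_blocks_conduction(self):
        sub = make_uniform_substrate(nx=40, ny=40, spacing_mm=0.25)
        grid = build_grid(sub)
        cx = cy = 20 * 0.25
        grid = apply_lesions(grid, rings=[(cx, cy, 2.0, 1.0)])
        edge = np.flatnonzero(np.arange(40 * 40) % 40 == 0)
        trace = run(grid, stimuli=[StimulusEvent(edge, 2.0, 2.0, 40.0)],
                    t_end_ms=300.0, dt=0.05, record_dt_ms=1e9, max_act=4)
        pts = sub.mesh.points
        inside = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) < 1.2
        inside &= grid.active
        assert inside.sum() > 10
        assert trace.act_counts[inside].sum() == 0  # distal side silent
        outside = ~inside & grid.active & (pts[:, 0] > 7.0)
        assert trace.act_counts[outside].mean() > 0.9  # wave went around

    def test_ring_thickness_matches_width(self):
        # 2 mm width at 235 um spacing -> >= 8 nodes across the annulus
        sub = make_uniform_substrate(nx=60, ny=60, spacing_mm=0.235)
        mask = lesion_mask_rings(sub.mesh, rings=[(7.0, 7.0, 4.0, 2.0)])
        iy = 7.0 / 0.235
        row = mask.reshape(60, 60)[int(round(iy))]
        runs = np.diff(np.flatnonzero(np.diff(row.astype(int)) != 0))
        thickness = row.sum() / 2  # two crossings of the annulus
        assert thickness >= 8

    def test_empty_lesion_spec_is_identity(self):
        grid = build_grid(make_uniform_substrate(nx=12, ny=12))
        grid2 = apply_lesions(grid)
        assert np.array_equal(grid.active, grid2.active)
        assert (grid.laplacian != grid2.laplacian).nnz == 0

    def test_total_lesion_rejected(self):
        grid = build_grid(make_uniform_substrate(nx=8, ny=8, spacing_mm=0.25))
        with pytest.raises(ModelError, match="all tissue"):
            apply_lesions(grid, holes=[(1.0, 1.0, 100.0)])


def test_scaling_field_composition():
    sub = make_uniform_substrate(nx=6, ny=6)
    sub.fibrotic[5] = True
    rem = ConductanceScaling.af_remodeling()
    field = build_scaling_field(sub, rem)
    from latwin.myocyte import CHANNEL_INDEX

    ik1 = CHANNEL_INDEX["IK1"]
    ina = CHANNEL_INDEX["INa"]
    assert field[ik1, 0] == pytest.approx(2.0)
    assert field[ik1, 5] == pytest.approx(2.0 * 0.5)   # remodeling x fibrosis
    assert field[ina, 5] == pytest.approx(0.6)
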