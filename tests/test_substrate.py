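"""Substrate construction: IDW, fibrosis probability, fibers, conductivity, regions."""

import numpy as np
import pytest

from latwin.myocyte import ModelError
from latwin.substrate import (CONDUCTIVITY_TABLE, REGION_NAMES, SheetMesh,
                              VoltagePointCloud, assign_conductivity,
                              assign_fibrosis, build_fiber_field,
                              build_substrate, fibrosis_probability,
                              idw_interpolate, segment_regions)


class TestIDW:
    def test_exact_at_sample_point(self):
        cloud = VoltagePointCloud([[0, 0, 0], [3, 0, 0]], [1.2, 0.4])
        vals, cov = idw_interpolate(cloud, [[0, 0, 0]], radius_mm=10)
        assert vals[0] == pytest.approx(1.2, abs=1e-12)
        assert cov[0]

    def test_equidistant_average(self):
        cloud = VoltagePointCloud([[0, 0, 0], [2, 0, 0]], [1.0, 2.0])
        vals, _ = idw_interpolate(cloud, [[1, 0, 0]], radius_mm=10)
        assert vals[0] == pytest.approx(1.5, rel=1e-12)

    def test_hand_computed_two_point_case(self):
        # distances 1 and 2 to samples 0 and 3 mV, power 2 -> 0.6 mV
        cloud = VoltagePointCloud([[1, 0, 0], [-2, 0, 0]], [0.0, 3.0])
        vals, _ = idw_interpolate(cloud, [[0, 0, 0]], radius_mm=10, power=2)
        assert vals[0] == pytest.approx(0.6, rel=1e-12)

    def test_bounded_by_sample_extrema(self, rng):
        pts = rng.uniform(0, 10, size=(40, 3))
        vals = rng.uniform(0, 2, size=40)
        cloud = VoltagePointCloud(pts, vals)
        nodes = rng.uniform(0, 10, size=(200, 3))
        out, cov = idw_interpolate(cloud, nodes, radius_mm=4)
        sel = cov
        assert np.all(out[sel] >= vals.min() - 1e-12)
        assert np.all(out[sel] <= vals.max() + 1e-12)

    def test_uncovered_nodes_flagged_and_filled(self):
        cloud = VoltagePointCloud([[0, 0, 0]], [1.5])
        vals, cov = idw_interpolate(cloud, [[50, 0, 0]], radius_mm=10)
        assert not cov[0]
        assert vals[0] == 1.5  # nearest-sample fallback

    def test_empty_cloud_rejected(self):
        with pytest.raises(ModelError):
            VoltagePointCloud(np.empty((0, 3)), [])

    def test_invalid_params_rejected(self):
        cloud = VoltagePointCloud([[0, 0, 0]], [1.0])
        with pytest.raises(ModelError):
            idw_interpolate(cloud, [[0, 0, 0]], radius_mm=0)
        with pytest.raises(ModelError):
            idw_interpolate(cloud, [[0, 0, 0]], power=0)


class TestFibrosisProbability:
    @pytest.mark.parametrize("v,expected", [
        (-0.5, 1.0),          # negative voltage branch
        (2.0, 0.0),           # above 1.74 mV
        (0.0, 0.998),         # cubic at 0: 99.8/100
    ])
    def test_branch_values(self, v, expected):
        assert fibrosis_probability(v) == pytest.approx(expected, abs=1e-12)

    def test_clamped_at_upper_boundary(self):
        # raw cubic at 1.74 is slightly negative (~ -8.3e-4); clamped to 0
        raw = (-40 * 1.74 ** 3 + 155 * 1.74 ** 2 - 206 * 1.74 + 99.8) / 100
        assert raw < 0
        assert fibrosis_probability(1.74) == 0.0

    def test_monotone_nonincreasing_on_active_range(self):
        v = np.linspace(0, 1.74, 2001)
        p = fibrosis_probability(v)
        assert np.all(np.diff(p) <= 1e-12)
        assert np.all((p >= 0) & (p <= 1))

    def test_nonfinite_rejected(self):
        with pytest.raises(ModelError):
            fibrosis_probability(np.nan)


class TestAssignFibrosis:
    def test_degenerate_probabilities(self):
        assert not assign_fibrosis(np.full(500, 5.0), seed=1).any()
        assert assign_fibrosis(np.full(500, -1.0), seed=1).all()

    def test_binomial_concentration(self):
        v = np.full(100_000, 0.5)
        p = fibrosis_probability(0.5)
        frac = assign_fibrosis(v, seed=42).mean()
        se = np.sqrt(p * (1 - p) / v.size)
        assert abs(frac - p) < 3 * se

    def test_seeded_reproducibility(self):
        v = np.random.default_rng(0).uniform(0, 1.7, 1000)
        a = assign_fibrosis(v, seed=7)
        b = assign_fibrosis(v, seed=7)
        c = assign_fibrosis(v, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestFiberField:
    def test_uniform_zero_angle(self):
        mesh = SheetMesh(8, 8, 0.5)
        vec = build_fiber_field(mesh, "uniform", {"angle_deg": 0})
        assert np.allclose(vec, [1, 0, 0])

    def test_circular_orthogonal_to_radius(self):
        mesh = SheetMesh(16, 16, 0.5)
        vec = build_fiber_field(mesh, "circular")
        lx, ly = mesh.extent_mm
        radial = mesh.points - [lx / 2, ly / 2, 0]
        dots = np.abs(np.einsum("ij,ij->i", vec, radial))
        assert dots.max() < 1e-9

    @pytest.mark.parametrize("mode", ["uniform", "circular", "atlas_like"])
    def test_unit_norm(self, mode):
        mesh = SheetMesh(12, 9, 0.4)
        vec = build_fiber_field(mesh, mode)
        assert np.max(np.abs(np.linalg.norm(vec, axis=1) - 1)) < 1e-12

    def test_unknown_mode_rejected(self):
        with pytest.raises(ModelError):
            build_fiber_field(SheetMesh(4, 4, 1.0), "spiral")


class TestConductivity:
    def test_table_values(self):
        sl, st_ = assign_conductivity(np.array([False, True]))
        assert sl[0] == 0.1264 and st_[0] == 0.0252
        assert sl[1] == 0.0546 and st_[1] == 0.0068
        assert sl[0] / st_[0] == pytest.approx(5.02, abs=0.01)

    def test_all_fibrotic_exhaustive(self):
        sl, st_ = assign_conductivity(np.ones(50, dtype=bool))
        assert np.all(sl == 0.0546) and np.all(st_ == 0.0068)

    def test_missing_entry_rejected(self):
        bad = {k: v for k, v in CONDUCTIVITY_TABLE.items()
               if k != "fibrotic_transverse"}
        with pytest.raises(ModelError):
            assign_conductivity(np.zeros(3, dtype=bool), bad)


class TestRegions:
    def test_partition_of_non_lesion_nodes(self):
        mesh = SheetMesh(30, 20, 0.5)
        lesion = np.zeros(mesh.n_nodes, dtype=bool)
        lesion[:40] = True
        labels = segment_regions(mesh, lesion)
        assert (labels >= 0).sum() == mesh.n_nodes - 40
        counts = [(labels == r).sum() for r in range(6)]
        assert all(c > 0 for c in counts)
        assert sum(counts) == mesh.n_nodes - 40

    def test_deterministic(self):
        mesh = SheetMesh(30, 20, 0.5)
        assert np.array_equal(segment_regions(mesh), segment_regions(mesh))

    def test_empty_region_rejected_with_name(self):
        mesh = SheetMesh(12, 6, 0.5)
        lesion = np.zeros(mesh.n_nodes, dtype=bool)
        ix = np.arange(mesh.n_nodes) % 12
        iy = np.arange(mesh.n_nodes) // 12
        lesion[(ix < 4) & (iy >= 3)] = True  # wipe out left lateral isthmus
        with pytest.raises(ModelError, match="left_lateral_isthmus"):
            segment_regions(mesh, lesion)

    def test_six_region_names(self):
        assert len(REGION_NAMES) == 6
        assert REGION_NAMES[0] == "septum"


def test_build_substrate_chain(rng):
    mesh = SheetMesh(24, 24, 0.5)
    pts = rng.uniform(0, 11.5, size=(300, 2))
    cloud = VoltagePointCloud(np.column_stack([pts, np.zeros(300)]),
                              rng.uniform(0, 2.0, 300))
    sub = build_substrate(mesh, cloud, seed=5, fiber_mode="atlas_like")
    assert sub.voltage_mV.shape == (mesh.n_nodes,)
    assert sub.fibrotic.dtype == bool
    # fibrotic nodes should concentrate at low interpolated voltage
    lo = sub.voltage_mV < 0.5
    hi = sub.voltage_mV > 1.2
    if lo.any() and hi.any():
        assert sub.fibrotic[lo].mean() > sub.fibrotic[hi].mean()
    # round trip through the frame writer keeps values
    df = sub.to_frame()
    assert len(df) == mesh.n_nodes
    assert df["sigma_l_Spm"].isin([0.1264, 0.0546]).all()
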