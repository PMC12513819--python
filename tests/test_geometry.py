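"""Structure handling, ROI algebra and OVH/OZH descriptors."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import brute_ovh, brute_ozh, brute_signed_distance
from vmatplan.geometry import (
    AmbiguousTargetError,
    AuxiliaryConfig,
    Curve,
    GridMismatchError,
    ROIMask,
    StructureSet,
    VoxelGrid,
    compute_ovh,
    compute_ozh,
    contract,
    curve_auc,
    difference,
    expand,
    make_auxiliary_rois,
    resolve_roi_names,
    signed_distance_field,
    z_expand,
)

DICT = {
    "PTV_50.4": "ptv",
    "Lunge ges": "total_lung",
    "ptv": "ptv",
    "Herz": "heart",
}


class TestNameResolution:
    def test_direct_lookup_case_insensitive(self):
        mapping, unresolved = resolve_roi_names(["PTV_50.4", "lunge GES", "Herz"], DICT)
        assert mapping == {"PTV_50.4": "ptv", "lunge GES": "total_lung", "Herz": "heart"}
        assert unresolved == []

    def test_unknown_name_reported_unresolved(self):
        mapping, unresolved = resolve_roi_names(["Unknown_ROI"], DICT)
        assert mapping == {}
        assert unresolved == ["Unknown_ROI"]

    def test_two_targets_is_ambiguous(self):
        with pytest.raises(AmbiguousTargetError):
            resolve_roi_names(["ptv", "PTV_50.4"], DICT)


class TestSignedDistance:
    def test_face_neighbors_of_single_voxel(self, mask_factory):
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[2, 2, 2] = True
        d = signed_distance_field(mask_factory(occ))
        for delta in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            assert d[2 + delta[0], 2 + delta[1], 2 + delta[2]] == pytest.approx(1.0)
        assert d[2, 2, 2] < 0

    def test_cube_center_is_deep_inside(self, mask_factory):
        occ = np.zeros((7, 7, 7), dtype=bool)
        occ[1:6, 1:6, 1:6] = True
        d = signed_distance_field(mask_factory(occ))
        assert d[3, 3, 3] <= -2.0

    def test_all_true_mask_is_nonpositive(self, mask_factory):
        d = signed_distance_field(mask_factory(np.ones((4, 4, 4), dtype=bool)))
        assert (d <= 0).all()

    def test_empty_mask_raises(self, mask_factory):
        with pytest.raises(ValueError, match="empty"):
            signed_distance_field(mask_factory(np.zeros((3, 3, 3), dtype=bool)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_all_pairs_oracle(self, mask_factory, seed):
        rng = np.random.default_rng(seed)
        occ = rng.random((8, 8, 8)) < 0.3
        occ[4, 4, 4] = True  # keep non-empty
        spacing = (1.0, 2.0, 1.5)
        d = signed_distance_field(mask_factory(occ, spacing=spacing))
        expected = brute_signed_distance(occ, spacing)
        sel = np.isfinite(expected)
        np.testing.assert_allclose(d[sel], expected[sel], atol=1e-9)


class TestRoiAlgebra:
    def test_expand_zero_is_identity(self, mask_factory):
        occ = np.zeros((6, 6, 6), dtype=bool)
        occ[2:4, 2:4, 2:4] = True
        m = mask_factory(occ)
        assert (expand(m, 0.0).voxels == occ).all()
        assert (contract(m, 0.0).voxels == occ).all()

    def test_difference_with_self_is_empty(self, mask_factory):
        occ = np.ones((4, 4, 4), dtype=bool)
        m = mask_factory(occ)
        assert difference(m, m).is_empty()

    def test_contract_of_expand_covers_original_sphere(self, mask_factory):
        # convex mask on a fine grid: closing keeps every original voxel
        idx = np.indices((11, 11, 11))
        occ = ((idx - 5) ** 2).sum(axis=0) <= 9
        m = mask_factory(occ)
        closed = contract(expand(m, 2.0), 2.0)
        assert (closed.voxels | ~occ).all()

    def test_expand_is_monotone_in_the_operand(self, mask_factory):
        rng = np.random.default_rng(7)
        small = rng.random((8, 8, 8)) < 0.15
        small[3, 3, 3] = True
        big = small | (rng.random((8, 8, 8)) < 0.15)
        ea = expand(mask_factory(small), 2.0).voxels
        eb = expand(mask_factory(big), 2.0).voxels
        assert (eb | ~ea).all()

    def test_z_expand_extends_along_third_axis_only(self, mask_factory):
        occ = np.zeros((5, 5, 9), dtype=bool)
        occ[2, 2, 3:6] = True
        out = z_expand(mask_factory(occ), 2.0)  # 2 mm = 2 slices at 1 mm
        assert set(np.argwhere(out.voxels)[:, 2]) == {1, 2, 3, 4, 5, 6, 7}
        assert (np.argwhere(out.voxels)[:, :2] == [2, 2]).all()

    def test_mismatched_grids_raise(self, mask_factory):
        a = mask_factory(np.ones((4, 4, 4), dtype=bool))
        b = mask_factory(np.ones((4, 4, 4), dtype=bool), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(GridMismatchError):
            difference(a, b)


class TestAuxiliaryStructures:
    def _case(self, with_esophagus=True):
        grid = VoxelGrid((20, 20, 12), (1.0, 1.0, 1.0))
        ext = np.zeros(grid.shape, dtype=bool)
        ext[1:19, 1:19, 1:11] = True
        ptv = np.zeros(grid.shape, dtype=bool)
        ptv[8:12, 8:12, 4:8] = True
        rois = {
            "external": ROIMask(grid, ext, "external", "external"),
            "ptv": ROIMask(grid, ptv, "ptv", "target"),
        }
        if with_esophagus:
            eso = np.zeros(grid.shape, dtype=bool)
            eso[10, 14, 3:9] = True
            rois["esophagus"] = ROIMask(grid, eso, "esophagus", "oar")
        return StructureSet(grid, rois, 50.4)

    def test_skin_is_a_rind_of_the_external(self):
        out = make_auxiliary_rois(self._case(), AuxiliaryConfig(skin_rind_mm=1.0))
        skin = out["skin"]
        assert skin.role == "auxiliary"
        core = ndimage.binary_erosion(out["external"].voxels)
        np.testing.assert_array_equal(skin.voxels, out["external"].voxels & ~core)

    def test_esophagus_extension_spans_more_slices(self):
        out = make_auxiliary_rois(self._case(), AuxiliaryConfig(eso_z_mm=2.0))
        zs = np.argwhere(out["esophagus_ext"].voxels)[:, 2]
        assert zs.min() == 1 and zs.max() == 10  # 3..8 extended by 2 slices

    def test_missing_esophagus_is_skipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = make_auxiliary_rois(self._case(with_esophagus=False))
        assert "esophagus_ext" not in out
        assert any("esophagus" in r.message for r in caplog.records)

    def test_anterior_avoid_excludes_ptv_margin(self):
        out = make_auxiliary_rois(self._case(), AuxiliaryConfig(avoid_margin_mm=3.0))
        avoid = out["anterior_avoid"]
        grown = expand(out["ptv"], 3.0)
        assert not (avoid.voxels & grown.voxels).any()
        assert avoid.voxels.any()


class TestOverlapHistograms:
    WINDOW = (-10.0, 15.0)

    def test_oar_equal_to_ptv_is_one_from_zero(self, mask_factory):
        occ = np.zeros((8, 8, 8), dtype=bool)
        occ[3:6, 3:6, 3:6] = True
        m = mask_factory(occ)
        ovh = compute_ovh(m, mask_factory(occ, name="ptv", role="target"), self.WINDOW, 1.0)
        assert ovh.values[ovh.abscissa >= 0].min() == 1.0

    def test_disjoint_oar_zero_below_the_gap(self, mask_factory):
        oar = np.zeros((20, 5, 5), dtype=bool)
        ptv = np.zeros((20, 5, 5), dtype=bool)
        ptv[2, 2, 2] = True
        oar[9, 2, 2] = True  # 7 mm away
        curve = compute_ovh(mask_factory(oar), mask_factory(ptv), self.WINDOW, 1.0)
        assert (curve.values[curve.abscissa < 7] == 0).all()
        assert curve.values[curve.abscissa >= 7].min() == 1.0

    def test_three_voxel_toy_fraction(self, mask_factory):
        # OAR voxels at signed distances {-1, 2, 4} mm from the target
        ptv = np.zeros((12, 3, 3), dtype=bool)
        ptv[2:5, 1, 1] = True
        oar = np.zeros((12, 3, 3), dtype=bool)
        oar[3, 1, 1] = True   # inside, distance -1
        oar[6, 1, 1] = True   # +2
        oar[8, 1, 1] = True   # +4
        curve = compute_ovh(mask_factory(oar), mask_factory(ptv), self.WINDOW, 1.0)
        val_at = dict(zip(curve.abscissa, curve.values))
        assert val_at[2.0] == pytest.approx(2.0 / 3.0)
        assert val_at[-1.0] == pytest.approx(1.0 / 3.0)
        assert val_at[4.0] == 1.0

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_exhaustive_oracle(self, mask_factory, seed):
        rng = np.random.default_rng(seed)
        shape = (12, 10, 8)
        spacing = (2.0, 1.0, 3.0)
        ptv = rng.random(shape) < 0.1
        ptv[6, 5, 4] = True
        oar = rng.random(shape) < 0.15
        oar[2, 2, 2] = True
        ts = np.arange(-10.0, 16.0, 1.0)
        ovh = compute_ovh(mask_factory(oar, spacing), mask_factory(ptv, spacing), (-10, 15), 1.0)
        np.testing.assert_allclose(ovh.values, brute_ovh(oar, ptv, spacing, ts), atol=1e-12)
        ozh = compute_ozh(mask_factory(oar, spacing), mask_factory(ptv, spacing), (-10, 15), 1.0)
        np.testing.assert_allclose(
            ozh.values, brute_ozh(oar, ptv, spacing, 0.0, ts), atol=1e-12
        )

    def test_ozh_limits(self, mask_factory):
        ptv = np.zeros((4, 4, 20), dtype=bool)
        ptv[1, 1, 5:10] = True
        inside = np.zeros((4, 4, 20), dtype=bool)
        inside[2, 2, 6:9] = True
        caudal = np.zeros((4, 4, 20), dtype=bool)
        caudal[2, 2, 0] = True  # 5 slices = 5 mm below the PTV extent
        w = (-10.0, 15.0)
        c_in = compute_ozh(mask_factory(inside), mask_factory(ptv), w, 1.0)
        assert c_in.values[c_in.abscissa == 0.0][0] == 1.0
        c_out = compute_ozh(mask_factory(caudal), mask_factory(ptv), w, 1.0)
        assert (c_out.values[c_out.abscissa < 5] == 0).all()
        assert c_out.values[c_out.abscissa >= 5].min() == 1.0

    def test_half_overlapping_slab_is_half(self, mask_factory):
        ptv = np.zeros((4, 4, 16), dtype=bool)
        ptv[1, 1, 0:8] = True
        slab = np.zeros((4, 4, 16), dtype=bool)
        slab[2, 2, 4:12] = True  # half inside the PTV z-interval
        c = compute_ozh(mask_factory(slab), mask_factory(ptv), (-10, 15), 1.0)
        assert c.values[c.abscissa == 0.0][0] == pytest.approx(0.5)

    def test_monotone_and_bounded_on_phantom(self, planar_case):
        for organ in ("total_lung", "heart"):
            curve = compute_ovh(planar_case[organ], planar_case.ptv, (-50, 200), 1.0)
            assert (np.diff(curve.values) >= 0).all()
            assert curve.values[-1] == 1.0  # window beyond the max distance
            ozh = compute_ozh(planar_case[organ], planar_case.ptv, (-50, 200), 1.0)
            assert (np.diff(ozh.values) >= 0).all()

    def test_empty_inputs_raise(self, mask_factory):
        full = mask_factory(np.ones((3, 3, 3), dtype=bool))
        empty = mask_factory(np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError):
            compute_ovh(empty, full)
        with pytest.raises(ValueError):
            compute_ovh(full, empty)


class TestCurveAuc:
    @pytest.mark.parametrize(
        "values,expected",
        [(lambda t: np.ones_like(t), 1.0), (lambda t: np.zeros_like(t), 0.0)],
    )
    def test_constants(self, values, expected):
        t = np.linspace(0, 10, 11)
        assert curve_auc(Curve(t, values(t))) == expected

    def test_linear_ramp_is_half(self):
        t = np.linspace(-50, 100, 151)
        ramp = (t - t[0]) / (t[-1] - t[0])
        assert curve_auc(Curve(t, ramp)) == pytest.approx(0.5)

    def test_invariant_under_refinement_for_piecewise_linear(self):
        coarse = np.linspace(0, 10, 6)
        fine = np.linspace(0, 10, 101)
        f = lambda t: np.clip(t / 10, 0, 1)
        assert curve_auc(Curve(coarse, f(coarse))) == pytest.approx(
            curve_auc(Curve(fine, f(fine))), abs=1e-12
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            curve_auc(Curve(np.array([1.0]), np.array([0.5])))
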