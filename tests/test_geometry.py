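import numpy as np
import pytest

from oartsim.geometry import (
    EmptyRestrictionError,
    GridGeometry,
    StructureMask,
    adjusted_local_hausdorff,
    contract,
    dice,
    directed_hausdorff,
    equivalent_sphere_radius,
    expand,
    make_sphere,
    margin_sweep,
    surface_voxels,
    volume_of,
)


def sphere_volume_ml(radius_mm: float) -> float:
    return 4.0 / 3.0 * np.pi * radius_mm**3 / 1000.0


# ---------------------------------------------------------------------------
# grid containers


class TestGridGeometry:
    def test_roundtrip_mm_indices(self, geom2):
        pts = np.array([[10.0, 30.0, 55.5], [0.0, 0.0, 0.0]])
        assert np.allclose(geom2.indices_to_mm(geom2.mm_to_indices(pts)), pts)

    def test_voxel_volume(self, geom2):
        assert geom2.voxel_volume_mm3 == pytest.approx(8.0)

    def test_rejects_degenerate_grids(self):
        with pytest.raises(ValueError):
            GridGeometry((4, 60, 60))
        with pytest.raises(ValueError):
            GridGeometry((60, 60, 60), (0.0, 1.0, 1.0))

    def test_anisotropic_spacing_respected(self):
        g = GridGeometry((20, 20, 20), (1.0, 2.0, 3.0))
        assert g.indices_to_mm(np.array([[1, 1, 1]]))[0] == pytest.approx([1.0, 2.0, 3.0])


class TestStructureMask:
    def test_shape_mismatch_rejected(self, geom2):
        with pytest.raises(ValueError):
            StructureMask(geom2, np.zeros((10, 10, 10), dtype=bool))

    def test_centroid_of_digitized_sphere(self, geom2, sphere20):
        assert np.allclose(sphere20.centroid_mm(), (59.3, 58.1, 60.7), atol=0.5)

    def test_centroid_of_empty_raises(self, geom2):
        empty = StructureMask(geom2, np.zeros(geom2.shape, dtype=bool))
        with pytest.raises(ValueError):
            empty.centroid_mm()


# ---------------------------------------------------------------------------
# volumes


class TestVolumes:
    def test_sphere_volume_oracle(self, geom2, sphere20):
        assert volume_of(sphere20) == pytest.approx(sphere_volume_ml(20.0), rel=0.02)

    def test_equivalent_sphere_radius_inverts_volume(self):
        for r in (5.0, 17.3, 42.0):
            assert equivalent_sphere_radius(sphere_volume_ml(r)) == pytest.approx(r)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            equivalent_sphere_radius(-1.0)


# ---------------------------------------------------------------------------
# margin morphology


class TestContractExpand:
    # the subvoxel estimator localizes the interface to better than
    # spacing/6, so a sphere of resulting radius r is recovered to a relative
    # volume tolerance of 3 * (spacing/6) / r

    def test_contract_sphere_matches_closed_form(self, geom2, sphere20):
        for m in (4.0, 5.0, 8.0):
            r = 20.0 - m
            got = volume_of(contract(sphere20, m))
            assert got == pytest.approx(sphere_volume_ml(r), rel=geom2.spacing[0] / (2 * r))

    def test_expand_sphere_matches_closed_form(self, geom2, sphere20):
        for m in (4.0, 5.0, 8.0):
            r = 20.0 + m
            got = volume_of(expand(sphere20, m))
            assert got == pytest.approx(sphere_volume_ml(r), rel=geom2.spacing[0] / (2 * r))

    def test_contract_expand_converge_with_resolution(self, geom1_small):
        # at 1 mm the same bound is twice as tight
        s = make_sphere(geom1_small, (39.3, 38.1, 40.7), 20.0)
        for m in (4.0, 8.0):
            vc = volume_of(contract(s, m))
            ve = volume_of(expand(s, m))
            assert vc == pytest.approx(sphere_volume_ml(20.0 - m), rel=1.0 / (2 * (20.0 - m)))
            assert ve == pytest.approx(sphere_volume_ml(20.0 + m), rel=1.0 / (2 * (20.0 + m)))

    def test_raw_mode_is_coarser_but_sane(self, geom2, sphere20):
        # subvoxel=False is the fast path: centre-to-centre distances, biased
        # by roughly half a voxel in radius
        for m in (4.0, 8.0):
            vc = volume_of(contract(sphere20, m, subvoxel=False))
            assert vc == pytest.approx(sphere_volume_ml(20.0 - m), rel=0.20)
            assert vc > sphere_volume_ml(20.0 - m)  # erodes too little

    def test_expand_then_contract_recovers_convex_mask(self, geom2, sphere20):
        back = contract(expand(sphere20, 6.0), 6.0)
        assert dice(back, sphere20) > 0.98

    def test_zero_margin_is_identity(self, sphere20):
        assert np.array_equal(contract(sphere20, 0.0).voxels, sphere20.voxels)
        assert np.array_equal(expand(sphere20, 0.0).voxels, sphere20.voxels)

    def test_negative_margin_rejected(self, sphere20):
        with pytest.raises(ValueError):
            contract(sphere20, -1.0)
        with pytest.raises(ValueError):
            expand(sphere20, -1.0)

    def test_full_contraction_returns_flagged_empty(self, geom2, sphere20):
        with pytest.warns(UserWarning, match="empty"):
            gone = contract(sphere20, 25.0)
        assert gone.is_empty()
        assert gone.meta.get("vanished") is True

    def test_composed_contraction_approximates_single_step(self, blob):
        # each step re-digitizes the interface, so composition is only
        # approximately the single-step contraction
        comp = contract(contract(blob, 2.0), 2.0)
        single = contract(blob, 4.0)
        assert dice(comp, single) > 0.95
        assert volume_of(comp) == pytest.approx(volume_of(single), rel=0.05)

    def test_contract_expand_duality_on_blob(self, blob):
        # expanding the complement equals contracting the mask
        inv = StructureMask(blob.geometry, ~blob.voxels, "inv")
        grown = expand(inv, 4.0)
        assert np.array_equal(~grown.voxels, contract(blob, 4.0).voxels)


class TestMarginSweep:
    def test_nesting_exact(self, sphere20):
        margins = (2.0, 5.0, 9.0, 13.0)
        sweep = margin_sweep(sphere20, margins)
        for m1, m2 in zip(margins, margins[1:]):
            inner, outer = sweep.ctvs[m2], sweep.ctvs[m1]
            assert not (inner.voxels & ~outer.voxels).any()

    def test_matches_individual_contractions(self, sphere20):
        sweep = margin_sweep(sphere20, (3.0, 7.0))
        for m in (3.0, 7.0):
            assert np.array_equal(sweep.ctvs[m].voxels, contract(sphere20, m).voxels)

    def test_vanished_margins_flagged(self, sphere20):
        sweep = margin_sweep(sphere20, (5.0, 30.0))
        assert sweep.ctvs[30.0].is_empty()
        assert sweep.ctvs[30.0].meta.get("vanished") is True

    def test_unsorted_margins_rejected(self, sphere20):
        with pytest.raises(ValueError):
            margin_sweep(sphere20, (5.0, 2.0))


# ---------------------------------------------------------------------------
# surface distances


class TestSurfaceDistances:
    def test_surface_voxels_of_sphere_form_thin_shell(self, geom2, sphere20):
        surf = surface_voxels(sphere20)
        n = int(sphere20.voxels.sum())
        # shell area ~ 4 pi r^2 / spacing^2 voxels
        expected = 4.0 * np.pi * 20.0**2 / 4.0
        assert surf.sum() == pytest.approx(expected, rel=0.35)
        assert (surf & ~sphere20.voxels).sum() == 0
        assert surf.sum() < n

    def test_concentric_spheres_hausdorff_equals_radius_gap(self, geom2):
        c = (59.3, 58.1, 60.7)
        a = make_sphere(geom2, c, 14.0)
        b = make_sphere(geom2, c, 20.0)
        voxel_diag = np.linalg.norm(geom2.spacing)
        assert abs(directed_hausdorff(a, b) - 6.0) <= voxel_diag
        assert abs(directed_hausdorff(b, a) - 6.0) <= voxel_diag

    def test_identical_masks_distance_zero(self, sphere20):
        assert directed_hausdorff(sphere20, sphere20) == 0.0

    def test_directed_hausdorff_is_directed(self, geom2):
        # small sphere inside a big one: max distance from the big surface to
        # the small one exceeds the reverse when the small sphere is off-centre
        a = make_sphere(geom2, (50.0, 60.0, 60.0), 8.0)
        b = make_sphere(geom2, (60.0, 60.0, 60.0), 25.0)
        assert directed_hausdorff(b, a) > directed_hausdorff(a, b)

    def test_restriction_to_disjoint_region_raises(self, geom2, sphere20):
        far = make_sphere(geom2, (15.0, 15.0, 15.0), 6.0)
        with pytest.raises(EmptyRestrictionError):
            directed_hausdorff(sphere20, sphere20, restrict_to=far)

    def test_direction_axis_selects_half_shell(self, geom2):
        # translate a sphere dorsally: the posterior-facing wall moves by
        # (translation) while the anterior-facing wall moves toward the target
        c1, shift = np.array([60.0, 52.0, 60.0]), 8.0
        a = make_sphere(geom2, c1, 16.0)
        b = make_sphere(geom2, c1 + [0.0, shift, 0.0], 16.0)
        voxel_diag = np.linalg.norm(geom2.spacing)
        d_post = directed_hausdorff(a, b, direction_axis=(1, +1))
        assert abs(d_post - shift) <= voxel_diag

    def test_adjusted_local_hausdorff_zero_for_isotropic_growth(self, geom2):
        c = (59.3, 58.1, 60.7)
        b1 = make_sphere(geom2, c, 16.0)
        b2 = make_sphere(geom2, c, 21.0)
        ctv = make_sphere(geom2, (59.3, 74.0, 60.7), 8.0, "ctv")  # touches the wall
        voxel_diag = np.linalg.norm(geom2.spacing)
        assert abs(adjusted_local_hausdorff(b1, b2, ctv)) <= voxel_diag

    def test_adjusted_local_hausdorff_detects_local_bulge(self, geom2):
        c = np.array([59.3, 58.1, 60.7])
        b1 = make_sphere(geom2, c, 16.0)
        bulge = make_sphere(geom2, c + [0.0, 14.0, 0.0], 8.0)
        b2 = StructureMask(geom2, b1.voxels | bulge.voxels, "b2")
        ctv = make_sphere(geom2, c + [0.0, 15.0, 0.0], 7.0, "ctv")
        # the bulge extends ~6 mm beyond the wall while the volume grows little
        assert adjusted_local_hausdorff(b1, b2, ctv) > 3.0


class TestDice:
    def test_identical(self, sphere20):
        assert dice(sphere20, sphere20) == 1.0

    def test_disjoint(self, geom2):
        a = make_sphere(geom2, (30.0, 30.0, 30.0), 8.0)
        b = make_sphere(geom2, (90.0, 90.0, 90.0), 8.0)
        assert dice(a, b) == 0.0

    def test_empty_pair_is_one(self, geom2):
        e = StructureMask(geom2, np.zeros(geom2.shape, dtype=bool))
        assert dice(e, e) == 1.0
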