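import warnings

import numpy as np
import pytest

from oartsim.deformation import (
    DisplacementField,
    SurfaceCorrespondence,
    TimeScaling,
    compose_fields,
    propagate,
    scale_field,
    surface_dvf,
    time_scale_factor,
)
from oartsim.geometry import GridGeometry, StructureMask, dice, make_sphere, volume_of


@pytest.fixture(scope="module")
def geom():
    return GridGeometry((50, 50, 50), (2.0, 2.0, 2.0))


class TestTimeScaling:
    def test_endpoints_exact(self):
        ts = TimeScaling(0.0, 23.7, 113.0, 219.4)
        assert time_scale_factor(ts, 0.0) == 0.0
        assert time_scale_factor(ts, 23.7) == 1.0

    def test_strictly_increasing_and_above_linear_ratio(self):
        # cube root of linearly growing volume is concave, so the normalized
        # wall displacement is front-loaded: K(t) exceeds the time ratio
        ts = TimeScaling(0.0, 20.0, 100.0, 220.0)
        times = np.linspace(0.0, 20.0, 21)
        ks = np.array([time_scale_factor(ts, t) for t in times])
        assert np.all(np.diff(ks) > 0)
        linear = times / 20.0
        assert np.all(ks[1:-1] > linear[1:-1])

    def test_extrapolates_beyond_t2(self):
        ts = TimeScaling(0.0, 15.0, 150.0, 220.0)
        assert time_scale_factor(ts, 30.0) > 1.0

    def test_degenerate_volumes_fall_back_to_linear(self):
        ts = TimeScaling(0.0, 20.0, 150.0, 150.0)
        with pytest.warns(UserWarning, match="linear"):
            assert time_scale_factor(ts, 5.0) == pytest.approx(0.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            TimeScaling(10.0, 10.0, 100.0, 150.0)
        with pytest.raises(ValueError):
            TimeScaling(0.0, 10.0, -5.0, 150.0)
        ts = TimeScaling(0.0, 10.0, 100.0, 150.0)
        with pytest.raises(ValueError):
            time_scale_factor(ts, -1.0)


class TestFieldContainers:
    def test_shape_validation(self, geom):
        support = StructureMask(geom, np.ones(geom.shape, dtype=bool))
        with pytest.raises(ValueError):
            DisplacementField(geom, np.zeros((3, 5, 5, 5)), support)
        bad = np.zeros((3,) + geom.shape, dtype=np.float32)
        bad[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            DisplacementField(geom, bad, support)

    def test_scale_field(self, geom):
        support = StructureMask(geom, np.ones(geom.shape, dtype=bool))
        vec = np.ones((3,) + geom.shape, dtype=np.float32)
        f = DisplacementField(geom, vec, support)
        assert np.allclose(scale_field(f, 0.5).magnitude(), np.sqrt(3) / 2)
        with pytest.raises(ValueError):
            scale_field(f, -1.0)

    def test_sample_outside_grid_is_zero(self, geom):
        support = StructureMask(geom, np.ones(geom.shape, dtype=bool))
        vec = np.ones((3,) + geom.shape, dtype=np.float32)
        f = DisplacementField(geom, vec, support)
        out = f.sample_mm(np.array([[-500.0, 0.0, 0.0]]))
        assert np.allclose(out, 0.0)


class TestSurfaceCorrespondence:
    def test_concentric_growth_is_radial(self, geom):
        c = np.array([50.0, 50.0, 50.0])
        a = make_sphere(geom, c, 14.0, "a")
        b = make_sphere(geom, c, 20.0, "b")
        corr = SurfaceCorrespondence(a, b)
        # surface points of a should be displaced outward by ~6 mm
        pts = c + 14.0 * np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 1], [-1, 0, 0], [0.6, 0.8, 0.0]]
        )
        disp = corr.displacement_at(pts)
        radial = np.einsum("ij,ij->i", disp, (pts - c) / 14.0)
        assert np.allclose(radial, 6.0, atol=1.5)
        # the centroid maps to (approximately) the centroid
        assert np.linalg.norm(corr.displacement_at(c[None])[0]) < 1.0

    def test_pure_translation_recovered(self, geom):
        shift = np.array([6.0, -4.0, 2.0])
        a = make_sphere(geom, (46.0, 52.0, 48.0), 13.0, "a")
        b = make_sphere(geom, np.array([46.0, 52.0, 48.0]) + shift, 13.0, "b")
        corr = SurfaceCorrespondence(a, b)
        pts = a.foreground_mm()
        disp = corr.displacement_at(pts)
        err = np.linalg.norm(disp - shift, axis=1)
        assert np.median(err) < 1.0
        assert err.max() < 3.0

    def test_propagate_maps_sphere_onto_target(self, geom):
        c = np.array([50.0, 50.0, 50.0])
        a = make_sphere(geom, c, 14.0, "a")
        b = make_sphere(geom, c + [0.0, 5.0, 0.0], 18.0, "b")
        dvf = surface_dvf(a, b)
        moved = propagate(a, dvf)
        # combined shift + growth: high absolute agreement and a large
        # improvement over not deforming at all
        assert dice(moved, b) >= 0.95
        assert dice(moved, b) > dice(a, b) + 0.15

    def test_zero_field_propagation_preserves_mask(self, geom):
        a = make_sphere(geom, (50.0, 50.0, 50.0), 14.0, "a")
        support = StructureMask(geom, np.ones(geom.shape, dtype=bool))
        f = DisplacementField(geom, np.zeros((3,) + geom.shape, np.float32), support)
        assert dice(propagate(a, f), a) > 0.995

    def test_half_scaled_field_gives_intermediate_volume(self, geom):
        c = np.array([50.0, 50.0, 50.0])
        a = make_sphere(geom, c, 14.0, "a")
        b = make_sphere(geom, c, 20.0, "b")
        dvf = surface_dvf(a, b)
        mid = propagate(a, scale_field(dvf, 0.5))
        r_mid = (3.0 * volume_of(mid) * 1e3 / (4 * np.pi)) ** (1 / 3)
        assert r_mid == pytest.approx(17.0, abs=0.6)

    def test_empty_structure_rejected(self, geom):
        a = make_sphere(geom, (50.0, 50.0, 50.0), 14.0)
        empty = StructureMask(geom, np.zeros(geom.shape, dtype=bool))
        with pytest.raises(ValueError):
            SurfaceCorrespondence(a, empty)

    def test_non_star_shaped_falls_back_with_warning(self, geom):
        # a thin C-shaped slab is far from star-shaped about its centroid
        vox = np.zeros(geom.shape, dtype=bool)
        vox[10:40, 10:40, 22:28] = True
        vox[16:40, 16:34, 22:28] = False
        a = StructureMask(geom, vox, "cshape")
        target = StructureMask(geom, np.roll(vox, 2, axis=0), "cshape2")
        with pytest.warns(UserWarning, match="star-shaped"):
            corr = SurfaceCorrespondence(a, target)
        disp = corr.displacement_at(a.foreground_mm())
        assert np.isfinite(disp).all()

    def test_steering_pair_pins_substructure(self, geom):
        # with a steering pair, the displacement near the steering structure
        # follows that structure rather than the primary pair
        c = np.array([50.0, 50.0, 50.0])
        a = make_sphere(geom, c, 16.0, "a")
        b = make_sphere(geom, c, 20.0, "b")
        sub_a = make_sphere(geom, c + [0.0, 14.0, 0.0], 5.0, "sa")
        sub_b = make_sphere(geom, c + [0.0, 18.0, 0.0], 5.0, "sb")
        corr = SurfaceCorrespondence(a, b, steering=[(sub_a, sub_b)])
        disp = corr.displacement_at((c + [0.0, 14.0, 0.0])[None])[0]
        assert disp[1] == pytest.approx(4.0, abs=1.5)


class TestCompose:
    def test_translations_add(self, geom):
        support = StructureMask(geom, np.ones(geom.shape, dtype=bool))

        def tfield(shift):
            v = np.zeros((3,) + geom.shape, dtype=np.float32)
            for c in range(3):
                v[c] = shift[c]
            return DisplacementField(geom, v, support)

        f = compose_fields(tfield((4.0, 0.0, 2.0)), tfield((-2.0, 6.0, 0.0)))
        inner = f.vectors[:, 10:40, 10:40, 10:40]
        assert np.allclose(inner[0], 2.0, atol=1e-5)
        assert np.allclose(inner[1], 6.0, atol=1e-5)
        assert np.allclose(inner[2], 2.0, atol=1e-5)

    def test_geometry_mismatch_rejected(self, geom):
        other = GridGeometry((50, 50, 50), (1.0, 1.0, 1.0))
        support_a = StructureMask(geom, np.ones(geom.shape, dtype=bool))
        support_b = StructureMask(other, np.ones(other.shape, dtype=bool))
        fa = DisplacementField(geom, np.zeros((3,) + geom.shape, np.float32), support_a)
        fb = DisplacementField(other, np.zeros((3,) + other.shape, np.float32), support_b)
        with pytest.raises(ValueError):
            compose_fields(fa, fb)


@pytest.fixture(scope="module")
def fraction():
    from oartsim.phantom import PhantomConfig, SeriesSpec, sample_series

    spec = SeriesSpec(n_fractions=1, interfraction_jitter=1.0)
    cfg = PhantomConfig(bladder_volume_start=150.0, dorsal_bias=0.3, seed=0)
    return sample_series(spec, cfg, rng_seed=11)[0]


class TestPhantomRoundTrip:
    """Deformation model vs the phantom's exact motion (small instance)."""

    def test_full_field_maps_t1_onto_t2(self, fraction):
        dvf = surface_dvf(
            fraction.anatomy_t1.bladder,
            fraction.anatomy_t2.bladder,
            steering=[(fraction.anatomy_t1.ctv, fraction.anatomy_t2.ctv)],
        )
        moved = propagate(fraction.anatomy_t1.bladder, dvf)
        assert dice(moved, fraction.anatomy_t2.bladder) >= 0.98

    def test_k_scaled_volume_tracks_linear_filling(self, fraction):
        v1 = fraction.anatomy_t1.bladder_volume
        v2 = fraction.anatomy_t2.bladder_volume
        t2 = fraction.adaptation_time
        ts = TimeScaling(0.0, t2, v1, v2)
        dvf = surface_dvf(fraction.anatomy_t1.bladder, fraction.anatomy_t2.bladder)
        for t in (0.35 * t2, 0.7 * t2):
            k = time_scale_factor(ts, t)
            moved = propagate(fraction.anatomy_t1.bladder, scale_field(dvf, k))
            expected = v1 + (t / t2) * (v2 - v1)
            assert volume_of(moved) == pytest.approx(expected, rel=0.03)
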