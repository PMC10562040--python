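"""WEPL ray tracing, Bragg/SOBP curves, dose grids and range extraction."""

import numpy as np
import pytest

from spectral_spr.proton_dose import (
    BeamSpec,
    DepthDoseProfile,
    PTVSphere,
    bragg_curve,
    central_axis_profile,
    compute_dose,
    energy_from_range,
    plan_beam,
    r90_range,
    range_comparison,
    range_from_energy,
    sobp_dose,
    sobp_weights,
    straggling_sigma_mm,
    wepl_along_ray,
)
from spectral_spr.segmentation_spr import SPRMap


def _uniform_map(value=1.0, shape=(20, 40, 10), spacing=(2.0, 2.0, 2.0)):
    origin = tuple(-(n * s) / 2 + s / 2 for n, s in zip(shape, spacing))
    return SPRMap(values=np.full(shape, float(value)), spacing=spacing, origin=origin)


def _edge_origin(spr, axis=1):
    """Point on the low-y face of the grid, centered in x and z."""
    o = np.asarray(spr.origin)
    sp = np.asarray(spr.spacing)
    start = o + (np.asarray(spr.values.shape) - 1) * sp / 2.0
    start[axis] = o[axis] - sp[axis] / 2.0
    return start


class TestWEPL:
    def test_water_identity(self):
        spr = _uniform_map(1.0)
        depths = np.linspace(0.0, 60.0, 25)
        wepl = wepl_along_ray(spr, _edge_origin(spr), (0.0, 1.0, 0.0), depths)
        np.testing.assert_allclose(wepl, depths, atol=1e-9)

    def test_half_density_scaling(self):
        spr = _uniform_map(0.5)
        depths = np.linspace(0.0, 60.0, 25)
        wepl = wepl_along_ray(spr, _edge_origin(spr), (0.0, 1.0, 0.0), depths)
        np.testing.assert_allclose(wepl, depths / 2.0, atol=1e-9)

    def test_two_slab_closed_form(self):
        spr = _uniform_map(1.0, shape=(10, 40, 10))
        # distal half (y >= 0) is lung-like
        spr.values[:, 20:, :] = 0.28
        depths = np.array([10.0, 40.0, 41.0, 60.0, 80.0])
        wepl = wepl_along_ray(spr, _edge_origin(spr), (0.0, 1.0, 0.0), depths)
        boundary = 40.0  # slab interface at y = 0, i.e. depth 40 from the face
        expected = np.where(depths <= boundary, depths,
                            boundary + 0.28 * (depths - boundary))
        np.testing.assert_allclose(wepl, expected, atol=1e-9)

    def test_monotone_nondecreasing_along_oblique_ray(self):
        rng = np.random.default_rng(5)
        spr = _uniform_map(1.0, shape=(16, 16, 16))
        spr.values[:] = rng.uniform(0.1, 1.8, spr.values.shape)
        d = np.array([1.0, 2.0, 2.0]) / np.linalg.norm([1.0, 2.0, 2.0])
        depths = np.linspace(0, 80, 200)
        wepl = wepl_along_ray(spr, (-40.0, -40.0, -40.0), d, depths)
        assert np.all(np.diff(wepl) >= -1e-12)

    def test_grid_refinement_invariance_on_smooth_map(self):
        coarse = _uniform_map(1.0, shape=(10, 20, 10), spacing=(4.0, 4.0, 4.0))
        fine = _uniform_map(1.0, shape=(20, 40, 20), spacing=(2.0, 2.0, 2.0))
        d = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        depths = np.array([70.0])
        wc = wepl_along_ray(coarse, (-60.0, -60.0, 0.0), d, depths)
        wf = wepl_along_ray(fine, (-60.0, -60.0, 0.0), d, depths)
        assert wc[0] == pytest.approx(wf[0], rel=0.005)

    def test_ray_missing_grid_is_flagged(self):
        spr = _uniform_map(1.0)
        out = wepl_along_ray(spr, (1000.0, 0.0, 0.0), (0.0, 1.0, 0.0), np.array([5.0]))
        assert out is None

    def test_non_unit_direction_rejected(self):
        spr = _uniform_map(1.0)
        with pytest.raises(ValueError, match="unit"):
            wepl_along_ray(spr, (0, 0, 0), (0.0, 2.0, 0.0), np.array([5.0]))


class TestBraggCurve:
    def test_range_energy_power_law_direct_evaluation(self):
        expected_mm = 10.0 * 0.0022 * 100.0**1.77
        assert range_from_energy(100.0) == pytest.approx(expected_mm, abs=0.1)
        assert energy_from_range(expected_mm) == pytest.approx(100.0, rel=1e-9)

    def test_peak_sits_near_r0_and_dose_vanishes_past_3_sigma(self):
        r0 = range_from_energy(120.0)
        sigma = straggling_sigma_mm(r0)
        z = np.arange(0.0, r0 + 10 * sigma, 0.05)
        d = bragg_curve(120.0, z)
        assert z[np.argmax(d)] == pytest.approx(r0, abs=2 * sigma)
        assert np.all(d[z > r0 + 3 * sigma] == 0.0)

    def test_monotone_distal_falloff_and_finite_integral(self):
        r0 = range_from_energy(90.0)
        z = np.arange(0.0, r0 + 20.0, 0.1)
        d = bragg_curve(90.0, z)
        peak = np.argmax(d)
        assert np.all(np.diff(d[peak:]) <= 1e-12)
        assert 0.0 < np.trapezoid(d, z) < np.inf

    def test_doubling_spr_halves_geometric_peak_depth(self):
        depth = np.arange(0.0, 120.0, 0.05)
        d1 = bragg_curve(100.0, depth)          # WEPL = depth (water)
        d2 = bragg_curve(100.0, 2.0 * depth)    # WEPL = 2 * depth
        assert depth[np.argmax(d2)] == pytest.approx(depth[np.argmax(d1)] / 2.0, abs=0.1)

    def test_energy_band_enforced(self):
        with pytest.raises(ValueError, match="band"):
            bragg_curve(60.0, np.array([10.0]))
        with pytest.raises(ValueError, match="band"):
            bragg_curve(231.0, np.array([10.0]))


class TestSOBP:
    def test_single_energy_at_its_peak_gets_unit_weight(self):
        z = np.arange(0.0, 90.0, 0.01)
        d = bragg_curve(100.0, z)
        peak = float(z[np.argmax(d)])
        w = sobp_weights((peak, peak), [100.0])
        assert w[0] == pytest.approx(1.0, abs=5e-3)

    def test_flatness_within_3_percent_on_30mm_interval(self):
        energies = np.arange(energy_from_range(115.0), energy_from_range(150.0) + 2, 2.0)
        w = sobp_weights((120.0, 150.0), energies)
        grid = np.arange(120.0, 150.001, 0.25)
        total = sobp_dose(grid, energies, w)
        assert np.abs(total / total.mean() - 1.0).max() <= 0.03

    def test_overshooting_energies_get_zero_weight(self):
        energies = [80.0, 88.0, 160.0]
        w = sobp_weights((40.0, 60.0), energies)
        assert w[2] == 0.0  # range(160) ~ 181 mm, far beyond the distal edge

    def test_uncoverable_interval_raises_with_gap(self):
        with pytest.raises(ValueError, match="coverable|usable"):
            sobp_weights((300.0, 320.0), [80.0, 90.0])


class TestDoseEngine:
    def _ptv(self):
        return PTVSphere(center=(0.0, 10.0, 0.0), radius=8.0)

    def test_water_phantom_central_axis_equals_sobp_curve(self):
        spr = _uniform_map(1.0, shape=(24, 40, 16), spacing=(2.0, 2.0, 2.0))
        ptv = self._ptv()
        beam = plan_beam(spr, BeamSpec(gantry_angle_deg=0.0, isocenter=ptv.center), ptv)
        profile = central_axis_profile(spr, beam)
        expected = sobp_dose(profile.depth_mm, beam.energies, beam.weights)
        np.testing.assert_allclose(profile.dose, expected, atol=1e-9)

    def test_opposed_beams_in_water_are_symmetric(self):
        spr = _uniform_map(1.0, shape=(16, 32, 8), spacing=(4.0, 4.0, 4.0))
        ptv = PTVSphere(center=(0.0, 0.0, 0.0), radius=10.0)
        b0 = plan_beam(spr, BeamSpec(gantry_angle_deg=0.0, isocenter=ptv.center), ptv)
        b1 = plan_beam(spr, BeamSpec(gantry_angle_deg=-180.0, isocenter=ptv.center), ptv)
        dose = compute_dose(spr, [b0, b1], ptv)
        flipped = dose.values[:, ::-1, :]
        np.testing.assert_allclose(dose.values, flipped, atol=1e-6 * dose.values.max())

    def test_one_percent_spr_scaling_shifts_r90_one_percent(self):
        spr = _uniform_map(1.0, shape=(16, 60, 8), spacing=(2.0, 2.0, 2.0))
        scaled = _uniform_map(1.01, shape=(16, 60, 8), spacing=(2.0, 2.0, 2.0))
        ptv = PTVSphere(center=(0.0, 20.0, 0.0), radius=8.0)
        beam = plan_beam(spr, BeamSpec(gantry_angle_deg=0.0, isocenter=ptv.center), ptv)
        r_ref = r90_range(central_axis_profile(spr, beam, depth_step_mm=0.1))
        r_scaled = r90_range(central_axis_profile(scaled, beam, depth_step_mm=0.1))
        assert r_scaled == pytest.approx(r_ref / 1.01, abs=0.25)

    def test_raising_spr_on_axis_never_increases_r90(self):
        spr = _uniform_map(1.0, shape=(16, 60, 8), spacing=(2.0, 2.0, 2.0))
        ptv = PTVSphere(center=(0.0, 20.0, 0.0), radius=8.0)
        beam = plan_beam(spr, BeamSpec(gantry_angle_deg=0.0, isocenter=ptv.center), ptv)
        r_before = r90_range(central_axis_profile(spr, beam, depth_step_mm=0.1))
        bumped = _uniform_map(1.0, shape=(16, 60, 8), spacing=(2.0, 2.0, 2.0))
        ix = bumped.values.shape[0] // 2
        bumped.values[ix - 1: ix + 1, 5, :] = 1.5
        r_after = r90_range(central_axis_profile(bumped, beam, depth_step_mm=0.1))
        assert r_after <= r_before + 1e-9

    def test_dose_engine_is_bitwise_deterministic(self):
        spr = _uniform_map(1.0, shape=(12, 24, 8), spacing=(4.0, 4.0, 4.0))
        ptv = PTVSphere(center=(0.0, 10.0, 0.0), radius=8.0)
        beam = plan_beam(spr, BeamSpec(gantry_angle_deg=0.0, isocenter=ptv.center), ptv)
        a = compute_dose(spr, [beam], ptv)
        b = compute_dose(spr, [beam], ptv)
        np.testing.assert_array_equal(a.values, b.values)

    def test_unplanned_beam_rejected(self):
        spr = _uniform_map(1.0)
        with pytest.raises(ValueError, match="plan_beam"):
            compute_dose(spr, [BeamSpec(gantry_angle_deg=0.0, isocenter=(0, 0, 0))],
                         PTVSphere((0, 0, 0), 5.0))


class TestBeamSpecValidation:
    def test_angle_range(self):
        with pytest.raises(ValueError, match="gantry"):
            BeamSpec(gantry_angle_deg=180.0, isocenter=(0, 0, 0))

    def test_couch_fixed_at_zero(self):
        with pytest.raises(ValueError, match="couch"):
            BeamSpec(gantry_angle_deg=0.0, couch_angle_deg=10.0, isocenter=(0, 0, 0))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            BeamSpec(gantry_angle_deg=0.0, isocenter=(0, 0, 0),
                     energies=(100.0,), weights=(-1.0,))


class TestR90:
    def test_linear_distal_edge_hand_interpolation(self):
        profile = DepthDoseProfile(depth_mm=np.array([0.0, 100.0, 110.0]),
                                   dose=np.array([0.0, 100.0, 0.0]))
        assert r90_range(profile) == pytest.approx(101.0, abs=1e-12)

    def test_flat_then_step(self):
        profile = DepthDoseProfile(depth_mm=np.array([0.0, 50.0, 50.001]),
                                   dose=np.array([1.0, 1.0, 0.0]))
        assert r90_range(profile) == pytest.approx(50.0, abs=1e-2)

    def test_monotone_increasing_profile_errors(self):
        profile = DepthDoseProfile(depth_mm=np.linspace(0, 10, 5),
                                   dose=np.linspace(0, 1, 5))
        with pytest.raises(ValueError, match="falloff"):
            r90_range(profile)


class TestRangeComparison:
    def test_published_lung_beam_arithmetic(self):
        table = range_comparison([101.28], [99.44], ["beam_45"])
        assert table.loc[0, "difference_mm"] == 1.84
        assert table.loc[0, "deviation_pct"] == 1.85

    def test_identical_profiles_give_zero(self):
        table = range_comparison([88.8], [88.8])
        assert table.loc[0, "difference_mm"] == 0.0
        assert table.loc[0, "deviation_pct"] == 0.0

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError, match="match"):
            range_comparison([1.0, 2.0], [1.0])
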