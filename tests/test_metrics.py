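"""Summary statistics: P_s/P, design curve, divergence estimators, footprint."""

import math
from dataclasses import replace

import numpy as np
import pytest

import lightpatch as lp
from lightpatch.engine import EmissionSpec, sample_emission, trace_gap_records
from lightpatch.metrics import (
    AngularPowerDistribution,
    BeamImage,
    ConeRegion,
    divergence_from_distribution,
    estimate_divergence_from_image,
    footprint_diameter,
    lateral_power_fraction,
    lateral_power_fraction_records,
    render_beam_image,
    sweep_d,
)


def _uniform_cone_distribution(theta_max=65.0):
    """Analytic uniform-solid-angle cone, binned at one degree."""
    edges = np.arange(0.0, 181.0, 1.0)
    lo, hi = np.radians(edges[:-1]), np.radians(edges[1:])
    power = np.cos(lo) - np.cos(np.minimum(hi, math.radians(theta_max)))
    power = np.clip(power, 0.0, None)
    power[edges[:-1] >= theta_max] = 0.0
    return AngularPowerDistribution(bin_edges=edges, power=power / power.sum())


def _delta_on_axis():
    edges = np.arange(0.0, 181.0, 1.0)
    power = np.zeros(180)
    power[0] = 1.0
    return AngularPowerDistribution(bin_edges=edges, power=power)


class TestLateralPowerFraction:
    def test_axial_beam_has_no_lateral_power(self):
        assert lateral_power_fraction(_delta_on_axis()) == 0.0

    def test_uniform_cone_closed_form(self):
        """Solid-angle ratio (cos43 - cos65)/(1 - cos65) = 0.535."""
        frac = lateral_power_fraction(_uniform_cone_distribution(65.0), ConeRegion(43.0))
        expected = (math.cos(math.radians(43)) - math.cos(math.radians(65))) / (
            1 - math.cos(math.radians(65))
        )
        assert frac == pytest.approx(expected, abs=0.01)

    def test_empty_distribution_rejected(self):
        edges = np.arange(0.0, 181.0, 1.0)
        empty = AngularPowerDistribution(bin_edges=edges, power=np.zeros(180))
        with pytest.raises(ValueError):
            lateral_power_fraction(empty)

    def test_result_in_unit_interval_and_ray_count_invariant(self, device):
        fracs = []
        for n in (20_000, 60_000):
            bundle = sample_emission(EmissionSpec(n_rays=n, seed=8), (0, 0, -15.0))
            rec = trace_gap_records(bundle, device)
            f = lateral_power_fraction_records(rec, (0, 0, -15.0))
            assert 0.0 <= f <= 1.0
            fracs.append(f)
        se = 3.0 * math.sqrt(0.25 / 20_000)
        assert abs(fracs[0] - fracs[1]) < se

    def test_far_field_mode_matches_distribution_binning(self, device, small_spec):
        bundle = sample_emission(small_spec, (0, 0, -15.0))
        rec = trace_gap_records(bundle, device)
        dist = lp.trace_gap(sample_emission(small_spec, (0, 0, -15.0)), device)
        far = lateral_power_fraction_records(rec, (0, 0, -15.0), ConeRegion(eval_range_um=None))
        binned = lateral_power_fraction(dist)
        assert far == pytest.approx(binned, abs=0.01)


class TestSweepD:
    def test_rows_sorted_and_deterministic(self, device):
        spec = EmissionSpec(n_rays=5000, seed=21)
        a = sweep_d(device, [15.0, 5.0], spec)
        b = sweep_d(device, [5.0, 15.0], spec)
        assert list(a["d_um"]) == [5.0, 15.0]
        assert np.array_equal(a["ps_over_p"].values, b["ps_over_p"].values)

    def test_plateau_exceeds_extremes(self, device):
        """The 5-25 um plateau beats both the smallest and the largest d."""
        spec = EmissionSpec(n_rays=20_000, seed=31)
        table = sweep_d(device, [0.5, 5.0, 15.0, 25.0, 120.0], spec)
        plateau = table[(table.d_um >= 5) & (table.d_um <= 25)]["ps_over_p"].mean()
        assert plateau > table.iloc[0]["ps_over_p"]
        assert plateau > table.iloc[-1]["ps_over_p"]

    def test_single_d_gives_one_row(self, device):
        table = sweep_d(device, [10.0], EmissionSpec(n_rays=2000, seed=0))
        assert len(table) == 1

    def test_empty_plan_rejected(self, device):
        with pytest.raises(ValueError):
            sweep_d(device, [], EmissionSpec(n_rays=100, seed=0))


class TestDivergenceFromDistribution:
    @pytest.mark.parametrize("threshold", [0.05, 0.5])
    def test_uniform_cone_is_130_at_any_threshold(self, threshold):
        angle = divergence_from_distribution(_uniform_cone_distribution(65.0), threshold)
        assert angle == pytest.approx(130.0, abs=2.0)

    def test_axial_delta_has_zero_divergence(self):
        assert divergence_from_distribution(_delta_on_axis()) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_closed_form_edge(self):
        """sigma = 10 deg at threshold 0.05 -> 2 sigma sqrt(2 ln 20) = 48.9 deg."""
        edges = np.arange(0.0, 181.0, 1.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        lo, hi = np.radians(edges[:-1]), np.radians(edges[1:])
        solid = 2 * math.pi * (np.cos(lo) - np.cos(hi))
        density = np.exp(-(centers**2) / (2 * 10.0**2))
        dist = AngularPowerDistribution(bin_edges=edges, power=density * solid)
        expected = 2.0 * 10.0 * math.sqrt(2.0 * math.log(20.0))
        assert divergence_from_distribution(dist, 0.05) == pytest.approx(expected, abs=1.5)

    def test_monotone_in_threshold(self):
        dist = _uniform_cone_distribution(40.0)
        loose = divergence_from_distribution(dist, 0.02)
        tight = divergence_from_distribution(dist, 0.5)
        assert loose >= tight

    def test_zero_distribution_rejected(self):
        edges = np.arange(0.0, 181.0, 1.0)
        with pytest.raises(ValueError):
            divergence_from_distribution(
                AngularPowerDistribution(bin_edges=edges, power=np.zeros(180))
            )


class TestRenderBeamImage:
    def test_single_axial_ray_is_a_bright_line(self):
        img = render_beam_image(
            [[0.0, 0.0, 0.0]],
            [[0.0, 0.0, 1.0]],
            [1.0],
            extent_um=(0.0, 100.0, -50.0, 50.0),
            pitch_um=1.0,
            blur_sigma_px=0.0,
        )
        row_energy = img.data.sum(axis=1)
        assert row_energy.argmax() == 50
        assert row_energy[50] > 0.99 * img.data.sum()

    def test_symmetric_pair_gives_mirror_image(self):
        # pixel-centred transverse extent so the axis is a row centre
        ang = math.radians(37.0)
        img = render_beam_image(
            [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]],
            [[math.sin(ang), 0, math.cos(ang)], [-math.sin(ang), 0, math.cos(ang)]],
            [0.5, 0.5],
            extent_um=(0.0, 100.0, -100.5, 100.5),
            pitch_um=1.0,
            blur_sigma_px=0.0,
        )
        assert np.allclose(img.data, img.data[::-1, :], atol=1e-9)

    def test_attenuation_dims_the_far_field(self):
        kw = dict(extent_um=(0.0, 200.0, -20.0, 20.0), pitch_um=1.0, blur_sigma_px=0.0)
        bright = render_beam_image([[0, 0, 0]], [[0, 0, 1]], [1.0], mu_per_um=0.0, **kw)
        dim = render_beam_image([[0, 0, 0]], [[0, 0, 1]], [1.0], mu_per_um=0.05, **kw)
        assert dim.data[:, -5:].sum() < 0.1 * bright.data[:, -5:].sum()

    def test_nonpositive_pitch_rejected(self):
        with pytest.raises(ValueError):
            render_beam_image([[0, 0, 0]], [[0, 0, 1]], [1.0], (0, 10, -5, 5), 0.0)


class TestEstimateDivergence:
    def test_round_trip_20_degrees(self):
        img, truth = lp.make_beam_image_fixture(20.0, seed=2)
        est = estimate_divergence_from_image(img)
        assert est.angle_deg == pytest.approx(truth["true_divergence_deg"], abs=2.0)

    def test_threshold_sensitivity_is_bounded(self):
        img, _ = lp.make_beam_image_fixture(40.0, seed=2)
        a = estimate_divergence_from_image(img, threshold=0.05).angle_deg
        b = estimate_divergence_from_image(img, threshold=0.10).angle_deg
        assert abs(a - b) < 3.0

    def test_blank_image_rejected(self):
        with pytest.raises(ValueError):
            estimate_divergence_from_image(BeamImage(np.zeros((50, 50)), 1.0))

    def test_clipped_beam_rejected(self):
        """A beam wider than the frame must raise, not silently underestimate."""
        half = math.radians(60.0)
        angles = np.linspace(-half, half, 501)
        dirs = np.column_stack([np.sin(angles), np.zeros(501), np.cos(angles)])
        img = render_beam_image(
            np.zeros((501, 3)),
            dirs,
            np.full(501, 1 / 501),
            extent_um=(-20.0, 300.0, -60.0, 60.0),  # far too narrow transversely
            pitch_um=1.0,
        )
        with pytest.raises(ValueError, match="increase extent"):
            estimate_divergence_from_image(img)

    def test_image_estimate_consistent_with_distribution_estimate(self):
        """The two divergence estimators agree on a clean synthetic cone."""
        theta_max = 25.0
        img, _ = lp.make_beam_image_fixture(2 * theta_max, seed=6)
        from_image = estimate_divergence_from_image(img).angle_deg
        from_dist = divergence_from_distribution(_uniform_cone_distribution(theta_max), 0.05)
        assert abs(from_image - from_dist) < 3.0


class TestFootprint:
    @pytest.mark.parametrize(
        "patch, pen, expected", [(2.5, 0.5, 3.5), (2.0, 0.5, 3.0), (4.0, 0.0, 4.0)]
    )
    def test_closed_form(self, patch, pen, expected):
        assert footprint_diameter(patch, pen) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            footprint_diameter(0.0, 0.5)
        with pytest.raises(ValueError):
            footprint_diameter(2.5, -0.1)


class TestDivergenceLadder:
    def test_device_class_ordering(self, device):
        """Flat-end < taper-without-gap < full device, at one fixed threshold."""
        ladder = lp.divergence_ladder(device, EmissionSpec(n_rays=30_000, seed=13))
        assert ladder["flat_end"] < ladder["taper_no_gap"] < ladder["full_device"]
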