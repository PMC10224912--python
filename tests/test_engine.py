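"""Monte Carlo engine: emission sampling, splitting, gap and slab transport."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest

import lightpatch as lp
from lightpatch.engine import (
    EmissionSpec,
    Ray,
    TraceSettings,
    interact,
    sample_emission,
    trace_gap,
    trace_gap_records,
    transport_slab,
)
from lightpatch.synthetic import degenerate_geometries


def _no_gap(device):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return replace(device, gap=replace(device.gap, d=0.0))


class TestSampleEmission:
    def test_solid_angle_fraction_beyond_43_degrees(self):
        """Closed-form check of the uniform-solid-angle density in the 65-deg cone."""
        spec = EmissionSpec(theta_max=65.0, n_rays=200_000, seed=1)
        bundle = sample_emission(spec)
        theta = np.degrees(np.arccos(bundle.directions[:, 2]))
        frac = np.mean(theta > 43.0)
        expected = (math.cos(math.radians(43)) - math.cos(math.radians(65))) / (
            1.0 - math.cos(math.radians(65))
        )
        assert expected == pytest.approx(0.535, abs=0.001)
        assert frac == pytest.approx(expected, abs=3.0 * math.sqrt(0.25 / spec.n_rays))

    def test_degenerate_cone_is_axial(self):
        bundle = sample_emission(EmissionSpec(theta_max=1e-6, n_rays=100, seed=0))
        assert np.allclose(bundle.directions[:, 2], 1.0, atol=1e-9)

    def test_same_seed_is_bit_identical(self):
        spec = EmissionSpec(n_rays=5000, seed=77)
        a, b = sample_emission(spec), sample_emission(spec)
        assert np.array_equal(a.directions, b.directions)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_normalized(self):
        bundle = sample_emission(EmissionSpec(n_rays=333, seed=0))
        assert bundle.weights.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("density", ["cosine-weighted", "side-weighted"])
    def test_alternative_densities_stay_in_cone(self, density):
        spec = EmissionSpec(theta_max=65.0, angular_density=density, n_rays=20_000, seed=3)
        theta = np.degrees(np.arccos(sample_emission(spec).directions[:, 2]))
        assert theta.max() <= 65.0 + 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            EmissionSpec(theta_max=120.0)
        with pytest.raises(ValueError):
            EmissionSpec(angular_density="isotropic")
        with pytest.raises(ValueError):
            EmissionSpec(n_rays=0)


class TestInteract:
    def test_normal_incidence_air_to_patch_split(self):
        ray = Ray(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0)
        children = interact(ray, np.zeros(3), np.array([0.0, 0.0, -1.0]), 1.0003, 1.49)
        assert len(children) == 2
        transmitted, reflected = children
        assert transmitted.weight == pytest.approx(0.9613, abs=1e-3)
        assert reflected.weight == pytest.approx(0.0387, abs=1e-3)
        assert np.allclose(transmitted.direction, [0.0, 0.0, 1.0])
        assert np.allclose(reflected.direction, [0.0, 0.0, -1.0])

    def test_tir_yields_single_reflected_child(self):
        u = np.array([math.sin(math.radians(60)), 0.0, math.cos(math.radians(60))])
        ray = Ray(np.zeros(3), u, 1.0)
        children = interact(ray, np.zeros(3), np.array([0.0, 0.0, -1.0]), 1.49, 1.0003)
        assert len(children) == 1
        assert children[0].weight == pytest.approx(1.0)
        assert np.allclose(children[0].direction, [u[0], 0.0, -u[2]])

    def test_index_matched_transmits_everything(self):
        ray = Ray(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0)
        children = interact(ray, np.zeros(3), np.array([0.0, 0.0, -1.0]), 1.4, 1.4)
        assert len(children) == 1
        assert children[0].weight == pytest.approx(1.0)

    def test_degenerate_normal_rejected(self):
        ray = Ray(np.zeros(3), np.array([0.0, 0.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            interact(ray, np.zeros(3), np.zeros(3), 1.0, 1.5)


class TestTraceGap:
    def test_flat_wall_oracle_per_ray(self, device):
        """Degenerate flat cavity reproduces closed-form Snell/Fresnel per ray."""
        flat = degenerate_geometries()["flat_wall"]["device"]
        flat = replace(flat, gap=replace(flat.gap, d=10.0))
        spec = EmissionSpec(theta_max=30.0, n_rays=2000, seed=3)
        bundle = sample_emission(spec, (0.0, 0.0, -10.0))
        rec = trace_gap_records(bundle, flat, TraceSettings(max_depth=1))
        assert len(rec.weights) == len(bundle)
        n_air, n_patch = device.index("air"), device.index("patch")
        theta_in = np.degrees(np.arccos(bundle.directions[:, 2]))
        expected_theta = np.degrees(np.arcsin(np.sin(np.radians(theta_in)) * n_air / n_patch))
        expected_t = np.array(
            [lp.fresnel_unpolarized(t, n_air, n_patch)[0] for t in theta_in]
        )
        got_theta = np.degrees(np.arccos(np.clip(rec.directions[:, 2], -1.0, 1.0)))
        assert np.abs(got_theta - expected_theta).max() < 1e-9
        assert np.abs(rec.weights - bundle.weights * expected_t).max() < 1e-12

    def test_energy_closure(self, device, small_spec):
        bundle = sample_emission(small_spec, (0.0, 0.0, -device.gap.d))
        rec = trace_gap_records(bundle, device)
        assert sum(rec.ledger.values()) == pytest.approx(1.0, abs=1e-6)

    def test_seed_determinism_bit_identical(self, device):
        spec = EmissionSpec(n_rays=2000, seed=11)
        a = trace_gap_records(sample_emission(spec, (0, 0, -15.0)), device)
        b = trace_gap_records(sample_emission(spec, (0, 0, -15.0)), device)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.directions, b.directions)
        assert a.ledger == b.ledger

    def test_d_to_zero_limit_matches_no_gap_configuration(self, device):
        """A vanishing cavity reduces to the directly refracted cone."""
        spec = EmissionSpec(n_rays=30_000, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tiny = replace(device, gap=replace(device.gap, d=0.05))
        dist_tiny = trace_gap(sample_emission(spec, (0, 0, -0.05)), tiny)
        dist_zero = trace_gap(sample_emission(spec), _no_gap(device))
        assert np.abs(dist_tiny.power - dist_zero.power).sum() < 0.02

    def test_python_and_fast_paths_agree(self, device):
        """The pluggable-profile tracer and the compiled tracer are the same physics."""
        spec = EmissionSpec(n_rays=400, seed=9)
        bundle = sample_emission(spec, (0, 0, -device.gap.d))
        taper_py = replace(
            device.taper, radius_fn=lambda z: 0.5 + 49.5 * (z / 280.0) ** 2
        )
        dev_py = replace(device, taper=taper_py, gap=replace(device.gap, cavity_profile=taper_py))
        rec_py = trace_gap_records(bundle, dev_py)
        rec_nb = trace_gap_records(bundle, device)
        assert len(rec_py.weights) == len(rec_nb.weights)
        assert rec_py.ledger["entered"] == pytest.approx(rec_nb.ledger["entered"], abs=1e-4)
        th_py = np.degrees(np.arccos(np.clip(rec_py.directions[:, 2], -1, 1)))
        th_nb = np.degrees(np.arccos(np.clip(rec_nb.directions[:, 2], -1, 1)))
        assert np.average(th_py, weights=rec_py.weights) == pytest.approx(
            np.average(th_nb, weights=rec_nb.weights), abs=0.05
        )

    def test_azimuthal_symmetry(self, device, small_spec):
        """The device is axisymmetric, so exit azimuths are uniform."""
        bundle = sample_emission(small_spec, (0, 0, -device.gap.d))
        rec = trace_gap_records(bundle, device)
        phi = np.arctan2(rec.directions[:, 1], rec.directions[:, 0])
        resultant = abs(np.sum(rec.weights * np.exp(1j * phi))) / rec.weights.sum()
        assert resultant < 3.0 / math.sqrt(len(rec.weights))


class TestTransportSlab:
    @staticmethod
    def _isotropic_mid_slab(n, seed):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        return lp.RayBundle(
            origins=np.zeros((n, 3)), directions=u, weights=np.full(n, 1.0 / n)
        )

    def test_ideal_single_pass_matches_solid_angle_closed_form(self, device):
        """With T forced to 1 below critical, hemisphere escape fractions are
        1 - cos(theta_c) closed forms."""
        bundle = self._isotropic_mid_slab(200_000, 12)
        exits = transport_slab(
            bundle, device.slab, device.media, TraceSettings(ideal_interfaces=True, single_pass=True)
        )
        tissue, air, _ = lp.side_split(exits)
        se = 3.0 / math.sqrt(len(bundle))
        assert tissue == pytest.approx((1 - math.cos(math.radians(69.97))) / 2, abs=se)
        assert air == pytest.approx((1 - math.cos(math.radians(42.17))) / 2, abs=se)

    def test_symmetric_slab_splits_evenly(self):
        sym = degenerate_geometries()["symmetric_slab"]["device"]
        bundle = self._isotropic_mid_slab(100_000, 3)
        exits = transport_slab(bundle, sym.slab, sym.media)
        tissue, air, _ = lp.side_split(exits)
        assert tissue == pytest.approx(air, abs=3.0 / math.sqrt(len(bundle)))

    def test_index_matched_slab_exits_on_first_pass(self):
        matched = degenerate_geometries()["index_matched_slab"]["device"]
        bundle = self._isotropic_mid_slab(20_000, 4)
        exits = transport_slab(bundle, matched.slab, matched.media)
        assert exits.ledger["exited"] == pytest.approx(1.0, abs=1e-9)
        assert exits.ledger["pruned"] == 0.0
        assert exits.ledger["depth_terminated"] == 0.0

    def test_full_fresnel_tissue_bias(self, device, small_spec):
        """Air above, tissue below: the tissue side collects more power."""
        bundle = sample_emission(small_spec, (0, 0, -device.gap.d))
        rec = trace_gap_records(bundle, device)
        exits = transport_slab(rec, device.slab, device.media)
        tissue, air, _ = lp.side_split(exits)
        assert tissue > air

    def test_slab_energy_closure(self, device, small_spec):
        bundle = sample_emission(small_spec, (0, 0, -device.gap.d))
        rec = trace_gap_records(bundle, device)
        exits = transport_slab(rec, device.slab, device.media)
        assert sum(exits.ledger.values()) == pytest.approx(exits.input_power, abs=1e-6)

    def test_exit_frame_output(self, device, small_spec):
        _, exits, _ = lp.simulate_device(device, small_spec)
        frame = exits.to_frame()
        assert set(frame.columns) == {"side", "x_mm", "y_mm", "exit_angle_deg", "weight"}
        assert set(frame["side"]).issubset({"tissue", "air", "edge"})
        assert (frame["weight"] > 0).all()


class TestPipeline:
    def test_full_pipeline_energy_closure(self, device, small_spec):
        _, exits, ledger = lp.simulate_device(device, small_spec)
        total = sum(ledger.values())
        assert total == pytest.approx(1.0, abs=1e-6)
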