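"""Monte Carlo transport: event physics, bookkeeping, and a cross-check of
the compiled kernel against a plain-Python reference propagation built
from the photon-level operations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcmldf.detection import LensModel, accept
from rcmldf.tissue import (
    ChromophoreConstants,
    LayerSpec,
    SkinModel,
    optics_at,
)
from rcmldf.transport import (
    BeamSpec,
    Photon,
    TransportConfig,
    doppler_shift_for_event,
    gaussian_focal_spot_diameter,
    interact,
    launch_photon,
    propagate_pixel,
    sample_rbc_velocity,
    sample_step,
    split_photon,
)


def unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestLaunch:
    def test_beam_ensemble_geometry(self, beam, rng):
        n = 20_000
        surface = np.empty((n, 2))
        focal = np.empty((n, 2))
        for i in range(n):
            p = launch_photon(beam, rng)
            assert p.weight == 1.0 and p.doppler_shift == 0.0
            assert np.linalg.norm(p.direction) == pytest.approx(1.0, abs=1e-9)
            surface[i] = p.position[:2]
            t = beam.focal_depth / p.direction[2]
            focal[i] = p.position[:2] + p.direction[:2] * t
        # symmetric about the axis
        assert np.abs(surface.mean(axis=0)).max() < 0.01
        # 1/e^2 diameter at the focal plane ~ nominal spot diameter
        d_waist = 4.0 * focal.std(axis=0).mean()
        assert d_waist == pytest.approx(beam.spot_diameter_1e2, rel=0.05)
        # surface footprint is the converging cone, much wider than the waist
        assert 4.0 * surface.std(axis=0).mean() > 10 * beam.spot_diameter_1e2

    def test_closed_form_focal_spot(self):
        d = gaussian_focal_spot_diameter(850.0, 1.96, 8.0)
        assert d * 1e3 == pytest.approx(4.417, abs=0.01)  # um

    def test_invalid_na(self, rng):
        with pytest.raises(ValueError, match="aperture"):
            launch_photon(BeamSpec(numerical_aperture=1.2), rng)


class TestSampleStep:
    def test_mean_free_path(self, rng):
        mut = 14.36
        s = np.array([sample_step(mut, rng) for _ in range(100_000)])
        assert s.mean() == pytest.approx(1 / mut, rel=0.02)

    def test_invalid_mut(self, rng):
        with pytest.raises(ValueError):
            sample_step(0.0, rng)


class TestRbcVelocity:
    def test_moments(self, rng):
        v = np.array([sample_rbc_velocity(3.0, rng) for _ in range(50_000)])
        speeds = np.linalg.norm(v, axis=1)
        assert speeds.mean() == pytest.approx(3.0, rel=0.03)
        assert speeds.max() <= 6.0 + 1e-12
        assert np.abs(v.mean(axis=0)).max() < 0.05

    def test_zero_speed(self, rng):
        assert np.all(sample_rbc_velocity(0.0, rng) == 0.0)


class TestDopplerShift:
    def test_null_cases(self):
        d = unit([0.3, -0.2, 0.9])
        assert doppler_shift_for_event(d, d, [5.0, 1.0, 2.0]) == 0.0
        assert doppler_shift_for_event(d, unit([1, 0, 0]), [0, 0, 0]) == 0.0

    def test_backscatter_closed_form(self):
        """180-degree backscatter off an antiparallel scatterer moving at
        30 mm/s: |df| = 2 n v / lambda ~ 9.88e4 Hz."""
        ki = np.array([0.0, 0.0, 1.0])
        f = doppler_shift_for_event(ki, -ki, [0.0, 0.0, -30.0])
        expected = 2 * 1.4 * 30.0 / (850e-6)
        assert f == pytest.approx(expected)
        assert f == pytest.approx(9.88e4, rel=2e-3)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_bound_and_antisymmetry(self, data):
        pts = st.floats(-1, 1)
        a = unit([data.draw(pts) + 1e-3, data.draw(pts), data.draw(pts) + 1.1])
        b = unit([data.draw(pts), data.draw(pts) - 1e-3, data.draw(pts) - 1.1])
        v = np.array([data.draw(pts), data.draw(pts), data.draw(pts)]) * 30
        f = doppler_shift_for_event(a, b, v)
        bound = 2 * 1.4 * np.linalg.norm(v) / 850e-6
        assert abs(f) <= bound * (1 + 1e-9) + 1e-12
        assert doppler_shift_for_event(a, b, -v) == pytest.approx(-f, abs=1e-9)


class TestInteract:
    def test_albedo_weighting_and_static_only(self, healthy_model, rng):
        o = optics_at(healthy_model, (0, 0, 0.05))  # epidermis: no blood
        p = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        for _ in range(50):
            w_before = p.weight
            interact(p, o, rng)
            assert p.weight == pytest.approx(
                w_before * o.mus_total / (o.mus_total + o.mua_total)
            )
        assert p.doppler_shift == 0.0
        assert p.n_scatters == 50

    def test_blood_layer_produces_shifts(self, healthy_model, rng):
        o = optics_at(healthy_model, (0, 0, 0.3))
        shifts = []
        for _ in range(500):
            p = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]))
            interact(p, o, rng)
            shifts.append(p.doppler_shift)
        assert np.count_nonzero(shifts) > 0

    def test_no_scatterers_raises(self, rng):
        from rcmldf.tissue import LocalOptics

        o = LocalOptics(0.1, 0.0, 0.0, (0, 0, 0), (0.3, 3, 30))
        p = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError, match="scatterers"):
            interact(p, o, rng)

    def test_dead_photon_rejected(self, healthy_model, rng):
        o = optics_at(healthy_model, (0, 0, 0.05))
        p = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), alive=False)
        with pytest.raises(ValueError):
            interact(p, o, rng)


class TestSplitPhoton:
    def test_below_window_unchanged(self):
        cfg = TransportConfig(split_value_threshold=300.0)
        p = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=1.0,
                   doppler_shift=100.0)
        out = split_photon(p, cfg)
        assert out == [p]

    @pytest.mark.parametrize("shift", [5e3, 8e4, 5e6])
    def test_weight_conserved_and_capped(self, shift):
        cfg = TransportConfig(split_value_threshold=300.0, split_mult=4,
                              max_split=3200)
        p = Photon(np.zeros(3), np.array([0.0, 0.0, 1.0]), weight=1.0,
                   doppler_shift=shift)
        out = split_photon(p, cfg)
        assert sum(c.weight for c in out) == pytest.approx(1.0, abs=1e-12)
        assert 1 <= len(out) <= 3200
        if shift * 1.0 > 300.0:
            assert len(out) > 1
        for c in out:
            assert c.doppler_shift == shift


def _uniform_slab(blood_slow=0.01, mus=5.0, mua=0.1, thickness=1.0):
    layer = LayerSpec("slab", thickness, blood_slow, 0.0, 0.0, 0.0, mus, mua)
    return SkinModel(layers=(layer,), constants=ChromophoreConstants())


def _python_reference_pixel(model, beam, lens, n_photons, seed):
    """Reference propagation assembled from the photon-level operations:
    homogeneous slab, so plain exponential steps need no boundary logic
    beyond top/bottom crossings."""
    rng = np.random.default_rng(seed)
    o = optics_at(model, (0, 0, model.total_depth / 2))
    mut = o.mus_total + o.mua_total
    detected_w = 0.0
    detected_moment = 0.0
    rl_thresh, rl_surv = 1e-4, 0.1
    for _ in range(n_photons):
        p = launch_photon(beam, rng)
        while p.alive:
            s = sample_step(mut, rng)
            new_pos = p.position + s * p.direction
            if new_pos[2] <= 0.0:  # exits the top surface
                t = -p.position[2] / p.direction[2]
                exit_xy = p.position[:2] + t * p.direction[:2]
                if accept(exit_xy, p.direction, lens,
                          focal_depth=beam.focal_depth):
                    detected_w += p.weight
                    detected_moment += p.weight * abs(p.doppler_shift)
                break
            if new_pos[2] >= model.total_depth:
                break
            p.position = new_pos
            interact(p, o, rng)
            if p.weight < rl_thresh:
                if rng.random() < rl_surv:
                    p.weight /= rl_surv
                else:
                    break
    return detected_w / n_photons, detected_moment / n_photons


class TestKernelAgainstReference:
    def test_reflectance_and_perfusion_agree(self):
        """Compiled kernel vs Python-op reference on a homogeneous slab
        with a loose aperture (for detection statistics)."""
        model = _uniform_slab()
        beam = BeamSpec()
        lens = LensModel(aperture_radius_um=300.0)
        cfg = TransportConfig(
            class_bias=(1.0, 1.0, 1.0),
            importance_survival=1.0,  # reference has no depth roulette
        )
        res = propagate_pixel(model, beam, cfg, lens, n_photons=40_000,
                              splitting=False, seed=7)
        refs = [
            _python_reference_pixel(model, beam, lens, 1200, seed=s)
            for s in range(4)
        ]
        ref_refl = np.mean([r[0] for r in refs])
        ref_perf = np.mean([r[1] for r in refs])
        se_refl = np.std([r[0] for r in refs]) / 2
        se_perf = np.std([r[1] for r in refs]) / 2
        assert res.reflectance == pytest.approx(ref_refl, abs=4 * se_refl)
        assert res.perfusion_per_photon == pytest.approx(ref_perf, abs=4 * se_perf)


class TestPropagatePixel:
    def test_transparent_medium_returns_nothing(self, beam, transport_config):
        model = SkinModel(
            layers=(LayerSpec("void", 3.0, 0, 0, 0, 0, 0.0, 0.0),)
        )
        res = propagate_pixel(model, beam, transport_config, n_photons=2000,
                              seed=3)
        assert res.ledger.weights.size == 0
        assert res.detected_weight == 0.0

    def test_opaque_overlayer_blocks_detection(self, beam, transport_config):
        layers = (
            LayerSpec("absorber", 0.5, 0, 0, 0, 0, 13.0, 500.0),
            LayerSpec("dermis", 3.0, 0.005, 0, 0, 0, 13.0, 0.1),
        )
        model = SkinModel(layers=layers)
        res = propagate_pixel(model, beam, transport_config, n_photons=5000,
                              seed=3)
        # a handful of single-scatter survivors can still trickle out, but
        # the signal collapses by ~3 orders of magnitude vs healthy skin
        assert res.reflectance < 1e-4

    def test_healthy_smoke_and_energy_balance(self, healthy_model, beam,
                                              transport_config):
        res = propagate_pixel(healthy_model, beam, transport_config,
                              n_photons=20_000, splitting=True, seed=11)
        assert 0.0 < res.reflectance < 1.0
        assert 0.0 < res.total_reflectance < 1.0
        assert np.count_nonzero(res.ledger.shifts) > 0  # blood was seen
        assert res.energy_balance_error() < 1e-9

    def test_fixed_seed_bit_reproducible(self, healthy_model, beam,
                                         transport_config):
        a = propagate_pixel(healthy_model, beam, transport_config,
                            n_photons=10_000, splitting=True, seed=21)
        b = propagate_pixel(healthy_model, beam, transport_config,
                            n_photons=10_000, splitting=True, seed=21)
        np.testing.assert_array_equal(a.ledger.weights, b.ledger.weights)
        np.testing.assert_array_equal(a.ledger.shifts, b.ledger.shifts)
        assert a.detected_first_moment == b.detected_first_moment

    def test_splitting_is_unbiased(self, healthy_model, beam):
        """Perfusion with splitting on vs off agrees within MC error."""
        cfg = TransportConfig()
        on = [propagate_pixel(healthy_model, beam, cfg, n_photons=50_000,
                              splitting=True, seed=40 + s).perfusion_per_photon
              for s in range(6)]
        off = [propagate_pixel(healthy_model, beam, cfg, n_photons=50_000,
                               splitting=False, seed=50 + s).perfusion_per_photon
               for s in range(6)]
        se = math.hypot(np.std(on) / np.sqrt(6), np.std(off) / np.sqrt(6))
        assert abs(np.mean(on) - np.mean(off)) < 3.5 * se

    def test_ksc1_perfusion_exceeds_healthy(self, healthy_model, ksc1_model,
                                            beam, transport_config):
        h = np.mean([propagate_pixel(healthy_model, beam, transport_config,
                                     n_photons=30_000, splitting=True,
                                     seed=60 + s).perfusion_per_photon
                     for s in range(5)])
        t = np.mean([propagate_pixel(ksc1_model, beam, transport_config,
                                     n_photons=30_000, splitting=True,
                                     seed=70 + s).perfusion_per_photon
                     for s in range(5)])
        assert t > h

    def test_invalid_focal_depth(self, healthy_model, transport_config):
        with pytest.raises(ValueError, match="focal depth"):
            propagate_pixel(healthy_model, BeamSpec(focal_depth=10.0),
                            transport_config, n_photons=10)
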