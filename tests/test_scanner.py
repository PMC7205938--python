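"""Detector geometry, crystal constants and digitizer stages."""

import math

import numpy as np
import pytest

from wristpet.scanner import (
    CRYSTALS,
    BLOCK_AXIAL_CM,
    CrystalMaterial,
    apply_deadtime,
    apply_energy_window,
    blur_energy,
    build_wristpet1,
    build_wristpet2,
    crystal_pathlength,
    detection_probability,
    energy_fwhm,
)

# (name, density, decay ns, E-res %, attenuation length mm, window ns)
TABLE = [
    ("GSO", 6.71, 60.0, 8.5, 14.3, 4.5),
    ("LSO", 7.40, 40.0, 10.0, 11.4, 4.5),
    ("BGO", 7.13, 300.0, 10.2, 10.4, 10.0),
    ("CeBr3", 5.20, 17.0, 5.2, 19.6, 4.5),
    ("LaBr3", 5.30, 26.0, 3.2, 24.0, 4.5),
]


@pytest.mark.parametrize("name,rho,decay,res,att,window", TABLE)
def test_shipped_crystal_constants(name, rho, decay, res, att, window):
    m = CRYSTALS[name]
    assert m.density == rho
    assert m.decay_time_ns == decay
    assert m.energy_resolution_511 == res
    assert m.attenuation_length_511_mm == att
    assert m.coincidence_window_ns == window
    assert "Z_eff" in m.metadata


class TestWristPet1:
    def test_block_count_and_pitch(self, wristpet1_bgo):
        assert len(wristpet1_bgo.blocks) == 14
        az = [b.azimuth for b in wristpet1_bgo.blocks]
        pitches = np.diff(az)
        assert np.allclose(pitches, -2 * np.pi / 14)
        assert math.degrees(-pitches[0]) == pytest.approx(25.714285714)

    def test_center_radius_is_inner_radius_plus_half_depth(self, wristpet1_bgo):
        for b in wristpet1_bgo.blocks:
            r = math.hypot(b.center[0], b.center[1])
            assert r == pytest.approx(5.5 + 1.0, rel=1e-12)

    def test_volar_arc_symmetric_about_negative_y(self, wristpet1_bgo):
        az = {b.angular_index: math.degrees(b.azimuth) for b in wristpet1_bgo.blocks}
        # blocks 4 and 11 are the horizontal-equator blocks
        assert az[4] == pytest.approx(0.0, abs=1e-9)
        assert az[11] == pytest.approx(-180.0, abs=1e-9)
        for i in range(4, 12):
            assert az[i] + az[15 - i] == pytest.approx(-180.0, abs=1e-9)

    def test_axial_fov(self, wristpet1_bgo):
        assert wristpet1_bgo.axial_fov == 3.0

    def test_coincidence_window_comes_from_material(self, wristpet1_bgo):
        assert wristpet1_bgo.coincidence_window_ns == 10.0


class TestWristPet2:
    def test_single_ring_has_8_blocks(self, wristpet2_bgo):
        assert len(wristpet2_bgo.blocks) == 8

    def test_four_rings(self, bgo):
        sc = build_wristpet2(bgo, 4)
        assert len(sc.blocks) == 32
        assert sc.axial_fov == 12.0
        z = sorted({b.center[2] for b in sc.blocks})
        assert z == pytest.approx([-4.5, -1.5, 1.5, 4.5])

    def test_blocks_occupy_lower_half(self, wristpet2_bgo):
        ys = np.array([b.center[1] for b in wristpet2_bgo.blocks])
        assert np.all(ys <= 1e-9)
        assert np.sum(np.abs(ys) < 1e-9) == 2  # the two equator blocks

    @pytest.mark.parametrize("n", [0, 5])
    def test_invalid_ring_count(self, bgo, n):
        with pytest.raises(ValueError):
            build_wristpet2(bgo, n)

    def test_deadtime_defaults_to_three_decay_times(self, wristpet2_bgo):
        assert wristpet2_bgo.deadtime_s == pytest.approx(900e-9)


class TestCrystalPathlength:
    def test_normal_incidence_through_center(self, wristpet1_bgo):
        b = wristpet1_bgo.blocks[0]
        d = np.array([math.cos(b.azimuth), math.sin(b.azimuth), 0.0])
        assert crystal_pathlength(b, (0.0, 0.0, 0.0), d) == pytest.approx(2.0, abs=1e-12)

    def test_miss_returns_zero(self, wristpet1_bgo):
        b = wristpet1_bgo.blocks[0]
        d = -np.array([math.cos(b.azimuth), math.sin(b.azimuth), 0.0])
        assert crystal_pathlength(b, (0.0, 0.0, 0.0), d) == 0.0

    def test_agrees_with_ray_marching_oracle(self, wristpet1_bgo):
        rng = np.random.default_rng(3)
        step = 1e-3
        ts = (np.arange(int(15.0 / step)) + 0.5) * step
        b = wristpet1_bgo.blocks[5]
        ca, sa = math.cos(b.azimuth), math.sin(b.azimuth)
        half = np.array([1.0, 1.225, 1.5])
        for _ in range(300):
            o = rng.uniform(-2, 2, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pts = o[None, :] + ts[:, None] * d[None, :]
            rel = pts - np.asarray(b.center)
            local = np.column_stack(
                [
                    rel[:, 0] * ca + rel[:, 1] * sa,
                    -rel[:, 0] * sa + rel[:, 1] * ca,
                    rel[:, 2],
                ]
            )
            inside = np.all(np.abs(local) <= half, axis=1)
            assert crystal_pathlength(b, o, d) == pytest.approx(
                inside.sum() * step, abs=0.01
            )


class TestDetectionProbability:
    def test_one_attenuation_length(self, bgo):
        lam_cm = bgo.attenuation_length_511_mm / 10
        assert detection_probability(lam_cm, bgo) == pytest.approx(1 - 1 / math.e, rel=1e-12)

    def test_bgo_full_depth(self, bgo):
        assert detection_probability(2.0, bgo) == pytest.approx(1 - math.exp(-20 / 10.4), rel=1e-12)
        assert detection_probability(2.0, bgo) == pytest.approx(0.8539, abs=1e-3)

    def test_zero_pathlength(self, bgo):
        assert detection_probability(0.0, bgo) == 0.0

    def test_efficiency_ordering_follows_attenuation_length(self):
        effs = {n: detection_probability(2.0, CRYSTALS[n]) for n in CRYSTALS}
        assert effs["BGO"] > effs["LSO"] > effs["GSO"] > effs["CeBr3"] > effs["LaBr3"]


class TestEnergyResponse:
    def test_bgo_fwhm_at_511(self, bgo):
        assert energy_fwhm(511.0, bgo) == pytest.approx(0.102 * 511.0, rel=1e-12)
        assert energy_fwhm(511.0, bgo) == pytest.approx(52.12, abs=0.01)

    def test_fwhm_scales_inverse_sqrt_energy(self, bgo):
        assert energy_fwhm(511.0 / 4, bgo) == pytest.approx(2 * energy_fwhm(511.0, bgo))

    def test_zero_resolution_returns_exact_energy(self, rng):
        ideal = CrystalMaterial("ideal", 7.0, 40.0, 0.0, 10.0, 4.5)
        assert blur_energy(511.0, ideal, rng) == 511.0

    def test_blur_is_unbiased(self, bgo, rng):
        draws = blur_energy(np.full(100_000, 511.0), bgo, rng)
        assert abs(draws.mean() - 511.0) < 0.5
        assert np.all(draws >= 0)


class TestEnergyWindow:
    def test_photopeak_accepted(self):
        assert apply_energy_window(511.0, (350.0, 650.0))

    def test_backscatter_rejected(self):
        # 180-degree Compton photon: 511/(1+2) = 170.33 keV
        assert not apply_energy_window(511.0 / 3.0, (350.0, 650.0))

    def test_boundaries_are_closed(self):
        assert apply_energy_window(350.0, (350.0, 650.0))
        assert apply_energy_window(650.0, (350.0, 650.0))
        assert not apply_energy_window(349.999, (350.0, 650.0))

    def test_invalid_window_raises(self):
        with pytest.raises(ValueError):
            apply_energy_window(400.0, (650.0, 350.0))


class TestDeadtime:
    def test_zero_tau_is_identity(self):
        times = np.array([0.0, 1e-9, 2e-9])
        assert apply_deadtime(times, 0.0).all()

    def test_event_inside_dead_window_removed(self):
        keep = apply_deadtime(np.array([0.0, 0.5e-6]), 1e-6)
        assert keep.tolist() == [True, False]

    def test_event_after_dead_window_kept(self):
        keep = apply_deadtime(np.array([0.0, 1.5e-6]), 1e-6)
        assert keep.tolist() == [True, True]

    def test_unsorted_raises(self):
        with pytest.raises(ValueError):
            apply_deadtime(np.array([1.0, 0.5]), 1e-6)

    def test_poisson_stream_matches_nonparalyzable_formula(self, rng):
        """Surviving rate ~ r/(1 + r*tau) at r*tau = 0.1."""
        r, tau, n = 1.0e4, 1.0e-5, 100_000
        times = np.cumsum(rng.exponential(1 / r, n))
        keep = apply_deadtime(times, tau)
        surviving_rate = keep.sum() / times[-1]
        assert surviving_rate == pytest.approx(r / (1 + r * tau), rel=0.02)
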