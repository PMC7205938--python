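"""Monte Carlo chain: decays, emission, transport, detection, sorting."""

import math

import numpy as np
import pytest
from scipy import stats

from wristpet.engine import (
    CoincidenceEvent,
    DecayEvent,
    SingleEvent,
    SinglesBatch,
    _PhantomArrays,
    _ScannerArrays,
    classify_coincidence,
    compton_scattered_energy,
    detect_batch,
    detect_photon,
    emit_annihilation,
    isotropic_directions,
    sample_decays,
    sample_klein_nishina_costheta,
    simulate,
    sort_coincidences,
    transport_batch,
    transport_photon,
)
from wristpet.flow import point_source_timeline
from wristpet.phantom import CylinderVolume, Material, PhantomModel, water_cylinder_phantom
from wristpet.scanner import CRYSTALS, CrystalMaterial, ScannerConfig, build_wristpet2


def make_singles(times, blocks, decay_ids=None, scattered=None):
    times = np.asarray(times, dtype=float)
    n = len(times)
    return SinglesBatch(
        times=times,
        blocks=np.asarray(blocks, dtype=int),
        energies=np.full(n, 511.0),
        decay_ids=np.asarray(decay_ids if decay_ids is not None else np.arange(n), dtype=np.int64),
        scattered=np.asarray(scattered if scattered is not None else np.zeros(n, bool)),
    )


class TestSampleDecays:
    def test_poisson_mean(self, rng):
        # 1 MBq over 1 ms -> Poisson(1000); mean of 100 repeats within 4 sigma
        tl = point_source_timeline((0, 0, 0), 1e6, [0.0], [1e-3])
        counts = [len(sample_decays(tl, rng)) for _ in range(100)]
        sem = math.sqrt(1000 / 100)
        assert abs(np.mean(counts) - 1000) < 4 * sem

    def test_zero_activity_no_decays(self, rng):
        tl = point_source_timeline((0, 0, 0), 0.0, [0.0], [1.0])
        assert len(sample_decays(tl, rng)) == 0

    def test_index_of_dispersion_near_one(self, rng):
        n_bins = 10_000
        starts = np.arange(n_bins, dtype=float)
        tl = point_source_timeline((0, 0, 0), np.full(n_bins, 5.0), starts, starts + 1.0)
        d = sample_decays(tl, rng)
        counts = np.histogram(d.times, bins=np.arange(n_bins + 1, dtype=float))[0]
        iod = counts.var() / counts.mean()
        assert iod == pytest.approx(1.0, abs=0.05)

    def test_positions_inside_segment(self, rng):
        tl = point_source_timeline((1.0, -2.0, 3.0), 1e5, [0.0], [0.1],
                                   radius=0.2, half_length=0.5)
        d = sample_decays(tl, rng)
        r = np.hypot(d.positions[:, 0] - 1.0, d.positions[:, 1] + 2.0)
        assert np.all(r <= 0.2 + 1e-12)
        assert np.all(np.abs(d.positions[:, 2] - 3.0) <= 0.5 + 1e-12)

    def test_times_sorted(self, rng):
        tl = point_source_timeline((0, 0, 0), 1e5, [0.0], [1.0])
        d = sample_decays(tl, rng)
        assert np.all(np.diff(d.times) >= 0)


class TestEmission:
    def test_back_to_back(self, rng):
        decay = DecayEvent(0, 1.0, (0.5, -0.5, 2.0), "seg")
        (p1, d1, e1), (p2, d2, e2) = emit_annihilation(decay, rng)
        assert e1 == e2 == 511.0
        assert np.dot(d1, d2) == pytest.approx(-1.0, abs=1e-12)
        np.testing.assert_array_equal(p1, p2)

    def test_directions_uniform_on_sphere(self, rng):
        d = isotropic_directions(10_000, rng)
        np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, rtol=1e-12)
        # z-component uniform on [-1, 1]
        p = stats.kstest(d[:, 2], stats.uniform(loc=-1, scale=2).cdf).pvalue
        assert p > 0.01


class TestComptonKinematics:
    def test_backscatter_energy(self):
        assert compton_scattered_energy(511.0, -1.0) == pytest.approx(511.0 / 3.0, rel=1e-12)
        assert compton_scattered_energy(511.0, -1.0) == pytest.approx(170.33, abs=0.01)

    def test_forward_scatter_keeps_energy(self):
        assert compton_scattered_energy(511.0, 1.0) == 511.0

    def test_klein_nishina_distribution(self, rng):
        """Sampler matches the numerically integrated KN distribution."""
        draws = sample_klein_nishina_costheta(np.full(20_000, 511.0), rng)
        mu = np.linspace(-1.0, 1.0, 4001)
        eps = 1.0 / (1.0 + (1.0 - mu))  # alpha = 1 at 511 keV
        pdf = eps**2 * (eps + 1.0 / eps - (1.0 - mu**2))
        cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(mu))])
        cdf /= cdf[-1]
        p = stats.kstest(draws, lambda x: np.interp(x, mu, cdf)).pvalue
        assert p > 0.01


def thin_phantom():
    """A phantom with negligible attenuation (everything escapes)."""
    mat = Material("near-vacuum", 1e-3, 1e-9, 0.99)
    vol = CylinderVolume("shell", (0.0, 0.0), 4.0, 20.0, mat, 0)
    return PhantomModel(volumes=(vol,))


class TestTransport:
    def test_negligible_mu_always_escapes_unscattered(self, rng):
        geom = _PhantomArrays(thin_phantom())
        n = 2000
        pos = np.zeros((n, 3))
        d = isotropic_directions(n, rng)
        alive, _, _, e, sc = transport_batch(geom, pos, d, rng)
        assert alive.all()
        assert not sc.any()
        assert np.all(e == 511.0)

    def test_unscattered_escape_through_8cm_water(self, rng):
        """Survival through a full water diameter matches Beer-Lambert."""
        geom = _PhantomArrays(water_cylinder_phantom())
        n = 100_000
        pos = np.tile([0.0, -3.9999, 0.0], (n, 1))
        d = np.tile([0.0, 1.0, 0.0], (n, 1))
        alive, _, _, _, sc = transport_batch(geom, pos, d, rng)
        unscattered = (alive & ~sc).mean()
        expected = math.exp(-0.0958 * 7.9999)
        assert unscattered == pytest.approx(expected, rel=0.01)

    def test_scattered_photons_lose_energy(self, rng):
        geom = _PhantomArrays(water_cylinder_phantom())
        n = 200_000
        pos = np.zeros((n, 3))
        d = isotropic_directions(n, rng)
        alive, _, _, e, sc = transport_batch(geom, pos, d, rng)
        assert sc.any()
        assert np.all(e[alive & sc] < 511.0)
        assert np.all(e[alive & ~sc] == 511.0)

    def test_scalar_wrapper_roundtrip(self, rng):
        out = transport_photon(((0.0, 0.0, 0.0), (0.0, 1.0, 0.0), 511.0), thin_phantom(), rng)
        assert out.escaped and not out.scattered
        assert out.energy == 511.0


class TestDetection:
    def test_miss_returns_none(self, wristpet2_bgo, rng):
        # straight up from the center: the half-ring only covers the bottom
        single = detect_photon(((0.0, 0.0, 0.0), (0.0, 0.0, 1.0), 511.0), wristpet2_bgo, rng)
        assert single is None

    def test_normal_incidence_acceptance_rate(self, wristpet1_bgo, rng):
        """Acceptance ~ (1 - exp(-2 cm / lambda)) x window pass fraction."""
        b = wristpet1_bgo.blocks[0]
        d = np.array([math.cos(b.azimuth), math.sin(b.azimuth), 0.0])
        n = 100_000
        sarr = _ScannerArrays(wristpet1_bgo)
        batch = detect_batch(
            sarr,
            np.zeros((n, 3)),
            np.tile(d, (n, 1)),
            np.full(n, 511.0),
            np.zeros(n),
            np.arange(n, dtype=np.int64),
            np.zeros(n, bool),
            rng,
            jitter_ns=0.0,
        )
        expected = 1 - math.exp(-2.0 / 1.04)  # window pass ~ 1 at 511 keV
        assert len(batch) / n == pytest.approx(expected, rel=0.02)

    def test_backscattered_photon_rejected_by_window(self, wristpet1_bgo, rng):
        b = wristpet1_bgo.blocks[0]
        d = np.array([math.cos(b.azimuth), math.sin(b.azimuth), 0.0])
        n = 20_000
        sarr = _ScannerArrays(wristpet1_bgo)
        batch = detect_batch(
            sarr,
            np.zeros((n, 3)),
            np.tile(d, (n, 1)),
            np.full(n, 511.0 / 3.0),
            np.zeros(n),
            np.arange(n, dtype=np.int64),
            np.ones(n, bool),
            rng,
        )
        # detected-but-rejected in >= 99% of geometric hits
        assert len(batch) < 0.01 * n

    def test_detected_energy_is_blurred(self, wristpet1_bgo, rng):
        b = wristpet1_bgo.blocks[3]
        d = np.array([math.cos(b.azimuth), math.sin(b.azimuth), 0.0])
        single = None
        while single is None:
            single = detect_photon(((0, 0, 0), d, 511.0), wristpet1_bgo, rng)
        assert 350.0 <= single.energy <= 650.0
        assert single.block == b.id


def brute_force_sorter(times, blocks, window):
    """Independent re-statement of the sorting rule for small cases."""
    n = len(times)
    pairs = []
    i = 0
    while i < n:
        members = [j for j in range(i, n) if times[j] <= times[i] + window]
        k = len(members)
        if k >= 2:
            all_good = all(
                blocks[p] != blocks[q]
                for ai, p in enumerate(members)
                for q in members[ai + 1 :]
            )
            if all_good:
                for ai, p in enumerate(members):
                    for q in members[ai + 1 :]:
                        pairs.append((p, q))
        i = members[-1] + 1
    return pairs


class TestCoincidenceSorting:
    W = 10e-9

    def test_pair_within_window(self):
        s = make_singles([0.0, self.W / 2], [1, 2])
        c = sort_coincidences(s, self.W)
        assert len(c) == 1

    def test_pair_outside_window(self):
        s = make_singles([0.0, 2 * self.W], [1, 2])
        assert len(sort_coincidences(s, self.W)) == 0

    def test_same_block_pair_discarded(self):
        s = make_singles([0.0, self.W / 2], [3, 3])
        assert len(sort_coincidences(s, self.W)) == 0

    def test_triple_on_distinct_blocks_gives_three_pairs(self):
        s = make_singles([0.0, self.W / 3, self.W / 2], [1, 2, 3])
        assert len(sort_coincidences(s, self.W)) == 3

    def test_triple_with_shared_block_discarded(self):
        s = make_singles([0.0, self.W / 3, self.W / 2], [1, 2, 1])
        assert len(sort_coincidences(s, self.W)) == 0

    def test_unsorted_raises(self):
        s = make_singles([1.0, 0.0], [1, 2])
        with pytest.raises(ValueError):
            sort_coincidences(s, self.W)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            n = rng.integers(1, 9)
            times = np.sort(rng.uniform(0, 5 * self.W, n))
            blocks = rng.integers(1, 5, n)
            s = make_singles(times, blocks)
            got = sorted(zip(sort_coincidences(s, self.W).first,
                             sort_coincidences(s, self.W).second))
            want = sorted(brute_force_sorter(times, blocks, self.W))
            assert [(int(a), int(b)) for a, b in got] == want

    def test_windows_consume_disjoint_singles(self, rng):
        """Sorting windows never reuse a single: pairs sharing an index
        belong to the same window, and distinct windows occupy disjoint
        index ranges."""
        n = 3000
        times = np.sort(rng.uniform(0, 1e-4, n))
        blocks = rng.integers(1, 9, n)
        c = sort_coincidences(make_singles(times, blocks), self.W)
        # union-find pairs into clusters and check index ranges are disjoint
        parent = {}

        def find(x):
            parent.setdefault(x, x)
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for f, s in zip(c.first, c.second):
            parent[find(int(f))] = find(int(s))
        clusters = {}
        for idx in parent:
            clusters.setdefault(find(idx), []).append(idx)
        spans = sorted((min(m), max(m)) for m in clusters.values())
        for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
            assert hi1 < lo2
            # singles of one window fit inside the coincidence window
            assert times[hi1] - times[lo1] <= self.W * (1 + 1e-9)


class TestClassification:
    def mk(self, decay_id, scattered):
        return SingleEvent(0.0, 1, 511.0, decay_id, scattered)

    def test_true(self):
        c = CoincidenceEvent(self.mk(7, False), self.mk(7, False), "")
        assert classify_coincidence(c) == "true"

    def test_scattered(self):
        c = CoincidenceEvent(self.mk(7, True), self.mk(7, False), "")
        assert classify_coincidence(c) == "scattered"

    def test_random(self):
        c = CoincidenceEvent(self.mk(7, False), self.mk(8, False), "")
        assert classify_coincidence(c) == "random"


def rectangle_solid_angle(a, b, d):
    """Solid angle of an a x b rectangle at on-axis distance d."""
    return 4 * math.atan(a * b / (2 * d * math.sqrt(4 * d * d + a * a + b * b)))


def ideal_two_block_scanner():
    """Opposed horizontal blocks with unit detection efficiency."""
    ideal = CrystalMaterial("ideal", 7.0, 1e-6, 0.0, 1e-6, 4.5)
    full = build_wristpet2(ideal, 1)
    opposed = tuple(b for b in full.blocks if b.angular_index in (4, 11))
    return ScannerConfig(
        name="two-block",
        blocks=opposed,
        material=ideal,
        ring_inner_diameter=full.ring_inner_diameter,
        n_axial_rings=1,
    )


class TestEndToEnd:
    def test_opposed_detector_closed_form(self):
        """Trues rate = decay rate x pair acceptance (analytic solid angle).

        With negligible phantom attenuation and unit crystal efficiency,
        the pair acceptance for two point-symmetric opposed blocks equals
        the solid-angle fraction Omega/(2 pi) of one inner face.
        """
        sc = ideal_two_block_scanner()
        tl = point_source_timeline((0, 0, 0), 2.0e4, [0.0], [10.0])
        res = simulate(tl, thin_phantom(), {"toy": sc}, 99, jitter_ns=0.0)["toy"]
        omega = rectangle_solid_angle(2.45, 3.0, 5.5)
        expected = res.n_decays * omega / (2 * math.pi)
        trues = res.coincidences.count("true")
        assert trues == pytest.approx(expected, abs=4 * math.sqrt(expected))

    def test_conservation_no_single_in_two_windows(self):
        sc = ideal_two_block_scanner()
        tl = point_source_timeline((0, 0, 0), 5.0e4, [0.0], [5.0])
        res = simulate(tl, thin_phantom(), {"toy": sc}, 5)["toy"]
        c = res.coincidences
        # each sorted window contributes disjoint singles; with 2 blocks
        # every window has at most 1 pair, so indices are globally unique
        used = np.concatenate([c.first, c.second])
        assert len(np.unique(used)) == len(used)

    def test_randoms_quadratic_trues_linear_in_activity(self):
        """log-log slopes of randoms (~2) and trues (~1) vs activity."""
        fast = CrystalMaterial("fast-bgo", 7.13, 1e-3, 10.2, 10.4, 10.0)
        sc = build_wristpet2(fast, 1)
        phantom = water_cylinder_phantom()
        activities = np.geomspace(3e6, 3e7, 4)
        trues, randoms = [], []
        for i, A in enumerate(activities):
            dur = 2.0e5 / A
            tl = point_source_timeline((0, -1.0, 0), A, [0.0], [dur])
            res = simulate(tl, phantom, {"s": sc}, 1000 + i)["s"]
            trues.append(res.coincidences.count("true") / dur)
            randoms.append(res.coincidences.count("random") / dur)
        slope_t = np.polyfit(np.log(activities), np.log(trues), 1)[0]
        slope_r = np.polyfit(np.log(activities), np.log(randoms), 1)[0]
        assert slope_t == pytest.approx(1.0, abs=0.1)
        assert slope_r == pytest.approx(2.0, abs=0.15)

    def test_crystal_ranking_bgo_highest(self):
        """BGO tops singles and coincidences for an identical source."""
        # low-activity regime (wrist concentrations): deadtime negligible,
        # so the attenuation-length ordering decides the ranking
        phantom = water_cylinder_phantom()
        tl = point_source_timeline((0, -2.0, 0), 2e5, [0.0], [5.0])
        scanners = {name: build_wristpet2(CRYSTALS[name], 1) for name in CRYSTALS}
        results = simulate(tl, phantom, scanners, 7)
        singles = {n: len(r.singles) for n, r in results.items()}
        coinc = {n: len(r.coincidences) for n, r in results.items()}
        assert max(singles, key=singles.get) == "BGO"
        assert max(coinc, key=coinc.get) == "BGO"

    def test_bit_reproducibility(self):
        sc = build_wristpet2(CRYSTALS["BGO"], 1)
        phantom = water_cylinder_phantom()
        tl = point_source_timeline((0, -2.0, 0), 1e6, [0.0], [0.2])
        a = simulate(tl, phantom, {"s": sc}, 123)["s"]
        b = simulate(tl, phantom, {"s": sc}, 123)["s"]
        np.testing.assert_array_equal(a.singles.times, b.singles.times)
        np.testing.assert_array_equal(a.singles.blocks, b.singles.blocks)
        assert len(a.coincidences) == len(b.coincidences)
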