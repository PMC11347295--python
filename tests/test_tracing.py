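"""Path tracer: cone sampling, marching, scanline profiles, MC estimator."""

import math

import numpy as np
import pytest
from scipy.stats import truncnorm

from sonopath.acoustics import attenuation_factor
from sonopath.scene import DEFAULT_TISSUES, LabelScene
from sonopath.tracing import (
    ConeSampler,
    SimConfig,
    TransducerConfig,
    beam_coherence_weight,
    march_ray,
    sample_cone_direction,
    trace_frame,
    trace_scanline,
)

AXIS_Z = np.array([0.0, 0.0, 1.0])


class TestConeSampler:
    def test_collapsed_cone_returns_axis(self, rng):
        sampler = ConeSampler(0.0, 0.0, 0.0, math.pi / 2)
        for _ in range(5):
            d, pdf = sample_cone_direction(AXIS_Z, sampler, rng)
            assert np.allclose(d, AXIS_Z)
            assert pdf == math.inf

    def test_polar_angle_mean_matches_truncated_normal(self, rng):
        """Empirical mean polar angle equals the closed-form truncated
        normal mean for (mu=0, sigma=pi/4, a=0, b=pi/2)."""
        sampler = ConeSampler(0.0, math.pi / 4, 0.0, math.pi / 2)
        phis = []
        for _ in range(20000):
            d, _ = sample_cone_direction(AXIS_Z, sampler, rng)
            phis.append(math.acos(np.clip(d[2], -1, 1)))
        expected = truncnorm(0.0, 2.0, loc=0.0, scale=math.pi / 4).mean()
        assert np.mean(phis) == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx(0.568, abs=0.001)

    def test_pdf_integrates_to_one_over_hemisphere(self):
        """Spherical quadrature of the returned solid-angle density."""
        sampler = ConeSampler(0.0, math.pi / 4, 0.0, math.pi / 2)
        phi = np.linspace(1e-6, math.pi / 2 - 1e-9, 4000)
        p = sampler.solid_angle_pdf(phi)
        integral = np.trapezoid(p * np.sin(phi) * 2.0 * math.pi, phi)
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_samples_respect_truncation_bounds(self, rng):
        sampler = ConeSampler(0.0, math.pi / 3, 0.1, 0.9)
        for _ in range(500):
            d, _ = sample_cone_direction(AXIS_Z, sampler, rng)
            phi = math.acos(np.clip(d[2], -1, 1))
            assert 0.1 - 1e-9 <= phi <= 0.9 + 1e-9

    def test_degenerate_axis_rejected(self, rng):
        sampler = ConeSampler(0.0, math.pi / 4, 0.0, math.pi / 2)
        with pytest.raises(ValueError):
            sample_cone_direction(np.zeros(3), sampler, rng)


class TestBeamCoherence:
    def test_on_beam_weight_is_one(self):
        assert beam_coherence_weight(0.1, 0.0) == pytest.approx(1.0)

    def test_half_weight_at_c0(self):
        assert beam_coherence_weight(0.1, 0.1) == pytest.approx(0.5)

    def test_strictly_decreasing(self):
        d = np.linspace(0, 10, 50)
        w = beam_coherence_weight(0.1, d)
        assert np.all(np.diff(w) < 0)


def fine_step_events(scene, origin, direction, max_range, step):
    """Independent fine-step traversal oracle: label changes at step/10."""
    ts = np.arange(0.0, max_range, step / 10.0)
    labels = scene.grid.label_at(origin + ts[:, None] * direction)
    idx = np.flatnonzero(labels[1:] != labels[:-1])
    return [(float(ts[i + 1]), int(labels[i]), int(labels[i + 1])) for i in idx]


class TestMarchRay:
    def test_homogeneous_volume_has_no_events(self, slab_scene):
        events = march_ray(
            slab_scene, np.array([0.0, 0.0, 50.0]), AXIS_Z, 30.0
        )
        assert events == []

    def test_flat_slab_two_events_at_faces(self, two_layer_scene):
        events = march_ray(
            two_layer_scene, np.array([0.0, 0.0, 0.0]), AXIS_Z, 100.0
        )
        assert len(events) == 2
        step = 0.25
        assert events[0].t_mm == pytest.approx(30.0, abs=step / 2)
        assert events[1].t_mm == pytest.approx(60.0, abs=step / 2)
        assert events[0].label_from == 0 and events[0].label_to == 1
        assert events[1].segment_mm == pytest.approx(30.0, abs=step)
        for ev in events:
            assert np.dot(ev.normal, AXIS_Z) <= 0  # oriented against the ray
            assert ev.cos_incidence == pytest.approx(1.0, abs=0.02)

    def test_two_sphere_scene_matches_fine_step_oracle(self, rng):
        water = DEFAULT_TISSUES["water"]
        soft = DEFAULT_TISSUES["soft_tissue"]
        fat = DEFAULT_TISSUES["fat"]
        sp = 0.5
        n = 80
        ax = (np.arange(n) - n / 2 + 0.5) * sp
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        labels = np.zeros((n, n, n), dtype=np.int16)
        labels[(xx - 3) ** 2 + yy**2 + (zz + 6) ** 2 <= 36] = 1
        labels[(xx + 4) ** 2 + yy**2 + (zz - 7) ** 2 <= 25] = 2
        scene = LabelScene.build(
            labels, [sp] * 3, [ax[0]] * 3, {0: water, 1: soft, 2: fat}, ambient=water
        )
        step = sp / 2.0
        centres = [np.array([3.0, 0.0, -6.0]), np.array([-4.0, 0.0, 7.0])]
        for k in range(6):
            origin = rng.uniform(-18, -12, 3)
            # aim through a sphere centre (transversal crossings; grazing
            # rays are out of contract for step marching)
            target = centres[k % 2] + rng.uniform(-1.0, 1.0, 3)
            direction = target - origin
            direction /= np.linalg.norm(direction)
            got = march_ray(scene, origin, direction, 35.0, step)
            expected = fine_step_events(scene, origin, direction, 35.0, step)
            assert len(got) == len(expected)
            for ev, (t, lf, lt) in zip(got, expected):
                assert ev.t_mm == pytest.approx(t, abs=step)
                assert (ev.label_from, ev.label_to) == (lf, lt)


def branch_enumeration_profile(depths, tissues_seq, transducer, max_collisions,
                               tau, gamma):
    """Exhaustive branch-tree oracle for a stack of flat interfaces at
    normal incidence with a collapsed sampling cone.

    Walks every reflect/refract branch of the binary tree with its exact
    probability (reflect with p = R), accumulating per-branch intensity
    deposits and boundary echoes on the radial grid exactly as a 1-D ray
    would, and returns the expectation and the per-bin branch variance of
    both profiles.  Independent of the tracer: pure 1-D bookkeeping.
    """
    from sonopath.acoustics import reflection_coefficient

    dr = transducer.radial_spacing_mm
    n = transducer.n_radial_samples
    f = transducer.center_frequency_mhz
    depth = transducer.depth_mm
    max_path = 1.5 * depth

    def medium_at(z):
        for (z0, z1), t in tissues_seq:
            if z0 <= z < z1:
                return t
        return tissues_seq[-1][1]

    def next_interface(z, going_down):
        cands = [d for d in depths if (d > z + 1e-9 if going_down else d < z - 1e-9)]
        if not cands:
            return None
        return min(cands) if going_down else max(cands)

    results = []  # (probability, intensity_profile, echo_profile)

    def walk(z, going_down, carried, collisions, travelled, prob, acc_i, acc_e):
        while True:
            sgn = 1.0 if going_down else -1.0
            med = medium_at(z + sgn * 1e-6)
            nxt = next_interface(z, going_down)
            remaining = max_path - travelled
            seg = min(abs(nxt - z), remaining) if nxt is not None else remaining
            ts = np.arange(0.5 * dr, seg, dr)
            zs = z + sgn * ts
            inb = (zs >= 0.0) & (zs < depth)
            vals = carried * attenuation_factor(ts[inb] / 10.0, f, med.attenuation)
            bins = np.minimum((zs[inb] / dr).astype(int), n - 1)
            np.add.at(acc_i, bins, vals)
            carried *= float(attenuation_factor(seg / 10.0, f, med.attenuation))
            travelled += seg
            hit = nxt is not None and abs(nxt - z) <= remaining
            z = z + sgn * seg
            if not hit or carried < 1e-12:
                results.append((prob, acc_i, acc_e))
                return
            t_from = med
            t_to = medium_at(z + sgn * 1e-6)
            R = reflection_coefficient(t_from.impedance, t_to.impedance, 1.0, 1.0)
            # echo deposited before branching, shared by both branches
            if 0.0 <= z < depth:
                b = min(int(z / dr + 0.5), n - 1)
                base = ((t_to.impedance - t_from.impedance) /
                        (t_to.impedance + t_from.impedance)) ** 2
                # the entered tissue's tau shapes the echo (model convention)
                acc_e[b] += carried * base * t_to.tau
            collisions += 1
            if collisions >= max_collisions:
                # both branches terminate right after the bounce
                results.append((prob * R, acc_i.copy(), acc_e.copy()))
                results.append((prob * (1.0 - R), acc_i, acc_e))
                return
            walk(z, not going_down, carried * R, collisions, travelled,
                 prob * R, acc_i.copy(), acc_e.copy())
            carried *= 1.0 - R
            prob *= 1.0 - R
            # refracted branch continues in the same direction (loop)

    walk(0.0, True, 1.0, 0, 0.0, 1.0, np.zeros(n), np.zeros(n))
    probs = np.array([r[0] for r in results])
    assert probs.sum() == pytest.approx(1.0, abs=1e-9)
    mean_i = sum(p * r for p, r, _ in results)
    mean_e = sum(p * r for p, _, r in results)
    var_i = sum(p * (r - mean_i) ** 2 for p, r, _ in results)
    var_e = sum(p * (r - mean_e) ** 2 for p, _, r in results)
    return mean_i, mean_e, var_i, var_e


class TestTraceScanline:
    def test_homogeneous_lossless_profile_is_constant(self):
        lossless = DEFAULT_TISSUES["water"]
        labels = np.zeros((20, 8, 100), dtype=np.int16)
        scene = LabelScene.build(
            labels, [0.5] * 3, [-5 + 0.25, -2 + 0.25, 0.25], {0: lossless},
            ambient=lossless,
        )
        tdx = TransducerConfig(
            scan_geometry="linear", num_elements=3, depth_mm=40.0
        )
        sim = SimConfig(num_rays=4, seed=0)
        inten, ech = trace_scanline(scene, tdx, sim, 1)
        # water attenuation is ~0.002 dB/(cm MHz): profile ~ 1 everywhere
        assert np.all(inten > 0.99)
        assert np.all(inten <= 1.0 + 1e-9)
        assert np.all(ech == 0.0)

    def test_single_interface_deterministic_profile(self, slab_scene):
        """MCPT disabled: transmitted fraction and Eq-style echo match the
        single-path hand computation."""
        water = DEFAULT_TISSUES["water"]
        soft = DEFAULT_TISSUES["soft_tissue"]
        tdx = TransducerConfig(
            scan_geometry="linear", num_elements=3, element_width_mm=1.0,
            kerf_mm=0.0, depth_mm=90.0,
        )
        sim = SimConfig(num_rays=1, enable_mcpt=False, seed=0)
        inten, ech = trace_scanline(slab_scene, tdx, sim, 1)
        dr = tdx.radial_spacing_mm
        Z1, Z2 = water.impedance, soft.impedance
        R = ((Z2 - Z1) / (Z2 + Z1)) ** 2
        atten_to_iface = attenuation_factor(4.0, 3.6, water.attenuation)
        for z in (55.0, 75.0):
            expected = (
                atten_to_iface
                * (1 - R)
                * attenuation_factor((z - 40.0) / 10.0, 3.6, soft.attenuation)
            )
            assert inten[int(z / dr)] == pytest.approx(expected, rel=0.02)
        echo_bin = np.argmax(ech)
        assert echo_bin * dr == pytest.approx(40.0, abs=0.1)
        # echo = R_pressure^2 * I * tau * cos^gamma at normal incidence
        assert ech[echo_bin] == pytest.approx(
            atten_to_iface * R * soft.tau, rel=0.02
        )

    def test_invalid_scanline_index(self, slab_scene):
        tdx = TransducerConfig(scan_geometry="linear", num_elements=3, depth_mm=50)
        with pytest.raises(IndexError):
            trace_scanline(slab_scene, tdx, SimConfig(num_rays=1), 5)

    def test_mc_estimator_matches_branch_enumeration(self, two_layer_scene):
        """Monte-Carlo profile on a two-interface slab equals the exhaustive
        branch-tree expectation within 3 standard errors (collapsed cone:
        the only randomness is the reflect/refract choice)."""
        water = DEFAULT_TISSUES["water"]
        soft = DEFAULT_TISSUES["soft_tissue"]
        tdx = TransducerConfig(
            scan_geometry="linear", num_elements=3, element_width_mm=1.0,
            kerf_mm=0.0, depth_mm=85.0,
        )
        N = 10_000
        sim = SimConfig(
            num_rays=N, max_collisions=4, cone_sigma=0.0, seed=42,
            beam_coherence_c0=0.1,
        )
        inten, ech = trace_scanline(two_layer_scene, tdx, sim, 1)
        mean_i, mean_e, var_i, var_e = branch_enumeration_profile(
            depths=[30.0, 60.0],
            tissues_seq=[((-1e9, 30.0), water), ((30.0, 60.0), soft),
                         ((60.0, 1e9), water)],
            transducer=tdx,
            max_collisions=4,
            tau=soft.tau,
            gamma=soft.gamma,
        )
        dr = tdx.radial_spacing_mm
        # compare intensity at probe depths away from the interfaces
        for z in (15.0, 45.0, 75.0):
            b = int(z / dr)
            se = math.sqrt(var_i[b] / N)
            assert abs(inten[b] - mean_i[b]) <= 3.0 * se + 1e-6 * mean_i[b] + 1e-9
        # echoes at the interfaces (the exit face into water carries
        # tau = 0 and is checked as an exact zero)
        for z in (30.0, 60.0):
            b = int(z / dr + 0.5)
            window = slice(max(b - 3, 0), b + 4)
            got = ech[window].sum()
            exp = mean_e[window].sum()
            se = math.sqrt(var_e[window].sum() / N)
            assert abs(got - exp) <= 3.0 * se + 0.02 * exp + 1e-12

    def test_mc_error_decreases_with_sample_size(self, two_layer_scene):
        """MC estimate converges toward the branch-tree expectation."""
        water = DEFAULT_TISSUES["water"]
        soft = DEFAULT_TISSUES["soft_tissue"]
        tdx = TransducerConfig(
            scan_geometry="linear", num_elements=3, element_width_mm=1.0,
            kerf_mm=0.0, depth_mm=85.0,
        )
        mean_i, _, _, _ = branch_enumeration_profile(
            [30.0, 60.0],
            [((-1e9, 30.0), water), ((30.0, 60.0), soft), ((60.0, 1e9), water)],
            tdx, 4, soft.tau, soft.gamma,
        )
        dr = tdx.radial_spacing_mm
        probe = [int(z / dr) for z in (45.0, 75.0)]
        errs = {}
        for N in (100, 10_000):
            sim = SimConfig(num_rays=N, max_collisions=4, cone_sigma=0.0, seed=7)
            inten, _ = trace_scanline(two_layer_scene, tdx, sim, 1)
            errs[N] = sum(abs(inten[b] - mean_i[b]) for b in probe)
        assert errs[10_000] <= errs[100] + 1e-9

    def test_energy_boundedness_deterministic(self, two_layer_scene):
        """With tau <= 1, gamma >= 0 and coherent weighting the deposited
        intensity never exceeds the launched intensity."""
        tdx = TransducerConfig(
            scan_geometry="linear", num_elements=3, element_width_mm=1.0,
            kerf_mm=0.0, depth_mm=85.0,
        )
        for mcpt in (False, True):
            sim = SimConfig(num_rays=64, enable_mcpt=mcpt, seed=3)
            inten, ech = trace_scanline(two_layer_scene, tdx, sim, 1)
            assert np.all(inten <= 1.0 + 1e-9)
            assert np.all(inten >= 0.0)
            assert np.all(np.isfinite(inten)) and np.all(np.isfinite(ech))


class TestTraceFrame:
    def _symmetric_scene(self):
        water = DEFAULT_TISSUES["water"]
        soft = DEFAULT_TISSUES["soft_tissue"]
        labels = np.zeros((80, 8, 120), dtype=np.int16)
        ax_x = (np.arange(80) - 40 + 0.5) * 0.5
        ax_z = (np.arange(120) + 0.5) * 0.5
        xx, zz = np.meshgrid(ax_x, ax_z, indexing="ij")
        sphere = (xx**2 + (zz - 30.0) ** 2) <= 64.0
        labels[sphere[:, None, :].repeat(8, axis=1)] = 1
        return LabelScene.build(
            labels, [0.5] * 3, [ax_x[0], -2 + 0.25, ax_z[0]],
            {0: water, 1: soft}, ambient=water,
        )

    def test_left_right_symmetry_deterministic(self):
        scene = self._symmetric_scene()
        tdx = TransducerConfig(
            scan_geometry="phased", num_scanlines=9, sector_deg=40, depth_mm=55.0
        )
        sim = SimConfig(num_rays=1, enable_mcpt=False, seed=0)
        prof = trace_frame(scene, tdx, sim)
        np.testing.assert_allclose(
            prof.intensity, prof.intensity[::-1], rtol=0.05, atol=1e-4
        )

    def test_seed_determinism_bitwise(self):
        # strong impedance contrast so reflect/refract branching actually
        # happens and different seeds take different paths
        water = DEFAULT_TISSUES["water"]
        bone = DEFAULT_TISSUES["bone"]
        labels = np.zeros((60, 8, 100), dtype=np.int16)
        ax_x = (np.arange(60) - 30 + 0.5) * 0.5
        ax_z = (np.arange(100) + 0.5) * 0.5
        xx, zz = np.meshgrid(ax_x, ax_z, indexing="ij")
        sphere = (xx**2 + (zz - 25.0) ** 2) <= 49.0
        labels[sphere[:, None, :].repeat(8, axis=1)] = 1
        scene = LabelScene.build(
            labels, [0.5] * 3, [ax_x[0], -2 + 0.25, ax_z[0]],
            {0: water, 1: bone}, ambient=water,
        )
        tdx = TransducerConfig(
            scan_geometry="phased", num_scanlines=5, sector_deg=30, depth_mm=45.0
        )
        sim = SimConfig(num_rays=16, seed=11)
        p1 = trace_frame(scene, tdx, sim)
        p2 = trace_frame(scene, tdx, sim)
        assert np.array_equal(p1.intensity, p2.intensity)
        assert np.array_equal(p1.echoes, p2.echoes)
        p3 = trace_frame(scene, tdx, SimConfig(num_rays=16, seed=12))
        assert not np.array_equal(p1.intensity, p3.intensity)

    def test_attenuating_occluder_shadows_distal_profile(self):
        """A high-attenuation sphere in the beam path cuts the distal
        intensity to a fraction of unshadowed neighbouring scanlines."""
        from sonopath.phantoms import make_artifact_sphere

        scene, truth = make_artifact_sphere("attenuating")
        tdx = TransducerConfig(
            scan_geometry="phased", num_scanlines=21, sector_deg=60, depth_mm=85.0
        )
        sim = SimConfig(num_rays=8, seed=5)
        prof = trace_frame(scene, tdx, sim)
        dr = tdx.radial_spacing_mm
        z_sel = slice(int(60.0 / dr), int(75.0 / dr))
        centre = prof.intensity[10, z_sel].mean()
        aside = prof.intensity[[2, 18], :][:, z_sel].mean()
        assert centre < 0.1 * aside
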