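"""Monte-Carlo path tracing of acoustic rays through a labelled scene.

For every scanline the tracer launches N rays along the beam axis.  Each ray
marches through the voxel volume, attenuates within each medium, and at
every impedance discontinuity (i) deposits a boundary echo, then (ii)
randomly reflects or refracts (Russian roulette with probability R), picking
the actual continuation direction by sampling in a truncated-normal cone
around the deterministic reflection/refraction axis.  Between boundaries the
carried intensity defines the radial intensity profile I_Tr(r); every
deposit is down-weighted by the beam-coherence factor
w_R = C0 / (C0 + d) where d is the perpendicular distance of the deposit
point from the scanline's main beam.

The returned profile is the per-radial-sample average over the N rays, and
is the large-scale (reflection/refraction/attenuation) input to the
convolutional speckle synthesis stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .acoustics import (
    BoundaryInteraction,
    attenuation_factor,
    surface_echo,
)
from .scene import LabelScene, surface_normal

__all__ = [
    "TransducerConfig",
    "SimConfig",
    "ConeSampler",
    "BoundaryEvent",
    "IntensityProfile",
    "sample_cone_direction",
    "beam_coherence_weight",
    "march_ray",
    "trace_scanline",
    "trace_frame",
]

#: Intensity floor below which a ray is terminated early.
INTENSITY_FLOOR = 1e-12
#: Floor on the solid-angle pdf of Eq.-style cone sampling (the density is
#: unbounded as the polar angle approaches the cone axis).
PDF_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TransducerConfig:
    """Virtual transducer geometry and sampling parameters.

    The array sits at ``position`` (mm) with the beam axis along +z and the
    lateral axis along +x.  ``phased`` geometry fans ``num_scanlines`` beams
    from the array centre across ``sector_deg``; ``linear`` geometry sends
    one parallel beam per element.
    """

    center_frequency_mhz: float = 3.6
    sampling_frequency_mhz: float = 50.0
    element_width_mm: float = 0.3
    element_height_mm: float = 13.0
    kerf_mm: float = 0.05
    num_elements: int = 96
    scan_geometry: str = "phased"  # "phased" | "linear"
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sector_deg: float = 75.0
    num_scanlines: int = 96
    depth_mm: float = 150.0
    sound_speed_mps: float = 1540.0

    def __post_init__(self) -> None:
        if self.center_frequency_mhz <= 0 or self.sampling_frequency_mhz <= 0:
            raise ValueError("frequencies must be positive")
        if self.num_elements < 1:
            raise ValueError("need at least one element")
        if self.scan_geometry not in ("phased", "linear"):
            raise ValueError("scan geometry must be 'phased' or 'linear'")
        if self.scan_geometry == "phased" and not 0.0 < self.sector_deg < 180.0:
            raise ValueError("sector angle must lie in (0, 180) degrees")

    @property
    def pitch_mm(self) -> float:
        return self.element_width_mm + self.kerf_mm

    @property
    def n_lines(self) -> int:
        return self.num_scanlines if self.scan_geometry == "phased" else self.num_elements

    @property
    def radial_spacing_mm(self) -> float:
        """RF sample spacing in depth: c / (2 fs) (round-trip time base)."""
        return self.sound_speed_mps * 1e3 / (2.0 * self.sampling_frequency_mhz * 1e6)

    @property
    def n_radial_samples(self) -> int:
        return int(round(self.depth_mm / self.radial_spacing_mm))

    @property
    def spatial_frequency_cyc_mm(self) -> float:
        """Carrier frequency of the RF pulse on the depth axis: 2 f0 / c."""
        return 2.0 * self.center_frequency_mhz * 1e6 / (self.sound_speed_mps * 1e3)

    def scanline_angles(self) -> np.ndarray:
        """Beam steering angles (radians) for phased geometry, 0 for linear."""
        if self.scan_geometry == "phased":
            half = math.radians(self.sector_deg) / 2.0
            return np.linspace(-half, half, self.n_lines)
        return np.zeros(self.n_lines)

    def scanline(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(origin, unit direction) of scanline ``k`` in world mm."""
        pos = np.asarray(self.position, dtype=float)
        if self.scan_geometry == "phased":
            ang = self.scanline_angles()[k]
            return pos, np.array([math.sin(ang), 0.0, math.cos(ang)])
        x = (k - (self.n_lines - 1) / 2.0) * self.pitch_mm
        return pos + np.array([x, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])

    def lateral_axis(self, k: int) -> np.ndarray:
        _, d = self.scanline(k)
        return np.array([d[2], 0.0, -d[0]])


@dataclass
class SimConfig:
    """Monte-Carlo simulation parameters (per scanline).

    ``num_rays`` rays are launched per scanline; each is followed for at
    most ``max_collisions`` boundary interactions.  The cone sampler draws
    the polar angle from a truncated normal psi(mu, sigma, a, b) (radians)
    and the azimuth uniformly.  ``pdf_weighting`` enables the literal
    explicit-pdf importance weight f cos(theta)/p(omega); the default treats
    the cone density as the scattering lobe itself so the density cancels
    and the per-bounce weight is f cos(theta) (see the methods note).

    By default the cone is applied to the *reflected* branch only -- the
    physical picture behind it is the conical spread of the wavefront
    reflected off curved structures -- while transmitted rays continue
    collimated along the deterministic refraction axis;
    ``cone_refraction=True`` scatters the refracted branch as well.
    """

    num_rays: int = 1000
    max_collisions: int = 7
    beam_coherence_c0: float = 0.1
    cone_mu: float = 0.0
    cone_sigma: float = math.pi / 4.0
    cone_a: float = 0.0
    cone_b: float = math.pi / 2.0
    seed: int = 0
    enable_mcpt: bool = True
    refraction_ratio: str = "impedance"  # "impedance" (as modelled) | "speed"
    pdf_weighting: bool = False
    cone_refraction: bool = False
    # structures thinner than this along the ray transmit without beam
    # deviation (thin-membrane rule; None = one wavelength at f0, 0 = off)
    thin_structure_mm: float | None = None
    step_mm: float | None = None  # marching step; default min(spacing)/2
    max_path_factor: float = 1.5  # total path length cap, in units of depth

    def __post_init__(self) -> None:
        if self.num_rays < 1 or self.max_collisions < 1:
            raise ValueError("num_rays and max_collisions must be >= 1")
        if not self.cone_a < self.cone_b:
            raise ValueError("cone sampler requires a < b")
        if self.refraction_ratio not in ("impedance", "speed"):
            raise ValueError("refraction_ratio must be 'impedance' or 'speed'")


# ---------------------------------------------------------------------------
# Cone sampling
# ---------------------------------------------------------------------------


class ConeSampler:
    """Truncated-normal cone sampler for reflection/refraction directions.

    The polar angle phi ~ psi(mu, sigma, a, b) (inverse-transform sampled),
    the azimuth is uniform on [0, 2 pi).  The solid-angle density is
    p(omega) = psi(phi) / (2 pi sin(phi)).  sigma = 0 collapses the cone:
    the axis is returned deterministically with an infinite density.
    """

    def __init__(self, mu: float, sigma: float, a: float, b: float):
        if not a < b:
            raise ValueError("require a < b")
        self.mu, self.sigma, self.a, self.b = mu, sigma, a, b
        if sigma > 0:
            alpha, beta = (a - mu) / sigma, (b - mu) / sigma
            self._dist = truncnorm(alpha, beta, loc=mu, scale=sigma)
        else:
            self._dist = None

    @classmethod
    def from_config(cls, sim: SimConfig) -> "ConeSampler":
        return cls(sim.cone_mu, sim.cone_sigma, sim.cone_a, sim.cone_b)

    def polar_pdf(self, phi) -> np.ndarray:
        if self._dist is None:
            raise ValueError("collapsed cone has a degenerate density")
        return self._dist.pdf(phi)

    def solid_angle_pdf(self, phi) -> np.ndarray:
        """p(omega) at polar angle phi, floored at PDF_FLOOR."""
        phi = np.asarray(phi, dtype=float)
        p = self.polar_pdf(phi) / (2.0 * np.pi * np.maximum(np.sin(phi), 1e-300))
        return np.maximum(p, PDF_FLOOR)

    def sample(self, axis: np.ndarray, rng: np.random.Generator):
        return sample_cone_direction(axis, self, rng)


def _orthonormal_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def sample_cone_direction(
    axis: np.ndarray, sampler: ConeSampler, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Draw a direction in a cone around ``axis``; returns (direction, pdf).

    The pdf is the solid-angle density psi(phi) / (2 pi sin(phi)) at the
    drawn sample (floored at PDF_FLOOR); a collapsed cone (sigma = 0)
    returns the axis itself with pdf = inf.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isfinite(n) or n < 1e-12:
        raise ValueError("degenerate cone axis")
    axis = axis / n
    if sampler._dist is None:
        return axis, math.inf
    u = rng.random()
    phi = float(sampler._dist.ppf(u))
    theta = rng.random() * 2.0 * math.pi
    e1, e2 = _orthonormal_basis(axis)
    direction = (
        math.cos(phi) * axis
        + math.sin(phi) * (math.cos(theta) * e1 + math.sin(theta) * e2)
    )
    direction /= np.linalg.norm(direction)
    return direction, float(sampler.solid_angle_pdf(phi))


def beam_coherence_weight(c0: float, d_mm) -> np.ndarray:
    """Beam-coherence weight w_R = C0 / (C0 + d): 1 on the main beam,
    decreasing as the sampled path strays a distance d (mm) from it."""
    if c0 <= 0:
        raise ValueError("C0 must be positive")
    d_mm = np.asarray(d_mm, dtype=float)
    if np.any(d_mm < 0):
        raise ValueError("distance must be non-negative")
    return c0 / (c0 + d_mm)


# ---------------------------------------------------------------------------
# Ray marching
# ---------------------------------------------------------------------------


@dataclass
class BoundaryEvent:
    """A label-change crossing along a ray."""

    t_mm: float            # distance from the ray origin
    point: np.ndarray      # world position of the crossing
    label_from: int
    label_to: int
    normal: np.ndarray     # unit normal oriented against the ray (n . v <= 0)
    cos_incidence: float   # |n . v|
    segment_mm: float      # path length inside the exited medium


def _refine_crossing(scene, origin, direction, t_lo, t_hi, lab_from, tol_mm):
    """Bisection of the label change between t_lo and t_hi to tol_mm."""
    grid = scene.grid
    while t_hi - t_lo > tol_mm:
        mid = 0.5 * (t_lo + t_hi)
        if grid.label_at(origin + mid * direction) == lab_from:
            t_lo = mid
        else:
            t_hi = mid
    return 0.5 * (t_lo + t_hi)


def march_ray(
    scene: LabelScene,
    origin: np.ndarray,
    direction: np.ndarray,
    max_range_mm: float,
    step_mm: float | None = None,
) -> list[BoundaryEvent]:
    """All label-change crossings along a straight ray, in order.

    Uniform-step voxel marching at ``step_mm`` (default min(spacing)/2) with
    bisection refinement of each crossing to 1/16 voxel.  Each event carries
    an SDF-gradient normal (oriented against the ray) and the path length
    travelled inside the exited medium.  A ray leaving the volume simply
    continues through the ambient medium; the event list ends at
    ``max_range_mm``.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    grid = scene.grid
    if step_mm is None:
        step_mm = 0.5 * float(grid.spacing.min())
    tol = float(grid.spacing.min()) / 16.0

    events: list[BoundaryEvent] = []
    ts = np.arange(0.0, max_range_mm + step_mm, step_mm)
    labels = grid.label_at(origin + ts[:, None] * direction)
    change = np.flatnonzero(labels[1:] != labels[:-1])
    t_prev = 0.0
    for idx in change:
        lab_from = int(labels[idx])
        lab_to = int(labels[idx + 1])
        t_cross = _refine_crossing(
            scene, origin, direction, ts[idx], ts[idx + 1], lab_from, tol
        )
        if t_cross > max_range_mm:
            break
        point = origin + t_cross * direction
        normal = _boundary_normal(scene, point, lab_from, lab_to, direction)
        cos_inc = float(abs(np.dot(normal, direction)))
        events.append(
            BoundaryEvent(
                t_mm=float(t_cross),
                point=point,
                label_from=lab_from,
                label_to=lab_to,
                normal=normal,
                cos_incidence=cos_inc,
                segment_mm=float(t_cross - t_prev),
            )
        )
        t_prev = t_cross
    return events


def _boundary_normal(scene, point, lab_from, lab_to, direction):
    """SDF-gradient normal at a crossing, oriented against the ray.

    Adjacent labels share the boundary surface, so either side's SDF yields
    the same normal up to sign; the smaller (more local) structure's SDF is
    preferred, falling back to whichever is available, then to the ray axis.
    """
    candidates = [lab for lab in (lab_to, lab_from) if lab != 0]
    candidates.sort(
        key=lambda lab: scene.sdf_by_label[lab].distances.size
        if lab in scene.sdf_by_label
        else np.inf
    )
    for lab in candidates:
        sdf = scene.sdf_by_label.get(lab)
        if sdf is None:
            continue
        try:
            n = surface_normal(sdf, point)
        except ValueError:
            continue
        if np.dot(n, direction) > 0:
            n = -n
        return n
    return -direction.copy()


# ---------------------------------------------------------------------------
# Scanline tracing
# ---------------------------------------------------------------------------


@dataclass
class IntensityProfile:
    """Per-scanline radial intensity returned to the transducer.

    ``intensity`` is the diffuse/transmitted intensity I_Tr(r) that weights
    the scatterer field; ``echoes`` holds boundary-echo intensity deposited
    at discrete radial samples (injected as impulses into the RF model).
    Both are averages over the launched rays.
    """

    intensity: np.ndarray        # (n_lines, n_samples), >= 0
    echoes: np.ndarray           # (n_lines, n_samples), >= 0
    origins: np.ndarray          # (n_lines, 3)
    directions: np.ndarray       # (n_lines, 3)
    radial_spacing_mm: float

    @property
    def n_lines(self) -> int:
        return self.intensity.shape[0]


def _ray_key(seed: int, scanline: int, ray: int) -> int:
    # counter-based Philox key per (scanline, ray): reproducible regardless
    # of execution order; seed < 2^31, scanline/ray < 2^16 in practice
    return (int(seed) << 64) ^ (int(scanline) << 32) ^ int(ray)


def _first_event(scene, pos, direction, remaining, step_mm, chunk=384):
    """First label-change along the ray, marching in chunks."""
    grid = scene.grid
    tol = float(grid.spacing.min()) / 16.0
    t0 = 0.0
    lab0 = int(grid.label_at(pos))
    while t0 < remaining:
        t_hi = min(t0 + chunk * step_mm, remaining)
        ts = np.arange(t0, t_hi + step_mm, step_mm)
        labels = grid.label_at(pos + ts[:, None] * direction)
        change = np.flatnonzero(labels != lab0)
        if change.size:
            i = change[0]
            t_cross = _refine_crossing(
                scene, pos, direction, ts[max(i - 1, 0)], ts[i], lab0, tol
            )
            if t_cross <= remaining:
                point = pos + t_cross * direction
                lab_to = int(grid.label_at(pos + (t_cross + 2 * tol) * direction))
                normal = _boundary_normal(scene, point, lab0, lab_to, direction)
                return BoundaryEvent(
                    t_mm=float(t_cross),
                    point=point,
                    label_from=lab0,
                    label_to=lab_to,
                    normal=normal,
                    cos_incidence=float(abs(np.dot(normal, direction))),
                    segment_mm=float(t_cross),
                )
            return None
        t0 = t_hi
    return None


def _deposit_segment(
    acc, o, d0, anchor, axis, pos, direction, seg_len, carried, alpha,
    f_mhz, c0, dr, n_samp
):
    """Add a path segment's intensity to the radial accumulation array.

    Samples the segment, projects each sample onto the scanline axis
    (o, d0) for radial binning, applies within-medium attenuation and the
    beam-coherence weight at the sample's perpendicular distance from the
    current main beam (anchor, axis) — the deterministic continuation the
    cone was sampled around, which re-anchors at every bounce.
    Returns the carried intensity at the segment end.
    """
    if seg_len <= 0:
        return carried
    # one sample per traversed radial bin: spacing dr along the scanline
    # axis corresponds to dr/|dir.d0| along the ray (capped for
    # near-perpendicular segments, whose samples share a bin anyway)
    dt = dr / max(abs(float(direction @ d0)), dr)
    s0 = float((pos - o) @ d0)
    s1 = s0 + seg_len * float(direction @ d0)
    span = n_samp * dr
    if (s0 < 0 and s1 < 0) or (s0 >= span and s1 >= span):
        ts = np.empty(0)
    else:
        ts = np.arange(0.5 * dt, seg_len, dt)
    if ts.size:
        pts = pos[None, :] + ts[:, None] * direction
        s = (pts - o) @ d0
        inb = (s >= 0.0) & (s < n_samp * dr)
        if np.any(inb):
            s = s[inb]
            tsel = ts[inb]
            relb = pts[inb] - anchor
            off = relb - (relb @ axis)[:, None] * axis[None, :]
            dperp = np.linalg.norm(off, axis=1)
            vals = (
                carried
                * attenuation_factor(tsel / 10.0, f_mhz, alpha)
                * beam_coherence_weight(c0, dperp)
            )
            bins = np.minimum((s / dr).astype(np.int64), n_samp - 1)
            acc += np.bincount(bins, weights=vals, minlength=n_samp)
    return carried * float(attenuation_factor(seg_len / 10.0, f_mhz, alpha))


def _reflect(v, n, cos1):
    return v + 2.0 * cos1 * n


def _refract(v, n, cos1, cos2, eta):
    t = eta * v + (eta * cos1 - cos2) * n
    nrm = np.linalg.norm(t)
    if nrm < 1e-12:
        return v.copy()
    return t / nrm


def trace_scanline(
    scene: LabelScene,
    transducer: TransducerConfig,
    sim: SimConfig,
    k: int,
    *,
    sampler: ConeSampler | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Trace one scanline; returns (intensity, echoes) radial profiles.

    With MCPT enabled, ``sim.num_rays`` stochastic paths are averaged; with
    it disabled a single deterministic ray is traced that always continues
    through boundaries (refraction axis) with the transmitted fraction.
    """
    if not 0 <= k < transducer.n_lines:
        raise IndexError(f"scanline {k} outside [0, {transducer.n_lines})")
    if sampler is None:
        sampler = ConeSampler.from_config(sim)
    o, d0 = transducer.scanline(k)
    dr = transducer.radial_spacing_mm
    n_samp = transducer.n_radial_samples
    depth = transducer.depth_mm
    f_mhz = transducer.center_frequency_mhz
    c0 = sim.beam_coherence_c0
    step = sim.step_mm or 0.5 * float(scene.grid.spacing.min())
    max_path = sim.max_path_factor * depth
    n_rays = sim.num_rays if sim.enable_mcpt else 1
    thin_mm = sim.thin_structure_mm
    if thin_mm is None:
        thin_mm = transducer.sound_speed_mps / (f_mhz * 1e3)  # one wavelength

    acc_i = np.zeros(n_samp)
    acc_e = np.zeros(n_samp)

    rays_traced = 0
    for ray in range(n_rays):
        rng = np.random.Generator(
            np.random.Philox(key=_ray_key(sim.seed, k, ray))
        )
        pos = o.copy()
        direction = d0.copy()
        beam_anchor = o.copy()
        beam_axis = d0.copy()
        carried = 1.0
        travelled = 0.0
        collisions = 0
        stochastic = False
        thin_entry = None  # (pre-entry direction, path position) while
        # traversing a refracted-into structure
        nudge = max(float(scene.grid.spacing.min()) / 16.0, 0.5 * step)
        while carried > INTENSITY_FLOOR and travelled < max_path:
            medium = scene.tissue(int(scene.grid.label_at(pos)))
            remaining = max_path - travelled
            ev = _first_event(scene, pos, direction, remaining, step)
            seg = ev.t_mm if ev is not None else remaining
            carried = _deposit_segment(
                acc_i, o, d0, beam_anchor, beam_axis, pos, direction, seg,
                carried, medium.attenuation, f_mhz, c0, dr, n_samp,
            )
            travelled += seg
            if ev is None:
                break
            t_from = scene.tissue(ev.label_from)
            t_to = scene.tissue(ev.label_to)
            Z1, Z2 = t_from.impedance, t_to.impedance
            pos = ev.point
            if abs(Z1 - Z2) <= 1e-9 * max(Z1, Z2):
                # acoustically matched: no impedance contrast, no interaction
                pos = pos + nudge * direction
                travelled += nudge
                carried *= float(
                    attenuation_factor(nudge / 10.0, f_mhz, t_to.attenuation)
                )
                continue
            ratio = (
                Z1 / Z2
                if sim.refraction_ratio == "impedance"
                else t_from.sound_speed / t_to.sound_speed
            )
            inter = BoundaryInteraction(Z1, Z2, ev.cos_incidence, ratio)
            # (i) boundary echo, deposited at the projection onto the axis
            rel = pos - o
            s_ev = float(rel @ d0)
            if 0.0 <= s_ev < depth:
                relb = pos - beam_anchor
                dperp = float(
                    np.linalg.norm(relb - (relb @ beam_axis) * beam_axis)
                )
                echo = surface_echo(
                    carried, Z1, Z2, ev.cos_incidence, t_to.tau, t_to.gamma
                )
                b = min(int(s_ev / dr + 0.5), n_samp - 1)
                acc_e[b] += echo * float(beam_coherence_weight(c0, dperp))
            # (ii) reflect-or-refract continuation
            n_hat = ev.normal
            cos1 = ev.cos_incidence
            if sim.enable_mcpt:
                u = rng.random()
                reflecting = inter.tir or u < inter.R
                stochastic = True
            else:
                reflecting = inter.tir
            if reflecting:
                axis = _reflect(direction, n_hat, cos1)
                f = inter.R
                thin_entry = None
            else:
                axis = _refract(direction, n_hat, cos1, inter.cos_theta2, ratio)
                f = inter.T
                if (
                    thin_entry is not None
                    and travelled - thin_entry[1] < thin_mm
                ):
                    # exit of a sub-wavelength structure: geometric
                    # refraction does not apply, the beam stays collimated
                    axis = thin_entry[0]
                    thin_entry = None
                else:
                    thin_entry = (direction.copy(), travelled)
            beam_anchor = pos
            beam_axis = axis
            if sim.enable_mcpt and (reflecting or sim.cone_refraction):
                direction, pdf = sample_cone_direction(axis, sampler, rng)
                thin_entry = None
                w = f * cos1
                if sim.pdf_weighting and math.isfinite(pdf):
                    w /= max(pdf, PDF_FLOOR)
            else:
                direction = axis
                w = f * cos1
            carried *= w
            # advance past the boundary; the skipped sliver still attenuates
            pos = pos + nudge * direction
            travelled += nudge
            med_next = scene.tissue(int(scene.grid.label_at(pos)))
            carried *= float(
                attenuation_factor(nudge / 10.0, f_mhz, med_next.attenuation)
            )
            collisions += 1
            if collisions >= sim.max_collisions:
                break
        rays_traced += 1
        if not stochastic:
            # no random choice was made: every further ray retraces this
            # exact path, so the single trace already is the average
            break

    return acc_i / rays_traced, acc_e / rays_traced


def trace_frame(
    scene: LabelScene,
    transducer: TransducerConfig,
    sim: SimConfig,
) -> IntensityProfile:
    """Trace every scanline of the frame (fan for phased, aperture for
    linear).  Deterministic given (scene, configs, seed)."""
    n_lines = transducer.n_lines
    n_samp = transducer.n_radial_samples
    intensity = np.zeros((n_lines, n_samp))
    echoes = np.zeros((n_lines, n_samp))
    origins = np.zeros((n_lines, 3))
    directions = np.zeros((n_lines, 3))
    sampler = ConeSampler.from_config(sim)
    for k in range(n_lines):
        origins[k], directions[k] = transducer.scanline(k)
        intensity[k], echoes[k] = trace_scanline(
            scene, transducer, sim, k, sampler=sampler
        )
    return IntensityProfile(
        intensity=intensity,
        echoes=echoes,
        origins=origins,
        directions=directions,
        radial_spacing_mm=transducer.radial_spacing_mm,
    )


def uniform_profile(
    transducer: TransducerConfig, value: float = 1.0
) -> IntensityProfile:
    """Boundary-free profile: I_Tr(r) = value everywhere (no echoes).

    The homogeneous-medium limit of the tracer, used by scenes with no
    impedance contrasts (e.g. the speckle slab)."""
    n_lines = transducer.n_lines
    n_samp = transducer.n_radial_samples
    origins = np.zeros((n_lines, 3))
    directions = np.zeros((n_lines, 3))
    for k in range(n_lines):
        origins[k], directions[k] = transducer.scanline(k)
    return IntensityProfile(
        intensity=np.full((n_lines, n_samp), float(value)),
        echoes=np.zeros((n_lines, n_samp)),
        origins=origins,
        directions=directions,
        radial_spacing_mm=transducer.radial_spacing_mm,
    )
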