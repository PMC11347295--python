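"""Scatterer field generation and convolutional (COLE-style) RF synthesis.

Speckle is produced by convolving a cosine-modulated Gaussian pulse with a
train of sub-wavelength scatterers.  Per scanline, scatterers within the
beam support are projected onto the scanline axis, binned to the closest
radial RF sample, weighted by their lateral/elevational beam weight w_q,
their amplitude a_q and the ray-traced intensity I_Tr at their radial
sample, and the binned train is convolved with the 1-D axial pulse.  The
lateral and elevational factors of the separable point-spread function are
realized by w_q; boundary echoes from the tracer are injected as impulses
and convolved with the same pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .scene import LabelScene
from .tracing import IntensityProfile, TransducerConfig

__all__ = [
    "ScattererSet",
    "PSFConfig",
    "FieldTable",
    "RFFrame",
    "generate_scatterers",
    "lateral_weight",
    "axial_pulse",
    "synthesize_rf",
]

#: Scatterers with beam weight below this are skipped (cost control with
#: negligible amplitude error).
WEIGHT_CUTOFF = 1e-3


@dataclass
class ScattererSet:
    """Sampled sub-wavelength scatterers."""

    positions: np.ndarray   # (N, 3) world mm
    amplitudes: np.ndarray  # (N,) >= 0
    labels: np.ndarray      # (N,) tissue label per scatterer

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, float)).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, float).reshape(-1)
        self.labels = np.asarray(self.labels).reshape(-1)
        if not (len(self.positions) == len(self.amplitudes) == len(self.labels)):
            raise ValueError("positions, amplitudes and labels must align")
        if self.amplitudes.size and not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")

    def __len__(self) -> int:
        return len(self.amplitudes)

    @classmethod
    def concatenate(cls, sets: list["ScattererSet"]) -> "ScattererSet":
        return cls(
            np.concatenate([s.positions for s in sets]) if sets else np.empty((0, 3)),
            np.concatenate([s.amplitudes for s in sets]) if sets else np.empty(0),
            np.concatenate([s.labels for s in sets]) if sets else np.empty(0, int),
        )


@dataclass
class FieldTable:
    """Precomputed pulse-echo amplitude sampled over (depth, dL, dE).

    A stand-in interface for fields exported from an external beam
    simulator; amplitudes are linearly interpolated, and lookups outside the
    table support return 0.
    """

    depth_mm: np.ndarray
    lateral_mm: np.ndarray
    elevation_mm: np.ndarray
    amplitudes: np.ndarray  # (n_depth, n_lat, n_elev)

    def __post_init__(self) -> None:
        from scipy.interpolate import RegularGridInterpolator

        self._interp = RegularGridInterpolator(
            (self.depth_mm, self.lateral_mm, self.elevation_mm),
            self.amplitudes,
            bounds_error=False,
            fill_value=0.0,
        )

    def __call__(self, depth, d_lat, d_elev):
        pts = np.stack(np.broadcast_arrays(depth, d_lat, d_elev), axis=-1)
        return self._interp(pts)

    @classmethod
    def from_file(cls, path) -> "FieldTable":
        """Load a field table from an .npz archive with arrays
        ``depth_mm``, ``lateral_mm``, ``elevation_mm`` (1-D grids) and
        ``amplitudes`` (n_depth, n_lat, n_elev)."""
        data = np.load(path)
        missing = [k for k in ("depth_mm", "lateral_mm", "elevation_mm",
                               "amplitudes") if k not in data]
        if missing:
            raise ValueError(f"field table file is missing arrays: {missing}")
        return cls(
            data["depth_mm"], data["lateral_mm"], data["elevation_mm"],
            data["amplitudes"],
        )


@dataclass
class PSFConfig:
    """Separable point-spread-function parameters.

    sigma_r/sigma_l/sigma_e are the Gaussian envelope standard deviations
    (mm) of the modulated PSF in the radial/lateral/elevation directions.
    In ``analytic`` weighting mode the scatterer weight is the
    depth-independent Gaussian beam profile with std (sigma_lat, sigma_elev);
    ``field-table`` mode interpolates a precomputed pulse-echo field.
    ``echo_gain`` converts deposited boundary-echo intensity into RF impulse
    amplitude on the same scale as the scatterer train (the absolute
    relative scale of the two contributions is a calibration choice).
    """

    sigma_r_mm: float = 0.25
    sigma_lat_mm: float = 1.0
    sigma_elev_mm: float = 1.0
    weighting: str = "analytic"  # "analytic" | "field-table"
    field_table: FieldTable | None = None
    echo_gain: float = 100.0

    def __post_init__(self) -> None:
        if min(self.sigma_r_mm, self.sigma_lat_mm, self.sigma_elev_mm) <= 0:
            raise ValueError("PSF standard deviations must be positive")
        if self.weighting not in ("analytic", "field-table"):
            raise ValueError("weighting must be 'analytic' or 'field-table'")
        if self.weighting == "field-table" and self.field_table is None:
            raise ValueError("field-table weighting requires a field table")


@dataclass
class RFFrame:
    """Per-scanline RF sample arrays at the transducer sampling rate."""

    rf: np.ndarray  # (n_lines, n_samples)
    radial_spacing_mm: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.rf)):
            raise ValueError("RF frame contains non-finite values")


# ---------------------------------------------------------------------------
# Scatterer generation
# ---------------------------------------------------------------------------


def generate_scatterers(
    scene: LabelScene,
    region: tuple[tuple[float, float], tuple[float, float], tuple[float, float]],
    density: float,
    rng: np.random.Generator,
    *,
    mode: str = "2d",
    label_density: dict[int, float] | None = None,
) -> ScattererSet:
    """Draw the tissue scatterer field over a rectangular region.

    Candidate sites are Poisson-distributed at ``density`` (per mm^2 of the
    x-z imaging plane in ``2d`` mode, where all scatterers sit at the
    region's elevation midpoint; per mm^3 in ``3d`` mode).  Each candidate
    is retained with the generation probability mu1 of its tissue; retained
    amplitudes are drawn from Normal(mu0, sigma0) truncated at zero.
    ``label_density`` raises the candidate density inside specific labels
    (e.g. dense strong reflectors such as nylon wires) by rejection
    sampling extra candidates over the labels' bounding boxes.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    (x0, x1), (y0, y1), (z0, z1) = region
    if mode == "2d":
        measure = (x1 - x0) * (z1 - z0)
    elif mode == "3d":
        measure = (x1 - x0) * (y1 - y0) * (z1 - z0)
    else:
        raise ValueError("mode must be '2d' or '3d'")
    n_cand = rng.poisson(density * measure)
    pos = np.empty((n_cand, 3))
    pos[:, 0] = rng.uniform(x0, x1, n_cand)
    pos[:, 2] = rng.uniform(z0, z1, n_cand)
    if mode == "2d":
        pos[:, 1] = 0.5 * (y0 + y1)
    else:
        pos[:, 1] = rng.uniform(y0, y1, n_cand)
    if label_density:
        extras = [pos]
        for lab, dens in label_density.items():
            extra_d = dens - density
            if extra_d <= 0:
                continue
            mask = scene.grid.labels == lab
            if not mask.any():
                continue
            ii = np.nonzero(mask)
            sp, og = scene.grid.spacing, scene.grid.origin
            lo = og + sp * np.array([a.min() for a in ii]) - sp
            hi = og + sp * np.array([a.max() for a in ii]) + sp
            if mode == "2d":
                m2 = (hi[0] - lo[0]) * (hi[2] - lo[2])
            else:
                m2 = np.prod(hi - lo)
            n2 = rng.poisson(extra_d * m2)
            p2 = np.empty((n2, 3))
            p2[:, 0] = rng.uniform(lo[0], hi[0], n2)
            p2[:, 2] = rng.uniform(lo[2], hi[2], n2)
            p2[:, 1] = 0.5 * (y0 + y1) if mode == "2d" else rng.uniform(lo[1], hi[1], n2)
            keep2 = np.asarray(scene.grid.label_at(p2)) == lab
            extras.append(p2[keep2])
        pos = np.concatenate(extras)
    labels = np.asarray(scene.grid.label_at(pos))

    n_tot = len(pos)
    keep = np.zeros(n_tot, dtype=bool)
    amps = np.zeros(n_tot)
    u_keep = rng.random(n_tot)
    for lab in np.unique(labels):
        tissue = scene.tissue(int(lab))
        m = labels == lab
        sel = m & (u_keep < tissue.mu1)
        keep |= sel
        n_sel = int(sel.sum())
        if n_sel and tissue.sigma0 > 0:
            # Normal(mu0, sigma0) truncated at 0 by resampling
            a = rng.normal(tissue.mu0, tissue.sigma0, n_sel)
            bad = a < 0
            while bad.any():
                a[bad] = rng.normal(tissue.mu0, tissue.sigma0, int(bad.sum()))
                bad = a < 0
            amps[sel] = a
        elif n_sel:
            amps[sel] = tissue.mu0
    return ScattererSet(pos[keep], amps[keep], labels[keep])


# ---------------------------------------------------------------------------
# Beam weighting and the axial pulse
# ---------------------------------------------------------------------------


def lateral_weight(d_lat, d_elev, config: PSFConfig, depth=0.0) -> np.ndarray:
    """Scatterer beam weight w_q at lateral/elevational offsets (mm).

    Analytic mode: depth-independent Gaussian
    w_q = exp(-1/2 (dL^2/sigma_L^2 + dE^2/sigma_E^2)).  Field-table mode
    interpolates the table at (depth, dL, dE); outside support -> 0.
    """
    if config.weighting == "field-table":
        return np.asarray(config.field_table(depth, d_lat, d_elev))
    d_lat = np.asarray(d_lat, float)
    d_elev = np.asarray(d_elev, float)
    return np.exp(
        -0.5
        * (
            d_lat**2 / config.sigma_lat_mm**2
            + d_elev**2 / config.sigma_elev_mm**2
        )
    )


def axial_pulse(psf: PSFConfig, transducer: TransducerConfig) -> np.ndarray:
    """1-D axial pulse: Gaussian envelope times the cos(2 pi f r) carrier,
    sampled at the RF radial spacing and truncated at ±3 sigma_r."""
    dr = transducer.radial_spacing_mm
    half = int(np.ceil(3.0 * psf.sigma_r_mm / dr))
    r = np.arange(-half, half + 1) * dr
    return np.exp(-0.5 * (r / psf.sigma_r_mm) ** 2) * np.cos(
        2.0 * np.pi * transducer.spatial_frequency_cyc_mm * r
    )


# ---------------------------------------------------------------------------
# RF synthesis
# ---------------------------------------------------------------------------


def synthesize_rf(
    profile: IntensityProfile,
    scatterers: ScattererSet,
    psf: PSFConfig,
    transducer: TransducerConfig,
) -> RFFrame:
    """COLE-style RF frame synthesis (intensity-weighted scatterer train
    convolved with the axial pulse, plus boundary-echo impulses).

    An empty scatterer set yields a frame of pure boundary echoes.
    """
    n_lines = transducer.n_lines
    dr = transducer.radial_spacing_mm
    n_samp = transducer.n_radial_samples
    if profile.intensity.shape != (n_lines, n_samp):
        raise ValueError("profile and transducer geometries disagree")
    pulse = axial_pulse(psf, transducer)
    rf = np.zeros((n_lines, n_samp))
    elev = np.array([0.0, 1.0, 0.0])

    pos = scatterers.positions
    amps = scatterers.amplitudes
    # scatterers sorted by lateral coordinate for fast per-line windowing in
    # linear geometry; phased geometry windows on |dL| after projection
    if len(scatterers) and transducer.scan_geometry == "linear":
        order = np.argsort(pos[:, 0])
        pos, amps = pos[order], amps[order]
        x_sorted = pos[:, 0]
    support = 2.0 * np.sqrt(np.log(1.0 / WEIGHT_CUTOFF))  # in units of sigma

    for k in range(n_lines):
        o = profile.origins[k]
        d = profile.directions[k]
        lat = np.array([d[2], 0.0, -d[0]])
        impulses = profile.echoes[k] * psf.echo_gain
        if len(scatterers):
            if transducer.scan_geometry == "linear":
                half = support * psf.sigma_lat_mm
                i0, i1 = np.searchsorted(x_sorted, [o[0] - half, o[0] + half])
                p, a = pos[i0:i1], amps[i0:i1]
            else:
                p, a = pos, amps
            rel = p - o
            s = rel @ d
            d_lat = rel @ lat
            d_elev = rel @ elev
            inb = (s >= 0.0) & (s < n_samp * dr)
            s, a = s[inb], a[inb]
            w = lateral_weight(d_lat[inb], d_elev[inb], psf, depth=s)
            keep = w >= WEIGHT_CUTOFF
            s, a, w = s[keep], a[keep], w[keep]
            bins = np.minimum((s / dr + 0.5).astype(np.int64), n_samp - 1)
            vals = w * a * profile.intensity[k, bins]
            impulses = impulses + np.bincount(bins, weights=vals, minlength=n_samp)
        rf[k] = fftconvolve(impulses, pulse, mode="same")
    return RFFrame(rf=rf, radial_spacing_mm=dr)
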