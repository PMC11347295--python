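"""RF-to-display conversion: envelope detection, time-gain compensation,
log compression with dynamic range and reject, and scan conversion.

The chain follows the conventional B-mode order: envelope (analytic-signal
magnitude), TGC (amplitude-domain depth gain), log compression to [0, 1]
over the dynamic-range window with a reject floor, then polar-to-Cartesian
(phased) or rectilinear (linear) resampling to the output pixel grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.signal import hilbert

from .tracing import TransducerConfig

__all__ = [
    "PostConfig",
    "BModeImage",
    "envelope",
    "tgc",
    "log_compress",
    "scan_convert",
    "rf_to_bmode",
]


@dataclass
class PostConfig:
    """Display-chain parameters (dB-domain)."""

    tgc_db_per_cm: float = 1.5
    dynamic_range_db: float = 75.0
    reject_db: float = 40.0
    pixel_spacing_mm: float = 0.23

    def __post_init__(self) -> None:
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic range must be positive")
        if self.reject_db < 0:
            raise ValueError("reject threshold must be non-negative")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")


@dataclass
class BModeImage:
    """Scan-converted 8-bit image with geometry metadata.

    ``pixels[i, j]`` maps to world (x, z) = (x_min + j * ps, z_min + i * ps)
    in the transducer frame (apex at the origin); pixels outside the fan
    mask are 0.
    """

    pixels: np.ndarray       # uint8 (nz, nx)
    pixel_spacing_mm: float
    mask: np.ndarray         # bool, valid fan region
    x_min_mm: float
    z_min_mm: float
    geometry: dict

    def world_to_pixel(self, x_mm, z_mm):
        ps = self.pixel_spacing_mm
        return (np.asarray(z_mm) - self.z_min_mm) / ps, (
            np.asarray(x_mm) - self.x_min_mm
        ) / ps

    def save_png(self, path: str | Path, *, metadata: bool = True) -> None:
        from PIL import Image

        path = Path(path)
        Image.fromarray(self.pixels, mode="L").save(path)
        if metadata:
            side = {
                "pixel_spacing_mm": self.pixel_spacing_mm,
                "x_min_mm": self.x_min_mm,
                "z_min_mm": self.z_min_mm,
                **self.geometry,
            }
            path.with_suffix(".json").write_text(json.dumps(side, indent=2))


def envelope(rf: np.ndarray) -> np.ndarray:
    """Envelope detection: magnitude of the analytic signal along the last
    (radial) axis."""
    rf = np.asarray(rf, dtype=float)
    if not np.all(np.isfinite(rf)):
        raise ValueError("RF contains non-finite values")
    return np.abs(hilbert(rf, axis=-1))


def tgc(env: np.ndarray, slope_db_per_cm: float, radial_spacing_mm: float) -> np.ndarray:
    """Time-gain compensation: sample at depth z gains 10^(slope z_cm / 20)
    (amplitude domain)."""
    env = np.asarray(env, dtype=float)
    z_cm = np.arange(env.shape[-1]) * radial_spacing_mm / 10.0
    return env * 10.0 ** (slope_db_per_cm * z_cm / 20.0)


def log_compress(
    gained: np.ndarray, dynamic_range_db: float, reject_db: float | None = None
) -> np.ndarray:
    """Log compression to [0, 1]: v = 20 log10(x / x_max); values below
    -dynamic_range map to 0 and the window maps linearly to (0, 1].  The
    reject threshold is applied after dynamic-range normalization as a dB
    floor below the peak: pixels with v < -reject are zeroed."""
    x = np.asarray(gained, dtype=float)
    x_max = x.max()
    if x_max <= 0:
        return np.zeros_like(x)
    with np.errstate(divide="ignore"):
        v = 20.0 * np.log10(x / x_max)
    out = np.clip((v + dynamic_range_db) / dynamic_range_db, 0.0, 1.0)
    if reject_db is not None and reject_db > 0:
        out[v < -min(reject_db, dynamic_range_db)] = 0.0
    return out


def scan_convert(
    compressed: np.ndarray,
    transducer: TransducerConfig,
    pixel_spacing_mm: float,
) -> BModeImage:
    """Resample compressed fan data (n_lines, n_samples) to a Cartesian
    8-bit raster by bilinear interpolation.

    Phased geometry: (beam angle, radius) -> (x, z) with the apex at the
    origin; linear geometry: rectilinear resample of the aperture.  Pixels
    outside the fan are zero and excluded from the returned mask.
    """
    dr = transducer.radial_spacing_mm
    n_lines, n_samp = compressed.shape
    depth = n_samp * dr
    ps = pixel_spacing_mm

    if transducer.scan_geometry == "phased":
        half = math.radians(transducer.sector_deg) / 2.0
        x_max = depth * math.sin(half)
        x = np.arange(-x_max, x_max + ps, ps)
        z = np.arange(0.0, depth + ps, ps)
        xx, zz = np.meshgrid(x, z)
        rr = np.hypot(xx, zz)
        th = np.arctan2(xx, zz)
        dth = 2.0 * half / (n_lines - 1)
        line_idx = (th + half) / dth
        samp_idx = rr / dr
        mask = (rr <= depth) & (np.abs(th) <= half)
        vals = ndimage.map_coordinates(
            compressed, [line_idx.ravel(), samp_idx.ravel()], order=1, mode="constant"
        ).reshape(xx.shape)
        vals[~mask] = 0.0
        geometry = {
            "scan_geometry": "phased",
            "sector_deg": transducer.sector_deg,
            "depth_mm": depth,
        }
        x_min = float(x[0])
    else:
        pitch = transducer.pitch_mm
        x_max = (n_lines - 1) / 2.0 * pitch
        x = np.arange(-x_max, x_max + ps, ps)
        z = np.arange(0.0, depth + ps, ps)
        xx, zz = np.meshgrid(x, z)
        line_idx = (xx + x_max) / pitch
        samp_idx = zz / dr
        mask = (np.abs(xx) <= x_max) & (zz <= depth)
        vals = ndimage.map_coordinates(
            compressed, [line_idx.ravel(), samp_idx.ravel()], order=1, mode="constant"
        ).reshape(xx.shape)
        vals[~mask] = 0.0
        geometry = {
            "scan_geometry": "linear",
            "aperture_mm": 2 * x_max,
            "depth_mm": depth,
        }
        x_min = float(x[0])

    pixels = np.clip(np.round(vals * 255.0), 0, 255).astype(np.uint8)
    return BModeImage(
        pixels=pixels,
        pixel_spacing_mm=ps,
        mask=mask,
        x_min_mm=x_min,
        z_min_mm=0.0,
        geometry=geometry,
    )


def rf_to_bmode(
    rf: np.ndarray,
    transducer: TransducerConfig,
    post: PostConfig,
) -> tuple[BModeImage, np.ndarray]:
    """Full display chain; returns (image, pre-compression envelope)."""
    env = envelope(rf)
    gained = tgc(env, post.tgc_db_per_cm, transducer.radial_spacing_mm)
    comp = log_compress(gained, post.dynamic_range_db, post.reject_db)
    img = scan_convert(comp, transducer, post.pixel_spacing_mm)
    return img, env
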