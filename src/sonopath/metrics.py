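"""Image-quality and geometric-accuracy statistics.

Implements the validation metrics: generalized contrast-to-noise ratio
(gCNR, one minus the histogram overlap of lesion and background samples —
invariant to monotone intensity transforms), classical CNR, amplitude
contrast in dB, first-order speckle statistics (envelope SNR and Rayleigh
goodness of fit), and peak-based target registration error on B-mode
images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .postprocess import BModeImage

__all__ = [
    "RegionSamples",
    "TREReport",
    "gcnr",
    "cnr",
    "contrast_db",
    "speckle_stats",
    "measure_tre",
]

#: Envelope SNR of fully developed (Rayleigh) speckle: sqrt(pi / (4 - pi)).
RAYLEIGH_SNR = math.sqrt(math.pi / (4.0 - math.pi))


@dataclass
class RegionSamples:
    """Paired lesion/background sample sets on a recorded value domain."""

    lesion: np.ndarray
    background: np.ndarray
    domain: str = "envelope"  # "envelope" (pre-compression) | "image"
    low_sample_warning: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.lesion = np.asarray(self.lesion, float).ravel()
        self.background = np.asarray(self.background, float).ravel()
        if self.lesion.size == 0 or self.background.size == 0:
            raise ValueError("both sample sets must be non-empty")
        n1, n2 = self.lesion.size, self.background.size
        if abs(n1 - n2) > 0.2 * max(n1, n2):
            raise ValueError(
                f"sample sizes differ by more than 20% ({n1} vs {n2})"
            )
        self.low_sample_warning = min(n1, n2) < 50


def gcnr(
    lesion: np.ndarray, background: np.ndarray, bins: int = 256
) -> tuple[float, float]:
    """Generalized contrast-to-noise ratio and the optimal threshold.

    gCNR = 1 - OVL, with OVL the summed bin-wise minimum of the two
    histograms normalized to unit mass over a shared binning.  Also returns
    epsilon0, the bin edge minimizing the pixel classification error.
    """
    lesion = np.asarray(lesion, float).ravel()
    background = np.asarray(background, float).ravel()
    if lesion.size == 0 or background.size == 0:
        raise ValueError("both sample sets must be non-empty")
    lo = min(lesion.min(), background.min())
    hi = max(lesion.max(), background.max())
    if hi <= lo:
        return 0.0, float(lo)
    edges = np.linspace(lo, hi, bins + 1)
    h_l, _ = np.histogram(lesion, bins=edges)
    h_b, _ = np.histogram(background, bins=edges)
    p_l = h_l / h_l.sum()
    p_b = h_b / h_b.sum()
    ovl = float(np.minimum(p_l, p_b).sum())
    # threshold minimizing classification error (equal priors): scan edges
    cum_l = np.concatenate([[0.0], np.cumsum(p_l)])
    cum_b = np.concatenate([[0.0], np.cumsum(p_b)])
    err = 0.5 * np.minimum(cum_l + (1.0 - cum_b), cum_b + (1.0 - cum_l))
    eps0 = float(edges[int(np.argmin(err))])
    return 1.0 - ovl, eps0


def cnr(lesion: np.ndarray, background: np.ndarray) -> float:
    """Contrast-to-noise ratio |mu_l - mu_b| / sqrt(sigma_l^2 + sigma_b^2)."""
    lesion = np.asarray(lesion, float).ravel()
    background = np.asarray(background, float).ravel()
    denom = math.sqrt(lesion.var() + background.var())
    if denom == 0.0:
        return math.inf if lesion.mean() != background.mean() else 0.0
    return float(abs(lesion.mean() - background.mean()) / denom)


def contrast_db(lesion: np.ndarray, background: np.ndarray) -> float:
    """Amplitude contrast 20 log10(mu_lesion / mu_background) in dB,
    intended for pre-compression envelope means."""
    mu_l = float(np.mean(lesion))
    mu_b = float(np.mean(background))
    if mu_l <= 0 or mu_b <= 0:
        raise ValueError("means must be positive for a dB contrast")
    return 20.0 * math.log10(mu_l / mu_b)


def speckle_stats(env: np.ndarray, bins: int = 100) -> dict:
    """First-order speckle statistics of envelope samples.

    Returns SNR (mean/std), the maximum-likelihood Rayleigh scale, and the
    sum of squared differences between the normalized histogram densities
    and the fitted Rayleigh density at the bin centres.
    """
    x = np.asarray(env, float).ravel()
    if x.size < 2:
        raise ValueError("need at least two samples")
    std = x.std()
    if std == 0.0:
        raise ValueError("zero-variance samples: SNR undefined")
    snr = float(x.mean() / std)
    scale = float(np.sqrt(np.mean(x**2) / 2.0))
    dens, edges = np.histogram(x, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fitted = (centers / scale**2) * np.exp(-0.5 * (centers / scale) ** 2)
    sse = float(np.sum((dens - fitted) ** 2))
    return {"snr": snr, "rayleigh_scale": scale, "sse": sse}


@dataclass
class TREReport:
    """Per-target registration errors (mm) with group statistics."""

    errors_mm: list[float]
    groups: dict[str, dict]
    missed: int

    @property
    def mean_mm(self) -> float:
        return float(np.mean(self.errors_mm)) if self.errors_mm else math.nan

    @property
    def std_mm(self) -> float:
        return float(np.std(self.errors_mm)) if self.errors_mm else math.nan


def _subpixel_peak(signal: np.ndarray, idx: int) -> float:
    """Quadratic (three-point) sub-sample refinement of a local maximum."""
    if idx <= 0 or idx >= len(signal) - 1:
        return float(idx)
    y0, y1, y2 = signal[idx - 1], signal[idx], signal[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def measure_tre(
    image: BModeImage,
    expected_groups: dict[str, list],
    *,
    gate_mm: float = 3.0,
    prominence_frac: float = 0.15,
) -> TREReport:
    """Target registration error between expected and imaged wire targets.

    For each group, a straight line is sampled through the expected target
    positions (a vertical line for targets sharing a lateral position, a
    horizontal line for targets sharing a depth), local maxima are detected
    with a prominence threshold, refined to sub-pixel by quadratic
    interpolation, and matched to expected positions by nearest neighbour
    within ``gate_mm``; unmatched targets are counted as missed and
    excluded from the statistics.
    """
    ps = image.pixel_spacing_mm
    img = image.pixels.astype(float)
    errors: list[float] = []
    groups_out: dict[str, dict] = {}
    missed = 0
    for name, centers in expected_groups.items():
        centers = np.atleast_2d(np.asarray(centers, float))
        xs, zs = centers[:, 0], centers[:, 2]
        vertical = np.ptp(xs) < np.ptp(zs)
        if vertical:
            line_x = float(np.mean(xs))
            coord_expected = zs
            n_pix = img.shape[0]
            rows = np.arange(n_pix)
            cols = np.full(n_pix, (line_x - image.x_min_mm) / ps)
            axis_mm = image.z_min_mm + rows * ps
        else:
            line_z = float(np.mean(zs))
            coord_expected = xs
            n_pix = img.shape[1]
            cols = np.arange(n_pix)
            rows = np.full(n_pix, (line_z - image.z_min_mm) / ps)
            axis_mm = image.x_min_mm + cols * ps
        signal = ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")
        prom = prominence_frac * (signal.max() - signal.min())
        peaks, _ = find_peaks(signal, prominence=max(prom, 1.0))
        peak_mm = np.array(
            [axis_mm[0] + _subpixel_peak(signal, p) * ps for p in peaks]
        )
        g_err = []
        g_missed = 0
        for c in coord_expected:
            if peak_mm.size == 0:
                g_missed += 1
                continue
            j = int(np.argmin(np.abs(peak_mm - c)))
            err = abs(float(peak_mm[j] - c))
            if err <= gate_mm:
                g_err.append(err)
            else:
                g_missed += 1
        errors.extend(g_err)
        missed += g_missed
        groups_out[name] = {
            "mean_mm": float(np.mean(g_err)) if g_err else math.nan,
            "std_mm": float(np.std(g_err)) if g_err else math.nan,
            "n": len(g_err),
            "missed": g_missed,
        }
    return TREReport(errors_mm=errors, groups=groups_out, missed=missed)
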