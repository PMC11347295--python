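"""Ray-traceable scene built from a labelled voxel volume.

The world is described by an integer label per voxel plus, for every label,
a narrow-band signed distance grid (negative inside the labelled region)
whose trilinear gradient provides smooth surface normals at boundaries, and
a table of per-tissue acoustic properties.

Coordinate convention (used everywhere in the package): voxel indices are
0-based and world coordinates are voxel-centre based — the world position of
voxel (0, 0, 0) is ``origin`` and voxel (i, j, k) sits at
``origin + (i, j, k) * spacing``.  Axes are x (lateral), y (elevation),
z (axial/depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "LabelGrid",
    "SDFGrid",
    "TissueAcoustics",
    "LabelScene",
    "compute_sdf",
    "surface_normal",
    "label_at",
    "load_label_volume",
    "load_tissue_table",
    "DEFAULT_TISSUES",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LabelGrid:
    """Labelled voxel volume with world geometry.

    Parameters
    ----------
    labels
        3-D array of non-negative integers; 0 is the ambient medium.
    spacing
        Per-axis voxel size in mm (all components > 0).
    origin
        World position (mm) of the centre of voxel (0, 0, 0).
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world points (mm)."""
        return (np.asarray(points, dtype=float) - self.origin) / self.spacing

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) * self.spacing + self.origin

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Nearest-voxel label lookup; points outside the volume return 0.

        Ties on voxel faces are resolved by rounding half down per axis.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        v = self.world_to_voxel(pts)
        # round-half-down: 0.5 -> 0
        idx = np.ceil(v - 0.5).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=-1)
        out = np.zeros(len(pts), dtype=self.labels.dtype)
        if np.any(inside):
            ii = idx[inside]
            out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def present_labels(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class SDFGrid:
    """Narrow-band signed distance grid for one label.

    ``distances`` holds signed distances in mm to the label's boundary,
    negative strictly inside the labelled voxel set, clamped to ±``band``.
    ``valid`` marks voxels whose (unclamped) distance lies within the band.
    """

    distances: np.ndarray
    valid: np.ndarray
    band: float
    spacing: np.ndarray
    origin: np.ndarray

    def value_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly interpolated signed distance at world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        coords = ((pts - self.origin) / self.spacing).T
        vals = ndimage.map_coordinates(
            self.distances, coords, order=1, mode="nearest"
        )
        if np.asarray(points).ndim == 1:
            return vals[0]
        return vals

    def in_band(self, point: np.ndarray) -> bool:
        idx = np.clip(
            np.round((np.asarray(point, float) - self.origin) / self.spacing),
            0,
            np.asarray(self.distances.shape) - 1,
        ).astype(int)
        return bool(self.valid[idx[0], idx[1], idx[2]])


@dataclass
class TissueAcoustics:
    """Acoustic and scatterer-model parameters of one tissue type.

    impedance : kg/(m^2 s); attenuation : dB/(cm MHz); sound_speed : m/s.
    mu0, sigma0 parameterize the scatterer amplitude distribution, mu1 the
    probability that a candidate scatterer is generated.  tau in [0, 3]
    scales boundary echoes between diffuse and specular; gamma in [-2, 2]
    shapes the angular dependence cos(theta)^gamma of boundary echoes.
    """

    impedance: float
    attenuation: float
    sound_speed: float
    mu0: float = 0.0
    sigma0: float = 0.0
    mu1: float = 0.0
    tau: float = 1.0
    gamma: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.impedance <= 0:
            raise ValueError("impedance must be positive")
        if self.attenuation < 0:
            raise ValueError("attenuation must be non-negative")
        if self.sound_speed <= 0:
            raise ValueError("sound speed must be positive")
        if not 0.0 <= self.mu1 <= 1.0:
            raise ValueError("mu1 must lie in [0, 1]")
        if not 0.0 <= self.tau <= 3.0:
            raise ValueError("tau must lie in [0, 3]")
        if not -2.0 <= self.gamma <= 2.0:
            raise ValueError("gamma must lie in [-2, 2]")


#: Default tissue parameterization. Impedance, attenuation and sound speed
#: are textbook soft-tissue values; the scatterer parameters (mu0, sigma0,
#: mu1) and the echo-shaping coefficients (tau, gamma) are model
#: hyperparameters chosen to produce plausible images and are meant to be
#: replaced by the user for quantitative work.
DEFAULT_TISSUES: dict[str, TissueAcoustics] = {
    "water": TissueAcoustics(1.48e6, 0.0022, 1480, 0.0, 0.0, 0.0, 0.0, 0.0, "water"),
    "soft_tissue": TissueAcoustics(1.63e6, 0.54, 1540, 0.5, 0.15, 1.0, 1.0, 0.7, "soft_tissue"),
    "phantom_background": TissueAcoustics(1.58e6, 0.5, 1540, 0.15, 0.05, 1.0, 1.0, 0.7, "phantom_background"),
    "fat": TissueAcoustics(1.38e6, 0.48, 1450, 0.4, 0.12, 0.8, 1.0, 0.5, "fat"),
    "blood": TissueAcoustics(1.61e6, 0.2, 1570, 0.05, 0.02, 0.3, 0.5, 0.0, "blood"),
    "myocardium": TissueAcoustics(1.70e6, 0.52, 1576, 0.6, 0.2, 1.0, 1.0, 0.1, "myocardium"),
    "bone": TissueAcoustics(7.80e6, 6.9, 3500, 0.3, 0.1, 0.5, 2.0, 0.1, "bone"),
    "nylon": TissueAcoustics(2.90e6, 1.0, 2600, 0.1, 0.02, 0.2, 1.0, 0.0, "nylon"),
    "cyst_fluid": TissueAcoustics(1.58e6, 0.02, 1540, 0.0, 0.0, 0.0, 0.0, 0.0, "cyst_fluid"),
    "lung": TissueAcoustics(0.26e6, 4.0, 650, 0.3, 0.1, 0.5, 1.5, 0.2, "lung"),
}

_TISSUE_FIELDS = (
    "impedance",
    "attenuation",
    "sound_speed",
    "mu0",
    "sigma0",
    "mu1",
    "tau",
    "gamma",
)


@dataclass
class LabelScene:
    """The ray-traceable world: labels + per-label SDFs + tissue table."""

    grid: LabelGrid
    sdf_by_label: dict[int, SDFGrid] = field(default_factory=dict)
    tissue_by_label: dict[int, TissueAcoustics] = field(default_factory=dict)
    ambient: TissueAcoustics = field(
        default_factory=lambda: DEFAULT_TISSUES["water"]
    )

    @classmethod
    def build(
        cls,
        labels: np.ndarray,
        spacing,
        origin,
        tissues: Mapping[int, TissueAcoustics],
        *,
        band_mm: float | None = None,
        ambient: TissueAcoustics | None = None,
    ) -> "LabelScene":
        """Assemble a scene, computing one narrow-band SDF per nonzero label."""
        grid = LabelGrid(labels, spacing, origin)
        if ambient is None:
            ambient = tissues.get(0, DEFAULT_TISSUES["water"])
        scene = cls(grid=grid, tissue_by_label=dict(tissues), ambient=ambient)
        for lab in grid.present_labels():
            lab = int(lab)
            if lab == 0:
                continue
            if lab not in scene.tissue_by_label:
                raise KeyError(f"label {lab} present in grid but missing from tissue table")
            scene.sdf_by_label[lab] = compute_sdf(grid, lab, band_mm)
        return scene

    def tissue(self, label: int) -> TissueAcoustics:
        if label == 0:
            return self.tissue_by_label.get(0, self.ambient)
        return self.tissue_by_label[label]

    def validate(self) -> None:
        for lab in self.grid.present_labels():
            lab = int(lab)
            if lab == 0:
                continue
            if lab not in self.sdf_by_label:
                raise ValueError(f"label {lab} has no SDF grid")
            if lab not in self.tissue_by_label:
                raise ValueError(f"label {lab} has no tissue entry")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_sdf(grid: LabelGrid, label: int, band_mm: float | None = None) -> SDFGrid:
    """Narrow-band signed distance grid for one label.

    Exact Euclidean distance transforms on the binary mask (inside and
    outside), signed by mask membership, shifted by half a voxel so the zero
    level sits on the boundary face between inside and outside voxels, and
    clamped to ±band.  The transform runs on the mask's bounding box plus a
    band margin; everything farther away is clamped positive.

    Parameters
    ----------
    band_mm
        Half-width of the valid narrow band; defaults to 4 voxels
        (4 * max(spacing)).  Must be at least 2 * max(spacing).
    """
    if label == 0:
        raise ValueError("label 0 is the ambient medium and has no SDF")
    mask = grid.labels == label
    if not mask.any():
        raise KeyError(f"label {label} does not occur in the grid")
    spacing = grid.spacing
    if band_mm is None:
        band_mm = 4.0 * float(spacing.max())
    if band_mm < 2.0 * spacing.max():
        raise ValueError("band must be at least 2 * max(spacing)")

    # crop to bounding box + band margin (distance farther out is > band)
    margin = np.ceil(band_mm / spacing).astype(int) + 1
    nz = [np.flatnonzero(mask.any(axis=tuple(a for a in range(3) if a != ax)))
          for ax in range(3)]
    lo = [max(0, int(n[0]) - m) for n, m in zip(nz, margin)]
    hi = [min(s, int(n[-1]) + 1 + m) for n, m, s in zip(nz, margin, mask.shape)]
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    mc = mask[sl]

    d_out = ndimage.distance_transform_edt(~mc, sampling=spacing)
    d_in = ndimage.distance_transform_edt(mc, sampling=spacing)
    half = 0.5 * float(spacing.min())
    sd_crop = np.where(mc, -(d_in - half), d_out - half)

    full = np.full(grid.shape, band_mm, dtype=np.float32)
    valid = np.zeros(grid.shape, dtype=bool)
    full[sl] = np.clip(sd_crop, -band_mm, band_mm)
    valid[sl] = np.abs(sd_crop) <= band_mm
    return SDFGrid(full, valid, float(band_mm), spacing.copy(), grid.origin.copy())


def surface_normal(sdf: SDFGrid, point: np.ndarray) -> np.ndarray:
    """Unit surface normal at a world point from the SDF's trilinear gradient.

    Points from the inside of the labelled region toward the outside.  The
    point must lie inside the valid narrow band.
    """
    point = np.asarray(point, dtype=float)
    if not sdf.in_band(point):
        raise ValueError("point lies outside the SDF's narrow band")
    # wide stencil: averages the trilinear gradient over neighbouring
    # cells, suppressing the EDT's voxel-scale staircase noise
    h = 2.0 * float(sdf.spacing.min())
    offsets = np.zeros((6, 3))
    for ax in range(3):
        offsets[2 * ax, ax] = h
        offsets[2 * ax + 1, ax] = -h
    vals = sdf.value_at(point[None, :] + offsets)
    g = (vals[0::2] - vals[1::2]) / (2.0 * h)
    norm = np.linalg.norm(g)
    if norm < 1e-12:
        raise ValueError("degenerate SDF gradient (skeleton point?)")
    return g / norm


def label_at(scene: LabelScene, point: np.ndarray) -> int | np.ndarray:
    """Nearest-voxel label at a world point; outside the volume returns 0."""
    return scene.grid.label_at(point)


# ---------------------------------------------------------------------------
# External interfaces: volume readers and tissue-table files
# ---------------------------------------------------------------------------


def load_label_volume(path: str | Path) -> LabelGrid:
    """Read an integer label volume from NIfTI (.nii/.nii.gz) or MetaImage
    (.mha/.mhd); spacing and origin come from the header.

    The affine is used only for spacing magnitudes and the translation; the
    volume is treated in its native index axes.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        labels = np.asarray(img.dataobj).astype(np.int32)
        spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
        origin = np.asarray(img.affine[:3, 3], dtype=float)
        return LabelGrid(labels, spacing, origin)
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        # GetArrayFromImage returns (z, y, x); transpose to (x, y, z)
        labels = sitk.GetArrayFromImage(img).astype(np.int32).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing(), dtype=float)
        origin = np.asarray(img.GetOrigin(), dtype=float)
        return LabelGrid(labels, spacing, origin)
    raise ValueError(f"unsupported label-volume format: {path.name}")


def save_label_volume(grid: LabelGrid, path: str | Path) -> None:
    """Write a LabelGrid as NIfTI with spacing/origin in the header."""
    import nibabel as nib

    affine = np.diag([*grid.spacing, 1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.labels.astype(np.int16), affine), str(path))


def load_tissue_table(path: str | Path) -> dict[int, TissueAcoustics]:
    """Read a YAML/JSON tissue table: one record per integer label with the
    eight acoustic fields.  A missing field is a hard error naming label and
    field."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    table: dict[int, TissueAcoustics] = {}
    for key, rec in raw.items():
        label = int(key)
        missing = [f for f in _TISSUE_FIELDS if f not in rec]
        if missing:
            raise ValueError(
                f"tissue record for label {label} is missing fields: {missing}"
            )
        table[label] = TissueAcoustics(
            **{f: float(rec[f]) for f in _TISSUE_FIELDS},
            name=str(rec.get("name", f"label{label}")),
        )
    return table
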