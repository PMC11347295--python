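"""Programmatic builders for the validation scenes.

Every builder is deterministic given its arguments and emits ground-truth
metadata (wire centres, lesion centres/radii/nominal contrasts) alongside
the scene, so the metrics stage never has to re-derive geometry.  The wire
layout mirrors a general-purpose calibration phantom: a vertical wire
column for axial accuracy plus near-field and far-field horizontal rows for
lateral accuracy.  Scenes use the background tissue as the ambient medium
(label 0), so only the embedded targets are voxelized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .scene import DEFAULT_TISSUES, LabelScene, TissueAcoustics
from .speckle import ScattererSet
from .tracing import IntensityProfile, TransducerConfig, uniform_profile

__all__ = [
    "PhantomSpec",
    "make_speckle_slab",
    "make_wire_phantom",
    "make_lesion_phantom",
    "make_artifact_sphere",
    "make_toy_heart",
]


@dataclass
class PhantomSpec:
    """Declarative description of a target-in-background phantom."""

    background: TissueAcoustics
    targets: list[dict] = field(default_factory=list)
    size_mm: tuple[float, float, float] = (80.0, 4.0, 150.0)
    spacing_mm: float = 0.12

    def validate(self) -> None:
        sx, sy, sz = self.size_mm
        for t in self.targets:
            cx, cy, cz = (float(v) for v in t["center"])
            r = float(t.get("radius", 0.0))
            if abs(cx) + r > sx / 2 or abs(cy) > sy / 2 or cz - r < 0 or cz + r > sz:
                raise ValueError(f"target {t} lies outside the volume")
            if t.get("shape") == "wire" and r < self.spacing_mm:
                raise ValueError("wire radius must be at least one voxel")


def _empty_grid(size_mm, spacing_mm, z0=0.0):
    """Label array + geometry for a volume centred on x=y=0, z in [z0, z0+Lz]."""
    size = np.asarray(size_mm, float)
    n = np.maximum(np.round(size / spacing_mm).astype(int), 1)
    labels = np.zeros(tuple(n), dtype=np.int16)
    spacing = np.full(3, float(spacing_mm))
    origin = np.array([-size[0] / 2.0, -size[1] / 2.0, z0])
    return labels, spacing, origin


def _voxel_centers(labels_shape, spacing, origin):
    ax = [origin[i] + spacing[i] * np.arange(labels_shape[i]) for i in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def make_speckle_slab(
    size_mm: float = 40.0,
    density: float = 600.0,
    amplitude: float = 1.0,
    rng: np.random.Generator | None = None,
    *,
    transducer: TransducerConfig | None = None,
    z0_mm: float = 2.0,
) -> tuple[ScattererSet, IntensityProfile, TransducerConfig]:
    """Homogeneous fully-developed-speckle slab.

    Random scatterers of fixed amplitude are distributed uniformly at
    ``density`` per mm^2 over a ``size_mm`` x ``size_mm`` region of the
    imaging plane; the intensity profile is identically 1 (no boundaries).
    Returns (scatterers, profile, linear-array transducer spanning the slab).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if transducer is None:
        n_el = int(round(size_mm / 0.4))
        transducer = TransducerConfig(
            scan_geometry="linear",
            num_elements=n_el,
            element_width_mm=0.35,
            kerf_mm=0.05,
            depth_mm=size_mm + z0_mm + 2.0,
        )
    n = rng.poisson(density * size_mm * size_mm)
    pos = np.empty((n, 3))
    pos[:, 0] = rng.uniform(-size_mm / 2.0, size_mm / 2.0, n)
    pos[:, 1] = 0.0
    pos[:, 2] = rng.uniform(z0_mm, z0_mm + size_mm, n)
    scat = ScattererSet(pos, np.full(n, float(amplitude)), np.ones(n, dtype=int))
    return scat, uniform_profile(transducer), transducer


def make_wire_phantom(
    spec: PhantomSpec | None = None,
    *,
    spacing_mm: float = 0.12,
    wire_radius_mm: float = 0.3,
) -> tuple[LabelScene, dict]:
    """Wire (distance-accuracy) phantom: thin high-impedance nylon cylinders
    perpendicular to the imaging plane in a homogeneous background.

    Default layout: a vertical column at x = 3 mm, depths 15..135 mm in
    10 mm steps (slightly off the sector axis so no two wires share a
    scanline and the column does not shadow itself); a near-field
    horizontal row at 40 mm depth (x = -30..30 mm) and a far-field row at
    120 mm depth (x = -40..40 mm), 10 mm pitch.  Returns the scene plus
    ground truth with exact world centres grouped as vertical /
    horizontal_near / horizontal_far, ordered by depth then lateral
    position.
    """
    bg = DEFAULT_TISSUES["phantom_background"]
    # a sub-resolution nylon wire behaves as a single coherent point
    # target: the random-scatterer model inside it would add speckle jitter
    # to its apparent position, so the wire tissue generates no random
    # scatterers (mu1=0) and the imaging stage plants one strong scatterer
    # at each exact centre; the impedance step keeps the weak facet echoes
    # and the boundary/shadowing behaviour
    wire = replace(DEFAULT_TISSUES["nylon"], mu1=0.0, tau=0.05)
    if spec is None:
        targets = []
        for z in np.arange(15.0, 136.0, 10.0):
            # offset from the row depths (40/120 mm) so no column blob
            # merges with a row blob
            targets.append({"shape": "wire", "center": (3.0, 0.0, float(z)),
                            "radius": wire_radius_mm, "group": "vertical"})
        for z, grp, half in ((40.0, "horizontal_near", 30.0),
                             (120.0, "horizontal_far", 40.0)):
            for x in np.arange(-half, half + 1.0, 10.0):
                targets.append({"shape": "wire", "center": (float(x), 0.0, z),
                                "radius": wire_radius_mm, "group": grp})
        spec = PhantomSpec(background=bg, targets=targets,
                           size_mm=(96.0, 3.0, 140.0), spacing_mm=spacing_mm)
    spec.validate()

    labels, spacing, origin = _empty_grid(spec.size_mm, spec.spacing_mm)
    xx, yy, zz = _voxel_centers(labels.shape, spacing, origin)
    for t in spec.targets:
        cx, _, cz = t["center"]
        r = t["radius"]
        labels[(xx - cx) ** 2 + (zz - cz) ** 2 <= r * r] = 1

    scene = LabelScene.build(
        labels, spacing, origin, {0: bg, 1: wire}, ambient=bg
    )
    groups: dict[str, list] = {"vertical": [], "horizontal_near": [], "horizontal_far": []}
    for t in spec.targets:
        groups.setdefault(t.get("group", "vertical"), []).append(list(t["center"]))
    for grp in groups.values():
        grp.sort(key=lambda c: (c[2], c[0]))
    truth = {
        "groups": groups,
        "wire_radius_mm": wire_radius_mm,
        "n_targets": sum(len(g) for g in groups.values()),
    }
    return scene, truth


#: Default lesion slots (x, z) in mm for up to four lesions.
_LESION_SLOTS = ((0.0, 28.0), (-14.0, 42.0), (14.0, 42.0), (0.0, 56.0))


def make_lesion_phantom(
    contrasts_db: tuple[float | None, ...] = (None, 15.0, 6.0),
    *,
    radius_mm: float = 4.0,
    spacing_mm: float = 0.25,
    background: TissueAcoustics | None = None,
) -> tuple[LabelScene, dict]:
    """Contrast-lesion phantom: spherical lesions in homogeneous background.

    Each entry of ``contrasts_db`` adds one lesion at the next default slot:
    a float scales the lesion's scatterer amplitude parameters (mu0, sigma0)
    by 10^(dB/20) relative to background; ``None`` makes the lesion anechoic
    (mu1 = 0).  Lesions are acoustically matched to the background
    (identical impedance, speed and attenuation), so measured contrast
    isolates the scatterer model.
    """
    bg = background or DEFAULT_TISSUES["phantom_background"]
    if len(contrasts_db) > len(_LESION_SLOTS):
        raise ValueError(f"at most {len(_LESION_SLOTS)} lesions supported")
    size = (76.0, 4.0, 72.0)
    labels, spacing, origin = _empty_grid(size, spacing_mm)
    xx, yy, zz = _voxel_centers(labels.shape, spacing, origin)

    tissues: dict[int, TissueAcoustics] = {0: bg}
    lesions = []
    for i, c_db in enumerate(contrasts_db):
        lab = i + 1
        cx, cz = _LESION_SLOTS[i]
        mask = (xx - cx) ** 2 + yy**2 + (zz - cz) ** 2 <= radius_mm**2
        labels[mask] = lab
        if c_db is None:
            tissues[lab] = replace(bg, mu1=0.0, name=f"lesion_anechoic")
        else:
            k = 10.0 ** (c_db / 20.0)
            tissues[lab] = replace(
                bg, mu0=bg.mu0 * k, sigma0=bg.sigma0 * k, name=f"lesion_{c_db:+g}dB"
            )
        lesions.append(
            {
                "label": lab,
                "center": [cx, 0.0, cz],
                "radius_mm": radius_mm,
                "contrast_db": c_db,
                "anechoic": c_db is None,
            }
        )
    scene = LabelScene.build(labels, spacing, origin, tissues, ambient=bg)
    return scene, {"lesions": lesions, "background": bg.name}


def make_artifact_sphere(
    mode: str = "attenuating",
    *,
    radius_mm: float = 8.0,
    center: tuple[float, float, float] = (0.0, 0.0, 40.0),
    spacing_mm: float = 0.25,
) -> tuple[LabelScene, dict]:
    """Sphere phantom for attenuation artefacts.

    ``fluid``: impedance-matched, scatterer-free, low-attenuation sphere
    (post-acoustic enhancement distal to it).  ``attenuating``: highly
    attenuating, impedance-mismatched sphere (distal shadowing).
    """
    bg = DEFAULT_TISSUES["phantom_background"]
    if mode == "fluid":
        sphere = replace(bg, attenuation=0.02, mu1=0.0, name="fluid")
    elif mode == "attenuating":
        sphere = replace(
            bg, impedance=7.8e6, attenuation=10.0, mu1=0.0, tau=1.0, name="attenuator"
        )
    else:
        raise ValueError("mode must be 'fluid' or 'attenuating'")
    size = (60.0, 4.0, 90.0)
    labels, spacing, origin = _empty_grid(size, spacing_mm)
    xx, yy, zz = _voxel_centers(labels.shape, spacing, origin)
    c = np.asarray(center, float)
    labels[(xx - c[0]) ** 2 + yy**2 + (zz - c[2]) ** 2 <= radius_mm**2] = 1
    scene = LabelScene.build(labels, spacing, origin, {0: bg, 1: sphere}, ambient=bg)
    truth = {"mode": mode, "center": list(center), "radius_mm": radius_mm}
    return scene, truth


def make_toy_heart(
    *,
    chamber_radii_mm: tuple[float, float] = (18.0, 14.0),
    wall_mm: float = 6.0,
    rib: bool = False,
    spacing_mm: float = 0.5,
) -> tuple[LabelScene, dict]:
    """Toy heart-like label volume: two ellipsoidal blood-filled chambers in
    a myocardium shell inside soft tissue, with an optional rib occluder in
    front of the transducer — sufficient for end-to-end smoke tests of
    chamber visibility and rib shadowing.

    Labels: 0 soft tissue (ambient), 1 myocardium, 2 blood, 3 bone (rib).
    """
    soft = DEFAULT_TISSUES["soft_tissue"]
    tissues = {
        0: soft,
        1: DEFAULT_TISSUES["myocardium"],
        2: DEFAULT_TISSUES["blood"],
        3: DEFAULT_TISSUES["bone"],
    }
    size = (90.0, 6.0, 110.0)
    labels, spacing, origin = _empty_grid(size, spacing_mm)
    xx, yy, zz = _voxel_centers(labels.shape, spacing, origin)

    centers = [(-16.0, 55.0), (16.0, 55.0)]
    for (cx, cz), r in zip(centers, chamber_radii_mm):
        shell = ((xx - cx) / (r + wall_mm)) ** 2 + ((zz - cz) / (1.3 * r + wall_mm)) ** 2
        labels[shell <= 1.0] = 1
    for (cx, cz), r in zip(centers, chamber_radii_mm):
        inner = ((xx - cx) / r) ** 2 + ((zz - cz) / (1.3 * r)) ** 2
        labels[inner <= 1.0] = 2
    if rib:
        labels[(xx - 0.0) ** 2 + (zz - 12.0) ** 2 <= 5.0**2] = 3

    present = {0: soft, **{k: v for k, v in tissues.items() if k in np.unique(labels)}}
    scene = LabelScene.build(labels, spacing, origin, present, ambient=soft)
    truth = {
        "chambers": [
            {"center": [cx, 0.0, cz], "radius_mm": r}
            for (cx, cz), r in zip(centers, chamber_radii_mm)
        ],
        "rib": {"center": [0.0, 0.0, 12.0], "radius_mm": 5.0} if rib else None,
        "labels": {"soft_tissue": 0, "myocardium": 1, "blood": 2, "bone": 3},
    }
    return scene, truth


def export_phantom(scene: LabelScene, truth: dict, out_dir: str | Path) -> None:
    """Write the label volume as NIfTI and the ground truth as YAML, so
    fixtures are reusable outside the test suite."""
    import yaml

    from .scene import save_label_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_label_volume(scene.grid, out / "labels.nii.gz")
    (out / "truth.yaml").write_text(yaml.safe_dump(truth))
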