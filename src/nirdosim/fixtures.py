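"""Synthetic phantom fixtures: layered heads and slabs with the standard file contract.

These generators stand in for template-derived human head phantoms so the
whole pipeline — probability maps, atlas, phantom synthesis, transport,
dosimetry — can run without any patient data.  Every fixture is a
deterministic function of its :class:`FixtureSpec`.

The layered head is a scalp/skull shell pair concentric on the world origin
with the brain compartment (CSF envelope, gray-matter shell, white-matter
core) offset anterior-superior, reflecting that the frontal cortex lies close
behind the forehead while the face, mouth and nose have no brain immediately
behind them.  That anatomy is what makes the treatment-paradigm placements
(forehead, head top, eye, occipital, oral, nasal analogs) genuinely different
in brain dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .phantom import LabelAtlas, ProbabilityMaps, VolumeGrid

__all__ = [
    "FixtureSpec",
    "make_layered_head",
    "make_slab",
    "PARADIGM_ANGLES",
    "DEFAULT_HEAD_RADII",
    "DEFAULT_BRAIN_OFFSET",
]

#: Concentric radii (mm), outer to inner: scalp surface, skull outer, skull
#: inner (CSF envelope), gray-matter outer, white-matter outer.
DEFAULT_HEAD_RADII: dict[str, float] = {
    "soft_tissue": 80.0,
    "skull": 73.0,
    "csf": 66.0,
    "gray_matter": 49.0,
    "white_matter": 38.0,
}

#: Brain-compartment center offset (anterior-superior), mm in RAS world.
DEFAULT_BRAIN_OFFSET: tuple[float, float, float] = (0.0, 8.0, 10.0)

#: Scalp placement angles (phi azimuth from +X, theta polar from +Z), degrees,
#: for the six treatment-paradigm analogs.  RAS frame: +X right, +Y anterior,
#: +Z superior.
PARADIGM_ANGLES: dict[str, tuple[float, float]] = {
    "forehead": (90.0, 45.0),
    "head_top": (0.0, 0.0),
    "ocular": (90.0, 90.0),
    "occipital": (270.0, 90.0),
    "nasal": (90.0, 105.0),
    "oral": (90.0, 135.0),
}

#: Eye-slab layer order and default thicknesses (mm) front to back.
EYE_SLAB_LAYERS: list[tuple[str, float]] = [
    ("eyelid_skin", 3.0),
    ("cornea", 1.0),
    ("aqueous", 3.0),
    ("lens", 4.0),
    ("vitreous", 17.0),
    ("sclera_retina", 2.0),
    ("orbital_fat", 10.0),
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic phantom.

    ``kind`` is "layered_head", "slab" or "eye_slab".  Heads use ``radii``
    (outer->inner per tissue class) and ``brain_offset``; slabs use
    ``layers`` (ordered (class, thickness mm) pairs along +Z).
    """

    kind: str = "layered_head"
    shape: tuple[int, int, int] = (170, 170, 170)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radii: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HEAD_RADII))
    brain_offset: tuple[float, float, float] = DEFAULT_BRAIN_OFFSET
    layers: Sequence[tuple[str, float]] = ()
    smooth_sigma: float = 0.0
    lobes: bool = False
    seed: int = 0


def make_layered_head(
    spec: FixtureSpec,
) -> tuple[ProbabilityMaps, LabelAtlas, np.ndarray]:
    """Build the layered spherical head: probability maps, atlas, head mask.

    Crisp shells (optionally smoothed into probabilistic boundaries by a
    Gaussian of ``smooth_sigma`` mm); the atlas splits gray matter into
    left/right hemisphere labels, optionally into octant 'lobes'.
    Deterministic given the spec.
    """
    radii = dict(spec.radii)
    order = ["soft_tissue", "skull", "csf", "gray_matter", "white_matter"]
    missing = [c for c in order if c not in radii]
    if missing:
        raise ValueError(f"layered head radii missing classes: {missing}")
    vals = [radii[c] for c in order]
    if any(a <= b for a, b in zip(vals[1:], vals[2:])) or vals[0] <= vals[1]:
        raise ValueError(f"radii must be strictly decreasing outer->inner, got {vals}")

    grid = VolumeGrid(spec.shape, spec.voxel_size)
    idx = np.indices(spec.shape, dtype=float)
    world = np.stack(
        [
            idx[k] * grid.affine[k, k] + grid.affine[k, 3]
            for k in range(3)
        ]
    )
    off = np.asarray(spec.brain_offset, dtype=float)
    r_head = np.sqrt((world**2).sum(axis=0))
    r_brain = np.sqrt(((world - off[:, None, None, None]) ** 2).sum(axis=0))
    if radii["gray_matter"] + np.linalg.norm(off) > radii["csf"]:
        raise ValueError("brain compartment does not fit inside the skull")

    inside_head = r_head <= radii["soft_tissue"]
    masks = {
        "soft_tissue": inside_head & (r_head > radii["skull"]),
        "skull": (r_head <= radii["skull"]) & (r_head > radii["csf"]),
        "csf": (r_head <= radii["csf"]) & (r_brain > radii["gray_matter"]),
        "gray_matter": (r_brain <= radii["gray_matter"])
        & (r_brain > radii["white_matter"]),
        "white_matter": r_brain <= radii["white_matter"],
    }
    maps = {cls: m.astype(float) for cls, m in masks.items()}

    if spec.smooth_sigma > 0:
        sig = [spec.smooth_sigma / v for v in spec.voxel_size]
        maps = {cls: ndimage.gaussian_filter(m, sigma=sig) for cls, m in maps.items()}
        total = sum(maps.values())
        scale = np.where(total > 1.0, total, 1.0)
        maps = {cls: m / scale for cls, m in maps.items()}

    probmaps = ProbabilityMaps(grid, maps)
    head_mask = probmaps.total() > 0.01

    labels = np.zeros(spec.shape, dtype=np.int32)
    gm = masks["gray_matter"]
    left = world[0] < 0
    if not spec.lobes:
        labels[gm & left] = 1
        labels[gm & ~left] = 2
        lookup = {1: "lh_gray_matter", 2: "rh_gray_matter"}
    else:
        lookup = {}
        lab = 1
        for sx, namex in ((True, "lh"), (False, "rh")):
            for sy, namey in ((True, "posterior"), (False, "anterior")):
                for sz, namez in ((True, "inferior"), (False, "superior")):
                    sel = gm & (left == sx) & ((world[1] < off[1]) == sy) & (
                        (world[2] < off[2]) == sz
                    )
                    labels[sel] = lab
                    lookup[lab] = f"{namex}_{namey}_{namez}"
                    lab += 1
    wm = masks["white_matter"]
    wm_label = max(lookup) + 1
    labels[wm] = wm_label
    lookup[wm_label] = "white_matter"

    atlas = LabelAtlas(grid, labels, lookup)
    return probmaps, atlas, head_mask


def make_slab(spec: FixtureSpec) -> ProbabilityMaps:
    """Planar layers stacked along +Z with given classes and thicknesses (mm).

    ``kind="eye_slab"`` with empty ``layers`` uses the canonical ocular layer
    sequence.  The first layer starts at voxel z = 0; thicknesses must fit
    inside the grid.
    """
    layers = list(spec.layers)
    if spec.kind == "eye_slab" and not layers:
        layers = list(EYE_SLAB_LAYERS)
    if not layers:
        raise ValueError("slab spec requires at least one (class, thickness) layer")
    grid = VolumeGrid(spec.shape, spec.voxel_size)
    vz = spec.voxel_size[2]
    total_mm = sum(t for _, t in layers)
    if total_mm > spec.shape[2] * vz:
        raise ValueError(
            f"layer thicknesses ({total_mm} mm) exceed grid extent "
            f"({spec.shape[2] * vz} mm)"
        )
    maps: dict[str, np.ndarray] = {}
    z0 = 0.0
    for cls, th in layers:
        if th <= 0:
            raise ValueError(f"non-positive layer thickness for {cls!r}")
        k0 = int(round(z0 / vz))
        k1 = int(round((z0 + th) / vz))
        vol = maps.setdefault(cls, np.zeros(spec.shape))
        vol[:, :, k0:k1] = 1.0
        z0 += th
    return ProbabilityMaps(grid, maps)
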