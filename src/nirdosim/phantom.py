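"""Voxel optical phantoms: grids, probability maps, atlases, and phantom synthesis.

A phantom is built from per-tissue probability maps (one volume per tissue
class, values in [0, 1], voxelwise sum <= 1) by applying the voxel mixing rule
of :mod:`nirdosim.optics` at every requested wavelength.  The result — termed
multispectral because each voxel carries the full wavelength-indexed
(mua, mus, g, n) set — is the medium the Monte Carlo engine propagates
photons through.

Conventions: 0-based voxel indices; world coordinates are voxel-center RAS mm
with the origin at the anterior commissure (grid center for synthetic
fixtures); volumes are 1 mm isotropic by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .optics import AIR, OpticalProperties, SpectralLibrary

__all__ = [
    "VolumeGrid",
    "ProbabilityMaps",
    "LabelAtlas",
    "OpticalPhantom",
    "SparseAnnotation",
    "clean_extracranial",
    "build_phantom",
    "annotate_and_interpolate",
    "region_volumes",
    "apply_rigid_transform",
]

HEAD_MASK_THRESHOLD = 0.01  # total tissue probability above which a voxel is "head"


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel grid geometry: shape, voxel size (mm) and voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"non-positive grid shape {self.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"non-positive voxel size {self.voxel_size}")
        if self.affine is None:
            # Default: RAS axes, origin at the grid center (anterior commissure
            # convention for synthetic phantoms).
            aff = np.eye(4)
            for k in range(3):
                aff[k, k] = self.voxel_size[k]
                aff[k, 3] = -self.voxel_size[k] * (self.shape[k] - 1) / 2.0
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
                raise ValueError("affine must be an invertible 4x4 matrix")
            object.__setattr__(self, "affine", aff)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if out.shape[0] == 1 else out

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        out = xyz @ inv[:3, :3].T + inv[:3, 3]
        return out[0] if out.shape[0] == 1 else out

    def compatible(self, other: "VolumeGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine)


class ProbabilityMaps:
    """Per-tissue-class probability volumes sharing one grid."""

    def __init__(self, grid: VolumeGrid, maps: Mapping[str, np.ndarray]):
        self.grid = grid
        self.maps: dict[str, np.ndarray] = {}
        for cls, vol in maps.items():
            vol = np.asarray(vol, dtype=float)
            if vol.shape != grid.shape:
                raise ValueError(
                    f"probability map {cls!r} shape {vol.shape} != grid {grid.shape}"
                )
            if vol.min() < -1e-9 or vol.max() > 1 + 1e-6:
                raise ValueError(f"probability map {cls!r} has values outside [0, 1]")
            self.maps[cls] = np.clip(vol, 0.0, 1.0)
        total = self.total()
        if total.max() > 1 + 1e-6:
            raise ValueError(f"voxelwise probability sum exceeds 1: max {total.max()}")

    def total(self, exclude: Sequence[str] = ()) -> np.ndarray:
        total = np.zeros(self.grid.shape)
        for cls, vol in self.maps.items():
            if cls not in exclude:
                total += vol
        return total

    @property
    def tissue_classes(self) -> list[str]:
        return list(self.maps)


class LabelAtlas:
    """Integer region labels (0 = unlabeled) with a label -> name lookup."""

    def __init__(self, grid: VolumeGrid, labels: np.ndarray, lookup: Mapping[int, str]):
        labels = np.asarray(labels)
        if labels.shape != grid.shape:
            raise ValueError(f"label volume shape {labels.shape} != grid {grid.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(labels)) - {0}
        missing = present - set(lookup)
        if missing:
            raise ValueError(f"labels present in volume but absent from lookup: {sorted(missing)}")
        self.grid = grid
        self.labels = labels
        self.lookup = dict(lookup)


@dataclass
class SparseAnnotation:
    """Sparse manual annotations plus the 1-D profile lines to interpolate along.

    ``points`` maps each point to a voxel index and either a tissue-class name
    (resolved through the library) or an explicit :class:`OpticalProperties`.
    ``profile_lines`` are ordered sequences of point indices; interpolation is
    applied along each polyline.
    """

    points: list[tuple[tuple[int, int, int], str | OpticalProperties]]
    profile_lines: list[list[int]] = field(default_factory=list)


class OpticalPhantom:
    """Multispectral voxel medium: per-wavelength mua/mus/g/n volumes + head mask."""

    def __init__(
        self,
        grid: VolumeGrid,
        wavelengths: Sequence[float],
        volumes: Mapping[float, Mapping[str, np.ndarray]],
        head_mask: np.ndarray,
    ):
        self.grid = grid
        self.wavelengths = [float(w) for w in wavelengths]
        self.volumes: dict[float, dict[str, np.ndarray]] = {}
        head_mask = np.asarray(head_mask, dtype=bool)
        if head_mask.shape != grid.shape:
            raise ValueError("head mask shape mismatch")
        self.head_mask = head_mask
        for wl in self.wavelengths:
            vols = volumes[wl]
            entry = {}
            for key in ("mua", "mus", "g", "n"):
                arr = np.asarray(vols[key], dtype=float)
                if arr.shape != grid.shape:
                    raise ValueError(f"{key}@{wl} shape mismatch")
                entry[key] = arr
            if entry["mua"].min() < 0 or entry["mus"].min() < 0:
                raise ValueError("negative interaction coefficient in phantom")
            if entry["n"].min() < 1.0 - 1e-12:
                raise ValueError("refractive index below 1 in phantom")
            self.volumes[wl] = entry

    def properties(self, wavelength: float) -> dict[str, np.ndarray]:
        try:
            return self.volumes[float(wavelength)]
        except KeyError:
            raise KeyError(
                f"wavelength {wavelength} nm not in phantom "
                f"(available: {self.wavelengths})"
            ) from None

    def copy(self) -> "OpticalPhantom":
        return OpticalPhantom(
            self.grid,
            self.wavelengths,
            {wl: {k: v.copy() for k, v in vols.items()} for wl, vols in self.volumes.items()},
            self.head_mask.copy(),
        )


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def clean_extracranial(
    mask: np.ndarray, min_component_voxels: int, connectivity: int = 26
) -> np.ndarray:
    """Remove small disconnected components (imaging artifacts) from a mask.

    Components smaller than ``min_component_voxels`` are dropped; the largest
    component is always kept regardless of its size.  ``connectivity`` selects
    6- (faces), 18- (faces+edges) or 26- (faces+edges+corners) neighbourhoods.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    labeled, ncomp = ndimage.label(mask, structure=_CONNECTIVITY_STRUCTS[connectivity])
    if ncomp == 0:
        return mask.copy()
    sizes = np.bincount(labeled.ravel())[1:]  # skip background
    keep = np.flatnonzero(sizes >= min_component_voxels) + 1
    largest = int(np.argmax(sizes)) + 1
    keep = set(keep.tolist()) | {largest}
    return np.isin(labeled, sorted(keep)) & mask


def build_phantom(
    probmaps: ProbabilityMaps,
    lib: SpectralLibrary,
    wavelengths: Sequence[float],
    head_mask_threshold: float = HEAD_MASK_THRESHOLD,
) -> OpticalPhantom:
    """Map tissue probabilities to voxel optical properties at each wavelength.

    Each voxel receives the probability-weighted average of its component
    tissue properties (air deficit included); the anisotropy g is
    scattering-weighted.  The head mask marks voxels whose total tissue
    probability (excluding the explicit 'air' class) exceeds the threshold;
    everything outside it is ambient (mua = mus = 0, n = 1).
    """
    wavelengths = [float(w) for w in wavelengths]
    for cls in probmaps.tissue_classes:
        for wl in wavelengths:
            try:
                lib.lookup(cls, wl)
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{cls}@{int(wl)} missing from spectral library") from exc

    shape = probmaps.grid.shape
    deficit = np.clip(1.0 - probmaps.total(), 0.0, 1.0)
    head_mask = probmaps.total(exclude=("air",)) > head_mask_threshold

    volumes: dict[float, dict[str, np.ndarray]] = {}
    for wl in wavelengths:
        mua = np.zeros(shape)
        mus = np.zeros(shape)
        n = np.full(shape, 0.0)
        g_num = np.zeros(shape)   # sum w*mus*g
        g_plain = np.zeros(shape)  # sum w*g  (fallback where nothing scatters)
        for cls, p in probmaps.maps.items():
            props = lib.lookup(cls, wl)
            mua += p * props.mua
            mus += p * props.mus
            n += p * props.n
            g_num += p * props.mus * props.g
            g_plain += p * props.g
        # air deficit: mua/mus/g contribute 0, n contributes 1
        n += deficit * AIR.n
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(mus > 0, g_num / np.where(mus > 0, mus, 1.0), g_plain)
        # ambient voxels are inert
        mua[~head_mask] = 0.0
        mus[~head_mask] = 0.0
        g[~head_mask] = 0.0
        n[~head_mask] = 1.0
        n = np.maximum(n, 1.0)
        volumes[wl] = {"mua": mua, "mus": mus, "g": g, "n": n}
    return OpticalPhantom(probmaps.grid, wavelengths, volumes, head_mask)


def _natural_hermite(s_nodes: np.ndarray, values: np.ndarray):
    """Natural cubic interpolant (zero second derivative at both ends).

    With only two nodes the natural conditions force the cubic to degenerate
    to the straight line, which CubicSpline handles via its 2-point special
    case.
    """
    if len(s_nodes) == 2:
        return lambda s: np.interp(s, s_nodes, values)
    return CubicSpline(s_nodes, values, bc_type="natural")


def annotate_and_interpolate(
    phantom: OpticalPhantom,
    ann: SparseAnnotation,
    lib: SpectralLibrary | None = None,
    method: str = "hermite",
) -> OpticalPhantom:
    """Apply sparse-annotation interpolation along 1-D profile lines.

    Along each profile polyline the four property fields between annotated
    nodes are replaced by the interpolant sampled at voxel centers.  Node
    voxels take node values exactly.  ``"hermite"`` uses the natural cubic
    interpolant (zero second derivative at the ends, C2 across interior
    nodes, i.e. continuous gradients at tissue boundaries); ``"linear"`` is
    piecewise linear.
    """
    if method not in ("hermite", "linear"):
        raise ValueError(f"unknown interpolation method {method!r}")
    out = phantom.copy()
    grid = phantom.grid

    for line in ann.profile_lines:
        if len(line) < 2:
            raise ValueError("profile line must reference at least 2 points")
        idx = [ann.points[i][0] for i in line]
        for ijk in idx:
            if not all(0 <= ijk[k] < grid.shape[k] for k in range(3)):
                raise ValueError(f"annotation voxel {ijk} outside grid {grid.shape}")
        # arc length of node voxel centers (mm)
        pts = np.array([grid.voxel_to_world(np.array(v, float)) for v in idx])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("profile line contains coincident consecutive points")
        s_nodes = np.concatenate([[0.0], np.cumsum(seg)])

        # rasterize the polyline; each touched voxel is sampled at the arc
        # length of its center projected onto the segment
        sample_vox: list[tuple[int, int, int]] = []
        sample_s: list[float] = []
        seen = set()
        for a in range(len(idx) - 1):
            p0 = np.array(idx[a], float)
            p1 = np.array(idx[a + 1], float)
            w0 = pts[a]
            seg_dir = (pts[a + 1] - pts[a]) / seg[a]
            nstep = max(8, int(np.ceil(np.linalg.norm(p1 - p0) * 4)))
            for t in np.linspace(0.0, 1.0, nstep):
                v = tuple(np.round(p0 + t * (p1 - p0)).astype(int))
                if v not in seen:
                    seen.add(v)
                    sample_vox.append(v)
                    vc = grid.voxel_to_world(np.array(v, float))
                    s_c = float(np.dot(vc - w0, seg_dir))
                    sample_s.append(s_nodes[a] + min(max(s_c, 0.0), seg[a]))

        for wl in out.wavelengths:
            vols = out.volumes[wl]
            node_props = []
            for i in line:
                _, spec = ann.points[i]
                if isinstance(spec, OpticalProperties):
                    node_props.append(spec)
                else:
                    if lib is None:
                        raise ValueError(
                            "annotation uses tissue-class names but no library given"
                        )
                    node_props.append(lib.lookup(spec, wl))
            for key in ("mua", "mus", "g", "n"):
                vals = np.array([getattr(p, key) for p in node_props])
                interp = (
                    _natural_hermite(s_nodes, vals)
                    if method == "hermite"
                    else (lambda s, sn=s_nodes, vv=vals: np.interp(s, sn, vv))
                )
                for v, s in zip(sample_vox, sample_s):
                    vols[key][v] = float(interp(s))
            # node voxels take node values exactly
            for ijk, p in zip(idx, node_props):
                for key in ("mua", "mus", "g", "n"):
                    vols[key][ijk] = getattr(p, key)
    return out


def region_volumes(atlas: LabelAtlas):
    """Per-region volume in mm^3 (voxel count x voxel volume), one row per label."""
    import pandas as pd

    vv = atlas.grid.voxel_volume
    counts = np.bincount(atlas.labels.ravel(), minlength=max(atlas.lookup, default=0) + 1)
    rows = [
        {"label": lab, "region": name, "volume_mm3": float(counts[lab] * vv) if lab < len(counts) else 0.0}
        for lab, name in sorted(atlas.lookup.items())
    ]
    return pd.DataFrame(rows).set_index("label")


def apply_rigid_transform(
    volume: np.ndarray,
    grid: VolumeGrid,
    transform: np.ndarray,
    interp: str = "trilinear",
    rigid_tol: float = 1e-6,
) -> np.ndarray:
    """Resample ``volume`` under a rigid world-space transform, on the same grid.

    ``transform`` maps input world coordinates to output world coordinates
    (rotation + translation).  Output voxel j takes the input value at
    ``A^-1 T^-1 A j`` where A is the grid affine; nearest-neighbour
    interpolation preserves the input's value set, trilinear is C0.
    """
    T = np.asarray(transform, dtype=float)
    if T.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=rigid_tol) or abs(
        np.linalg.det(R) - 1.0
    ) > rigid_tol or not np.allclose(T[3], [0, 0, 0, 1], atol=rigid_tol):
        raise ValueError("transform is not rigid (rotation + translation)")
    if interp not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation {interp!r}")
    A = grid.affine
    M = np.linalg.inv(A) @ np.linalg.inv(T) @ A
    order = 0 if interp == "nearest" else 1
    return ndimage.affine_transform(
        np.asarray(volume, dtype=float),
        M[:3, :3],
        offset=M[:3, 3],
        order=order,
        mode="constant",
        cval=0.0,
    )
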