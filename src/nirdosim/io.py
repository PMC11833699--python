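"""Readers and writers for the standard on-disk artifacts.

Volumes travel as NIfTI-1 (reoriented to RAS on load, affines preserved,
gzip supported); label lookups as two-column TSV; rigid transforms as 4x4
whitespace text matrices; sources and flow tables as JSON; dose tables as
TSV; simulation results as HDF5.  Writers record the tool version and a
config hash in headers/sidecars so a pipeline rerun is auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .phantom import LabelAtlas, OpticalPhantom, ProbabilityMaps, VolumeGrid
from .transport import SimConfig, SimResult, SourceSpec

__all__ = [
    "read_nifti",
    "write_nifti",
    "read_label_lookup",
    "write_label_lookup",
    "read_transform",
    "write_transform",
    "read_sources",
    "write_sources",
    "save_phantom",
    "load_phantom",
    "save_result",
    "load_result",
    "write_dose_table",
]

DOSE_TABLE_COLUMNS = [
    "kind",
    "name",
    "pct_of_absorbed",
    "pct_of_launched",
    "mean_fluence_mw_mm2",
    "volume_mm3",
    "empty",
]


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def read_nifti(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Load a NIfTI volume, reoriented to RAS, as (data, grid)."""
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(tuple(data.shape), tuple(float(z) for z in zooms), img.affine)
    return data, grid


def write_nifti(path: str | Path, data: np.ndarray, grid: VolumeGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms(grid.voxel_size)
    img.header["descrip"] = f"nirdosim {__version__}".encode()[:79]
    nib.save(img, str(path))


def read_label_lookup(path: str | Path) -> dict[int, str]:
    """Two-column TSV: label_id <tab> region_name."""
    lookup: dict[int, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'label<TAB>name', got {line!r}")
        try:
            lookup[int(parts[0])] = parts[1]
        except ValueError:
            raise ValueError(f"{path}:{lineno}: label id {parts[0]!r} is not an integer")
    return lookup


def write_label_lookup(path: str | Path, lookup: dict[int, str]) -> None:
    lines = [f"{lab}\t{name}" for lab, name in sorted(lookup.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_transform(path: str | Path) -> np.ndarray:
    mat = np.loadtxt(str(path))
    if mat.shape != (4, 4):
        raise ValueError(f"{path}: transform must be a 4x4 matrix, got {mat.shape}")
    return mat


def write_transform(path: str | Path, transform: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(transform), fmt="%.12g")


def write_sources(path: str | Path, sources: list[SourceSpec]) -> None:
    recs = [asdict(s) for s in sources]
    Path(path).write_text(json.dumps({"version": __version__, "sources": recs}, indent=1))


def read_sources(path: str | Path) -> list[SourceSpec]:
    raw = json.loads(Path(path).read_text())
    recs = raw["sources"] if isinstance(raw, dict) else raw
    out = []
    for i, rec in enumerate(recs):
        rec = {k: v for k, v in rec.items() if k != "version"}
        for key in ("center", "direction", "in_plane"):
            if rec.get(key) is not None:
                rec[key] = tuple(rec[key])
        try:
            out.append(SourceSpec(**rec))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: source record {i}: {exc}") from exc
    return out


def save_phantom(directory: str | Path, phantom: OpticalPhantom, name: str = "phantom") -> Path:
    """Persist a phantom as one NIfTI per parameter per wavelength + JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "wavelengths": phantom.wavelengths,
        "volumes": {},
        "head_mask": f"{name}_head_mask.nii.gz",
    }
    for wl in phantom.wavelengths:
        for key, arr in phantom.volumes[wl].items():
            fn = f"{name}_{key}_{int(wl)}nm.nii.gz"
            write_nifti(directory / fn, arr, phantom.grid)
            manifest["volumes"].setdefault(str(wl), {})[key] = fn
    write_nifti(directory / manifest["head_mask"], phantom.head_mask.astype(np.uint8), phantom.grid)
    manifest["config_hash"] = _config_hash(manifest)
    mpath = directory / f"{name}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_phantom(manifest_path: str | Path) -> OpticalPhantom:
    manifest_path = Path(manifest_path)
    man = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    volumes: dict[float, dict[str, np.ndarray]] = {}
    grid = None
    for wl_s, files in man["volumes"].items():
        wl = float(wl_s)
        volumes[wl] = {}
        for key, fn in files.items():
            data, g = read_nifti(base / fn)
            volumes[wl][key] = data
            grid = g
    mask, _ = read_nifti(base / man["head_mask"])
    return OpticalPhantom(grid, list(volumes), volumes, mask > 0.5)


def save_result(path: str | Path, result: SimResult) -> None:
    """Persist all SimResult tallies and metadata to HDF5 (exact round trip)."""
    with h5py.File(str(path), "w") as f:
        f.attrs["version"] = __version__
        f.attrs["config"] = json.dumps(asdict(result.config))
        f.attrs["config_hash"] = _config_hash(asdict(result.config))
        f.attrs["sources"] = json.dumps([asdict(s) for s in result.sources])
        f.attrs["absorbed_fraction"] = result.absorbed_fraction
        f.attrs["escaped_fraction"] = result.escaped_fraction
        f.attrs["capped_fraction"] = result.capped_fraction
        f.attrs["launched_weight"] = result.launched_weight
        f.attrs["shape"] = result.grid.shape
        f.attrs["voxel_size"] = result.grid.voxel_size
        f.attrs["affine"] = result.grid.affine
        f.create_dataset("fluence", data=result.fluence, compression="gzip")
        f.create_dataset("absorbed", data=result.absorbed, compression="gzip")
        if result.gated_fluence is not None:
            f.create_dataset("gated_fluence", data=result.gated_fluence, compression="gzip")
        if result.per_source_fluence is not None:
            for i, (pf, pa) in enumerate(
                zip(result.per_source_fluence, result.per_source_absorbed)
            ):
                f.create_dataset(f"per_source/fluence_{i}", data=pf, compression="gzip")
                f.create_dataset(f"per_source/absorbed_{i}", data=pa, compression="gzip")
            f.attrs["per_source_weight"] = result.per_source_weight


def load_result(path: str | Path) -> SimResult:
    with h5py.File(str(path), "r") as f:
        cfg = SimConfig(**json.loads(f.attrs["config"]))
        sources = []
        for rec in json.loads(f.attrs["sources"]):
            for key in ("center", "direction", "in_plane"):
                if rec.get(key) is not None:
                    rec[key] = tuple(rec[key])
            sources.append(SourceSpec(**rec))
        grid = VolumeGrid(
            tuple(int(s) for s in f.attrs["shape"]),
            tuple(float(v) for v in f.attrs["voxel_size"]),
            np.array(f.attrs["affine"]),
        )
        gated = f["gated_fluence"][...] if "gated_fluence" in f else None
        per_f = per_a = None
        per_w: list[float] = []
        if "per_source" in f:
            n = len([k for k in f["per_source"] if k.startswith("fluence_")])
            per_f = [f[f"per_source/fluence_{i}"][...] for i in range(n)]
            per_a = [f[f"per_source/absorbed_{i}"][...] for i in range(n)]
            per_w = list(f.attrs["per_source_weight"])
        return SimResult(
            grid=grid,
            fluence=f["fluence"][...],
            absorbed=f["absorbed"][...],
            absorbed_fraction=float(f.attrs["absorbed_fraction"]),
            escaped_fraction=float(f.attrs["escaped_fraction"]),
            capped_fraction=float(f.attrs["capped_fraction"]),
            launched_weight=float(f.attrs["launched_weight"]),
            config=cfg,
            sources=sources,
            gated_fluence=gated,
            per_source_fluence=per_f,
            per_source_absorbed=per_a,
            per_source_weight=per_w,
        )


def write_dose_table(path: str | Path, table: pd.DataFrame) -> None:
    """Dose table TSV with the documented fixed column order."""
    cols = [c for c in DOSE_TABLE_COLUMNS if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.10g")
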