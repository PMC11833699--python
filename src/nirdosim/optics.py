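"""Tissue optical properties: types, the spectral library, and derived quantities.

Light transport in tissue is governed by four voxelwise parameters: the
absorption coefficient ``mua`` (mm^-1), the scattering coefficient ``mus``
(mm^-1), the scattering anisotropy ``g`` (mean cosine of the single-scattering
deflection), and the refractive index ``n``.  Two derived quantities matter in
the diffusive regime: the reduced scattering coefficient ``mus' = (1 - g) mus``
and the effective attenuation coefficient
``mueff = sqrt(3 mua (mua + mus'))``, the asymptotic decay rate of diffuse
fluence far from sources.

A :class:`SpectralLibrary` maps ``(tissue_class, wavelength_nm)`` to an
:class:`OpticalProperties` set and is the single source of truth for tissue
optics.  A voxel that contains a mixture of tissues (probabilistic
segmentation) receives the probability-weighted average of the component
properties via :func:`mix_properties`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "OpticalProperties",
    "SpectralLibrary",
    "TissueWeights",
    "reduced_scattering",
    "effective_attenuation",
    "mix_properties",
    "default_library",
    "load_library",
]

#: Hard ceiling applied to g when sampling scattering angles; g -> 1 makes the
#: inverse-CDF numerically singular.
G_MAX_SAMPLING = 0.999

#: Minimum set of head tissue classes every full head phantom uses.
HEAD_CLASSES = ("gray_matter", "white_matter", "csf", "skull", "soft_tissue", "air")

#: Extended classes for ocular/orbital work.
OCULAR_CLASSES = (
    "cornea",
    "aqueous",
    "lens",
    "vitreous",
    "orbital_fat",
    "muscle",
    "sclera_retina",
    "eyelid_skin",
)

WEIGHT_SUM_TOL = 1e-6


@dataclass(frozen=True)
class OpticalProperties:
    """One tissue's optical parameter set at one wavelength.

    Parameters
    ----------
    mua : float
        Absorption coefficient, mm^-1 (>= 0).
    mus : float
        Scattering coefficient, mm^-1 (>= 0).
    g : float
        Scattering anisotropy, in [-1, 1].
    n : float
        Refractive index (>= 1).
    """

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.mus < 0:
            raise ValueError(f"mus must be >= 0, got {self.mus}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError(f"g must lie in [-1, 1], got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")


#: Properties of ambient / sinus air: no interaction, vacuum-like index.
AIR = OpticalProperties(mua=0.0, mus=0.0, g=0.0, n=1.0)


def reduced_scattering(props: OpticalProperties) -> float:
    """Reduced scattering coefficient mus' = (1 - g) mus, mm^-1."""
    return (1.0 - props.g) * props.mus


def effective_attenuation(props: OpticalProperties) -> float:
    """Effective attenuation coefficient mueff = sqrt(3 mua (mua + mus')), mm^-1.

    Zero iff ``mua`` is zero: a non-absorbing medium has no asymptotic
    attenuation of diffuse fluence, however strongly it scatters.
    """
    musp = reduced_scattering(props)
    return math.sqrt(3.0 * props.mua * (props.mua + musp))


class TissueWeights:
    """Per-voxel tissue composition: fractional weights over tissue classes.

    Weights lie in [0, 1] and sum to at most 1 (+ small tolerance); any
    deficit from 1 is interpreted as air, which keeps background and sinus
    voxels optically inert without renormalizing the segmentation.
    """

    __slots__ = ("weights",)

    def __init__(self, weights: Mapping[str, float]):
        for cls, w in weights.items():
            if not 0.0 <= w <= 1.0 + WEIGHT_SUM_TOL:
                raise ValueError(f"weight for {cls!r} outside [0, 1]: {w}")
        total = sum(weights.values())
        if total > 1.0 + WEIGHT_SUM_TOL:
            raise ValueError(f"tissue weights sum to {total} > 1")
        self.weights = dict(weights)

    @property
    def air_deficit(self) -> float:
        return max(0.0, 1.0 - sum(self.weights.values()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"TissueWeights({self.weights!r})"


class SpectralLibrary:
    """Mapping (tissue_class, wavelength nm) -> :class:`OpticalProperties`.

    Wavelength lookups at a stored node return the stored entry exactly;
    lookups between two nodes linearly interpolate every property.
    Extrapolation outside a tissue's node range is refused.
    """

    def __init__(self, entries: Mapping[str, Mapping[float, OpticalProperties]]):
        if not entries:
            raise ValueError("spectral library must contain at least one tissue class")
        self._entries: dict[str, dict[float, OpticalProperties]] = {}
        for cls, nodes in entries.items():
            if not nodes:
                raise ValueError(f"tissue class {cls!r} has no wavelength entries")
            clean: dict[float, OpticalProperties] = {}
            for wl, props in nodes.items():
                wl = float(wl)
                if wl <= 0:
                    raise ValueError(f"non-positive wavelength {wl} for {cls!r}")
                if not isinstance(props, OpticalProperties):
                    props = OpticalProperties(**props)
                clean[wl] = props
            self._entries[cls] = dict(sorted(clean.items()))
        air = self._entries.get("air")
        if air is not None:
            for wl, props in air.items():
                if props.mua != 0.0 or props.mus != 0.0 or props.n != 1.0:
                    raise ValueError(
                        f"'air' must have mua=0, mus=0, n=1; found {props} at {wl} nm"
                    )

    @property
    def tissue_classes(self) -> list[str]:
        return list(self._entries)

    def wavelengths(self, tissue: str) -> list[float]:
        return list(self._entries[tissue])

    def __contains__(self, tissue: str) -> bool:
        return tissue in self._entries

    def lookup(self, tissue: str, wavelength: float) -> OpticalProperties:
        """Properties of ``tissue`` at ``wavelength`` (nm).

        Exact node -> stored entry; between nodes -> per-property linear
        interpolation; outside the node range -> ``ValueError``.
        """
        try:
            nodes = self._entries[tissue]
        except KeyError:
            raise KeyError(f"unknown tissue class {tissue!r}") from None
        wavelength = float(wavelength)
        if wavelength in nodes:
            return nodes[wavelength]
        wls = list(nodes)
        if wavelength < wls[0] or wavelength > wls[-1]:
            raise ValueError(
                f"wavelength {wavelength} nm outside node range "
                f"[{wls[0]}, {wls[-1]}] for {tissue!r} (extrapolation refused)"
            )
        import bisect

        hi = bisect.bisect_left(wls, wavelength)
        lo = hi - 1
        w0, w1 = wls[lo], wls[hi]
        f = (wavelength - w0) / (w1 - w0)
        a, b = nodes[w0], nodes[w1]
        return OpticalProperties(
            mua=a.mua + f * (b.mua - a.mua),
            mus=a.mus + f * (b.mus - a.mus),
            g=a.g + f * (b.g - a.g),
            n=a.n + f * (b.n - a.n),
        )

    def to_dict(self) -> dict:
        return {
            cls: {
                str(int(wl) if wl == int(wl) else wl): {
                    "mua": p.mua, "mus": p.mus, "g": p.g, "n": p.n
                }
                for wl, p in nodes.items()
            }
            for cls, nodes in self._entries.items()
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def _validate_schema(raw: dict, source: str) -> dict[str, dict[float, OpticalProperties]]:
    entries: dict[str, dict[float, OpticalProperties]] = {}
    for cls, nodes in raw.items():
        if cls.startswith("_"):  # comment keys
            continue
        if not isinstance(nodes, dict):
            raise ValueError(f"{source}: entry for {cls!r} is not a mapping")
        entries[cls] = {}
        for wl, props in nodes.items():
            try:
                wlf = float(wl)
            except (TypeError, ValueError):
                raise ValueError(f"{source}: bad wavelength key {wl!r} in {cls!r}")
            if not isinstance(props, dict):
                raise ValueError(f"{source}: {cls!r}@{wl}: not a mapping")
            missing = {"mua", "mus", "g", "n"} - set(props)
            if missing:
                raise ValueError(
                    f"{source}: {cls!r}@{wl}: missing fields {sorted(missing)}"
                )
            entries[cls][wlf] = OpticalProperties(
                mua=float(props["mua"]),
                mus=float(props["mus"]),
                g=float(props["g"]),
                n=float(props["n"]),
            )
    return entries


def load_library(path: str | Path) -> SpectralLibrary:
    """Read a spectral library from a JSON or YAML file.

    Schema: ``{tissue: {wavelength_nm: {mua, mus, g, n}}}`` with mua/mus in
    mm^-1.  Validation errors name the offending file and field.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping of tissue classes")
    return SpectralLibrary(_validate_schema(raw, str(path)))


def default_library() -> SpectralLibrary:
    """The library of documented default properties shipped with the package.

    Values are literature-plausible stand-ins at 670/810/850/980/1070 nm for
    the head and ocular tissue classes; they are configurable defaults, not
    measurements.
    """
    text = resources.files("nirdosim.data").joinpath(
        "default_tissue_optics.json"
    ).read_text()
    return SpectralLibrary(_validate_schema(json.loads(text), "default_tissue_optics"))


def mix_properties(
    weights: TissueWeights | Mapping[str, float],
    lib: SpectralLibrary,
    wavelength: float,
) -> OpticalProperties:
    """Probability-weighted voxel average of component tissue properties.

    mua, mus and n are weight-averaged arithmetically (any deficit from a unit
    weight sum contributes air: mua=mus=0, n=1).  The anisotropy g is averaged
    with weights ``w_i * mus_i`` — g is only meaningful where scattering
    occurs — falling back to the plain weight average when no component
    scatters.  Every output parameter lies inside the closed interval spanned
    by the component values.
    """
    if not isinstance(weights, TissueWeights):
        weights = TissueWeights(weights)
    if not weights.weights:
        raise ValueError("empty tissue weights")
    items = [(cls, w, lib.lookup(cls, wavelength)) for cls, w in weights.weights.items()]
    deficit = weights.air_deficit
    if deficit > 0:
        items.append(("air", deficit, AIR))
    total_w = sum(w for _, w, _ in items)
    mua = sum(w * p.mua for _, w, p in items) / total_w
    mus = sum(w * p.mus for _, w, p in items) / total_w
    n = sum(w * p.n for _, w, p in items) / total_w
    gw = sum(w * p.mus for _, w, p in items)
    if gw > 0:
        g = sum(w * p.mus * p.g for _, w, p in items) / gw
    else:
        g = sum(w * p.g for _, w, p in items) / total_w
    # guard convexity against denormal-weight rounding
    g_vals = [p.g for _, w, p in items if w > 0]
    if g_vals:
        g = min(max(g, min(g_vals)), max(g_vals))
    return OpticalProperties(mua=mua, mus=mus, g=g, n=n)
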