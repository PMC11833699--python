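"""Voxel Monte Carlo photon transport with time-resolved fluence recording.

Photon packets are launched from LED-like surface sources, propagated through
the voxel medium by 3-D DDA traversal, and tallied with a track-length fluence
estimator.  Between scattering events a packet's weight decays continuously as
``exp(-mua * l)`` along its path, so the absorbed energy in a voxel equals the
fluence tally times ``mua`` times the voxel volume *exactly* and the global
balance launched = absorbed + escaped (+ capped) holds to floating-point
rounding when Russian roulette is off.  Scattering directions are drawn from
the Henyey-Greenstein phase function; refractive-index mismatches at voxel
faces are handled with unpolarized Fresnel reflection/refraction (including
entry from and escape to the ambient medium).  Packet time advances by
``sum(l_i * n_i) / c`` and indexes optional time gates for tPSF work.

Units: mm, ns, nm, mW.  Fluence tallies are mm^-2 per launched unit weight;
:func:`scale_to_physical` converts to mW/mm^2 using the total source power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .optics import G_MAX_SAMPLING
from .phantom import OpticalPhantom, VolumeGrid

__all__ = [
    "SourceSpec",
    "SimConfig",
    "SimResult",
    "place_source_on_scalp",
    "sample_launch",
    "sample_hg",
    "fresnel",
    "run_mc",
    "scale_to_physical",
    "C_MM_PER_NS",
]

C_MM_PER_NS = 299.792458  # speed of light in vacuum
_NUDGE_MM = 1e-7  # tie-break nudge across voxel faces


@dataclass(frozen=True)
class SourceSpec:
    """An emitting LED surface: disk or rectangle, collimated by default.

    ``direction`` is the emission direction (unit vector pointing into the
    head).  ``power_density`` is in mW/cm^2; total power (mW) is power
    density times emitting area.
    """

    kind: str  # "disk" | "rect" | "point" (isotropic, for engine validation)
    center: tuple[float, float, float]
    direction: tuple[float, float, float]
    wavelength: float
    power_density: float = 20.0  # mW/cm^2, the clinical device default
    radius: float | None = None  # disk, mm
    width: float | None = None  # rect, mm
    height: float | None = None  # rect, mm
    in_plane: tuple[float, float, float] | None = None  # rect orientation

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError(f"direction must be a unit vector, |d|={np.linalg.norm(d)}")
        if self.kind == "disk":
            if self.radius is None or self.radius < 0:
                raise ValueError("disk source requires radius >= 0")
        elif self.kind == "rect":
            if not self.width or not self.height or self.width <= 0 or self.height <= 0:
                raise ValueError("rect source requires positive width and height")
        elif self.kind == "point":
            pass  # isotropic point emitter; geometry-free
        else:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.power_density < 0:
            raise ValueError("power density must be >= 0")

    @property
    def area_mm2(self) -> float:
        if self.kind == "disk":
            return math.pi * self.radius**2
        if self.kind == "point":
            return 1.0  # nominal 1 mm^2 so power_density still defines a power
        return self.width * self.height

    @property
    def power_mw(self) -> float:
        """Total emitted power: power_density [mW/cm^2] x area [cm^2]."""
        return self.power_density * self.area_mm2 / 100.0

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2, direction) frame of the emitting plane."""
        u = np.asarray(self.direction, dtype=float)
        if self.in_plane is not None:
            e1 = np.asarray(self.in_plane, dtype=float)
            e1 = e1 - np.dot(e1, u) * u
            if np.linalg.norm(e1) < 1e-12:
                raise ValueError("in_plane vector parallel to emission direction")
        else:
            trial = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(trial, u)) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            e1 = trial - np.dot(trial, u) * u
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        return e1, e2, u


@dataclass(frozen=True)
class SimConfig:
    """Monte Carlo run configuration.

    Roulette defaults (threshold 1e-4, survival 0.1) follow the MCML
    convention.  ``n_gates = 0`` records steady state only; otherwise
    ``n_gates`` gates of ``time_gate_ns`` each are recorded, with the last
    gate acting as a catch-all so the gate sum always equals steady state.
    """

    n_photons: int = 100_000
    seed: int = 0
    time_gate_ns: float = 0.3
    n_gates: int = 0
    weight_threshold: float = 1e-4
    roulette_survival: float = 0.1
    roulette: bool = True
    ambient_n: float = 1.0
    max_path_mm: float = 20_000.0
    per_source: bool = False
    cosine_lobe: bool = False

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ValueError("roulette_survival must lie in (0, 1)")
        if self.time_gate_ns <= 0:
            raise ValueError("time_gate_ns must be > 0")
        if self.ambient_n < 1.0:
            raise ValueError("ambient_n must be >= 1")


@dataclass
class SimResult:
    """Tallies of one Monte Carlo run, normalized per launched unit weight."""

    grid: VolumeGrid
    fluence: np.ndarray  # mm^-2 per launched photon
    absorbed: np.ndarray  # fraction of launched energy per voxel
    absorbed_fraction: float
    escaped_fraction: float
    capped_fraction: float
    launched_weight: float
    config: SimConfig
    sources: list[SourceSpec]
    gated_fluence: np.ndarray | None = None  # (n_gates, *grid.shape)
    per_source_fluence: list[np.ndarray] | None = None
    per_source_absorbed: list[np.ndarray] | None = None
    per_source_weight: list[float] = field(default_factory=list)


def fresnel(n1: float, n2: float, cos_incident: float) -> tuple[float, float, bool]:
    """Unpolarized Fresnel reflectance at a planar index step.

    Returns ``(R, cos_transmit, tir)``.  ``R`` is the average of the s- and
    p-polarized reflectances; total internal reflection gives ``R = 1`` and
    ``tir = True`` (``cos_transmit`` is then 0).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("refractive indices must be >= 1")
    if not 0.0 < cos_incident <= 1.0:
        raise ValueError("cos_incident must lie in (0, 1]")
    if n1 == n2:
        return 0.0, cos_incident, False
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_incident**2)
    if sin_t2 >= 1.0:
        return 1.0, 0.0, True
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_incident - n2 * cos_t) / (n1 * cos_incident + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_incident) / (n1 * cos_t + n2 * cos_incident)
    return 0.5 * (rs * rs + rp * rp), cos_t, False


def sample_hg(g: float, rng: np.random.Generator, size: int | None = None):
    """Sample the Henyey-Greenstein deflection cosine; E[cos theta] = g.

    g is clamped to [-0.999, 0.999]; g = 0 gives the isotropic uniform
    cosine.
    """
    g = float(np.clip(g, -G_MAX_SAMPLING, G_MAX_SAMPLING))
    xi = rng.random(size) if size is not None else rng.random()
    if abs(g) < 1e-9:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    return np.clip(ct, -1.0, 1.0)


def sample_launch(
    source: SourceSpec, rng: np.random.Generator, size: int = 1, cosine_lobe: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Draw launch positions uniform over the emitting surface.

    Returns ``(positions (size,3), directions (size,3))``.  Emission is
    collimated along ``source.direction`` unless ``cosine_lobe`` draws from a
    cosine-weighted hemisphere about it.
    """
    if source.kind == "point":
        pos = np.tile(np.asarray(source.center, dtype=float), (size, 1))
        ct = 2.0 * rng.random(size) - 1.0  # isotropic emission
        st = np.sqrt(1.0 - ct**2)
        ph = 2.0 * math.pi * rng.random(size)
        dirs = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=1)
        return pos, dirs
    e1, e2, u = source.frame()
    c = np.asarray(source.center, dtype=float)
    if source.kind == "disk":
        r = source.radius * np.sqrt(rng.random(size))
        th = 2.0 * math.pi * rng.random(size)
        a = r * np.cos(th)
        b = r * np.sin(th)
    else:
        a = (rng.random(size) - 0.5) * source.width
        b = (rng.random(size) - 0.5) * source.height
    pos = c[None, :] + a[:, None] * e1[None, :] + b[:, None] * e2[None, :]
    if not cosine_lobe:
        dirs = np.tile(u, (size, 1))
    else:
        ct = np.sqrt(rng.random(size))  # cosine-weighted polar angle
        st = np.sqrt(1.0 - ct**2)
        ph = 2.0 * math.pi * rng.random(size)
        dirs = (
            st[:, None] * np.cos(ph)[:, None] * e1[None, :]
            + st[:, None] * np.sin(ph)[:, None] * e2[None, :]
            + ct[:, None] * u[None, :]
        )
    return pos, dirs


def place_source_on_scalp(
    head_mask: np.ndarray,
    grid: VolumeGrid,
    phi_deg: float,
    theta_deg: float,
    standoff: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Put a source on the head surface along the (phi, theta) ray from the origin.

    theta is the polar angle from +Z, phi the azimuth from +X, in the RAS
    world frame whose origin is the anterior commissure.  The source center is
    the *outermost* head-surface intersection of the ray pushed outward by
    ``standoff`` mm; the emission direction points back toward the origin.
    """
    head_mask = np.asarray(head_mask, dtype=bool)
    if not head_mask.any():
        raise ValueError("head mask is empty")
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    d = np.array(
        [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
    )
    # march outward and record the farthest masked voxel
    t_max = float(np.linalg.norm(np.array(grid.shape) * np.array(grid.voxel_size))) + 2.0
    step = min(grid.voxel_size) / 4.0
    ts = np.arange(0.0, t_max, step)
    pts = ts[:, None] * d[None, :]
    vox = np.round(grid.world_to_voxel(pts)).astype(int)
    inside = np.all((vox >= 0) & (vox < np.array(grid.shape)), axis=1)
    hit = np.zeros(len(ts), dtype=bool)
    hit[inside] = head_mask[tuple(vox[inside].T)]
    if not hit.any():
        raise ValueError(f"ray (phi={phi_deg}, theta={theta_deg}) misses head")
    t_surf = ts[np.flatnonzero(hit)[-1]]
    center = (t_surf + standoff) * d
    return center, -d


@njit(inline="always")
def _splitmix64(state: np.uint64) -> tuple[np.uint64, np.uint64]:
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return state, z ^ (z >> np.uint64(31))


@njit(inline="always")
def _xs_next(s0: np.uint64, s1: np.uint64) -> tuple[np.uint64, np.uint64, float]:
    # xorshift128+: fast, passes BigCrush minus linearity tests — ample for MC
    x = s0
    y = s1
    s0n = y
    x ^= x << np.uint64(23)
    s1n = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
    u = np.float64((s1n + y) >> np.uint64(11)) * 1.1102230246251565e-16  # 2^-53
    if u >= 1.0:
        u = 0.9999999999999999
    return s0n, s1n, u


@njit(cache=True, fastmath=True)
def _mc_kernel(
    props,  # (nx, ny, nz, 4) float32: mua, mus, g, n interleaved for locality
    vx, vy, vz, ox, oy, oz,
    px, py, pz, dx, dy, dz, w0,
    ambient_n, wth, roulette_on, p_survive, max_path,
    gate_ns, n_gates,
    fluence, gates,
    seed,
):
    """Propagate one batch of photon packets; returns (absorbed, escaped, capped).

    Tallies are *track-length integrals of weight* (weight x mm); the caller
    divides by voxel volume and launched weight.  Positions are world mm on an
    axis-aligned grid with voxel (i,j,k) spanning [ox + i*vx, ox + (i+1)*vx) x
    ...; the current voxel index is carried incrementally so a position may
    sit exactly on a face without ambiguity.  Randomness comes from an inline
    xorshift128+ stream seeded via splitmix64; the run is bit-reproducible for
    a fixed seed.
    """
    nx, ny, nz = props.shape[0], props.shape[1], props.shape[2]
    c = 299.792458
    absorbed = 0.0
    escaped = 0.0
    capped = 0.0
    xmax = ox + nx * vx
    ymax = oy + ny * vy
    zmax = oz + nz * vz
    inv_vx = 1.0 / vx
    inv_vy = 1.0 / vy
    inv_vz = 1.0 / vz

    st = np.uint64(seed)
    st, s0 = _splitmix64(st)
    st, s1 = _splitmix64(st)
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(1)

    for ph in range(px.size):
        x = px[ph]; y = py[ph]; z = pz[ph]
        ux = dx[ph]; uy = dy[ph]; uz = dz[ph]
        w = w0[ph]
        t = 0.0
        path = 0.0

        # advance to the grid bounding box if launched outside it
        if x < ox or x >= xmax or y < oy or y >= ymax or z < oz or z >= zmax:
            t_enter = 0.0
            t_exit = 1e30
            ok = True
            for ax in range(3):
                if ax == 0:
                    p0 = x; u0 = ux; lo = ox; hi = xmax
                elif ax == 1:
                    p0 = y; u0 = uy; lo = oy; hi = ymax
                else:
                    p0 = z; u0 = uz; lo = oz; hi = zmax
                if abs(u0) < 1e-300:
                    if p0 < lo or p0 >= hi:
                        ok = False
                        break
                else:
                    t1 = (lo - p0) / u0
                    t2 = (hi - p0) / u0
                    if t1 > t2:
                        t1, t2 = t2, t1
                    if t1 > t_enter:
                        t_enter = t1
                    if t2 < t_exit:
                        t_exit = t2
            if (not ok) or t_enter > t_exit:
                escaped += w
                continue
            s0v = t_enter + 1e-7
            x += ux * s0v; y += uy * s0v; z += uz * s0v
            t += s0v * ambient_n / c
            path += s0v

        i = int(math.floor((x - ox) * inv_vx))
        j = int(math.floor((y - oy) * inv_vy))
        k = int(math.floor((z - oz) * inv_vz))
        # per-direction reciprocals, refreshed on every direction change
        inv_ux = 1.0 / ux if ux != 0.0 else 1e30
        inv_uy = 1.0 / uy if uy != 0.0 else 1e30
        inv_uz = 1.0 / uz if uz != 0.0 else 1e30

        s0, s1, xi = _xs_next(s0, s1)
        tau = -math.log(xi)
        alive = True
        while alive:
            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                escaped += w
                break
            a_v = np.float64(props[i, j, k, 0])
            s_v = np.float64(props[i, j, k, 1])
            n_v = np.float64(props[i, j, k, 3])

            # distance to the next voxel face along the direction of travel
            if ux > 0.0:
                db = (ox + (i + 1) * vx - x) * inv_ux
                axis = 0
            elif ux < 0.0:
                db = (ox + i * vx - x) * inv_ux
                axis = 0
            else:
                db = 1e30
                axis = 0
            if uy > 0.0:
                d0 = (oy + (j + 1) * vy - y) * inv_uy
                if d0 < db:
                    db = d0; axis = 1
            elif uy < 0.0:
                d0 = (oy + j * vy - y) * inv_uy
                if d0 < db:
                    db = d0; axis = 1
            if uz > 0.0:
                d0 = (oz + (k + 1) * vz - z) * inv_uz
                if d0 < db:
                    db = d0; axis = 2
            elif uz < 0.0:
                d0 = (oz + k * vz - z) * inv_uz
                if d0 < db:
                    db = d0; axis = 2
            if db < 0.0:
                db = 0.0

            if s_v > 0.0:
                s_scat = tau / s_v
            else:
                s_scat = 1e30
            at_face = db <= s_scat
            s = db if at_face else s_scat

            hit_cap = False
            if path + s > max_path:
                s = max_path - path
                if s < 0.0:
                    s = 0.0
                hit_cap = True

            # continuous absorption along the segment; small arguments take a
            # 4th-order series (error < 3e-14) to skip the exp call
            if a_v > 0.0:
                xarg = a_v * s
                if xarg < 0.005:
                    att = 1.0 - xarg * (1.0 - xarg * 0.5 * (1.0 - xarg / 3.0 * (1.0 - xarg * 0.25)))
                else:
                    att = math.exp(-xarg)
                dw = w * (1.0 - att)
                fl = dw / a_v
            else:
                dw = 0.0
                fl = w * s
            fluence[i, j, k] += fl
            if n_gates > 0:
                gi = int(t / gate_ns)
                if gi >= n_gates:
                    gi = n_gates - 1
                gates[gi, i, j, k] += fl
            absorbed += dw
            w -= dw
            x += ux * s; y += uy * s; z += uz * s
            t += s * n_v / c
            path += s
            if s_v > 0.0:
                tau -= s_v * s

            if hit_cap:
                capped += w
                break

            if at_face:
                # neighbour index and its refractive index (ambient outside)
                i2 = i; j2 = j; k2 = k
                if axis == 0:
                    i2 += 1 if ux > 0.0 else -1
                elif axis == 1:
                    j2 += 1 if uy > 0.0 else -1
                else:
                    k2 += 1 if uz > 0.0 else -1
                if 0 <= i2 < nx and 0 <= j2 < ny and 0 <= k2 < nz:
                    n2 = np.float64(props[i2, j2, k2, 3])
                else:
                    n2 = ambient_n
                if n2 != n_v:
                    if axis == 0:
                        ci = abs(ux)
                    elif axis == 1:
                        ci = abs(uy)
                    else:
                        ci = abs(uz)
                    if ci > 1.0:
                        ci = 1.0
                    eta = n_v / n2
                    sin_t2 = eta * eta * (1.0 - ci * ci)
                    if sin_t2 >= 1.0:
                        refl = 1.0
                        ct = 0.0
                    else:
                        ct = math.sqrt(1.0 - sin_t2)
                        rs = (n_v * ci - n2 * ct) / (n_v * ci + n2 * ct)
                        rp = (n_v * ct - n2 * ci) / (n_v * ct + n2 * ci)
                        refl = 0.5 * (rs * rs + rp * rp)
                    s0, s1, xi = _xs_next(s0, s1)
                    if xi < refl:
                        # reflect: flip the crossed component, stay in voxel
                        if axis == 0:
                            ux = -ux
                            inv_ux = -inv_ux
                        elif axis == 1:
                            uy = -uy
                            inv_uy = -inv_uy
                        else:
                            uz = -uz
                            inv_uz = -inv_uz
                        continue
                    # refract: scale tangential components by eta
                    if axis == 0:
                        sgn = 1.0 if ux > 0.0 else -1.0
                        ux = sgn * ct
                        uy *= eta
                        uz *= eta
                    elif axis == 1:
                        sgn = 1.0 if uy > 0.0 else -1.0
                        uy = sgn * ct
                        ux *= eta
                        uz *= eta
                    else:
                        sgn = 1.0 if uz > 0.0 else -1.0
                        uz = sgn * ct
                        ux *= eta
                        uy *= eta
                    inv = 1.0 / math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux *= inv; uy *= inv; uz *= inv
                    inv_ux = 1.0 / ux if ux != 0.0 else 1e30
                    inv_uy = 1.0 / uy if uy != 0.0 else 1e30
                    inv_uz = 1.0 / uz if uz != 0.0 else 1e30
                # move into the neighbour voxel
                i = i2; j = j2; k = k2
                continue

            # scattering event: Henyey-Greenstein deflection about (ux,uy,uz)
            g_v = np.float64(props[i, j, k, 2])
            if g_v > 0.999:
                g_v = 0.999
            elif g_v < -0.999:
                g_v = -0.999
            s0, s1, xi = _xs_next(s0, s1)
            if -1e-9 < g_v < 1e-9:
                ctt = 2.0 * xi - 1.0
            else:
                tmp = (1.0 - g_v * g_v) / (1.0 - g_v + 2.0 * g_v * xi)
                ctt = (1.0 + g_v * g_v - tmp * tmp) / (2.0 * g_v)
                if ctt > 1.0:
                    ctt = 1.0
                elif ctt < -1.0:
                    ctt = -1.0
            stt = math.sqrt(1.0 - ctt * ctt)
            # uniform azimuth without trig: rejection-sample the unit disk and
            # use the double-angle identities on (ax, ay)
            while True:
                s0, s1, xi = _xs_next(s0, s1)
                ax2 = 2.0 * xi - 1.0
                s0, s1, xi = _xs_next(s0, s1)
                ay2 = 2.0 * xi - 1.0
                r2 = ax2 * ax2 + ay2 * ay2
                if 0.0 < r2 < 1.0:
                    break
            cp = (ax2 * ax2 - ay2 * ay2) / r2
            sp = 2.0 * ax2 * ay2 / r2
            if abs(uz) > 0.99999:
                ux = stt * cp
                uy = stt * sp
                uz = ctt if uz > 0.0 else -ctt
            else:
                den = math.sqrt(1.0 - uz * uz)
                ux_n = stt * (ux * uz * cp - uy * sp) / den + ux * ctt
                uy_n = stt * (uy * uz * cp + ux * sp) / den + uy * ctt
                uz_n = -den * stt * cp + uz * ctt
                inv = 1.0 / math.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n * inv; uy = uy_n * inv; uz = uz_n * inv
            inv_ux = 1.0 / ux if ux != 0.0 else 1e30
            inv_uy = 1.0 / uy if uy != 0.0 else 1e30
            inv_uz = 1.0 / uz if uz != 0.0 else 1e30
            s0, s1, xi = _xs_next(s0, s1)
            tau = -math.log(xi)

            if w < wth:
                if roulette_on:
                    s0, s1, xi = _xs_next(s0, s1)
                    if xi < p_survive:
                        w /= p_survive
                    else:
                        alive = False
                # roulette off: keep going until escape or max_path

    return absorbed, escaped, capped


def _check_axis_aligned(grid: VolumeGrid) -> tuple[np.ndarray, np.ndarray]:
    A = grid.affine
    if not np.allclose(A[:3, :3], np.diag(np.diag(A[:3, :3]))) or np.any(
        np.diag(A[:3, :3]) <= 0
    ):
        raise ValueError("transport requires an axis-aligned RAS grid (diagonal affine)")
    voxel = np.diag(A[:3, :3]).copy()
    origin_corner = A[:3, 3] - voxel / 2.0  # lower corner of voxel (0,0,0)
    return voxel, origin_corner


def run_mc(
    phantom: OpticalPhantom, sources: Sequence[SourceSpec], config: SimConfig
) -> SimResult:
    """Run the Monte Carlo transport and return normalized tallies.

    Photons are allocated across sources in proportion to source power, with
    per-photon launch weights chosen so that the summed launch weight is
    exactly ``n_photons`` and each source's share of launched energy equals
    its share of total power.  Deterministic (bit-identical tallies) for a
    fixed (config, sources, phantom) in single-threaded execution.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("at least one source is required")
    for s in sources:
        if float(s.wavelength) not in phantom.volumes:
            raise ValueError(
                f"source wavelength {s.wavelength} nm not present in phantom "
                f"(has {phantom.wavelengths})"
            )
    voxel, corner = _check_axis_aligned(phantom.grid)
    vv = phantom.grid.voxel_volume

    powers = np.array([s.power_mw for s in sources], dtype=float)
    if powers.sum() <= 0:
        # all-zero power: equal photon split, equal weights
        powers = np.ones(len(sources))
    frac = powers / powers.sum()
    n_alloc = np.maximum(1, np.round(frac * config.n_photons).astype(int))

    shape = phantom.grid.shape
    total_fluence = np.zeros(shape)
    total_absorbed_arr = np.zeros(shape)
    gates = (
        np.zeros((config.n_gates,) + shape) if config.n_gates > 0 else None
    )
    per_fluence: list[np.ndarray] = []
    per_absorbed: list[np.ndarray] = []
    per_weight: list[float] = []
    absorbed_w = 0.0
    escaped_w = 0.0
    capped_w = 0.0
    launched_w = 0.0

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(sources))

    packed_cache: dict[float, np.ndarray] = {}

    def packed(wl: float) -> np.ndarray:
        wl = float(wl)
        if wl not in packed_cache:
            vols = phantom.properties(wl)
            arr = np.empty(shape + (4,), dtype=np.float32)
            arr[..., 0] = vols["mua"]
            arr[..., 1] = vols["mus"]
            arr[..., 2] = vols["g"]
            arr[..., 3] = vols["n"]
            packed_cache[wl] = np.ascontiguousarray(arr)
        return packed_cache[wl]

    for si, (src, n_i) in enumerate(zip(sources, n_alloc)):
        rng = np.random.default_rng(children[si])
        kernel_seed = int(children[si].generate_state(2)[1] % (2**31 - 1))
        pos, dirs = sample_launch(src, rng, size=int(n_i), cosine_lobe=config.cosine_lobe)
        w0 = np.full(int(n_i), frac[si] * config.n_photons / n_i)
        vols = phantom.properties(src.wavelength)
        tally = np.zeros(shape)
        gate_tally = (
            gates if gates is not None else np.zeros((0, 1, 1, 1))
        )
        # per-source gating shares the global gate array (gates sum over sources)
        a, e, c = _mc_kernel(
            packed(src.wavelength),
            voxel[0], voxel[1], voxel[2], corner[0], corner[1], corner[2],
            np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
            np.ascontiguousarray(pos[:, 2]),
            np.ascontiguousarray(dirs[:, 0]), np.ascontiguousarray(dirs[:, 1]),
            np.ascontiguousarray(dirs[:, 2]),
            w0,
            config.ambient_n, config.weight_threshold,
            config.roulette, config.roulette_survival, config.max_path_mm,
            config.time_gate_ns, config.n_gates,
            tally, gate_tally,
            kernel_seed,
        )
        absorbed_w += a
        escaped_w += e
        capped_w += c
        launched_w += float(w0.sum())
        total_fluence += tally
        # multiply by the same float32-rounded mua the kernel used so the
        # voxel-summed absorbed energy matches the kernel's scalar tally
        mua_kernel = vols["mua"].astype(np.float32).astype(np.float64)
        absorbed_arr = tally * mua_kernel  # weight*mm * mm^-1 = absorbed weight
        total_absorbed_arr += absorbed_arr
        if config.per_source:
            per_fluence.append(tally / (vv * float(w0.sum())) * frac[si])
            per_absorbed.append(absorbed_arr / float(w0.sum()) * frac[si])
            per_weight.append(float(w0.sum()))

    # normalize: fluence per launched unit weight, absorbed as energy fraction
    norm_f = total_fluence / (vv * launched_w)
    norm_a = total_absorbed_arr / launched_w
    gated = gates / (vv * launched_w) if gates is not None else None

    return SimResult(
        grid=phantom.grid,
        fluence=norm_f,
        absorbed=norm_a,
        absorbed_fraction=absorbed_w / launched_w,
        escaped_fraction=escaped_w / launched_w,
        capped_fraction=capped_w / launched_w,
        launched_weight=launched_w,
        config=config,
        sources=sources,
        gated_fluence=gated,
        per_source_fluence=per_fluence if config.per_source else None,
        per_source_absorbed=per_absorbed if config.per_source else None,
        per_source_weight=per_weight,
    )


def scale_to_physical(
    result: SimResult, sources: Sequence[SourceSpec] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convert per-photon tallies to physical units.

    Returns ``(fluence_rate mW/mm^2, absorbed_power mW)`` volumes obtained by
    multiplying the normalized tallies by the total source power
    (sum of power_density x area over sources).  Linear in power.
    """
    sources = list(sources) if sources is not None else result.sources
    if not sources:
        raise ValueError("no sources given for physical scaling")
    total_power = sum(s.power_mw for s in sources)
    return result.fluence * total_power, result.absorbed * total_power
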