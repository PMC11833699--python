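"""ANSI Z136.1 maximum permissible exposure (MPE) in the 0.700-1.400 um band.

Only the long-exposure continuous-wave branches relevant to LED
photobiomodulation are implemented: the skin MPE for exposures longer than
10 s and the extended-source ocular MPE for exposures at least T2.  The
standard expresses limits in W/cm^2 (skin) or mW/cm^2 (ocular); this module
reports them in mW/mm^2 (1 W/cm^2 = 10 mW/mm^2, 1 mW/cm^2 = 0.01 mW/mm^2).

Wavelength-dependent correction factors (lambda in micrometers):
  CA = 10^(2 (lambda - 0.700)) for 0.700 <= lambda < 1.050, else 5.0 up to 1.400
  CC = 1.0 for 1.050 <= lambda <= 1.150 (the only CC branch used here)
  CE = min(alpha, 100 mrad) / 1.5 mrad   (extended sources)
  T2 = 10 * 10^((min(alpha, 100) - 1.5) / 98.5) s  (100 s at alpha >= 100)
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ExposureSpec",
    "MPEResult",
    "evaluate_exposure",
    "mpe_skin",
    "mpe_ocular_extended",
    "safety_margin",
]

ALPHA_MAX_MRAD = 100.0
ALPHA_MIN_MRAD = 1.5


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure scenario: wavelength, duration, and angular subtense.

    ``alpha_mrad`` is only meaningful for ocular evaluation (extended sources
    subtend more than 100 mrad at the eye and earn the CE relaxation).
    """

    wavelength_nm: float
    duration_s: float = 100.0
    alpha_mrad: float = ALPHA_MAX_MRAD

    def __post_init__(self) -> None:
        if not 700.0 <= self.wavelength_nm <= 1400.0:
            raise ValueError("wavelength outside the supported 700-1400 nm band")
        if self.duration_s <= 0:
            raise ValueError("duration must be > 0")
        if self.alpha_mrad <= 0:
            raise ValueError("angular subtense must be > 0")


@dataclass(frozen=True)
class MPEResult:
    """A computed exposure limit and the measured-to-limit margin."""

    limit_mw_mm2: float
    basis: str  # "skin" | "ocular_extended"
    margin: float | None = None
    passed: bool | None = None
    parameters: dict | None = None


def _check_band(wavelength_nm: float) -> float:
    if not 700.0 <= wavelength_nm <= 1400.0:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside the supported 700-1400 nm band"
        )
    return wavelength_nm / 1000.0  # micrometers


def _ca(lam_um: float) -> float:
    if lam_um < 1.050:
        return 10.0 ** (2.0 * (lam_um - 0.700))
    return 5.0


def mpe_skin(wavelength_nm: float, duration_s: float = 100.0) -> float:
    """Long-exposure skin MPE, mW/mm^2.

    limit = 0.2 * CA W/cm^2 for exposures longer than 10 s; shorter-exposure
    branches are out of scope and raise.
    """
    lam = _check_band(wavelength_nm)
    if duration_s <= 10.0:
        raise ValueError("only the long-exposure (> 10 s) skin branch is supported")
    limit_w_cm2 = 0.2 * _ca(lam)
    return limit_w_cm2 * 10.0  # W/cm^2 -> mW/mm^2


def mpe_ocular_extended(
    wavelength_nm: float, duration_s: float = 100.0, alpha_mrad: float = ALPHA_MAX_MRAD
) -> float:
    """Long-exposure extended-source ocular MPE, mW/mm^2.

    With alpha_eff = min(alpha, 100) mrad: CE = alpha_eff / 1.5,
    T2 = 10 * 10^((alpha_eff - 1.5)/98.5) s, and

      limit = 1.8 * CA * CE * T2^(-1/4) mW/cm^2    (0.700-1.050 um)
      limit = 9.0 * CC * CE * T2^(-1/4) mW/cm^2    (1.050-1.400 um, CC per band)

    Point sources (alpha < 1.5 mrad) are a different branch of the standard
    and are refused.
    """
    lam = _check_band(wavelength_nm)
    if alpha_mrad < ALPHA_MIN_MRAD:
        raise ValueError("alpha < 1.5 mrad is the point-source branch (unsupported)")
    alpha_eff = min(alpha_mrad, ALPHA_MAX_MRAD)
    ce = alpha_eff / ALPHA_MIN_MRAD
    t2 = 10.0 * 10.0 ** ((alpha_eff - ALPHA_MIN_MRAD) / 98.5)
    if duration_s < t2:
        raise ValueError(f"only exposures >= T2 ({t2:.3g} s) are supported")
    if lam < 1.050:
        limit_mw_cm2 = 1.8 * _ca(lam) * ce * t2 ** (-0.25)
    else:
        if lam <= 1.150:
            cc = 1.0
        elif lam <= 1.200:
            cc = 10.0 ** (18.0 * (lam - 1.150))
        else:
            cc = 8.0
        limit_mw_cm2 = 9.0 * cc * ce * t2 ** (-0.25)
    return limit_mw_cm2 / 100.0  # mW/cm^2 -> mW/mm^2


def evaluate_exposure(
    spec: ExposureSpec, measured_mw_mm2: float, basis: str = "ocular_extended"
) -> MPEResult:
    """Compute the applicable MPE for an exposure scenario and check a measurement."""
    if basis == "skin":
        limit = mpe_skin(spec.wavelength_nm, spec.duration_s)
        params = {"duration_s": spec.duration_s}
    elif basis == "ocular_extended":
        limit = mpe_ocular_extended(spec.wavelength_nm, spec.duration_s, spec.alpha_mrad)
        params = {"duration_s": spec.duration_s, "alpha_mrad": spec.alpha_mrad}
    else:
        raise ValueError(f"unknown basis {basis!r}")
    res = safety_margin(measured_mw_mm2, limit, basis)
    return MPEResult(
        limit_mw_mm2=res.limit_mw_mm2, basis=basis,
        margin=res.margin, passed=res.passed, parameters=params,
    )


def safety_margin(measured_mw_mm2: float, limit_mw_mm2: float, basis: str = "") -> MPEResult:
    """Measured-to-limit margin; passes when measured <= limit (inclusive)."""
    if measured_mw_mm2 <= 0 or limit_mw_mm2 <= 0:
        raise ValueError("measured fluence and limit must both be positive")
    margin = measured_mw_mm2 / limit_mw_mm2
    return MPEResult(
        limit_mw_mm2=limit_mw_mm2,
        basis=basis or "unspecified",
        margin=margin,
        passed=margin <= 1.0,
    )
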