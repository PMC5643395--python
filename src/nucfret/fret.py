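"""Core FRET arithmetic: intensity corrections, proximity ratio, efficiency.

The proximity ratio P = I_A / (I_A + I_D) is the primary observable of both
the microplate-scanning and the single-pair FRET experiments.  It is related
to the FRET efficiency E through the setup-dependent detection factor
(gamma-factor), and E to the dye separation R through the Foerster radius R0:

    E = N_A / (N_A + gamma * N_D) = 1 / (1 + (R/R0)^6)
    P = gamma / (gamma - 1 + 1/E)
    gamma = (eta_A * phi_A) / (eta_D * phi_D)

Ensemble intensities are corrected for background, donor crosstalk into the
acceptor channel (alpha) and direct acceptor excitation (delta) before P is
formed.  Corrected intensities may be negative; they are never clamped, so
that P histograms can extend below 0 and above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._errors import UndefinedValueError, ValidationError

__all__ = [
    "DyePair",
    "CorrectionSet",
    "WellIntensities",
    "correct_intensities",
    "proximity_ratio",
    "efficiency_from_counts",
    "efficiency_from_distance",
    "distance_from_efficiency",
    "p_from_efficiency",
    "efficiency_from_p",
    "gamma_factor",
    "corrections_from_plate",
]


@dataclass(frozen=True)
class DyePair:
    """A donor/acceptor dye pair and its detection parameters.

    Parameters
    ----------
    forster_radius_nm
        Foerster radius R0 in nm (distance at which E = 0.5).
    det_eff_donor, det_eff_acceptor
        Detection efficiencies eta_D, eta_A of the two channels.
    qy_donor, qy_acceptor
        Fluorescence quantum yields phi_D, phi_A.
    gamma
        Detection factor; derived as (eta_A*phi_A)/(eta_D*phi_D) when not
        given explicitly.
    """

    forster_radius_nm: float = 5.0
    det_eff_donor: float = 1.0
    det_eff_acceptor: float = 1.0
    qy_donor: float = 1.0
    qy_acceptor: float = 1.0
    gamma: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("forster_radius_nm", "det_eff_donor", "det_eff_acceptor",
                     "qy_donor", "qy_acceptor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"DyePair.{name} must be > 0")
        derived = (self.det_eff_acceptor * self.qy_acceptor) / (
            self.det_eff_donor * self.qy_donor)
        if self.gamma is None:
            object.__setattr__(self, "gamma", derived)
        else:
            if self.gamma <= 0:
                raise ValidationError("DyePair.gamma must be > 0")
            if abs(self.gamma - derived) > 1e-12:
                raise ValidationError(
                    f"gamma={self.gamma} inconsistent with "
                    f"(eta_A*phi_A)/(eta_D*phi_D)={derived}")


@dataclass(frozen=True)
class CorrectionSet:
    """Background, crosstalk and direct-excitation corrections.

    ``crosstalk_alpha`` is the fraction of (background-subtracted) donor
    signal leaking into the acceptor channel; ``direct_exc_delta`` the
    fraction of the acceptor-excitation signal subtracted to account for
    direct excitation of the acceptor by the donor laser.
    """

    bkg_donor: float = 0.0
    bkg_acceptor: float = 0.0
    bkg_acceptor_aex: float = 0.0
    crosstalk_alpha: float = 0.0
    direct_exc_delta: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.crosstalk_alpha < 1.0):
            raise ValidationError("crosstalk_alpha must be in [0, 1)")
        if not (0.0 <= self.direct_exc_delta < 1.0):
            raise ValidationError("direct_exc_delta must be in [0, 1)")
        if min(self.bkg_donor, self.bkg_acceptor, self.bkg_acceptor_aex) < 0:
            raise ValidationError("backgrounds must be >= 0")


@dataclass(frozen=True)
class WellIntensities:
    """Raw microplate well intensities I_D^Dex, I_A^Dex, I_A^Aex."""

    i_d_dex: float
    i_a_dex: float
    i_a_aex: float = 0.0
    well_id: str = ""
    nacl_mm: float = 0.0

    def __post_init__(self):
        if min(self.i_d_dex, self.i_a_dex, self.i_a_aex) < 0:
            raise ValidationError(
                f"raw intensities must be >= 0 (well {self.well_id!r})")


def correct_intensities(w: WellIntensities,
                        c: CorrectionSet) -> tuple[float, float]:
    """Background / crosstalk / direct-excitation corrected intensities.

    Returns ``(i_d_corr, i_a_corr)`` where::

        i_d_corr = I_D^Dex - bkg_donor
        i_a_corr = I_A^Dex - bkg_acceptor - alpha*i_d_corr
                   - delta*(I_A^Aex - bkg_acceptor_aex)

    Negative corrected values are preserved (no clamping).
    """
    vals = (w.i_d_dex, w.i_a_dex, w.i_a_aex)
    if not all(math.isfinite(v) for v in vals):
        raise ValidationError(
            f"non-finite intensity in well {w.well_id!r}: {vals}")
    i_d_corr = w.i_d_dex - c.bkg_donor
    i_a_corr = (w.i_a_dex - c.bkg_acceptor
                - c.crosstalk_alpha * i_d_corr
                - c.direct_exc_delta * (w.i_a_aex - c.bkg_acceptor_aex))
    return i_d_corr, i_a_corr


def proximity_ratio(i_a_corr: float, i_d_corr: float,
                    ident: str | None = None) -> float:
    """P = I_A / (I_A + I_D) on corrected intensities.

    Unbounded (may fall outside [0, 1]) when corrections drive an intensity
    negative.  A zero denominator raises :class:`UndefinedValueError`
    carrying ``ident``.
    """
    denom = i_a_corr + i_d_corr
    if denom == 0:
        raise UndefinedValueError(
            "proximity ratio undefined: corrected total is zero", ident)
    return i_a_corr / denom


def efficiency_from_counts(n_a: float, n_d: float, gamma: float = 1.0) -> float:
    """FRET efficiency E = N_A / (N_A + gamma*N_D); for gamma=1, E == P."""
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    denom = n_a + gamma * n_d
    if denom <= 0:
        raise UndefinedValueError("efficiency undefined: N_A + gamma*N_D <= 0")
    return n_a / denom


def efficiency_from_distance(r_nm, r0_nm: float = 5.0):
    """E = 1 / (1 + (R/R0)^6)."""
    r = np.asarray(r_nm, dtype=float)
    if np.any(r <= 0) or r0_nm <= 0:
        raise ValidationError("distances must be > 0")
    out = 1.0 / (1.0 + (r / r0_nm) ** 6)
    return out if out.ndim else float(out)


def distance_from_efficiency(e, r0_nm: float = 5.0):
    """Inverse of :func:`efficiency_from_distance`; requires 0 < E < 1."""
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr <= 0) or np.any(e_arr >= 1):
        raise ValidationError("efficiency must lie in (0, 1) for inversion")
    if r0_nm <= 0:
        raise ValidationError("r0 must be > 0")
    out = r0_nm * (1.0 / e_arr - 1.0) ** (1.0 / 6.0)
    return out if out.ndim else float(out)


def p_from_efficiency(e, gamma: float = 1.0):
    """P = gamma / (gamma - 1 + 1/E); identity for gamma = 1."""
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr <= 0) or np.any(e_arr > 1):
        raise ValidationError("efficiency must lie in (0, 1]")
    out = gamma / (gamma - 1.0 + 1.0 / e_arr)
    return out if out.ndim else float(out)


def efficiency_from_p(p, gamma: float = 1.0):
    """Inverse of :func:`p_from_efficiency`: E = P / (gamma - (gamma-1)*P)."""
    if gamma <= 0:
        raise ValidationError("gamma must be > 0")
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr > 1):
        raise ValidationError("proximity ratio must lie in (0, 1]")
    out = p_arr / (gamma - (gamma - 1.0) * p_arr)
    return out if out.ndim else float(out)


def gamma_factor(dye: DyePair) -> float:
    """gamma = (eta_A * phi_A) / (eta_D * phi_D)."""
    return (dye.det_eff_acceptor * dye.qy_acceptor) / (
        dye.det_eff_donor * dye.qy_donor)


def corrections_from_plate(plate) -> CorrectionSet:
    """Estimate a :class:`CorrectionSet` from control wells of a plate table.

    ``plate`` is a DataFrame with columns ``well_id, nacl_mm, i_d_dex,
    i_a_dex, i_a_aex, role``.  Buffer wells give channel backgrounds;
    donor-only wells give the crosstalk fraction alpha; acceptor-only wells
    give the direct-excitation fraction delta.  Roles that are absent leave
    the corresponding correction at zero.
    """
    roles = plate["role"].astype(str)
    buf = plate[roles == "buffer"]
    bkg_d = float(buf["i_d_dex"].mean()) if len(buf) else 0.0
    bkg_a = float(buf["i_a_dex"].mean()) if len(buf) else 0.0
    bkg_aa = float(buf["i_a_aex"].mean()) if len(buf) else 0.0

    donly = plate[roles == "donor_only"]
    alpha = 0.0
    if len(donly):
        d = donly["i_d_dex"].to_numpy(float) - bkg_d
        a = donly["i_a_dex"].to_numpy(float) - bkg_a
        ok = d > 0
        if not ok.any():
            raise ValidationError("donor-only wells have no donor signal")
        alpha = float(np.mean(a[ok] / d[ok]))

    aonly = plate[roles == "acceptor_only"]
    delta = 0.0
    if len(aonly):
        aa = aonly["i_a_aex"].to_numpy(float) - bkg_aa
        a = aonly["i_a_dex"].to_numpy(float) - bkg_a
        ok = aa > 0
        if not ok.any():
            raise ValidationError(
                "acceptor-only wells have no acceptor-excitation signal")
        delta = float(np.mean(a[ok] / aa[ok]))

    return CorrectionSet(bkg_donor=bkg_d, bkg_acceptor=bkg_a,
                         bkg_acceptor_aex=bkg_aa,
                         crosstalk_alpha=max(0.0, alpha),
                         direct_exc_delta=max(0.0, delta))
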