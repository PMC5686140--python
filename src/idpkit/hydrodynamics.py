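"""Stokes-radius calibration and conformational-state classification.

Globular proteins, molten globules (MG), premolten globules (PMG) and
urea-unfolded chains each follow a characteristic power law between Stokes
radius Rs (Å) and molecular mass MM (Da); log10 throughout:

    log Rs(std)  = 0.369 log MM - 0.254      (SEC calibration standards)
    log Rs(NF)   = 0.357 log MM - 0.204      (natively folded)
    log Rs(U)    = 0.521 log MM - 0.649      (fully unfolded in urea)
    log Rs(PMG)  = 0.392 log MM - 0.210      (premolten globule)
    log Rs(MG)   = 0.334 log MM - 0.053      (molten globule)
    log Rs(DimNF)= 0.357 log(2 MM) - 0.204   (natively folded dimer)
    Rs(IDP)      = 2.49 N^0.509              (IDP power law, N residues)

The compaction index CI = (Rs_U - Rs_obs)/(Rs_U - Rs_NF) locates an
observed Stokes radius between the fully expanded (CI = 0) and natively
folded (CI = 1) limits.  ``hydro_report`` assembles the full table of
expected radii, observed/expected ratios, CI and a nearest-state call for
one protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

#: (slope, intercept) of log10 Rs vs log10 MM per conformational state.
STATE_COEFFS = {
    "NF": (0.357, -0.204),
    "MG": (0.334, -0.053),
    "PMG": (0.392, -0.210),
    "U": (0.521, -0.649),
}

#: IDP Rs power law Rs = R0 * N**nu.
IDP_RS_R0 = 2.49
IDP_RS_NU = 0.509

#: Order of states from most to least compact (used for tie-breaking).
_COMPACTNESS_ORDER = ["NF", "DimNF", "MG", "PMG", "IDP", "U"]


def rs_standard(mm: float) -> float:
    """Stokes radius (Å) of a globular SEC calibration standard of mass
    ``mm`` (Da): 10**(0.369 log10 MM - 0.254)."""
    if mm <= 0:
        raise InputError(f"molecular mass must be positive, got {mm}")
    return 10 ** (0.369 * np.log10(mm) - 0.254)


def expected_rs(mm: float, state: str) -> float:
    """Expected Stokes radius (Å) for a given conformational state.

    ``state`` is one of NF, MG, PMG, U, DimNF.  DimNF is the NF law
    evaluated at twice the mass (a natively folded dimer).
    """
    if mm <= 0:
        raise InputError(f"molecular mass must be positive, got {mm}")
    if state == "DimNF":
        return expected_rs(2 * mm, "NF")
    try:
        slope, intercept = STATE_COEFFS[state]
    except KeyError:
        raise InputError(
            f"unknown state {state!r}; expected one of "
            f"{sorted(STATE_COEFFS) + ['DimNF']}"
        ) from None
    return 10 ** (slope * np.log10(mm) + intercept)


def rs_idp(n_residues: int) -> float:
    """Expected Stokes radius (Å) of an IDP of ``n_residues`` residues:
    Rs = 2.49 N**0.509."""
    if n_residues <= 0:
        raise InputError("residue count must be positive")
    return IDP_RS_R0 * n_residues ** IDP_RS_NU


def compaction_index(rs_obs: float, mm: float) -> float:
    """Compaction index CI = (Rs_U - Rs_obs)/(Rs_U - Rs_NF).

    1 at the natively folded radius, 0 at the fully unfolded radius.
    Values outside [0, 1] are returned as-is with a warning.
    """
    if rs_obs <= 0:
        raise InputError("observed Rs must be positive")
    rs_u = expected_rs(mm, "U")
    rs_nf = expected_rs(mm, "NF")
    if rs_u == rs_nf:
        raise InputError("degenerate calibration: Rs_U equals Rs_NF")
    ci = (rs_u - rs_obs) / (rs_u - rs_nf)
    if not 0.0 <= ci <= 1.0:
        warnings.warn(
            f"compaction index {ci:.3f} outside [0, 1]: the observed radius "
            "lies outside the NF-U bracket",
            stacklevel=2,
        )
    return ci


@dataclass
class HydroStateReport:
    """Expected radii, ratios and state call for one observed Stokes radius."""

    mm: float
    rs_obs: float
    n_residues: int | None
    expected: dict = field(default_factory=dict)   #: state -> Rs (Å)
    ratios: dict = field(default_factory=dict)     #: state -> rs_obs/Rs_state
    ci: float = float("nan")
    nearest_state: str = ""
    tie_states: tuple = ()

    def as_row(self, precision: int = 1) -> dict:
        """Table-style row with radii rounded to 0.1 Å."""
        row = {"MM_Da": self.mm, "Rs_obs_A": round(self.rs_obs, precision)}
        for state, rs in self.expected.items():
            row[f"Rs_{state}_A"] = round(rs, precision)
        for state, ratio in self.ratios.items():
            row[f"ratio_{state}"] = round(ratio, 2)
        row["CI"] = round(self.ci, 2)
        row["nearest_state"] = self.nearest_state
        if self.n_residues is not None:
            row["N"] = self.n_residues
        return row


def classify_state(ratios: dict[str, float]) -> tuple[str, tuple]:
    """State whose ratio Rs_obs/Rs_state is closest to 1.

    Ties (within 1e-9) are broken toward the more compact state; all tied
    states are reported explicitly in the second element.
    """
    items = sorted(
        ratios.items(),
        key=lambda kv: (abs(kv[1] - 1.0), _COMPACTNESS_ORDER.index(kv[0])),
    )
    best_dev = abs(items[0][1] - 1.0)
    tied = tuple(s for s, r in items if abs(abs(r - 1.0) - best_dev) < 1e-9)
    return items[0][0], tied


def hydro_report(
    mm: float, rs_obs: float, n_residues: int | None = None
) -> HydroStateReport:
    """Assemble the full hydrodynamic report for one protein.

    ``n_residues`` should be the residue count of the measured construct
    (including any expression-tag residues), since that is the species the
    IDP power law is compared against; it is echoed in the report.
    """
    report = HydroStateReport(mm=mm, rs_obs=rs_obs, n_residues=n_residues)
    for state in ("NF", "MG", "PMG", "U", "DimNF"):
        report.expected[state] = expected_rs(mm, state)
    if n_residues is not None:
        report.expected["IDP"] = rs_idp(n_residues)
    report.ratios = {s: rs_obs / r for s, r in report.expected.items()}
    report.ci = compaction_index(rs_obs, mm)
    report.nearest_state, report.tie_states = classify_state(report.ratios)
    return report


# ---------------------------------------------------------------------------
# SEC calibration
# ---------------------------------------------------------------------------

@dataclass
class SECCalibration:
    """Log-linear SEC calibration: elution volume -> log10 Stokes radius."""

    slope: float
    intercept: float
    standards: list  #: list of (MM Da, Ve mL)
    residuals: np.ndarray
    ve_range: tuple

    def rs(self, ve: float) -> float:
        """Stokes radius (Å) for elution volume ``ve`` (mL); warns when
        extrapolating beyond the calibrated range."""
        lo, hi = self.ve_range
        if not lo <= ve <= hi:
            warnings.warn(
                f"elution volume {ve} outside calibrated range [{lo}, {hi}]: "
                "extrapolating",
                stacklevel=2,
            )
        return 10 ** (self.slope * ve + self.intercept)


def calibrate_sec(standards) -> SECCalibration:
    """Fit log10(Rs) vs elution volume for globular standards.

    ``standards`` is a sequence of ``(MM in Da, Ve in mL)`` pairs; the
    Stokes radius of each standard is derived from its mass via the
    globular-standard power law (``rs_standard``).
    """
    standards = list(standards)
    if len(standards) < 3:
        raise InputError("at least 3 SEC standards are required")
    mm = np.array([s[0] for s in standards], dtype=float)
    ve = np.array([s[1] for s in standards], dtype=float)
    log_rs = np.log10([rs_standard(m) for m in mm])
    slope, intercept = np.polyfit(ve, log_rs, 1)
    residuals = log_rs - (slope * ve + intercept)
    return SECCalibration(
        slope=float(slope),
        intercept=float(intercept),
        standards=standards,
        residuals=residuals,
        ve_range=(float(ve.min()), float(ve.max())),
    )


def rs_from_elution(calibration: SECCalibration, ve: float) -> float:
    """Stokes radius (Å) from an elution volume via a fitted calibration."""
    return calibration.rs(ve)
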