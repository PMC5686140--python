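"""Circular-dichroism utilities for disordered proteins.

Covers the far-UV CD workflow: conversion of raw differential absorbance to
mean molar residue ellipticity (MRE), an alpha-helicity estimate from the
220 nm ellipticity, the double-wavelength (200 nm / 222 nm) classification
of IDPs into random-coil-like and premolten-globule-like forms, Boltzmann
sigmoid fitting of thermal melts, and isodichroic-point detection across a
spectral family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import InputError, FitError


@dataclass
class CDSpectrum:
    """A CD spectrum on a wavelength grid.

    ``kind`` is ``"deltaA"`` for raw differential absorbance or ``"mre"``
    for mean molar residue ellipticity (deg cm^2 dmol^-1).  The metadata
    needed for conversion are the cuvette path length (cm), protein
    concentration (mg/mL), molecular mass (Da) and residue count.
    """

    wavelength: np.ndarray
    values: np.ndarray
    kind: str = "mre"
    path_cm: float | None = None
    conc_mg_ml: float | None = None
    mass_da: float | None = None
    n_residues: int | None = None
    label: str = ""

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength.size != self.values.size:
            raise InputError("wavelength and values must have equal length")
        d = np.diff(self.wavelength)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InputError("wavelength grid must be strictly monotone")
        if self.kind not in ("deltaA", "mre"):
            raise InputError("kind must be 'deltaA' or 'mre'")

    def at(self, wavelength: float) -> float:
        """Signal linearly interpolated at one wavelength."""
        wl, v = self.wavelength, self.values
        if wl[0] > wl[-1]:
            wl, v = wl[::-1], v[::-1]
        if not wl[0] <= wavelength <= wl[-1]:
            raise InputError(f"{wavelength} nm outside the measured range")
        return float(np.interp(wavelength, wl, v))


def to_mre(spectrum: CDSpectrum) -> CDSpectrum:
    """Convert differential absorbance to mean molar residue ellipticity.

    MRE = 3300 * M * dA / (l * c * n) with l the path length in cm, c the
    concentration in mg/mL, M the molecular mass in Da and n the residue
    count.
    """
    if spectrum.kind != "deltaA":
        raise InputError("spectrum is not raw differential absorbance")
    meta = (spectrum.path_cm, spectrum.conc_mg_ml, spectrum.mass_da,
            spectrum.n_residues)
    if any(m is None or m <= 0 for m in meta):
        raise InputError(
            "path_cm, conc_mg_ml, mass_da and n_residues must all be set "
            "and positive for MRE conversion"
        )
    l, c, m, n = meta
    mre = 3300.0 * m * spectrum.values / (l * c * n)
    return CDSpectrum(
        spectrum.wavelength.copy(), mre, kind="mre",
        path_cm=l, conc_mg_ml=c, mass_da=m, n_residues=n,
        label=spectrum.label,
    )


def mre_helix_max(n_residues: int, coefficient: float = 40000.0,
                  chain_correction: float = 2.5) -> float:
    """MRE at 220 nm of a fully alpha-helical chain of ``n_residues``:
    the chain-length-corrected value -coefficient * (1 - correction/n)."""
    if n_residues <= chain_correction:
        raise InputError(
            f"residue count must exceed the chain correction {chain_correction}"
        )
    return -coefficient * (1.0 - chain_correction / n_residues)


def helicity_fraction(
    mre_220: float, n_residues: int,
    coefficient: float = 40000.0, chain_correction: float = 2.5,
) -> float:
    """Alpha-helix fraction: MRE at 220 nm divided by the 100%-helix value
    for the same chain length.  Clipped to [0, 1] with a warning."""
    frac = mre_220 / mre_helix_max(n_residues, coefficient, chain_correction)
    if not 0.0 <= frac <= 1.0:
        warnings.warn(
            f"helicity fraction {frac:.3f} outside [0, 1]: clipping",
            stacklevel=2,
        )
    return float(np.clip(frac, 0.0, 1.0))


# ---------------------------------------------------------------------------
# RC-like vs PMG-like double-wavelength classification
# ---------------------------------------------------------------------------

#: Class centroids of the double-wavelength plot (MRE at 200 nm, 222 nm),
#: deg cm^2 dmol^-1.  Consensus mean values for sets of well-characterized
#: random-coil-like and premolten-globule-like IDPs, as used for this kind
#: of plot in the IDP literature.
RC_CENTROID = (-18900.0, -1700.0)
PMG_CENTROID = (-10700.0, -3900.0)
#: Within-class spreads used to scale the two (very differently sized) axes.
_CLASS_SCALE = (2800.0, 1100.0)


def classify_rc_pmg(
    mre_200: float, mre_222: float, boundary_tol: float = 0.05
):
    """Classify an IDP as random-coil-like or premolten-globule-like.

    The point (MRE_200, MRE_222) is assigned to the nearest class centroid
    (axes scaled by the within-class spreads); points whose two distances
    differ by less than ``boundary_tol`` (relative) are labelled
    ``"boundary"``.  Returns ``(label, (mre_200, mre_222))``.
    """
    p = np.array([mre_200, mre_222])
    scale = np.array(_CLASS_SCALE)
    d_rc = np.linalg.norm((p - np.array(RC_CENTROID)) / scale)
    d_pmg = np.linalg.norm((p - np.array(PMG_CENTROID)) / scale)
    denom = (d_rc + d_pmg) / 2.0
    if denom == 0 or abs(d_rc - d_pmg) <= boundary_tol * denom:
        label = "boundary"
    else:
        label = "RC-like" if d_rc < d_pmg else "PMG-like"
    return label, (mre_200, mre_222)


# ---------------------------------------------------------------------------
# thermal melt
# ---------------------------------------------------------------------------

def _boltzmann(t, low, high, tm, slope):
    return low + (high - low) / (1.0 + np.exp((tm - t) / slope))


@dataclass
class MeltFit:
    """Four-parameter Boltzmann fit of a thermal melt."""

    tm: float                 #: midpoint temperature, °C
    slope: float              #: transition width, °C
    baseline_low: float       #: low-temperature asymptote
    baseline_high: float      #: high-temperature asymptote
    stderr: dict = field(default_factory=dict)
    quality: str = "ok"       #: "ok" or "poor"
    residual_sd: float = 0.0

    def predict(self, t):
        return _boltzmann(np.asarray(t, float), self.baseline_low,
                          self.baseline_high, self.tm, self.slope)


def melt_fit(temperature, signal, quality_r2: float = 0.9) -> MeltFit:
    """Fit a melt curve to the Boltzmann sigmoid
    ``S(T) = A + (B - A)/(1 + exp((Tm - T)/s))``.

    Reports the midpoint Tm, the width s, both baselines, asymptotic
    standard errors and a quality flag (``"poor"`` when the sigmoid
    explains less than ``quality_r2`` of the signal variance).

    Raises
    ------
    FitError
        On non-convergence or when the fitted transition amplitude is
        indistinguishable from the residual noise (e.g. a flat curve).
    """
    t = np.asarray(temperature, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 8:
        raise InputError("need at least 8 temperature points")
    span = t.max() - t.min()
    p0 = (y[0], y[-1], float(t.mean()), max(span / 10.0, 1.0))
    try:
        popt, pcov = curve_fit(_boltzmann, t, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise FitError(f"melt fit did not converge: {err}") from None
    low, high, tm, slope = popt
    resid = y - _boltzmann(t, *popt)
    resid_sd = float(np.std(resid, ddof=min(4, t.size - 1)))
    amplitude = abs(high - low)
    if not np.all(np.isfinite(pcov)) or amplitude < 3.0 * resid_sd:
        raise FitError(
            "melt fit degenerate: transition amplitude indistinguishable "
            "from noise"
        )
    if not t.min() <= tm <= t.max():
        warnings.warn(
            f"fitted midpoint {tm:.1f} °C lies outside the measured range",
            stacklevel=2,
        )
    errs = np.sqrt(np.diag(pcov))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return MeltFit(
        tm=float(tm), slope=float(slope),
        baseline_low=float(low), baseline_high=float(high),
        stderr={"baseline_low": errs[0], "baseline_high": errs[1],
                "tm": errs[2], "slope": errs[3]},
        quality="ok" if r2 >= quality_r2 else "poor",
        residual_sd=resid_sd,
    )


# ---------------------------------------------------------------------------
# isodichroic point
# ---------------------------------------------------------------------------

@dataclass
class IsodichroicResult:
    wavelength: float | None
    found: bool
    degenerate: bool
    sd_profile: np.ndarray = field(repr=False, default=None)


def isodichroic_point(
    spectra: list[CDSpectrum],
    tolerance: float = 0.05,
    spread_window_nm: float = 10.0,
    min_spread: float = 0.2,
) -> IsodichroicResult:
    """Locate the isodichroic (common-crossing) point of a spectral family.

    A genuine isodichroic point is a wavelength where spectra that differ
    strongly nearby all coincide and *cross* — the across-family
    differences change sign there.  The candidate region is restricted to
    wavelengths whose neighbourhood (within ``spread_window_nm``) shows an
    across-spectra spread of at least ``min_spread`` of the maximum
    spread; within it the across-spectra standard deviation is minimized.
    The minimum qualifies when (a) it is below ``tolerance`` times the
    overall signal range and (b) the most different pair of spectra swaps
    order across the candidate wavelength (the sign-flip test, which
    rejects wavelengths where the family merely converges without
    crossing).  A family of (near-)identical spectra is reported as
    degenerate with no isodichroic point.  All spectra must share the
    same wavelength grid.
    """
    if len(spectra) < 3:
        raise InputError("need at least 3 spectra")
    wl = spectra[0].wavelength
    for s in spectra[1:]:
        if s.wavelength.size != wl.size or not np.allclose(s.wavelength, wl):
            raise InputError("spectra are not on a common wavelength grid")
    mat = np.vstack([s.values for s in spectra])
    sd = mat.std(axis=0)
    spread = mat.max(axis=0) - mat.min(axis=0)
    signal_range = float(mat.max() - mat.min())
    if signal_range == 0 or spread.max() <= tolerance * signal_range:
        return IsodichroicResult(None, False, True, sd)
    # neighbourhood spread: max spread within +/- spread_window_nm
    near = np.array([
        spread[np.abs(wl - w) <= spread_window_nm].max() for w in wl
    ])
    candidate = near >= min_spread * spread.max()
    if not np.any(candidate):
        return IsodichroicResult(None, False, True, sd)
    masked = np.where(candidate, sd, np.inf)
    i = int(masked.argmin())
    if sd[i] > tolerance * signal_range:
        return IsodichroicResult(None, False, False, sd)
    # sign-flip test on the most different pair of spectra
    pair_best, diff_best = None, -1.0
    for a in range(mat.shape[0]):
        for b in range(a + 1, mat.shape[0]):
            total = float(np.abs(mat[a] - mat[b]).sum())
            if total > diff_best:
                diff_best, pair_best = total, (a, b)
    d = mat[pair_best[0]] - mat[pair_best[1]]
    left = d[(wl < wl[i]) & (wl >= wl[i] - spread_window_nm)]
    right = d[(wl > wl[i]) & (wl <= wl[i] + spread_window_nm)]
    if left.size and right.size and left.mean() * right.mean() >= 0:
        return IsodichroicResult(None, False, False, sd)
    return IsodichroicResult(float(wl[i]), True, False, sd)
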