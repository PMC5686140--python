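"""Synthetic-data generators with embedded ground truth.

Every analysis stage of the toolkit has a matching generator here, so the
whole pipeline can be exercised and validated without any external data:
sequences with prescribed composition and target charge-patterning kappa,
scattering curves from analytic models or conformer ensembles (including
two-population mixtures) with Gaussian noise, log-linear SEC calibrations,
Boltzmann melt curves, and two-state CD spectral families with a designed
isodichroic crossing.

All generators are deterministic for a fixed seed and return the ground
truth alongside the fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, UndefinedKappaError
from .sequence import ProteinSequence
from .descriptors import kappa
from .hydrodynamics import rs_standard
from .saxs import ScatteringCurve, sphere_intensity, debye_coil_intensity
from .ensemble import Conformer, generate_pool, pool_curves

#: An ASR1-like amino-acid composition: Glu-rich (~16%), with E, A, H, K
#: and G together near 68% of residues, f+ ~ 0.136 and f- ~ 0.201 — the
#: composition regime of hydrophilic, charged plant stress IDPs.
ASR1_LIKE_COMPOSITION = {
    "E": 0.161, "A": 0.155, "H": 0.125, "K": 0.120, "G": 0.120,
    "D": 0.040, "R": 0.016, "S": 0.050, "Q": 0.040, "T": 0.030,
    "V": 0.030, "Y": 0.030, "L": 0.025, "M": 0.020, "F": 0.013,
    "P": 0.015, "N": 0.010,
}


def _noise_sigma(intensity: np.ndarray, q: np.ndarray, snr: float) -> np.ndarray:
    # relative error grows toward high q, as in real detector statistics
    return np.abs(intensity) / snr * (1.0 + q / q.max())


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def gen_sequence(
    length: int,
    composition: dict[str, float],
    target_kappa: float,
    seed: int,
    tol: float = 0.01,
    max_iter: int = 20000,
    seq_id: str = "synthetic",
):
    """Generate a sequence with a prescribed composition and target kappa.

    Residue counts follow ``composition`` (largest-remainder rounding);
    charge patterning is then tuned by simulated-annealing swaps of residue
    positions (always involving at least one charged residue) until the
    kappa of the sequence is within ``tol`` of ``target_kappa`` or the
    iteration cap is reached.  Returns ``(ProteinSequence, achieved_kappa)``.
    """
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-6:
        raise InputError(f"composition sums to {total}, expected 1")
    if not 0.0 <= target_kappa <= 1.0:
        raise InputError("target kappa must lie in [0, 1]")

    # largest-remainder apportionment of counts
    raw = {aa: frac * length for aa, frac in composition.items()}
    counts = {aa: int(np.floor(v)) for aa, v in raw.items()}
    short = length - sum(counts.values())
    for aa in sorted(raw, key=lambda a: raw[a] - counts[a], reverse=True)[:short]:
        counts[aa] += 1

    residues = [aa for aa, c in counts.items() for _ in range(c)]
    charged_pos = [i for i, c in enumerate(residues) if c in "KRDE"]
    if not charged_pos:
        raise UndefinedKappaError(
            "composition contains no charged residues: kappa is undefined"
        )

    rng = np.random.default_rng(seed)
    rng.shuffle(residues)

    def current_kappa(seq_list):
        return kappa("".join(seq_list))

    k_now = current_kappa(residues)
    best = (abs(k_now - target_kappa), residues.copy(), k_now)
    temperature = 0.02
    for it in range(max_iter):
        if abs(k_now - target_kappa) <= tol:
            break
        ch = [i for i, c in enumerate(residues) if c in "KRDE"]
        i = int(rng.choice(ch))
        j = int(rng.integers(0, length))
        if residues[i] == residues[j]:
            continue
        residues[i], residues[j] = residues[j], residues[i]
        k_new = current_kappa(residues)
        d_old = abs(k_now - target_kappa)
        d_new = abs(k_new - target_kappa)
        if d_new <= d_old or rng.random() < np.exp((d_old - d_new) / temperature):
            k_now = k_new
            if d_new < best[0]:
                best = (d_new, residues.copy(), k_new)
        else:
            residues[i], residues[j] = residues[j], residues[i]
        temperature *= 0.9995
    if abs(k_now - target_kappa) > tol:
        _, residues, k_now = best
        if abs(k_now - target_kappa) > tol:
            import warnings

            warnings.warn(
                f"annealing stalled at kappa={k_now:.4f} "
                f"(target {target_kappa})",
                stacklevel=2,
            )
    return ProteinSequence(seq_id, "".join(residues)), float(k_now)


# ---------------------------------------------------------------------------
# scattering curves
# ---------------------------------------------------------------------------

@dataclass
class SaxsFixture:
    curve: ScatteringCurve
    truth: dict


def gen_saxs(
    model: tuple,
    q: np.ndarray,
    snr: float,
    seed: int,
) -> SaxsFixture:
    """Generate a noisy scattering curve from a known model.

    ``model`` is one of::

        ("sphere", radius_A)
        ("debye_coil", rg_A)
        ("two_population", intensity_a, intensity_b, weight_a)
        ("curve", intensity_array)          # precomputed noiseless curve

    Gaussian noise with sigma(q) = I(q)/snr * (1 + q/q_max) is added; the
    generating parameters are embedded in the returned truth dict.
    """
    if snr <= 0:
        raise InputError("snr must be positive")
    q = np.asarray(q, dtype=float)
    kind = model[0]
    if kind == "sphere":
        radius = model[1]
        intensity = sphere_intensity(q, radius)
        truth = {"model": kind, "radius": radius,
                 "rg": radius * np.sqrt(3.0 / 5.0), "dmax": 2.0 * radius}
    elif kind == "debye_coil":
        rg = model[1]
        intensity = debye_coil_intensity(q, rg)
        truth = {"model": kind, "rg": rg}
    elif kind == "two_population":
        ia, ib, wa = model[1], model[2], model[3]
        ia = np.asarray(ia, dtype=float)
        ib = np.asarray(ib, dtype=float)
        intensity = wa * ia / ia[0] + (1.0 - wa) * ib / ib[0]
        truth = {"model": kind, "weight_a": wa}
    elif kind == "curve":
        intensity = np.asarray(model[1], dtype=float)
        truth = {"model": kind}
    else:
        raise InputError(f"unknown model kind {kind!r}")

    rng = np.random.default_rng(seed)
    sigma = _noise_sigma(intensity, q, snr)
    noisy = intensity + rng.normal(0.0, 1.0, q.size) * sigma
    truth["snr"] = snr
    return SaxsFixture(
        ScatteringCurve(q, noisy, sigma, label=kind, meta=dict(truth)), truth
    )


def gen_two_population_pools(
    n_residues: int,
    n_per_pool: int,
    seed: int,
    q: np.ndarray,
    weight_compact: float = 0.5,
    snr: float = 200.0,
):
    """Compact + expanded conformer pools and their mixture target curve.

    Returns ``(pool, curves, target_fixture, truth)`` where ``pool`` is the
    concatenated conformer list (compact first), ``curves`` the per-conformer
    Debye curves, and ``truth`` carries the mean Rg of each sub-pool and the
    planted mixture weight.
    """
    compact = generate_pool(n_residues, n_per_pool, seed, preset="compact")
    expanded = generate_pool(n_residues, n_per_pool, seed + 1, preset="expanded")
    pool = compact + expanded
    curves = pool_curves(pool, q)
    ia = curves[:n_per_pool].mean(axis=0)
    ib = curves[n_per_pool:].mean(axis=0)
    fixture = gen_saxs(("two_population", ia, ib, weight_compact),
                       q, snr, seed + 2)
    truth = {
        "rg_compact": float(np.mean([c.rg for c in compact])),
        "rg_expanded": float(np.mean([c.rg for c in expanded])),
        "weight_compact": weight_compact,
    }
    fixture.truth.update(truth)
    return pool, curves, fixture, truth


# ---------------------------------------------------------------------------
# SEC calibration
# ---------------------------------------------------------------------------

def gen_sec_calibration(
    n_standards: int = 6,
    noise: float = 0.0,
    seed: int = 0,
    ve_intercept: float = 20.0,
    ve_slope: float = -7.0,
    mm_range: tuple = (1.2e4, 4.4e5),
):
    """Synthetic SEC standards on an exact log-linear calibration.

    Standards are globular proteins with masses log-spaced over
    ``mm_range``; elution volumes follow
    ``Ve = ve_intercept + ve_slope * log10(Rs)`` with optional relative
    Gaussian noise on Ve.  Returns ``(standards, truth)`` with the true
    line parameters.
    """
    if n_standards < 3:
        raise InputError("need at least 3 standards")
    rng = np.random.default_rng(seed)
    mm = np.logspace(np.log10(mm_range[0]), np.log10(mm_range[1]), n_standards)
    rs = np.array([rs_standard(m) for m in mm])
    ve = ve_intercept + ve_slope * np.log10(rs)
    if noise > 0:
        ve = ve * (1.0 + rng.normal(0.0, noise, ve.size))
    standards = list(zip(mm.tolist(), ve.tolist()))
    truth = {
        "ve_intercept": ve_intercept, "ve_slope": ve_slope,
        "rs": rs, "noise": noise,
    }
    return standards, truth


# ---------------------------------------------------------------------------
# melt curves
# ---------------------------------------------------------------------------

def gen_melt(
    tm: float = 51.0,
    slope: float = 5.0,
    baselines: tuple = (-4200.0, -1800.0),
    snr: float = 20.0,
    temperatures: np.ndarray | None = None,
    seed: int = 0,
):
    """Boltzmann-sigmoid melt curve with Gaussian noise.

    Noise sigma is (amplitude / snr).  Returns
    ``(temperature, signal, truth)``.
    """
    if temperatures is None:
        temperatures = np.arange(20.0, 80.5, 2.0)
    t = np.asarray(temperatures, dtype=float)
    low, high = baselines
    clean = low + (high - low) / (1.0 + np.exp((tm - t) / slope))
    rng = np.random.default_rng(seed)
    sigma = abs(high - low) / snr
    y = clean + rng.normal(0.0, sigma, t.size)
    truth = {"tm": tm, "slope": slope, "baselines": baselines, "sigma": sigma}
    return t, y, truth


# ---------------------------------------------------------------------------
# CD spectral families
# ---------------------------------------------------------------------------

def gen_cd_family(
    n_spectra: int = 6,
    crossing_nm: float = 205.0,
    wavelengths: np.ndarray | None = None,
    snr: float = 100.0,
    seed: int = 0,
    two_state: bool = True,
):
    """Family of far-UV CD spectra from a two-state transition.

    Spectra are convex combinations of a coil-like and a helix-like basis
    spectrum; the helix basis is offset so both bases agree exactly at
    ``crossing_nm``, which every two-state combination then shares as an
    isodichroic point.  With ``two_state=False`` a third, independent
    component breaks the common crossing.  Returns
    ``(list of CDSpectrum, truth)``.
    """
    from .cd import CDSpectrum

    if wavelengths is None:
        wavelengths = np.arange(190.0, 260.5, 0.5)
    wl = np.asarray(wavelengths, dtype=float)

    # coil-like basis: deep minimum near 200 nm
    coil = -20000.0 * np.exp(-((wl - 198.0) ** 2) / (2 * 8.0**2))
    # helix-like basis: double minimum at 208/222, positive lobe at 193
    helix = (
        -33000.0 * np.exp(-((wl - 208.0) ** 2) / (2 * 6.0**2))
        - 32000.0 * np.exp(-((wl - 222.0) ** 2) / (2 * 7.0**2))
        + 60000.0 * np.exp(-((wl - 193.0) ** 2) / (2 * 5.0**2))
    )
    # scale the helix basis so both bases cross exactly at crossing_nm
    # (scaling rather than offsetting keeps the long-wavelength baseline
    # at zero, as in real far-UV CD)
    c0 = np.interp(crossing_nm, wl, coil)
    h0 = np.interp(crossing_nm, wl, helix)
    if c0 == 0 or h0 == 0 or np.sign(c0) != np.sign(h0):
        raise InputError(
            f"bases cannot be made to cross at {crossing_nm} nm by scaling"
        )
    helix = helix * (c0 / h0)

    rng = np.random.default_rng(seed)
    fractions = np.linspace(0.0, 1.0, n_spectra)
    scale = max(abs(coil).max(), abs(helix).max())
    spectra = []
    for i, f in enumerate(fractions):
        clean = (1.0 - f) * coil + f * helix
        if not two_state:
            # third spectral component centred on the would-be crossing
            # wavelength destroys the common intersection
            clean = clean + 6000.0 * (i % 3) * np.exp(
                -((wl - crossing_nm) ** 2) / (2 * 6.0**2)
            )
        noisy = clean + rng.normal(0.0, scale / snr, wl.size)
        spectra.append(CDSpectrum(wl, noisy, kind="mre", label=f"f={f:.2f}"))
    truth = {"crossing_nm": crossing_nm if two_state else None,
             "fractions": fractions}
    return spectra, truth


# ---------------------------------------------------------------------------
# conformer pools (re-export for discoverability)
# ---------------------------------------------------------------------------

def gen_conformer_pool(n_residues: int, n_conformers: int, seed: int,
                       preset: str = "coil") -> list[Conformer]:
    """Self-avoiding Cα conformer pool (see :func:`idpkit.ensemble.generate_pool`)."""
    return generate_pool(n_residues, n_conformers, seed, preset=preset)
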