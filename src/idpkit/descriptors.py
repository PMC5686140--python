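"""Charge-patterning and composition descriptors for disordered sequences.

Implements the standard single-sequence descriptors used to place an IDP on
the diagram of states: fractions of charged residues (f+, f-), net charge
per residue (NCPR = f+ - f-), total fraction of charged residues
(FCR = f+ + f-), the charge-patterning parameter kappa (0 = opposite
charges well mixed, 1 = fully segregated), the charge-hydropathy plot with
the empirical folded/disordered boundary H = (R + 1.151)/2.785, a rescaled
Kyte-Doolittle hydropathy mean, and per-residue composition deviation from
the SWISS-PROT average.

Histidine is treated as neutral at pH 7 by default; every charge-dependent
function accepts ``his_charged=True`` for acidic-pH work, in which case His
is counted as positive.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict
from itertools import permutations

import numpy as np
import pandas as pd

from .exceptions import InputError, UndefinedKappaError
from .sequence import ProteinSequence, STANDARD_AA

# Kyte & Doolittle hydropathy scale (canonical 1982 values).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

NEGATIVE = frozenset("DE")
_POSITIVE_NEUTRAL_HIS = frozenset("KR")
_POSITIVE_CHARGED_HIS = frozenset("KRH")

#: Disorder-promoting residues (composition-bias convention of the
#: TOP-IDP / SWISS-PROT comparison scale).
DISORDER_PROMOTING = frozenset("AGRDHQKSEP")
#: Order-promoting residues.
ORDER_PROMOTING = frozenset("WFYIMLVCT")


def _positive_set(his_charged: bool) -> frozenset:
    return _POSITIVE_CHARGED_HIS if his_charged else _POSITIVE_NEUTRAL_HIS


def reference_composition() -> dict[str, float]:
    """Frozen SWISS-PROT average residue frequencies, normalized to sum 1."""
    with importlib.resources.files("idpkit.data").joinpath(
        "swissprot_composition.csv"
    ).open() as fh:
        df = pd.read_csv(fh, comment="#")
    freqs = df.set_index("residue")["percent"].astype(float)
    freqs /= freqs.sum()
    return freqs.to_dict()


# ---------------------------------------------------------------------------
# charge fractions
# ---------------------------------------------------------------------------

def charged_fractions(seq: ProteinSequence, his_charged: bool = False):
    """Return ``(f_plus, f_minus)`` — fractions of positive (K, R) and
    negative (D, E) residues."""
    pos = _positive_set(his_charged)
    n = seq.n
    f_plus = sum(1 for c in seq.residues if c in pos) / n
    f_minus = sum(1 for c in seq.residues if c in NEGATIVE) / n
    return f_plus, f_minus


def ncpr_fcr(f_plus: float, f_minus: float):
    """Net charge per residue and fraction of charged residues.

    NCPR = f+ - f-;  FCR = f+ + f-.
    """
    for name, f in (("f_plus", f_plus), ("f_minus", f_minus)):
        if not 0.0 <= f <= 1.0:
            raise InputError(f"{name}={f} outside [0, 1]")
    if f_plus + f_minus > 1.0 + 1e-12:
        raise InputError("f_plus + f_minus exceeds 1")
    return f_plus - f_minus, f_plus + f_minus


# ---------------------------------------------------------------------------
# kappa
# ---------------------------------------------------------------------------

def _charges(residues: str, his_charged: bool) -> np.ndarray:
    pos = _positive_set(his_charged)
    return np.array(
        [1 if c in pos else -1 if c in NEGATIVE else 0 for c in residues],
        dtype=np.int8,
    )


def _sigma(f_plus: float, f_minus: float) -> float:
    """Charge asymmetry sigma = (f+ - f-)^2 / (f+ + f-); 0 for no charges."""
    f = f_plus + f_minus
    if f == 0:
        return 0.0
    return (f_plus - f_minus) ** 2 / f


def _delta(charges: np.ndarray, blob: int) -> float:
    """Mean squared deviation of blob-level asymmetry from the global one.

    Blobs are all full windows of length ``blob`` at stride 1 (no partial
    terminal blobs).
    """
    n = charges.size
    sigma_seq = _sigma((charges > 0).mean(), (charges < 0).mean())
    # sliding window counts via cumulative sums
    pos = np.concatenate([[0], np.cumsum(charges > 0)])
    neg = np.concatenate([[0], np.cumsum(charges < 0)])
    fp = (pos[blob:] - pos[:-blob]) / blob
    fm = (neg[blob:] - neg[:-blob]) / blob
    f = fp + fm
    sig = np.zeros_like(fp)
    nz = f > 0
    sig[nz] = (fp[nz] - fm[nz]) ** 2 / f[nz]
    return float(np.mean((sig - sigma_seq) ** 2))


def _delta_max(charges: np.ndarray, blob: int) -> float:
    """Delta of the maximally segregated permutation of the composition.

    Built deterministically: the canonical block arrangements
    (pos|neu|neg, pos|neg|neu, neu|pos|neg) are evaluated and the largest
    delta is taken.
    """
    p = np.count_nonzero(charges > 0)
    m = np.count_nonzero(charges < 0)
    z = charges.size - p - m
    pos = np.ones(p, dtype=np.int8)
    neg = -np.ones(m, dtype=np.int8)
    neu = np.zeros(z, dtype=np.int8)
    arrangements = (
        np.concatenate([pos, neu, neg]),
        np.concatenate([pos, neg, neu]),
        np.concatenate([neu, pos, neg]),
    )
    return max(_delta(a, blob) for a in arrangements)


def kappa(
    seq: ProteinSequence | str,
    blob_sizes=(5, 6),
    his_charged: bool = False,
) -> float:
    """Charge-patterning parameter kappa in [0, 1].

    For each blob size g the blob-level charge asymmetries are compared
    with the whole-sequence asymmetry (delta_g) and normalized by the
    delta of the maximally charge-segregated permutation of the same
    composition (delta_max,g); kappa is the mean of the per-blob-size
    ratios, clipped to [0, 1].

    Raises
    ------
    UndefinedKappaError
        If the sequence has no charged residues (FCR = 0).
    InputError
        If the sequence is shorter than the largest blob size.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq
    charges = _charges(residues, his_charged)
    if not np.any(charges != 0):
        raise UndefinedKappaError("kappa undefined: sequence has no charged residues")
    if charges.size < max(blob_sizes):
        raise InputError(
            f"sequence length {charges.size} shorter than largest blob "
            f"size {max(blob_sizes)}"
        )
    ratios = []
    for g in blob_sizes:
        dmax = _delta_max(charges, g)
        if dmax == 0:
            # composition cannot be segregated (e.g. all residues charged
            # with the same sign): patterning is undefined at this blob size
            continue
        ratios.append(_delta(charges, g) / dmax)
    if not ratios:
        raise UndefinedKappaError(
            "kappa undefined: composition admits no charge segregation"
        )
    return float(np.clip(np.mean(ratios), 0.0, 1.0))


def delta_max_bruteforce(charges: np.ndarray, blob: int) -> float:
    """Exhaustive-maximum delta over all distinct permutations.

    Exponential; intended as a test oracle for short sequences only.
    """
    if charges.size > 12:
        raise InputError("brute-force delta_max limited to length <= 12")
    best = 0.0
    for perm in set(permutations(charges.tolist())):
        best = max(best, _delta(np.array(perm, dtype=np.int8), blob))
    return best


# ---------------------------------------------------------------------------
# diagram of states
# ---------------------------------------------------------------------------

def phase_diagram_region(f_plus: float, f_minus: float) -> int:
    """Diagram-of-states region (1-5) from the charged fractions.

    Region 1: weak polyampholytes/polyelectrolytes (FCR < 0.25), globule or
    tadpole-like.  Region 2: boundary region (0.25 <= FCR <= 0.35,
    |NCPR| <= 0.35).  Region 3: strong polyampholytes (FCR > 0.35,
    |NCPR| <= 0.35), swollen coils.  Regions 4 and 5: strong negative
    (f- > 0.35) and positive (f+ > 0.35) polyelectrolytes with
    |NCPR| > 0.35.
    """
    ncpr, fcr = ncpr_fcr(f_plus, f_minus)
    if abs(ncpr) > 0.35:
        return 4 if f_minus > 0.35 else 5
    if fcr > 0.35:
        return 3
    if fcr >= 0.25:
        return 2
    return 1


# ---------------------------------------------------------------------------
# hydropathy and the charge-hydropathy plot
# ---------------------------------------------------------------------------

def hydropathy_mean(seq: ProteinSequence) -> float:
    """Mean Kyte-Doolittle hydropathy rescaled to the 0-9 scale
    (KD + 4.5 per residue, averaged)."""
    vals = [KYTE_DOOLITTLE[c] + 4.5 for c in seq.residues]
    return float(np.mean(vals))


@dataclass(frozen=True)
class CHPlotPoint:
    """A sequence's coordinates on the charge-hydropathy plot."""

    R: float             #: mean net charge |NCPR|
    H: float             #: normalized mean hydrophobicity in [0, 1]
    boundary: float      #: boundary hydropathy (R + 1.151)/2.785
    distance: float      #: boundary - H (positive on the disordered side)
    is_disordered: bool


def charge_hydropathy(
    seq: ProteinSequence, window: int = 5, his_charged: bool = False
) -> CHPlotPoint:
    """Charge-hydropathy plot coordinates and boundary call.

    H is the mean over ``window``-residue sliding windows of Kyte-Doolittle
    hydropathy rescaled to [0, 1]; the sequence is predicted disordered if
    H < (R + 1.151)/2.785.  ``distance`` is the vertical offset from the
    boundary (the boundary hydropathy minus H).
    """
    if seq.n < window:
        raise InputError(f"sequence shorter than the {window}-residue window")
    f_plus, f_minus = charged_fractions(seq, his_charged)
    r = abs(f_plus - f_minus)
    kd = np.array([(KYTE_DOOLITTLE[c] + 4.5) / 9.0 for c in seq.residues])
    win_means = np.convolve(kd, np.ones(window) / window, mode="valid")
    h = float(np.mean(win_means))
    boundary = (r + 1.151) / 2.785
    return CHPlotPoint(r, h, boundary, boundary - h, h < boundary)


# ---------------------------------------------------------------------------
# composition deviation
# ---------------------------------------------------------------------------

def composition_profile(seq: ProteinSequence) -> dict[str, float]:
    """Per-residue-type fractions CP_X (sums to 1)."""
    n = seq.n
    return {aa: seq.residues.count(aa) / n for aa in STANDARD_AA}


def composition_deviation(
    seq: ProteinSequence, reference: dict[str, float] | None = None
) -> pd.DataFrame:
    """Deviation D_X = (CP_X - CSP_X)/CSP_X from a reference composition.

    Returns a DataFrame indexed by residue with columns ``fraction``
    (CP_X), ``reference`` (CSP_X), ``deviation`` (D_X) and ``category``
    (disorder-promoting / order-promoting / neutral).
    """
    if reference is None:
        reference = reference_composition()
    cp = composition_profile(seq)
    rows = []
    for aa in STANDARD_AA:
        csp = reference.get(aa, 0.0)
        if csp <= 0:
            if cp[aa] > 0:
                raise InputError(
                    f"deviation undefined for {aa}: reference fraction is 0 "
                    f"but the sequence contains it"
                )
            dev = 0.0
        else:
            dev = (cp[aa] - csp) / csp
        cat = (
            "disorder-promoting" if aa in DISORDER_PROMOTING
            else "order-promoting" if aa in ORDER_PROMOTING
            else "neutral"
        )
        rows.append((aa, cp[aa], csp, dev, cat))
    return pd.DataFrame(
        rows, columns=["residue", "fraction", "reference", "deviation", "category"]
    ).set_index("residue")


# ---------------------------------------------------------------------------
# isoelectric point (convenience; pKa-set dependent)
# ---------------------------------------------------------------------------

_PKA = {  # EMBOSS pKa set
    "Cterm": 3.6, "Nterm": 8.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}


def isoelectric_point(seq: ProteinSequence, tol: float = 1e-4) -> float:
    """Isoelectric point by bisection on the Henderson-Hasselbalch net
    charge.  Provided as a convenience; the value depends on the pKa set
    (EMBOSS here) and is not meant to match any particular published table.
    """
    counts = {aa: seq.residues.count(aa) for aa in "CDEHKRY"}

    def net_charge(ph: float) -> float:
        q = 1.0 / (1.0 + 10 ** (ph - _PKA["Nterm"]))
        q -= 1.0 / (1.0 + 10 ** (_PKA["Cterm"] - ph))
        for aa in "HKR":
            q += counts[aa] / (1.0 + 10 ** (ph - _PKA[aa]))
        for aa in "CDEY":
            q -= counts[aa] / (1.0 + 10 ** (_PKA[aa] - ph))
        return q

    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargePatterningReport:
    """All sequence-level descriptors for one protein."""

    id: str
    N: int
    f_plus: float
    f_minus: float
    NCPR: float
    FCR: float
    kappa: float | None
    PDR: int
    hydropathy: float
    CH_R: float
    CH_H: float
    CH_distance: float

    def as_dict(self) -> dict:
        return asdict(self)


def analyze_sequence(
    seq: ProteinSequence,
    kappa_blobs=(5, 6),
    his_charged: bool = False,
) -> ChargePatterningReport:
    """Compute the full charge-patterning report for one sequence."""
    f_plus, f_minus = charged_fractions(seq, his_charged)
    ncpr, fcr = ncpr_fcr(f_plus, f_minus)
    try:
        k = kappa(seq, kappa_blobs, his_charged)
    except UndefinedKappaError:
        k = None
    ch = charge_hydropathy(seq, his_charged=his_charged)
    return ChargePatterningReport(
        id=seq.id,
        N=seq.n,
        f_plus=f_plus,
        f_minus=f_minus,
        NCPR=ncpr,
        FCR=fcr,
        kappa=k,
        PDR=phase_diagram_region(f_plus, f_minus),
        hydropathy=hydropathy_mean(seq),
        CH_R=ch.R,
        CH_H=ch.H,
        CH_distance=ch.distance,
    )
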