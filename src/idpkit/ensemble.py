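"""Coarse-grained ensemble optimization against a scattering curve.

Emulates the pool-then-select strategy used for disordered proteins: a
large pool of random-coil Cα-trace conformers is generated by self-avoiding
chain growth, a coarse-grained Debye scattering curve is computed for each
conformer, and a genetic algorithm picks a small sub-ensemble (a multiset
of at most ``max_ensemble`` conformers, 50 by default) whose average curve
minimizes chi^2 against the target.  Comparing the Rg distribution of the
selected sub-ensemble with that of the unselected pool reveals whether the
scattering data demand particular chain dimensions — e.g. a bimodal
selected distribution from a two-population sample.

This is a residue-level emulation of atomistic pool generators: conformers
are Cα traces with a 3.8 Å virtual bond, a coil-like bond-angle
distribution and hard-sphere excluded volume, not all-atom models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, FitError
from .saxs import ScatteringCurve

CA_BOND_LENGTH = 3.8       #: Å, consecutive Cα-Cα distance
EXCLUDED_RADIUS = 4.0      #: Å, hard-sphere clash distance (non-adjacent)

#: Bond-angle (mean, sd) presets in degrees; "coil" reproduces Flory-like
#: dimensions for disordered chains, the others give deliberately compact
#: or expanded pools for two-population experiments.
ANGLE_PRESETS = {
    "coil": (120.0, 25.0),
    "compact": (95.0, 15.0),
    "expanded": (150.0, 12.0),
}


@dataclass(frozen=True)
class Conformer:
    """A Cα-trace conformer."""

    coords: np.ndarray  #: (N, 3) array, Å

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def rg(self) -> float:
        c = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((c**2).sum(axis=1).mean()))


def _grow_chain(n, rng, angle_mean, angle_sd, bond, r_ex, step_attempts=60):
    pts = np.zeros((n, 3))
    pts[1] = (bond, 0.0, 0.0)
    for i in range(2, n):
        prev = pts[i - 1] - pts[i - 2]
        u = prev / np.linalg.norm(prev)
        t = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        v = np.cross(u, t)
        v /= np.linalg.norm(v)
        w = np.cross(u, v)
        for _ in range(step_attempts):
            theta = np.deg2rad(rng.normal(angle_mean, angle_sd))
            phi = rng.uniform(0.0, 2.0 * np.pi)
            d = np.cos(np.pi - theta) * u + np.sin(np.pi - theta) * (
                np.cos(phi) * v + np.sin(phi) * w
            )
            new = pts[i - 1] + bond * d
            diff = pts[: i - 1] - new
            if np.min(np.einsum("ij,ij->i", diff, diff)) < r_ex**2:
                continue
            pts[i] = new
            break
        else:
            return None
    return pts


def generate_pool(
    n_residues: int,
    n_conformers: int,
    seed: int,
    angle_mean: float | None = None,
    angle_sd: float | None = None,
    preset: str = "coil",
    bond_length: float = CA_BOND_LENGTH,
    excluded_radius: float = EXCLUDED_RADIUS,
    max_regrow: int = 1000,
) -> list[Conformer]:
    """Generate a pool of self-avoiding random-coil Cα conformers.

    Chains are grown residue by residue with fixed bond length, bond angle
    drawn from a normal distribution (``preset`` or explicit
    ``angle_mean``/``angle_sd``), uniform dihedral, and hard-sphere
    excluded volume between non-adjacent residues; a chain that cannot be
    extended is regrown from scratch.  Deterministic for a fixed seed.
    """
    if n_residues < 10:
        raise InputError("n_residues must be >= 10")
    pm, ps = ANGLE_PRESETS.get(preset, ANGLE_PRESETS["coil"])
    if angle_mean is None:
        angle_mean = pm
    if angle_sd is None:
        angle_sd = ps
    rng = np.random.default_rng(seed)
    pool = []
    for _ in range(n_conformers):
        for attempt in range(max_regrow):
            pts = _grow_chain(
                n_residues, rng, angle_mean, angle_sd, bond_length, excluded_radius
            )
            if pts is not None:
                pool.append(Conformer(pts))
                break
        else:
            raise FitError(
                f"chain regrow failed {max_regrow} times; "
                "consider a smaller excluded radius"
            )
    return pool


# ---------------------------------------------------------------------------
# Debye scattering
# ---------------------------------------------------------------------------

def debye_curve(
    conformer: Conformer | np.ndarray,
    q: np.ndarray,
    sigma_f: float = 3.0,
) -> ScatteringCurve:
    """Coarse-grained Debye scattering curve of a single conformer.

    I(q) = f(q)^2 * sum_ij sin(q r_ij)/(q r_ij) with a Gaussian
    dummy-residue form factor f(q) = exp(-q^2 sigma_f^2 / 2); the
    intensity is normalized so that I(0) = N^2.
    """
    coords = conformer.coords if isinstance(conformer, Conformer) else np.asarray(conformer, float)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise InputError("q must be positive")
    n = coords.shape[0]
    if n == 1:
        intensity = np.exp(-(q**2) * sigma_f**2)
        return ScatteringCurve(q, intensity, label="debye")
    diff = coords[:, None, :] - coords[None, :, :]
    rij = np.sqrt((diff**2).sum(axis=-1))
    iu, ju = np.triu_indices(n, k=1)
    d = rij[iu, ju]
    # sum over ordered pairs = N (diagonal) + 2 * upper triangle
    sinc = np.sinc(np.outer(q, d) / np.pi)
    intensity = (n + 2.0 * sinc.sum(axis=1)) * np.exp(-(q**2) * sigma_f**2)
    return ScatteringCurve(q, intensity, label="debye")


def pool_curves(
    pool: list[Conformer], q: np.ndarray, sigma_f: float = 3.0
) -> np.ndarray:
    """Stack of Debye curves for a pool, shape (n_conformers, len(q))."""
    return np.vstack([debye_curve(c, q, sigma_f).intensity for c in pool])


def chi_squared(i_calc: np.ndarray, curve: ScatteringCurve):
    """Reduced chi^2 of a calculated curve against a measured one.

    chi^2 = (1/(K-1)) * sum_k ((mu*I_calc_k - I_k)/sigma_k)^2 with the
    scale factor mu determined in closed form by least squares.  Returns
    ``(chi2, mu)``.
    """
    i_calc = np.asarray(i_calc, dtype=float)
    if i_calc.shape != curve.q.shape:
        raise InputError("calculated curve does not match the target q grid")
    if curve.q.size < 2:
        raise InputError("need at least 2 points for chi^2")
    w2 = curve.weights() ** 2
    mu = float(np.sum(w2 * i_calc * curve.intensity) / np.sum(w2 * i_calc**2))
    chi2 = float(np.sum(w2 * (mu * i_calc - curve.intensity) ** 2) / (curve.q.size - 1))
    return chi2, mu


# ---------------------------------------------------------------------------
# genetic-algorithm sub-ensemble selection
# ---------------------------------------------------------------------------

@dataclass
class EnsembleFit:
    """Result of a sub-ensemble selection run."""

    indices: np.ndarray          #: selected conformer indices (multiset)
    chi2: float
    mu: float
    pool_rg: np.ndarray          #: Rg of every pool conformer
    selected_rg: np.ndarray      #: Rg of the selected multiset (with repeats)
    converged: bool
    generations_run: int
    history: np.ndarray = field(repr=False, default=None)

    @property
    def n_distinct(self) -> int:
        return np.unique(self.indices).size


def ga_select(
    curves: np.ndarray,
    target: ScatteringCurve,
    pool_rg: np.ndarray,
    max_ensemble: int = 50,
    generations: int = 300,
    population: int = 100,
    mutation_rate: float = 0.05,
    elitism: int = 2,
    tournament: int = 3,
    patience: int = 50,
    seed: int = 0,
) -> EnsembleFit:
    """Select a sub-ensemble whose average curve best fits the target.

    Individuals are multisets of ``max_ensemble`` conformer indices
    (repetition allowed, so effective ensembles of any size up to
    ``max_ensemble`` are reachable); fitness is the negative reduced
    chi^2 of the multiset-average curve.  Tournament selection,
    single-point crossover, per-gene mutation and elitism; the initial
    population is seeded with the best single conformers so the selected
    ensemble can never fit worse than the best individual conformer.
    Deterministic for a fixed seed.
    """
    curves = np.asarray(curves, dtype=float)
    n_pool = curves.shape[0]
    if n_pool < max_ensemble:
        raise InputError("pool smaller than the maximum ensemble size")
    rng = np.random.default_rng(seed)

    def fitness(pop_idx: np.ndarray) -> np.ndarray:
        avg = curves[pop_idx].mean(axis=1)
        out = np.empty(pop_idx.shape[0])
        for i, row in enumerate(avg):
            out[i], _ = chi_squared(row, target)
        return out

    # greedy seeding: rank single conformers by chi^2
    singles = np.array([chi_squared(curves[i], target)[0] for i in range(n_pool)])
    order = np.argsort(singles)
    pop = rng.integers(0, n_pool, size=(population, max_ensemble))
    n_seed = min(10, population)
    for k in range(n_seed):
        pop[k] = order[k % n_pool]

    chi = fitness(pop)
    best_chi = np.inf
    best_ind = pop[0].copy()
    stall = 0
    history = []
    gen = 0
    for gen in range(1, generations + 1):
        gen_best = chi.argmin()
        if chi[gen_best] < best_chi - 1e-12:
            best_chi = float(chi[gen_best])
            best_ind = pop[gen_best].copy()
            stall = 0
        else:
            stall += 1
        history.append(best_chi)
        if stall >= patience:
            break
        # tournament selection
        contenders = rng.integers(0, population, size=(population, tournament))
        winners = contenders[np.arange(population), chi[contenders].argmin(axis=1)]
        parents = pop[winners]
        # single-point crossover on consecutive pairs
        children = parents.copy()
        for a in range(0, population - 1, 2):
            cut = rng.integers(1, max_ensemble)
            children[a, cut:], children[a + 1, cut:] = (
                parents[a + 1, cut:].copy(), parents[a, cut:].copy(),
            )
        # mutation
        mutate = rng.random(children.shape) < mutation_rate
        children[mutate] = rng.integers(0, n_pool, size=mutate.sum())
        # elitism: best individuals survive unchanged
        elite_idx = np.argsort(chi)[:elitism]
        children[:elitism] = pop[elite_idx]
        pop = children
        chi = fitness(pop)

    converged = stall >= patience or gen == generations
    if not converged:
        warnings.warn("GA terminated without convergence", stacklevel=2)
    chi2, mu = chi_squared(curves[best_ind].mean(axis=0), target)
    return EnsembleFit(
        indices=np.sort(best_ind),
        chi2=chi2,
        mu=mu,
        pool_rg=np.asarray(pool_rg, dtype=float),
        selected_rg=np.asarray(pool_rg, dtype=float)[np.sort(best_ind)],
        converged=converged,
        generations_run=gen,
        history=np.array(history),
    )


# ---------------------------------------------------------------------------
# Rg distributions and bimodality
# ---------------------------------------------------------------------------

def detect_bimodality(
    hist: np.ndarray, valley_depth: float = 0.2, smooth: bool = True
) -> tuple:
    """Two-peak detection on a histogram.

    Returns ``(is_bimodal, peak_bin_indices)``.  The histogram is bimodal
    when two local maxima are separated by a valley at least
    ``valley_depth`` (fraction) below both peaks.  A light 1-2-1 smoothing
    pass (default on) suppresses single-bin sampling noise; peak pairs are
    examined from the tallest down, so the reported modes are the two
    dominant peaks, not incidental wiggles.
    """
    hist = np.asarray(hist, dtype=float)
    work = hist
    if smooth and hist.size >= 3:
        work = np.convolve(hist, [0.25, 0.5, 0.25], mode="same")
    peaks = [
        i for i in range(len(work))
        if work[i] > 0
        and (i == 0 or work[i] >= work[i - 1])
        and (i == len(work) - 1 or work[i] >= work[i + 1])
        and not (i > 0 and work[i] == work[i - 1])  # plateau: keep left edge
    ]
    # examine pairs from the tallest down
    for a, b in sorted(
        ((a, b) for ai, a in enumerate(peaks) for b in peaks[ai + 1:]),
        key=lambda ab: -(work[ab[0]] + work[ab[1]]),
    ):
        valley = work[a : b + 1].min()
        lo = min(work[a], work[b])
        if lo > 0 and valley <= (1.0 - valley_depth) * lo:
            return True, (a, b)
    return False, ()


def rg_distribution(
    fit: EnsembleFit,
    bins: np.ndarray | None = None,
):
    """Pool and selected-ensemble Rg histograms plus a bimodality flag.

    Returns ``(bin_edges, pool_hist, selected_hist, is_bimodal, modes)``.
    When the selected distribution is bimodal, ``modes`` are the mass
    centers (mean selected Rg) of the two components split at the valley
    between the detected peaks — a far more stable location estimate for
    a 50-member multiset than the raw maximum bin.  Histograms are
    density-normalized.
    """
    if bins is None:
        lo = np.floor(min(fit.pool_rg.min(), 15.0) / 2.5) * 2.5
        hi = np.ceil(max(fit.pool_rg.max(), 80.0) / 2.5) * 2.5
        bins = np.arange(lo, hi + 2.5, 2.5)
    pool_hist, edges = np.histogram(fit.pool_rg, bins=bins, density=True)
    sel_hist, _ = np.histogram(fit.selected_rg, bins=bins, density=True)
    flag, peak_idx = detect_bimodality(sel_hist)
    modes: tuple = ()
    if flag:
        i, j = peak_idx
        valley = i + int(np.argmin(sel_hist[i : j + 1]))
        split = (edges[valley] + edges[valley + 1]) / 2.0
        low = fit.selected_rg[fit.selected_rg <= split]
        high = fit.selected_rg[fit.selected_rg > split]
        if low.size and high.size:
            modes = (float(low.mean()), float(high.mean()))
        else:
            centers = (edges[:-1] + edges[1:]) / 2.0
            modes = tuple(float(centers[p]) for p in peak_idx)
    return edges, pool_hist, sel_hist, flag, modes


# ---------------------------------------------------------------------------
# pool serialization (multi-model Cα PDB + sidecar Rg table)
# ---------------------------------------------------------------------------

def save_pool_pdb(pool: list[Conformer], path) -> None:
    """Write a pool as a multi-model PDB of Cα records."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = pool[0].n_residues
    arrays = []
    for conf in pool:
        atoms = struc.AtomArray(n)
        atoms.coord = conf.coords.astype(np.float32)
        atoms.chain_id = np.full(n, "A")
        atoms.res_id = np.arange(1, n + 1)
        atoms.res_name = np.full(n, "GLY")
        atoms.atom_name = np.full(n, "CA")
        atoms.element = np.full(n, "C")
        arrays.append(atoms)
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def load_pool_pdb(path) -> list[Conformer]:
    """Read a multi-model Cα PDB back into a conformer pool."""
    from biotite.structure.io.pdb import PDBFile

    stack = PDBFile.read(str(path)).get_structure()
    return [Conformer(np.asarray(stack[i].coord, dtype=float))
            for i in range(stack.stack_depth())]
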