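# Methods

This note records the models implemented in idpkit, the defaults and why
they were chosen, the numerical choices that matter, and what the
synthetic-data validation does and does not establish.

## Sequence descriptors

Charges at pH 7 are K, R (+1) and D, E (−1); histidine is neutral by
default (pKa ≈ 6.5), with `his_charged=True` available for acidic-pH work.
All charge fractions are per-residue over the full chain.

**κ (charge patterning).** For blob sizes g = 5 and 6, every full window
of g residues (stride 1; no partial terminal blobs) contributes an
asymmetry σ = (f⁺ − f⁻)²/(f⁺ + f⁻) (0 for chargeless blobs);
δ_g is the mean squared deviation of blob asymmetries from the
whole-chain asymmetry, normalized by δ_g of a maximally charge-segregated
permutation of the same composition, and κ is the mean of the two ratios,
clipped to [0, 1]. The normalizing permutation is built deterministically
from three canonical block orders (pos|neu|neg, pos|neg|neu, neu|pos|neg),
taking the largest δ. This is the field convention, not the true
permutation maximum: with neutral residues present, full-window blob
decomposition underweights chain termini, so arrangements with
interior-placed charge blocks (e.g. AKKAAEEA vs KKAAAAEE at g = 3) — or,
when g approaches the chain length, end-split arrangements (KEEEEK) — can
exceed the canonical construction. The [0, 1] clip absorbs this
finite-size effect; for realistic chain lengths (N ≳ 50, g = 5–6) it is
negligible.

**Diagram of states.** Regions are assigned in order: |NCPR| > 0.35 →
region 4 (f⁻ > 0.35) or 5 (f⁺ > 0.35); FCR > 0.35 → region 3 (strong
polyampholyte, swollen coils); 0.25 ≤ FCR ≤ 0.35 → region 2 (boundary);
otherwise region 1 (weak polyampholytes/polyelectrolytes, globules and
tadpoles). Evaluating the high-|NCPR| and high-FCR conditions first makes
the regions disjoint.

**Charge–hydropathy plot.** R = |NCPR|; H is the mean over 5-residue
sliding windows of Kyte–Doolittle hydropathy rescaled to [0, 1] as
(KD + 4.5)/9; a chain is predicted disordered when H < (R + 1.151)/2.785.
The reported CH-distance is the vertical offset (boundary − H); the
perpendicular distance to the boundary line would be a factor
1/√(1 + 2.785⁻²) smaller and the two conventions cannot be told apart at
two published decimal places, so the simpler one is used and stated here.
The tabulated hydropathy column is the unwindowed mean of (KD + 4.5)
(0–9 scale).

**Composition deviation** uses a frozen SWISS-PROT average-composition
table shipped as package data (the live database drifts between
releases); D_X = (CP_X − CSP_X)/CSP_X, with the disorder-promoting set
{A,G,R,D,H,Q,K,S,E,P} and order-promoting set {W,F,Y,I,M,L,V,C,T}
flagged. The isoelectric-point helper (bisection on
Henderson–Hasselbalch sums, EMBOSS pKa set) is a convenience only; pI is
strongly pKa-set dependent and is not validated against any published
table.

## Low-complexity segmentation

Complexity is Shannon entropy of the window composition in bits/position.
Windows of W = 12 at or below the trigger threshold K1 = 2.2 seed
segments; maximal runs of overlapping windows at or below the extension
threshold K2 = 2.5 are absorbed; overlapping runs merge. The original
algorithm's final optimal-subsequence refinement (P0 minimization) is
omitted — segment counts and approximate spans are the quantities this
package reports, and boundaries may differ from canonical SEG output by a
couple of residues at each end. Coordinates are 1-based inclusive; BED
export converts to 0-based half-open.

## Hydrodynamics

All logarithms are base 10; only then do the printed power-law
coefficients reproduce published Stokes-radius tables at 0.1 Å. The
per-state laws are

    log Rs(std)  = 0.369 log MM − 0.254
    log Rs(NF)   = 0.357 log MM − 0.204
    log Rs(MG)   = 0.334 log MM − 0.053
    log Rs(PMG)  = 0.392 log MM − 0.210
    log Rs(U)    = 0.521 log MM − 0.649
    Rs(DimNF)    = Rs(NF) at 2·MM
    Rs(IDP)      = 2.49 · N^0.509

with MM in Da, Rs in Å. These lines do not cross for MM in the
5–100 kDa working range, so NF < MG < PMG < U ordering is guaranteed
there. CI = (Rsᵁ − Rsᵒᵇˢ)/(Rsᵁ − Rsᴺᶠ) is returned unclamped, with a
warning outside [0, 1]. Nearest-state classification takes the state
whose Rsᵒᵇˢ/Rs ratio is closest to 1, breaking exact ties toward the more
compact state and reporting all tied states. The IDP law uses the residue
count of the measured construct (tags included), since that is the
species in the column; the count used is echoed in every report. Reports
round radii to 0.1 Å; full precision is kept internally.

SEC calibration fits log₁₀ Rs (derived from standard masses via the
standards law) linearly against elution volume by ordinary least squares;
≥ 3 standards are required, residuals are exposed, and queries outside
the calibrated volume range warn about extrapolation.

## SAXS

The internal momentum-transfer unit is Å⁻¹ (q = 4π/λ · sin θ). File
readers auto-detect nm⁻¹ input (q_max > 1.5 suggests nm⁻¹), divide by 10
and record the conversion; an explicit unit flag overrides the heuristic.

**Guinier.** The fit window grows from the lowest usable q while
q·Rg ≤ 1.3 (the default; some practitioners prefer 1.0, exposed as a
flag), iterating until window and Rg are mutually consistent; weights are
1/σ of ln I. A pure linear fit of ln I on q² carries 2–7% systematic bias
at q·Rg = 1.3 on sphere and Gaussian-coil oracles because the true curve
is not exactly Gaussian inside the window; the default fit therefore adds
a q⁴ column that absorbs the leading correction (Rg is always read off
the q² coefficient), reducing the bias below 0.3% on both oracles.
`curvature_correction=False` restores the textbook two-parameter fit.
A window that shows no decay is widened before a "non-Guinier curve"
error is raised, so a handful of noisy low-q points cannot fail the fit.

**P(r) by regularized IFT.** P(r) is expanded in `ceil(Dmax·q_max/π) + 5`
sine functions on [0, Dmax] (endpoint zeros automatic); coefficients come
from penalized weighted least squares against I(q) through the kernel
sin(qr)/(qr), with the smoothness penalty ∫P″² (diagonal in the sine
basis). The regularization weight is chosen at the maximum-curvature
point of the L-curve, restricted to solutions whose misfit is within a
factor 4 of the best achievable. Rg and I(0) follow from moments of
P(r). Curves without uncertainties get uniform weights and a warning.

**Automatic Dmax.** A Dmax grid (2.2–4.5 × Guinier Rg) is scanned; a
candidate must reproduce the Guinier Rg within 2% with P(r) non-negative
to within 5% of its maximum. Taking simply the smallest such Dmax
truncates the P(r) tail (on sphere oracles it lands ~7% below the true
diameter while still passing the 2% band), so the selected Dmax is the
smallest passing value at the onset of the Rg plateau — one further grid
step changes Rg_pr by < 0.2%. Sphere oracles then recover Dmax = 2R
within ~3%. At low signal-to-noise (≲ 50) the Guinier Rg itself scatters
by several percent and the agreement criterion may find no candidate; the
IFT with a user-fixed Dmax remains accurate there.

**Shape diagnostics.** The Porod classifier estimates log-log slopes in
sliding windows (a quarter-decade wide) above q = 0.1 Å⁻¹ and reports
"globular-like" if any window reaches slope ≤ −3.5 (Porod's q⁻⁴ law for a
sharp interface), else "no sharp interface" (Gaussian coils tend to −2).

**Expected sizes.** Flory coil Rg = 2.54·N^0.522 Å; globular
Rg = √(3/5)·4.75·N^0.29 Å (the √ applies to 3/5 only — the alternative
reading is inconsistent with the values this law is known to produce);
unfolded log Rg = 0.58·log N + 0.80; sphere-equivalent radius
(3N·134 Å³ / 4π)^{1/3} with Rg = √(3/5)·radius; and Rg = √(3/5)·Rs for a
globule of known Stokes radius.

## Ensemble optimization

This stage is a residue-level emulation of atomistic pool-generator +
genetic-selection workflows; it is built for distributional conclusions
(does the data demand particular chain dimensions? one population or
two?), not atomic accuracy.

**Conformers** are Cα traces: bond length 3.8 Å, bond angle drawn from a
normal distribution, uniform dihedrals, hard-sphere excluded volume of
4.0 Å between non-adjacent residues, grown sequentially with rejection
and whole-chain regrowth (error after 1,000 failed regrowths). Angle
presets: coil (120° ± 25°) reproduces Flory-scale dimensions (mean pool
Rg ≈ 31–32 Å at N = 143, within 25% of the 33.9 Å power-law value);
compact (95° ± 15°, mean Rg ≈ 26 Å) and expanded (150° ± 12°, mean
Rg ≈ 58 Å) exist for two-population experiments. These presets were
calibrated once against the Flory law and are not adjusted per dataset.

**Scattering** is the exact Debye double sum with a Gaussian
dummy-residue form factor exp(−q²σ_f²/2), σ_f = 3 Å, normalized to
I(0) = N². The form factor adds 3σ_f² to the apparent Guinier Rg² — a
1–2% effect at production chain sizes, visible for very short chains.

**Selection.** Individuals are multisets of exactly `max_ensemble` (50)
pool indices, so effective ensembles of any size up to 50 are reachable
through repetition. Fitness is the reduced χ² of the multiset-average
curve with the closed-form least-squares scale factor. Tournament
selection (size 3), single-point crossover, per-gene mutation at 0.05,
elitism of 2, population 100, up to 300 generations with a 50-generation
patience window; the initial population is seeded with the best single
conformers, which guarantees the final χ² never exceeds the best
single-conformer χ². These GA hyperparameters are this package's own
defaults; published ensemble-selection tools do not document theirs.
Everything is deterministic under a fixed seed.

**Bimodality.** Rg histograms use 2.5 Å bins over [15, 80] Å. Two-peak
detection runs on a lightly smoothed (1-2-1 kernel) histogram and flags
bimodality when two local maxima are separated by a valley ≥ 20% below
both; peak pairs are examined from the tallest down. The reported mode
locations are the mass centers of the two components split at the valley
— for a 50-member multiset this is far more stable than the raw maximum
bin, whose position over a broad component wanders by tens of percent
between GA seeds.

## Circular dichroism

MRE conversion is Θ = 3300·M·ΔA/(l·c·n) (l in cm, c in mg/mL, M in Da,
n residues). Helicity is MRE₂₂₀ divided by the chain-length-corrected
100%-helix value −40,000·(1 − 2.5/n); both coefficients are configurable
because conventions (220 vs 222 nm, −36,000 to −40,000) vary across the
literature, and results are clipped to [0, 1] with a warning. The
200/222 nm classifier assigns a point to the nearer of two literature
consensus centroids — RC-like (−18,900, −1,700) and PMG-like
(−10,700, −3,900) deg·cm²·dmol⁻¹ — with axes scaled by the within-class
spreads; points whose two distances differ by < 5% are labelled
"boundary".

Thermal melts are fitted to the four-parameter Boltzmann sigmoid
S(T) = A + (B − A)/(1 + exp((Tm − T)/s)) by Levenberg–Marquardt with
data-driven starting values; fits whose transition amplitude is below
three residual standard deviations (flat curves) raise an error rather
than returning a meaningless midpoint, and a quality flag marks fits
explaining < 90% of the variance.

The isodichroic-point detector restricts candidates to wavelengths whose
±10 nm neighbourhood shows substantial across-spectra spread, takes the
minimum of the across-spectra standard deviation there, requires it below
5% of the overall signal range, and additionally requires the most
different pair of spectra to swap order across the candidate (the
sign-flip test). The last condition is what distinguishes a true crossing
from a wavelength where the family merely converges — minimum-variance
alone produces false positives in long-wavelength tails where all spectra
approach zero together.

## Synthetic data and what the tests show

Every generator is deterministic under its seed and embeds its ground
truth. Noise is Gaussian throughout; scattering noise uses
σ(q) = I(q)/SNR · (1 + q/q_max) so relative error grows toward high
angles, as in real detectors. Defaults mirror the experimental regime the
package targets: SEC calibrations spanning ~12–440 kDa, q ranges of
0.003–0.45 Å⁻¹, melt curves over 20–80 °C with a ~51 °C midpoint, CD
families crossing near 205 nm, ASR1-like sequence compositions (Glu-rich,
E+A+H+K+G ≈ 68%).

The generators deliberately omit instrument artifacts: no radiation
damage, aggregation tails, capillary fouling, buffer-subtraction errors,
detector dead zones, or CD dynode-voltage cutoffs. Passing the test suite
therefore establishes that the estimators recover known ground truth
under well-behaved noise — the inverse-problem machinery is correct — not
that the pipeline is robust to pathological real-world data, which still
requires the usual visual diagnostics (Guinier residuals, P(r) shape,
fit-quality flags) that every result object exposes.

The two-population experiment (compact + expanded pools of 1,000
conformers each at N = 143, a 50/50 mixture target at SNR 200, three GA
seeds) is run at a deliberately reduced pool size relative to
production-scale ensemble work (10,000 conformers) to keep the validation
suite fast; recovery of bimodality and of both component locations within
15% is stable across seeds at this scale, and cross-seed selected-Rg
distributions overlap ≥ 0.9 (kernel-density estimate).

## Known limitations

* SEG boundaries are trigger/extension spans, not P0-refined optima.
* The CH-distance convention (vertical offset) is one of two plausible
  readings of the published boundary; both fit the available precision.
* `auto_dmax` requires a trustworthy Guinier Rg and so degrades below
  SNR ≈ 50; fix Dmax manually there.
* The ensemble stage's χ² values are comparable within a pool but not
  calibrated against atomistic form-factor calculations.
* pI values are pKa-set dependent and intentionally unvalidated.
* No 3-D shape reconstruction, no atomistic curve prediction, no CD
  spectral deconvolution — these remain the territory of the established
  dedicated tools.
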