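# Methods

This note documents the models behind `scandose`, the parameters that
matter, the synthetic-data assumptions, and the design choices made where
the design was genuinely open.

## Kinetic model and TIAC rescaling

Organ kinetics are sums of exponentials per source region, with a fixed
source vocabulary: right kidney, left kidney, spleen, liver, red bone
marrow (RBM), and remainder (rest of body). The central assumption is
that the biological clearance of the DOTATATE vector does not depend on
the radiolabel, so a lutetium-177 curve determines the curve for any
other label once physical decay is exchanged (`strip_physical_decay` /
`apply_physical_decay`). TIACs are computed analytically term by term
(Σ A_j/λ_j); `integrate_tiac` rejects non-decaying terms as divergent.

Two rescaling routes coexist deliberately:

* the **ratio rule**, TIAC_PR = TIAC_Lu · T_PR/T_Lu, which is the method
  used to produce per-nuclide TIAC tables in practice and is exact only
  when the biological curve is constant;
* **exact integration** of the re-decayed biological curve, which for a
  clearing biology and a shorter-lived target always gives a *larger*
  TIAC than the ratio rule, since (λ_b+λ_ref)/(λ_b+λ_tgt) > λ_ref/λ_tgt.

`rescale_diagnostic` reports the per-region gap; the property suite
asserts the inequality over randomized curves. The bundled reference
TIAC table is itself not perfectly self-consistent under the ratio rule
with the stated half-lives: regenerating it reproduces the scandium-44
column within 0.15%, while the scandium-43, gallium-68 and scandium-44m
columns carry residuals up to about 7% (they are consistent with slightly
different reference half-lives). The package reproduces each column from
the stated half-lives (Sc-43 3.89 h, Sc-44 4.04 h, Sc-44m 58.7 h,
Ga-68 68 min, Lu-177 6.64 d) and writes a residual report rather than
guessing which constants the table's authors actually used.

### Bi-exponential fitting

Three acquisition times (4, 24, 168 h) cannot determine four free
parameters, so `fit_biexponential` accepts the normalised uptake at t=0
(`amplitude_sum`) as a known constraint, reducing the problem to three
parameters; the administered activity and injected fraction are known
quantities of the study design, so this is information the analyst has.
Residuals are taken in log space (measurements are positive with
multiplicative noise), optimised by Levenberg–Marquardt from a
deterministic multi-start ladder of slow/fast half-life guesses, with
seeded jittered restarts; three-point fits are ill-conditioned and the
deterministic start set keeps results reproducible. Non-convergence
raises an error carrying the best residual.

## Decay data

Each nuclide carries one emission line per radiation class: yield per
decay and mean energy (MeV). Beta spectra are represented by their mean
energy only, matching the information content of summary decay tables
and the local-deposition transport contract. The curated fixture file
corrects three print-corrupted cells (noted line by line in its
provenance column); the lutetium-177 X-ray yield correction (1.4E+00) is
flagged for verification against the primary decay-data compilation
rather than asserted as ground truth. The loader validates, never
repairs. Annihilation-photon lines must agree with 511 keV within table
rounding, and for the positron emitters the curated annihilation yields
are consistent with twice the β⁺ yields within 5%. Unit constants
(MeV→J = 1.602176634E−13; 1 MBq·h = 3.6E9 decays) are defined once.

## Voxel phantom Monte Carlo

The transport model is a deliberate desk-scale simplification, not a
replication of production Monte Carlo codes:

* **Charged particles** (β±, conversion and Auger electrons) deposit
  their full mean energy in the decay voxel's region — electron ranges
  are sub-voxel at the 4–12 mm voxels used here. Positron range is
  neglected; annihilation photons are a separate emission line emitted
  from the origin voxel, so no extra 2× bookkeeping is introduced.
* **Photons** (γ, X, annihilation) undergo analog transport: free paths
  are sampled against optical depth accumulated along an axis-aligned
  voxel traversal (path lengths in mass-attenuation units, so density
  varies per voxel); interactions split between photoelectric absorption
  (full local deposit) and incoherent scatter with Klein–Nishina
  sampling (Compton electron deposited at the interaction voxel);
  photons at or below the 50 keV cutoff deposit locally; leaving the
  grid is escape. Coherent scatter and pair production are omitted: the
  highest photon energy in scope is 1.2 MeV, below the practical
  pair-production threshold, and coherent scatter deposits no energy.
* **Attenuation data** are water-equivalent: incoherent cross-sections
  from the Klein–Nishina formula times the electron density of water,
  photoelectric absorption as an E⁻³ heuristic anchored near the
  tabulated 100 keV value, on a log-log-interpolated 48-point grid from
  10 keV to 2 MeV. All tissues share these mass coefficients and differ
  only by density; tissue-specific tables are a configuration extension
  point (`AttenuationTable`).

Decay origins are sampled per unit mass (voxel probability ∝ voxel
mass, uniform position within the voxel); for composite source regions
this reproduces the mass-weighted split, and remainder decays are
distributed uniformly per unit mass over the whole remainder region.
Energy bookkeeping is exact per history — Compton losses are computed as
E − E′ — so Σφ + escape = 1 to round-off, which the table constructor
asserts at 1e−9.

Each history owns a splitmix64 stream keyed by (global seed, history
index), so results are reproducible for a given seed and history count
and independent of execution order. Per-entry relative standard errors
come from history-level variance; `estimate_uncertainty` reports entries
above a threshold (5% is the conventional check). Default history counts
in the tests and acceptance script are 10³–10⁵ per emission line: at
these sizes self-dose fractions resolve well below 5% relative error and
a full six-source scandium-44 chain runs in seconds on one core, which
is the intended scale of this simulator. Validation rests on closed
forms and statistics rather than physics fidelity: the central-source
sphere in absorption-only mode against 1 − e^{−μR} (using the effective
radius of the voxelised sphere to remove discretisation bias), 1/√N
error scaling, seed invariance within statistics, and agreement of two
independent runs within combined uncertainties — an internal stand-in
for the cross-code comparisons used with production Monte Carlo.

## Dose assembly

S-values are additive over emission lines and converted so one MBq·h of
TIAC equals 3.6E9 decays (Y=1, E=1 MeV, φ=1 into 1 kg gives
5.768E−4 Gy/(MBq·h)). Doses are AD/IA = Σ_S TIAC·S. Left and right
kidneys are separate sources and targets; a combined "kidneys" dose is
reported as their mass-weighted mean. Effective dose uses the ICRP 103
tissue weighting factors (bundled as a data fixture, sum checked to 1);
w_R = 1 for every emission class in scope, so equivalent dose equals
absorbed dose numerically. Because a four-organ + remainder source model
cannot populate all named tissues, tissues without an explicit dose
inherit the remainder region's dose; effective doses are computed per
phantom (no sex averaging), and labelled as per-phantom coefficients.
Uncertainty propagation is first-order with independent absorbed-fraction
errors; TIACs are treated as exact, so reported dose uncertainties
reflect Monte Carlo statistics only.

The simplified phantom and physics mean absolute organ-dose coefficients
from the internal Monte Carlo are *not* expected to reproduce
reference-phantom values; published per-phantom effective-dose
coefficients are bundled as inputs for the mixture analysis, which keeps
the mixture arithmetic independent of transport fidelity.

## Mixtures

"Scandium-44m at p% of scandium-44" is read as activity fractions
f·(1−p) and f·p of the scandium-44 share at administration time, balance
scandium-43 — a 15% impurity of a pure scandium-44 sample is an 85/15
split. This interpretation reproduces the published 100 MBq totals; the
additive reading (100:15 renormalised) does not. The impurity share is
capped at 15%, the worst-case production scenario. No decay-chain
in-growth is modelled: coefficients are fixed per-nuclide properties
mixed linearly at administration time. The default scan grid is the
11 × 16 composition table (scandium-44 share 0–100% step 10%, impurity
0–15% step 1%). The impurity diagnostic with the bundled male rounded
coefficients evaluates to ≈8.4% (female ≈6.8%); a published figure of
8.1% is not exactly recoverable from rounded coefficients and is likely
based on unrounded values — recorded here, not forced.

## Synthetic data

`generate_tac_dataset` draws, per region, a two-term biological curve
whose dominant effective half-life (biological + lutetium-177 physical)
is uniform in 50–80 h — the range reported for parenchymal organs in
lutetium-177 DOTATATE therapy — plus a faster washout component (2–10 h
half-life, 10–30% of the uptake). Default uptake is instantaneous
(positive amplitudes), the regime in which ratio rescaling is exact; an
optional uptake-phase mode adds a negative-amplitude 1 h term to
exercise the rescaling bias. Sampling uses the 4/24/168 h schedule with
multiplicative log-normal noise (default 5% relative sd, mean-one
parameterisation). What passing tests show is therefore recovery under
the model's own assumptions: real patient data add biodistribution
differences between tracers, segmentation error and non-exponential
phases that the generator does not emulate.

`generate_phantom` builds a water ellipsoidal body (default half-extents
16 × 12 × 28 cm, 8 mm voxels) with non-overlapping ellipsoidal organs
whose semi-axes are rescaled to hit target masses (liver 1800 g, spleen
150 g, kidneys 150 g each, RBM surrogate 1100 g) at their densities;
voxelised masses land within ~5%. The RBM surrogate is a single
ellipsoid — no skeletal microstructure. Placement is seeded rejection
sampling; an infeasible request errors after bounded retries.

## Numerical choices and limitations

* Time unit is hours everywhere; day/minute half-lives convert at the
  boundary. Energies are MeV internally.
* TIAC tables are written with 4 decimals (the conventional table
  format); CSVs elsewhere keep full precision.
* Curves may carry negative amplitudes, but curve values must be
  non-negative on a test grid and total integrals non-negative.
* The transport cutoff (50 keV) biases self-absorption of soft photons
  upward by design; below-cutoff lines deposit at the origin.
* The Monte Carlo is single-threaded; the per-history stream design
  would keep results identical under parallel scheduling but no
  parallel driver is included.
* The ICRP 110 raw-format phantom reader is an interface stub; real
  reference-phantom dosimetry is outside this package's fidelity scope.
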