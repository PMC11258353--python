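# Methods

This note documents the models behind `gbas`, their assumptions, the
parameters that matter, how the synthetic generators were calibrated, and
what the tests do and do not demonstrate.

## Allosteric kinetics

The engineered enzyme is modelled as Michaelis–Menten with a purely
V_max-acting inhibition factor:

    v(S) = f · V_max · S/(K_m + S)
    f    = dmso · (1 − α_max · w_species · h(c))

*Why V_max-only.* The dual-electrode kinetics show the ligand lowering the
saturating rate of the engineered variant while the wild-type V_max is
unchanged; K_m is held fixed by default. A K_m effect is not modelled
(nothing constrains it), but the factorized form means one could be added
without touching callers.

*Dose response h(c).* Observed inhibition is flat from 338 pM to 2 µM, so
h = 1 across that window and above it (the response is treated as
saturated; no high-dose relief is modelled). Below 338 pM no data exist;
we use a Hill roll-off (EC50 = c_lo/3, coefficient 1) **rescaled to reach
exactly 1 at c_lo**, keeping h continuous and monotone with h → 0 as
c → 0. A raw Hill term would sit at 0.75 at the window edge and jump.

*Contexts for α_max.* The fractional inhibition is measurement-context
dependent and the presets keep them separate rather than averaging:

| context | α_max | anchor |
|---|---|---|
| solution, colorimetric | 0.18 | 112 → 92 a.u./s at 80 mM glucose |
| immobilized, ratiometric | 1 − 4.85/6.37 ≈ 0.239 | ratio references 6.37 → 4.85 |
| immobilized, blood amperometry | 0.18 | 3.9 → 3.2 µA corrected currents |

The discrepancy between the solution (18%) and ratiometric (24%)
attenuation of the same film chemistry is an empirical fact of the source
measurements that the package does not attempt to explain.

*Vehicle.* DMSO inhibits GDH slightly; a single multiplicative factor
(default 0.95) applies whenever a dose carries vehicle. No number is
published for its magnitude; 5% is a plausible small-cosolvent effect, and
it cancels wherever both arms are vehicle-matched (every headline
comparison).

*Assay model.* DCPIP absorbance decreases linearly, A(t) = max(0, A0 −
k_abs·v·t), with k_abs = 1 by default (activity units are arbitrary).
Replicate noise is **multiplicative Gaussian on the rate, one draw per
replicate** — that is how an assay CV (7.6% purified, 11% whole-cell) is
defined operationally — not per-timepoint noise, which would shrink with
trace length. Activities are recovered as minus the OLS slope;
Michaelis–Menten fits use Levenberg–Marquardt with positivity bounds.

## Amperometry

Steady-state current is affine in the enzymatic rate, i_ss = baseline +
sensitivity·v, and the transient toward each new plateau is first-order
with τ = 10 s, a stand-in for stirred-cell mixing (no transient model is
published; nothing downstream depends on τ once settled). Steady currents
are extracted from the trailing window of each inter-injection segment,
excluding the right boundary sample, which already belongs to the next
segment. Background correction subtracts a catalytically dead film
(modelled as the apo enzyme, standing in for the BSA control), with
uncertainties added in quadrature. Blood enters only through dilution:
a 60 µL aliquot of ~5.6 mM-glucose blood in 8 mL electrolyte leaves
~0.042 mM glucose; matrix effects beyond dilution and control subtraction
are not modelled. The blood electrode's sensitivity is calibrated so the
estradiol arm reads 3.9 µA.

## Ratiometric decoder

The ratio r = i_5E+/i_wt cancels the glucose dependence to the extent the
two films share K_m shape; with the preset film kinetics
(K_m = 0.08 vs 0.02 mM) the blank ratio curve rises and plateaus, varying
<2% (sd/mean) over 0.5–1.2 mM — the operational regime of blood diluted
200 µL into 2 mL.

Uncertainty uses first-order (delta-method) propagation assuming
independent electrodes. A caution on validating this against Monte Carlo:
the ratio of two normals has no finite second moment, so an empirical MC
sd is tail-dominated once the denominator CV reaches ~10% (about +4% vs
the formula at CV 10%). At the decoder's replicate-mean CV (7.6%/√3 ≈ 4.4%)
the delta method and MC agree well inside 2%, and that is the regime in
which the device operates.

Classification is nearest-reference with the midpoint boundary
(6.37 + 4.85)/2 = 5.61; the published descriptions ("near 6.37", "around
4.85") pin only the references, so the midpoint is the symmetric choice.
z-scores to each reference combine measurement and reference sds in
quadrature; if both |z| exceed 3 the call is refused as INDETERMINATE
(the ratio is implausible under either state). Glucose below the strict
0.4 mM gate refuses as OUT_OF_RANGE; a missing glucose estimate passes
with a warning, since undiluted blood is reliably 4–6 mM. Sensitivity and
specificity of synthetic cohorts are scored **over in-range samples** —
with blood at 5.6 ± 1.0 mM and a 200 µL/2 mL dilution, roughly a tenth of
samples legitimately fall below the gate, and a refusal is the correct
device behaviour, not a misclassification; INDETERMINATE, by contrast,
counts as a failure.

t-tests are unpaired and two-tailed, pooled-variance by default (Welch
available), with a summary-statistics entry point because published
comparisons arrive as mean ± sd, n. Recomputing the published pairs gives
p = 2.6e-4 for (112±2 vs 92±2, n=3) and p = 0.013 for (6.1±0.5 vs 4.6±0.4,
n=3); the package reports its own p-values.

## Fuel cell and OECT

K_total lumps every potential term (cathode formal potential, O2/H2O
activities, anode formal potential) into one calibratable constant — its
printed decomposition is not evaluated (the concentration-ratio term there
appears to be missing a logarithm). Anchors: 0.690 V for the blood-fed
cell, 0.620 V for the glucose-free cell gating the OECT.

The OCP time course assumes zero-order consumption of the initial anolyte
glucose C0 at rate V_max — valid while C ≫ K_m, which holds for the
20 mM-scale injections (a warning is emitted otherwise) — with
stoichiometric gluconolactone accumulation. The domain (0, C0/V_max) is
open: both ends are logarithmic singularities, and the coupled simulation
clamps the first `t_min_s` (default 1 s) after injection rather than
guessing an initial product concentration.

Discharge uses ohmic plus Nernstian concentration losses,
V(j) = OCP − R_int·j + (RT/2F)·ln(1 − j/j_lim), with j_lim proportional to
the enzymatic rate. R_int = 3624.4 Ω·cm² and j_lim_scale = 5.105 are
calibrated so the estradiol-blood case yields j_max = 179 µA cm⁻² and
P_max = 32 µW cm⁻² exactly. With those losses the 4-HT case comes out
lower in both (j_max ≈ 142, P_max ≈ 31.6) — the correct direction, but the
measured 4-HT magnitudes (157, 26) cannot be reproduced simultaneously by
any ohmic + Nernstian parameterization: the RT/2F slope is too shallow to
pull P_max down 19% while j_max falls only 12%. Tests therefore assert the
estradiol anchors and the direction of the ligand effect, not the 4-HT
magnitudes.

The OECT is a linear small-signal device: |I_sd| = max(0, I_sd0 − g_m·V_g)
at fixed V_sd = −0.6 V, with g_m = 11.29 mS calibrated from the ~7.0 mA
channel depletion when the 620 mV glucose-free cell connects to the gate.
No channel physics (ion drift, capacitive gating) is modelled.

The readout statistic has two variants. The exact derivative of the
composed model is |dI_sd/dt| = g_m·(RT/2F)·|V_max/(C0 − V_max·t) + 1/t|;
the `paper` variant drops the 1/t (product-accumulation) term, keeping
only the consumption term — it is the default because it is the statistic
the study's hypothesis is framed in, and unlike the exact variant it is
monotone in V_max at *every* valid t. The exact variant is verified
against centred finite differences to 1e-6 relative. Note the dropped 1/t
term dominates shortly after injection, which is where measured slew rates
(hundreds of µA/s) live; absolute reproduction of those rates would
require modelling the injection/mixing transient, which we do not attempt
— the modulation statistic is computed from the measured rate pair.

## Screening statistics

Round 1 formalizes the by-eye colour comparison as a fold threshold:
permissive iff decay rate ≥ 3× the empty-vector control within the 5-min
window (the control carries the reagent's intrinsic drift, so the
comparison removes it). The threshold is a config knob; at the generator's
5-fold effect and 11% CV the call is essentially error-free. Round 2 is a
pooled two-tailed t-test on triplicates (DMSO vs 4-HT), allosteric iff
permissive and p < 0.05. At the study's effect size (31% mean change,
CV 11%, n = 3) the closed-form noncentral-t power is 0.846 — so a
classifier run over a truth-labelled synthetic library recovers ~60 of 71
allosteric sites, and the library-level *truth* fractions (51.1%, 15.6%)
are the quantities that correspond to the published counts.

Enrichment is a chi-square of site counts per secondary-structure class
against a null proportional to class residue counts. Coverage uses the
coupon-collector inclusion–exclusion sum evaluated in log space (terms are
C(n,k)·((n−k)/n)^N with huge binomials against tiny powers), truncated
when terms drop below 1e-18, with the union lower bound reported
alongside; for 7392 picks of 454 variants both give 99.996%.

## Synthetic generators

The generators encode the study conditions: 454 positions, 232 permissive
of which 71 allosteric (assigned exactly, not in expectation), allosteric
effects ~ Normal(0.31, 0.10) truncated above 0.10, whole-cell CV 11%,
purified CV 7.6%, 140,340 multinomial reads, blood glucose
Normal(5.6, 1.0) mM truncated positive, 1 µM 4-HT doses in DMSO with
vehicle-matched negatives. The synthetic secondary-structure annotation is
a deterministic six-bladed propeller-like layout (4 × 9-residue strands
per blade, loop linkers, occasional helices, interface flags at termini
and one loop per blade) — a stand-in for testing enrichment logic, not the
real GDH assignment — and allosteric truth sites are biased 3:1 toward
loop/interface residues so enrichment detection is exercised.

What passing tests show: the pipeline's statistics behave correctly under
noise of the reported magnitude and structure. What they do not show:
robustness to real-data pathologies the generators omit — plate/batch
effects, heteroscedastic or correlated replicates, read-count hotspots,
electrode fouling and drift, blood matrix effects beyond dilution.

## Problem sizes and numerics

Default simulation sizes — 100-replicate CV recovery, 200-fit bias
studies, 10,000-variant null calibration, 200-sample cohorts, 10⁶-draw
Monte Carlo — were chosen as the smallest sizes at which the sampling
error of each check is comfortably below its tolerance; the full suite
runs in a few seconds. All randomness flows through
`numpy.random.default_rng` with explicit seeds; equal means give t = 0,
p = 1 exactly; degenerate inputs (apo enzymes, empty tables, singular
time points, non-positive denominators) raise typed exceptions from
`gbas.errors` rather than propagating NaNs.
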