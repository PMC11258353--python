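# gbas

**Glucometer-based allosteric 4-hydroxytamoxifen (4-HT) sensor — modelling
and analysis toolkit.**

`gbas` implements, as tested and reusable Python, the computational content
of a point-of-care therapeutics biosensor built around an engineered
glucose-oxidizing enzyme. The sensing element is PQQ-dependent glucose
dehydrogenase (GDH) carrying an estrogen-receptor ligand-binding domain
(LBD) insertion: binding of the tamoxifen metabolite 4-HT allosterically
represses glucose turnover, so the drug signal rides on an ordinary
glucometer-style glucose current. The package is aimed at people modelling
or analysing such sensors — enzyme engineers screening insertion libraries,
and electrochemists designing the readout.

## What it models

**Kinetics** (`gbas.kinetics`). Allosteric Michaelis–Menten rates,

&nbsp;&nbsp;&nbsp;&nbsp;v(S) = f · V_max · S / (K_m + S), &nbsp;
f = dmso · (1 − α_max · w_species · h(c)),

where the ligand acts purely on V_max: α_max is the maximal fractional
inhibition (0.18 for the engineered variant in solution), w a per-species
selectivity weight (17β-estradiol ≈ 0), and h(c) the dose response — flat
across the operational window 338 pM–2 µM. Includes the DCPIP
colorimetric-assay forward model and slope/Michaelis–Menten fitting.

**Amperometry** (`gbas.amperometry`). Staircase i–t traces with first-order
settling toward i_ss = baseline + sensitivity·v, steady-state extraction,
BSA-control background correction, and whole-blood responses where the
sample's own glucose (~5.6 mM) is the substrate.

**Decoder** (`gbas.decoder`). The ratiometric algorithm: normalize the
engineered electrode's current by a wild-type GDH electrode in the same
cell. Above 0.4 mM glucose the ratio r = i_5E+/i_wt is glucose-invariant;
r ≈ 6.37 means no 4-HT, r ≈ 4.85 means 4-HT present (midpoint boundary
5.61, with INDETERMINATE and OUT_OF_RANGE refusal states). First-order
error propagation and pooled/Welch t-tests included.

**Fuel cell + OECT** (`gbas.efc_oect`). The self-powered readout: Nernstian
open-circuit potential OCP = K_total + (RT/2F)·ln(C_glucose/C_gluconolactone),
its time course under zero-order consumption, polarization/power curves
with ohmic + concentration losses, and the transistor-amplified statistic
|dI_sd/dt| = g_m·|dOCP/dt| (both the consumption-only and exact-derivative
variants).

**Screening** (`gbas.screening`). Two-round domain-insertion library
analysis over all 454 GDH positions: fold-threshold permissive calls,
triplicate t-test allosteric calls, summary fractions (~51% permissive,
~16% allosteric), loop/sheet/helix enrichment, and coupon-collector library
coverage by inclusion–exclusion.

**Synthetic data** (`gbas.synthetic_data`). Seeded generators for every
input — screen tables with ground truth, annotations, assay replicates at
the reported CVs (11% whole-cell, 7.6% purified), blood cohorts, and
calibrated enzyme/electrode presets — so the entire pipeline runs and is
tested offline.

## Worked example

```python
from gbas.kinetics import LigandDose, catalytic_rate
from gbas.decoder import decode
from gbas.amperometry import BloodSample
from gbas.synthetic_data import (solution_gdh5e_plus, electrode_gdh5e_plus,
    electrode_gdh_wt, calibrated_dual_loadings, simulate_dual_measurement)
from gbas.screening import coverage_probability

# allosteric repression in the colorimetric assay
e = solution_gdh5e_plus()
blank, ht = LigandDose("none", 0, 0.01), LigandDose("4-HT", 1e-9, 0.01)
print(f"blank rate @80 mM: {catalytic_rate(e, 80, blank):.1f} a.u./s")
print(f"+1 nM 4-HT:        {catalytic_rate(e, 80, ht):.1f} a.u./s")

# decode a simulated 4-HT-positive blood sample (200 uL into 2 mL)
e5, ew = electrode_gdh5e_plus(), electrode_gdh_wt()
L = calibrated_dual_loadings(e5, ew)
sample = BloodSample(5.6, LigandDose("4-HT", 1e-6, 0.01),
                     volume_uL=200, electrolyte_mL=2.0)
d = decode(simulate_dual_measurement(sample, e5, ew, L, seed=1))
print(f"ratio = {d.ratio:.2f} +/- {d.ratio_sd:.2f}  ->  {d.call.value}")

# did 7392 colony picks cover the whole 454-variant library?
print(f"coverage = {coverage_probability(7392, 454).probability:.6f}")
```

prints

```
blank rate @80 mM: 112.0 a.u./s
+1 nM 4-HT:        91.8 a.u./s
ratio = 5.03 +/- 0.46  ->  POSITIVE_4HT
coverage = 0.999962
```

The first two lines are the ~18% allosteric attenuation of the glucose
oxidation rate; the decoded ratio falls on the 4-HT side of the 5.61
boundary, so the binary call is positive; the last line says picking 7392
colonies samples every insertion variant with >99.9% probability.

A CLI wraps the common runs: `gbas gen-fixtures`, `gbas screen`,
`gbas decode`, `gbas simulate amperogram`, `gbas efc-oect` (see `--help`).

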