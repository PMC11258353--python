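"""Seeded generators for every input the pipeline consumes.

The generators reproduce the statistical structure of the study conditions:
a 454-position insertion library with ~51% permissive and ~16% allosteric
sites, triplicate colorimetric activities with CV 11% (whole cell) or 7.6%
(purified protein), multinomially distributed sequencing reads, blood
samples around 5.6 mM glucose, and dual-electrode current measurements
whose blank/positive ratios sit at the 6.37 / 4.85 references.

Enzyme presets are calibrated per measurement context, because the
fractional 4-HT inhibition observed in solution (18%) differs from the one
implied by the immobilized current ratio (1 - 4.85/6.37 ~ 24%):

* ``solution_*``   — colorimetric assay scale (blank rate 112 a.u. at
  80 mM glucose), alpha_max = 0.18;
* ``electrode_*``  — immobilized-film kinetics (Km values giving the
  rise-then-plateau ratio curve), alpha_max = 1 - 4.85/6.37 for the
  ratiometric decoder and 0.18 for the amperometric blood context.

Everything takes an explicit seed and is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as gio
from .amperometry import BloodSample, ElectrodeSpec, InjectionEvent, simulate_it_trace
from .config import save_run_config
from .decoder import (
    Call,
    Decision,
    DualMeasurement,
    GroupStats,
    RatioReference,
    decode,
)
from .errors import ConfigError, InvalidInputError
from .kinetics import (
    EnzymeParams,
    LigandDose,
    catalytic_rate,
    simulate_dcpip_trace,
)
from .screening import N_POSITIONS

__all__ = [
    "SimConfig",
    "DEFAULT_SELECTIVITY",
    "solution_gdh5e_plus",
    "solution_gdh_wt",
    "electrode_gdh5e_plus",
    "electrode_gdh_wt",
    "amperometric_gdh5e_plus",
    "calibrated_blood_electrode",
    "calibrated_dual_loadings",
    "generate_ss_annotation",
    "generate_screen_table",
    "generate_assay_replicates",
    "generate_blood_cohort",
    "simulate_dual_measurement",
    "evaluate_cohort",
    "write_fixtures",
]

#: Relative inhibition weights of endocrine therapeutics on the engineered
#: variant (cognate 4-HT = 1; 17beta-estradiol is not sensed).
DEFAULT_SELECTIVITY: Mapping[str, float] = {
    "4-HT": 1.0,
    "hexestrol": 0.9,
    "diethylstilbestrol": 0.85,
    "lasofoxifene": 0.8,
    "17β-estradiol": 0.0,
}

#: Fractional inhibition implied by the immobilized ratio references.
RATIOMETRIC_ALPHA = 1.0 - 4.85 / 6.37


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generators."""

    seed: int
    n_positions: int = N_POSITIONS
    frac_permissive: float = 0.511
    frac_allosteric_given_permissive: float = 71 / 232
    allosteric_effect_mean: float = 0.31
    allosteric_effect_sd: float = 0.10
    allosteric_effect_min: float = 0.10
    cv_whole_cell: float = 0.11
    cv_protein: float = 0.076
    blood_glucose_mean_mM: float = 5.6
    blood_glucose_sd_mM: float = 1.0
    ligand_conc_M: float = 1e-6
    n_reads_total: int = 140_340
    r1_fold_effect: float = 5.0
    loop_bias_odds: float = 3.0

    def __post_init__(self) -> None:
        for name in ("frac_permissive", "frac_allosteric_given_permissive"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.cv_whole_cell < 0 or self.cv_protein < 0:
            raise ConfigError("CVs must be >= 0")
        if self.n_positions < 1:
            raise ConfigError("n_positions must be >= 1")


# ---------------------------------------------------------------------------
# calibrated enzyme and device presets
# ---------------------------------------------------------------------------

def solution_gdh5e_plus() -> EnzymeParams:
    """Engineered variant, solution colorimetric scale.

    vmax is set so the DMSO-blank rate at 80 mM glucose is 112 a.u./s;
    1 nM 4-HT then yields 112 * (1 - 0.18) ~ 92 a.u./s.
    """
    km = 1.0
    dmso = 0.95
    vmax = 112.0 / (dmso * 80.0 / (km + 80.0))
    return EnzymeParams(
        name="GDH-5E+", vmax_blank=vmax, km_mM=km, alpha_max=0.18,
        selectivity=dict(DEFAULT_SELECTIVITY), dmso_factor=dmso,
    )


def solution_gdh_wt() -> EnzymeParams:
    """Wild-type GDH in solution: no ligand response, ~2x slower than 5E+."""
    e5 = solution_gdh5e_plus()
    return EnzymeParams(
        name="GDH", vmax_blank=e5.vmax_blank / 2.0, km_mM=e5.km_mM,
        alpha_max=0.0, dmso_factor=e5.dmso_factor,
    )


def electrode_gdh5e_plus() -> EnzymeParams:
    """Engineered variant immobilized in the redox-polymer film.

    alpha_max is the attenuation implied by the immobilized ratio
    references (6.37 -> 4.85); the slightly larger Km than wild type
    produces the rising-then-plateau ratio curve.
    """
    return EnzymeParams(
        name="GDH-5E+/Fc-LPEI", vmax_blank=50.0, km_mM=0.08,
        alpha_max=RATIOMETRIC_ALPHA, selectivity=dict(DEFAULT_SELECTIVITY),
        dmso_factor=0.95,
    )


def electrode_gdh_wt() -> EnzymeParams:
    """Wild-type GDH film for the normalizing electrode (WE-2)."""
    return EnzymeParams(
        name="GDH/Fc-LPEI", vmax_blank=25.0, km_mM=0.02,
        alpha_max=0.0, dmso_factor=0.95,
    )


def amperometric_gdh5e_plus() -> EnzymeParams:
    """Engineered film for the single-electrode blood experiment (18% effect)."""
    e = electrode_gdh5e_plus()
    return EnzymeParams(
        name=e.name, vmax_blank=e.vmax_blank, km_mM=e.km_mM, alpha_max=0.18,
        selectivity=dict(DEFAULT_SELECTIVITY), dmso_factor=e.dmso_factor,
    )


def calibrated_blood_electrode(
    enzyme: EnzymeParams | None = None,
    sample: BloodSample | None = None,
    target_uA: float = 3.9,
) -> ElectrodeSpec:
    """ElectrodeSpec whose sensitivity puts the estradiol-blood response at 3.9 uA."""
    enzyme = enzyme or amperometric_gdh5e_plus()
    sample = sample or BloodSample(
        glucose_mM=5.6,
        dose=LigandDose("17β-estradiol", 100e-6, vehicle_dmso=0.01),
        volume_uL=60.0, electrolyte_mL=8.0,
    )
    rate = catalytic_rate(enzyme, sample.final_glucose_mM, sample.final_dose)
    if rate <= 0:
        raise InvalidInputError("reference blood condition gives zero rate")
    return ElectrodeSpec(sensitivity_uA_per_rate=target_uA / rate)


def calibrated_dual_loadings(
    e5: EnzymeParams | None = None,
    ew: EnzymeParams | None = None,
    glucose_mM: float = 5.6 * 0.2 / 2.2,
    target_blank_ratio: float = 6.37,
    blank_dose: LigandDose = LigandDose("none", 0.0, 0.01),
) -> tuple[float, float]:
    """Loadings (k1, k2) putting the blank ratio at 6.37 at the operating point.

    The default operating point is 200 uL of 5.6 mM-glucose blood diluted
    into 2 mL electrolyte (~0.51 mM).
    """
    e5 = e5 or electrode_gdh5e_plus()
    ew = ew or electrode_gdh_wt()
    v5 = catalytic_rate(e5, glucose_mM, blank_dose)
    vw = catalytic_rate(ew, glucose_mM, blank_dose)
    if v5 <= 0 or vw <= 0:
        raise InvalidInputError("calibration point gives zero rate")
    return target_blank_ratio * vw / v5, 1.0


# ---------------------------------------------------------------------------
# library generators
# ---------------------------------------------------------------------------

def generate_ss_annotation(n_positions: int = N_POSITIONS) -> pd.DataFrame:
    """Deterministic synthetic secondary-structure annotation.

    Emulates a six-bladed beta-propeller: blades of four ~9-residue strands
    separated by short loops, occasional helical linkers, and terminal
    loops.  Interface flags mark the termini and one loop per blade,
    standing in for the dimer-contact surface.  This is a synthetic layout
    for testing enrichment logic, not the real GDH assignment.
    """
    blade = (["loop"] * 5 + ["sheet"] * 9) * 4 + ["helix"] * 6
    labels: list[str] = ["loop"] * 8
    while len(labels) < n_positions:
        labels.extend(blade)
    labels = labels[:n_positions]
    residues = np.arange(1, n_positions + 1)
    interface = np.zeros(n_positions, dtype=bool)
    interface[: min(12, n_positions)] = True
    interface[-min(12, n_positions):] = True
    for start in range(8, n_positions, len(blade)):  # first loop of each blade
        interface[start: min(start + 5, n_positions)] = True
    return pd.DataFrame({"residue": residues, "ss_class": labels, "interface": interface})


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    """Resampling-based truncated normal (lower bound only)."""
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def generate_screen_table(cfg: SimConfig) -> pd.DataFrame:
    """Synthetic two-round screen table with ground-truth labels.

    Label counts are hit exactly (232 permissive / 71 allosteric at
    defaults); allosteric truth sites are biased toward loop and interface
    residues with the configured odds.  Replicate activities carry the
    whole-cell CV; reads are multinomial over positions.
    """
    n = cfg.n_positions
    n_perm = int(round(cfg.frac_permissive * n))
    n_allo = int(round(cfg.frac_allosteric_given_permissive * n_perm))
    if not 0 <= n_allo <= n_perm <= n:
        raise ConfigError(
            f"infeasible fractions: {n_allo} allosteric of {n_perm} permissive of {n}"
        )
    rng = np.random.default_rng(cfg.seed)
    positions = np.arange(1, n + 1)
    perm_positions = np.sort(rng.choice(positions, n_perm, replace=False))

    ss = generate_ss_annotation(n)
    flexible = (
        (ss["ss_class"] == "loop") | ss["interface"].astype(bool)
    ).to_numpy()
    weights = np.where(flexible[perm_positions - 1], cfg.loop_bias_odds, 1.0)
    weights = weights / weights.sum()
    allo_positions = np.sort(
        rng.choice(perm_positions, n_allo, replace=False, p=weights)
    )

    is_perm = np.isin(positions, perm_positions)
    is_allo = np.isin(positions, allo_positions)
    truth = np.where(is_allo, "allosteric", np.where(is_perm, "permissive", "inactive"))

    reads = rng.multinomial(cfg.n_reads_total, np.full(n, 1.0 / n))

    cv = cfg.cv_whole_cell
    control_rate = 1.0
    base_r1 = np.where(is_perm, cfg.r1_fold_effect * control_rate, control_rate)
    r1 = np.maximum(0.0, base_r1 * (1.0 + cv * rng.standard_normal(n)))

    base_act = np.where(is_perm, 100.0, 5.0)
    effects = np.zeros(n)
    effects[is_allo] = _truncated_normal(
        rng, cfg.allosteric_effect_mean, cfg.allosteric_effect_sd,
        cfg.allosteric_effect_min, int(is_allo.sum()),
    )
    dmso = base_act[:, None] * (1.0 + cv * rng.standard_normal((n, 3)))
    ht = (base_act * (1.0 - effects))[:, None] * (1.0 + cv * rng.standard_normal((n, 3)))

    return pd.DataFrame({
        "position": positions,
        "reads": reads,
        "r1_rate": r1,
        "r1_control_rate": control_rate,
        "dmso_1": dmso[:, 0], "dmso_2": dmso[:, 1], "dmso_3": dmso[:, 2],
        "ht_1": ht[:, 0], "ht_2": ht[:, 1], "ht_3": ht[:, 2],
        "truth_label": truth,
    })


# ---------------------------------------------------------------------------
# assay and cohort generators
# ---------------------------------------------------------------------------

def generate_assay_replicates(
    enzyme: EnzymeParams,
    glucose_mM: float,
    dose: LigandDose,
    n: int,
    cv: float,
    seed: int | None,
) -> np.ndarray:
    """Replicate activities: multiplicative Gaussian noise around the model rate."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if cv < 0:
        raise InvalidInputError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    v = catalytic_rate(enzyme, glucose_mM, dose)
    return np.maximum(0.0, v * (1.0 + cv * rng.standard_normal(n)))


def generate_blood_cohort(
    cfg: SimConfig,
    n_samples: int,
    positive_fraction: float,
    volume_uL: float = 200.0,
    electrolyte_mL: float = 2.0,
) -> tuple[list[BloodSample], np.ndarray]:
    """Blood samples with truth labels; glucose ~ trunc-Normal(5.6, 1.0) mM.

    Positives carry the configured 4-HT dose in DMSO; negatives carry a
    matched vehicle-only dose.  The number of positives is exactly
    ``round(n_samples * positive_fraction)``, in seeded random order.
    """
    if n_samples < 1:
        raise InvalidInputError("n_samples must be >= 1")
    if not 0.0 <= positive_fraction <= 1.0:
        raise InvalidInputError("positive_fraction must be in [0, 1]")
    rng = np.random.default_rng(cfg.seed)
    glucose = _truncated_normal(
        rng, cfg.blood_glucose_mean_mM, cfg.blood_glucose_sd_mM, 0.0, n_samples
    )
    n_pos = int(round(n_samples * positive_fraction))
    truth = np.zeros(n_samples, dtype=bool)
    truth[rng.permutation(n_samples)[:n_pos]] = True
    samples = [
        BloodSample(
            glucose_mM=float(g),
            dose=(
                LigandDose("4-HT", cfg.ligand_conc_M, vehicle_dmso=0.01)
                if pos
                else LigandDose("none", 0.0, vehicle_dmso=0.01)
            ),
            volume_uL=volume_uL,
            electrolyte_mL=electrolyte_mL,
        )
        for g, pos in zip(glucose, truth)
    ]
    return samples, truth


def simulate_dual_measurement(
    sample: BloodSample,
    e5: EnzymeParams,
    ew: EnzymeParams,
    loadings: tuple[float, float],
    n_rep: int = 3,
    cv: float = 0.076,
    seed: int | None = 0,
) -> DualMeasurement:
    """Replicate dual-electrode currents for one diluted blood sample."""
    rng = np.random.default_rng(seed)
    s = sample.final_glucose_mM
    dose = sample.final_dose
    k1, k2 = loadings
    i5 = k1 * catalytic_rate(e5, s, dose) * (1.0 + cv * rng.standard_normal(n_rep))
    iw = k2 * catalytic_rate(ew, s, dose) * (1.0 + cv * rng.standard_normal(n_rep))
    def gs(x: np.ndarray) -> GroupStats:
        return GroupStats(float(x.mean()), float(x.std(ddof=1)) if n_rep > 1 else 0.0, n_rep)
    return DualMeasurement(gs(i5), gs(iw), glucose_mM_est=s)


def evaluate_cohort(
    samples: Sequence[BloodSample],
    truth: np.ndarray,
    e5: EnzymeParams | None = None,
    ew: EnzymeParams | None = None,
    loadings: tuple[float, float] | None = None,
    refs: RatioReference = RatioReference(),
    n_rep: int = 3,
    cv: float = 0.076,
    seed: int = 0,
) -> dict:
    """Decode a synthetic cohort and score it against truth.

    Sensitivity/specificity are computed over in-range samples only:
    OUT_OF_RANGE is a refusal dictated by the glucose gate, not a call.
    INDETERMINATE counts as a misclassification.
    """
    e5 = e5 or electrode_gdh5e_plus()
    ew = ew or electrode_gdh_wt()
    loadings = loadings or calibrated_dual_loadings(e5, ew)
    decisions: list[Decision] = []
    for k, sample in enumerate(samples):
        m = simulate_dual_measurement(sample, e5, ew, loadings, n_rep, cv,
                                      seed=seed * 1_000_003 + k)
        decisions.append(decode(m, refs))
    calls = np.array([d.call for d in decisions], dtype=object)
    in_range = calls != Call.OUT_OF_RANGE
    pos = np.asarray(truth, dtype=bool)
    tp = int(np.sum(in_range & pos & (calls == Call.POSITIVE_4HT)))
    tn = int(np.sum(in_range & ~pos & (calls == Call.NEGATIVE)))
    n_pos = int(np.sum(in_range & pos))
    n_neg = int(np.sum(in_range & ~pos))
    return {
        "decisions": decisions,
        "n_in_range": int(in_range.sum()),
        "n_out_of_range": int((~in_range).sum()),
        "sensitivity": tp / n_pos if n_pos else float("nan"),
        "specificity": tn / n_neg if n_neg else float("nan"),
    }


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(out_dir: str | Path, cfg: SimConfig) -> dict:
    """Emit every CSV/YAML fixture the pipeline reads, plus a manifest.

    Deterministic for a fixed config: the manifest records the seed and a
    sha256 per file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # screening inputs
    screen = generate_screen_table(cfg)
    screen.to_csv(out / "screen_table.csv", index=False)
    generate_ss_annotation(cfg.n_positions).to_csv(out / "ss_annotation.csv", index=False)

    # colorimetric traces: blank vs 4-HT triplicates
    e_sol = solution_gdh5e_plus()
    blank = LigandDose("none", 0.0, 0.01)
    ht = LigandDose("4-HT", 1e-9, 0.01)
    traces = []
    for cond_id, dose in (("glc80_blank", blank), ("glc80_4HT_1nM", ht)):
        for rep in range(3):
            tr = simulate_dcpip_trace(
                e_sol, 80.0, dose, duration_s=600, dt_s=15, cv=cfg.cv_protein,
                seed=cfg.seed * 7 + rep + (0 if dose is blank else 100),
                a0=100.0, k_abs=1e-3, replicate_id=rep,
            )
            traces.append((cond_id, tr))
    gio.write_assay_traces(out / "assay_traces.csv", traces)

    # amperometric staircase
    electrode = calibrated_blood_electrode()
    enzyme = amperometric_gdh5e_plus()
    schedule = [
        InjectionEvent(180.0, 0.25, LigandDose("4-HT", 12.5e-6, 0.01)),
        InjectionEvent(360.0, 0.25, LigandDose("4-HT", 12.5e-6, 0.01)),
    ]
    amp = simulate_it_trace(electrode, enzyme, schedule, duration_s=540.0,
                            noise_uA=0.05, seed=cfg.seed)
    gio.write_amperogram(out / "amperogram.csv", out / "amperogram_events.csv", amp)

    # dual-electrode measurements: one blank, one positive blood sample
    e5, ew = electrode_gdh5e_plus(), electrode_gdh_wt()
    loadings = calibrated_dual_loadings(e5, ew)
    samples, truth = generate_blood_cohort(cfg, 2, 0.5)
    pairs = [
        (f"sample_{k}_{'pos' if t else 'neg'}",
         simulate_dual_measurement(s, e5, ew, loadings, cv=cfg.cv_protein,
                                   seed=cfg.seed + 50 + k))
        for k, (s, t) in enumerate(zip(samples, truth))
    ]
    gio.write_dual_measurements(out / "dual_measurements.csv", pairs)

    # run configuration
    save_run_config(
        out / "run_config.yaml",
        enzymes={
            "gdh5e_solution": e_sol,
            "gdh_wt_solution": solution_gdh_wt(),
            "gdh5e_electrode": e5,
            "gdh_wt_electrode": ew,
        },
        electrode=electrode,
        extra={"simulation": {"seed": cfg.seed, "cv_protein": cfg.cv_protein,
                              "cv_whole_cell": cfg.cv_whole_cell}},
    )

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": cfg.seed,
        "files": {name: _sha256(out / name) for name in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
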