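"""Forward model of amperometric electrode currents.

An enzyme/redox-polymer film on a carbon electrode converts glucose
turnover into an oxidation current.  Under constant applied potential in a
stirred cell, each glucose (or glucose + ligand) injection moves the
steady-state current to

    i_ss = baseline + sensitivity * v(enzyme, glucose, dose)

and the measured current relaxes toward it first-order with settling time
``tau_s``.  Routines here simulate staircase i-t traces, extract per-step
steady currents, subtract a protein-free (BSA) control, and model the
whole-blood experiment where the only glucose is the sample's own
(~5.6 mM in adults) diluted into the electrolyte.

Potentials are stored vs SHE; measured-vs-SCE values convert by +244 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    IncompatibleSchedulesError,
    InsufficientDataError,
    InvalidInputError,
    InvalidScheduleError,
)
from .kinetics import NO_DOSE, EnzymeParams, LigandDose, catalytic_rate

__all__ = [
    "SCE_TO_SHE_MV",
    "ElectrodeSpec",
    "InjectionEvent",
    "Amperogram",
    "BloodSample",
    "StepCurrent",
    "simulate_it_trace",
    "steady_state_currents",
    "background_correct",
    "blood_response",
]

#: Additive conversion from potentials measured vs SCE to the SHE scale (mV).
SCE_TO_SHE_MV = 244.0


@dataclass(frozen=True)
class ElectrodeSpec:
    """Geometry and transduction constants of one working electrode."""

    area_cm2: float = 0.25  # AvCarb strip; 0.0707 for a 3 mm glassy carbon disc
    sensitivity_uA_per_rate: float = 1.0
    baseline_uA: float = 0.0
    tau_s: float = 10.0
    applied_potential_mV_SHE: float = 544.0

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise InvalidInputError("electrode area must be > 0")
        if self.sensitivity_uA_per_rate < 0:
            raise InvalidInputError("sensitivity must be >= 0")
        if self.tau_s <= 0:
            raise InvalidInputError("tau_s must be > 0")


@dataclass(frozen=True)
class InjectionEvent:
    """One injection: glucose increment and the ligand condition after it."""

    time_s: float
    delta_glucose_mM: float = 0.0
    dose: LigandDose = NO_DOSE

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise InvalidInputError("event time must be >= 0")


@dataclass(frozen=True)
class Amperogram:
    """A current-vs-time trace with its injection schedule and electrode."""

    times_s: np.ndarray
    current_uA: np.ndarray
    events: tuple[InjectionEvent, ...]
    electrode: ElectrodeSpec

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        i = np.asarray(self.current_uA, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "current_uA", i)
        object.__setattr__(self, "events", tuple(self.events))
        if t.shape != i.shape or t.ndim != 1:
            raise InvalidInputError("times and current must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")


@dataclass(frozen=True)
class BloodSample:
    """A whole-blood aliquot added to the electrochemical cell."""

    glucose_mM: float = 5.6
    dose: LigandDose = NO_DOSE
    volume_uL: float = 60.0
    electrolyte_mL: float = 8.0

    def __post_init__(self) -> None:
        if self.glucose_mM < 0:
            raise InvalidInputError("blood glucose must be >= 0")
        if self.volume_uL <= 0 or self.electrolyte_mL <= 0:
            raise InvalidInputError("volumes must be > 0")

    @property
    def dilution(self) -> float:
        """Volume fraction of blood in the final cell contents."""
        v_b = self.volume_uL / 1000.0
        return v_b / (v_b + self.electrolyte_mL)

    @property
    def final_glucose_mM(self) -> float:
        """Glucose concentration in the cell after dilution."""
        return self.glucose_mM * self.dilution

    @property
    def final_dose(self) -> LigandDose:
        """Ligand dose after the same dilution (vehicle fraction diluted too)."""
        d = self.dilution
        return replace(
            self.dose,
            concentration_M=self.dose.concentration_M * d,
            vehicle_dmso=self.dose.vehicle_dmso * d,
        )


def simulate_it_trace(
    electrode: ElectrodeSpec,
    enzyme: EnzymeParams,
    schedule: Sequence[InjectionEvent],
    duration_s: float = 600.0,
    dt_s: float = 0.5,
    noise_uA: float = 0.05,
    seed: int | None = 0,
) -> Amperogram:
    """Simulate a staircase amperometric i-t trace.

    After each event the current relaxes first-order (``tau_s``) toward the
    new steady state; additive Gaussian noise of sd ``noise_uA`` is applied
    pointwise.  Events must be in strictly increasing time order, lie within
    the trace, and never drive glucose negative.
    """
    events = list(schedule)
    times_ev = [e.time_s for e in events]
    if any(t2 <= t1 for t1, t2 in zip(times_ev, times_ev[1:])):
        raise InvalidScheduleError("injection events must be strictly ordered in time")
    if events and events[-1].time_s >= duration_s:
        raise InvalidScheduleError("all events must occur before duration_s")
    if noise_uA < 0:
        raise InvalidInputError("noise_uA must be >= 0")

    glucose = 0.0
    dose = NO_DOSE
    # steady-state current per segment (before first event: resting cell)
    seg_bounds = [0.0] + times_ev + [duration_s]
    seg_iss = [electrode.baseline_uA + electrode.sensitivity_uA_per_rate
               * catalytic_rate(enzyme, glucose, dose)]
    for e in events:
        glucose += e.delta_glucose_mM
        if glucose < -1e-12:
            raise InvalidScheduleError("schedule drives glucose negative")
        glucose = max(glucose, 0.0)
        dose = e.dose
        seg_iss.append(
            electrode.baseline_uA
            + electrode.sensitivity_uA_per_rate * catalytic_rate(enzyme, glucose, dose)
        )

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    i_det = np.empty_like(t)
    decay = np.exp(-dt_s / electrode.tau_s)
    current = seg_iss[0]
    seg = 0
    for k, tk in enumerate(t):
        while seg + 1 < len(seg_bounds) - 1 and tk >= seg_bounds[seg + 1]:
            seg += 1
        target = seg_iss[seg]
        if k > 0:
            current = target + (current - target) * decay
        else:
            current = seg_iss[0]
        i_det[k] = current

    if noise_uA > 0:
        rng = np.random.default_rng(seed)
        i_det = i_det + noise_uA * rng.standard_normal(i_det.shape)
    return Amperogram(t, i_det, tuple(events), electrode)


class StepCurrent(NamedTuple):
    """Steady-state summary for one post-injection step."""

    event_index: int
    mean_uA: float
    sd_uA: float


def steady_state_currents(
    amp: Amperogram, settle_s: float = 30.0, window_s: float = 20.0
) -> list[StepCurrent]:
    """Per-step steady currents from the trailing window of each segment.

    For every event, the segment runs to the next event (or trace end); the
    mean/sd are taken over the final ``window_s`` seconds, which must start
    at least ``settle_s`` after the event.
    """
    if not amp.events:
        raise InsufficientDataError("amperogram has no injection events")
    bounds = [e.time_s for e in amp.events] + [float(amp.times_s[-1])]
    out: list[StepCurrent] = []
    for idx in range(len(amp.events)):
        t0, t1 = bounds[idx], bounds[idx + 1]
        if t1 - t0 < settle_s + window_s:
            raise InsufficientDataError(
                f"segment after event {idx} ({t1 - t0:.1f} s) shorter than "
                f"settle ({settle_s}) + window ({window_s}) s"
            )
        # right boundary belongs to the next segment, except at trace end
        last = idx == len(amp.events) - 1
        mask = (amp.times_s >= t1 - window_s) & (
            (amp.times_s <= t1) if last else (amp.times_s < t1)
        )
        vals = amp.current_uA[mask]
        if vals.size < 2:
            raise InsufficientDataError("steady-state window contains < 2 samples")
        out.append(StepCurrent(idx + 1, float(vals.mean()), float(vals.std(ddof=1))))
    return out


def _schedules_match(a: Amperogram, b: Amperogram, tol: float = 1e-9) -> bool:
    if len(a.events) != len(b.events):
        return False
    return all(
        abs(ea.time_s - eb.time_s) <= tol
        and abs(ea.delta_glucose_mM - eb.delta_glucose_mM) <= tol
        for ea, eb in zip(a.events, b.events)
    )


def background_correct(
    sample: Amperogram,
    control: Amperogram,
    settle_s: float = 30.0,
    window_s: float = 20.0,
) -> list[StepCurrent]:
    """Subtract control (e.g. BSA-film) steady currents from the sample's.

    Both traces must share the injection schedule.  Step uncertainties add
    in quadrature.
    """
    if not _schedules_match(sample, control):
        raise IncompatibleSchedulesError("sample and control schedules differ")
    s_steps = steady_state_currents(sample, settle_s, window_s)
    c_steps = steady_state_currents(control, settle_s, window_s)
    return [
        StepCurrent(s.event_index, s.mean_uA - c.mean_uA,
                    float(np.hypot(s.sd_uA, c.sd_uA)))
        for s, c in zip(s_steps, c_steps)
    ]


def blood_response(
    electrode: ElectrodeSpec,
    enzyme: EnzymeParams,
    sample: BloodSample,
    *,
    inject_at_s: float = 180.0,
    duration_s: float = 420.0,
    noise_uA: float = 0.0,
    seed: int | None = 0,
) -> StepCurrent:
    """Background-corrected steady current (uA) for one blood aliquot.

    The blood's own glucose (diluted into the electrolyte) is the only
    substrate.  The control electrode carries a catalytically dead film
    (the BSA control), simulated as the apo enzyme.
    """
    event = InjectionEvent(inject_at_s, sample.final_glucose_mM, sample.final_dose)
    amp = simulate_it_trace(electrode, enzyme, [event], duration_s,
                            noise_uA=noise_uA, seed=seed)
    dead = replace(enzyme, holo=False)
    ctrl = simulate_it_trace(electrode, dead, [event], duration_s,
                             noise_uA=noise_uA,
                             seed=None if seed is None else seed + 1)
    settle = max(5.0 * electrode.tau_s, 30.0)
    window = min(60.0, (duration_s - inject_at_s - settle) * 0.9)
    return background_correct(amp, ctrl, settle_s=settle, window_s=window)[0]
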