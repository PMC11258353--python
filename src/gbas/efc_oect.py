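"""Physics of the self-powered sensor and its transistor readout.

A glucose/O2 enzymatic fuel cell (EFC) oxidizes glucose at a GDH bioanode
and reduces O2 at a laccase cathode.  Its open-circuit potential follows a
Nernst expression in the glucose/gluconolactone couple,

    OCP = K_total + (RT/2F) ln(C_glucose / C_gluconolactone),

with every potential- and cathode-side term lumped into the single
calibratable constant ``K_total``.  Under zero-order consumption of an
initial anolyte charge C0 at rate V_max (valid while glucose saturates the
enzyme), glucose converts stoichiometrically to gluconolactone, giving

    OCP(t) = K_total + (RT/2F) ln((C0 - Vmax*t) / (Vmax*t)),   0 < t < C0/Vmax.

Discharge behaviour is modelled with ohmic plus Nernstian concentration
losses, V(j) = OCP - R_int*j + (RT/2F) ln(1 - j/j_lim), where the limiting
current density j_lim scales with the enzymatic rate — so allosteric
inhibition lowers both the maximal current and the peak power.

The organic electrochemical transistor (OECT) gate is driven by the EFC:
a depletion-mode PEDOT:PSS channel loses drain current linearly with gate
voltage, |I_sd| = max(0, I_sd0 - g_m * V_g).  Differentiating the composed
model gives the readout statistic |dI_sd/dt|.  Two variants are provided:
``"exact"`` keeps the full derivative of OCP(t); ``"paper"`` keeps only the
consumption term Vmax/(C0 - Vmax*t), dropping the 1/t contribution of the
growing gluconolactone pool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import DomainError, InvalidInputError, InvalidScheduleError, NoFuelError
from .kinetics import NO_DOSE, EnzymeParams, LigandDose, catalytic_rate

__all__ = [
    "GAS_CONSTANT_R",
    "FARADAY_F",
    "nernst_slope_V",
    "FuelCellSpec",
    "PolarizationCurve",
    "OectSpec",
    "OectTrace",
    "ScheduleEvent",
    "ocp_nernst",
    "ocp_time_course",
    "polarization_curve",
    "oect_drain_current",
    "disd_dt",
    "coupled_simulation",
    "percent_modulation",
]

GAS_CONSTANT_R = 8.314  # J mol^-1 K^-1
FARADAY_F = 96485.0  # C mol^-1


def nernst_slope_V(t_K: float = 298.15) -> float:
    """RT/2F in volts (two electrons per glucose oxidized)."""
    return GAS_CONSTANT_R * t_K / (2.0 * FARADAY_F)


@dataclass(frozen=True)
class FuelCellSpec:
    """Lumped parameters of the glucose/O2 EFC.

    ``k_total_V`` absorbs the cathode formal potential, O2/H2O activity
    terms and the anode formal potential; it is calibrated to a measured
    OCP rather than computed from first principles.  ``j_lim_scale``
    converts the enzymatic rate (a.u./s) into a limiting current density
    (uA cm^-2); ``rate_to_mM_per_s`` converts it into the zero-order
    anolyte glucose consumption rate used by the OCP time course.
    """

    k_total_V: float = 0.690
    t_K: float = 298.15
    r_int_ohm_cm2: float = 3624.4
    j_lim_scale: float = 5.105
    c0_glucose_mM: float = 19.8
    anode_area_cm2: float = 0.25
    rate_to_mM_per_s: float = 2.5e-4

    def __post_init__(self) -> None:
        if self.t_K <= 0:
            raise InvalidInputError("temperature must be > 0 K")
        if self.r_int_ohm_cm2 <= 0 or self.j_lim_scale <= 0:
            raise InvalidInputError("R_int and j_lim_scale must be > 0")
        if self.c0_glucose_mM < 0:
            raise InvalidInputError("C0 glucose must be >= 0")
        if self.anode_area_cm2 <= 0 or self.rate_to_mM_per_s <= 0:
            raise InvalidInputError("area and rate conversion must be > 0")


@dataclass(frozen=True)
class PolarizationCurve:
    """Discharge sweep: cell voltage and power density vs current density."""

    j_uA_cm2: np.ndarray
    v_volt: np.ndarray
    p_uW_cm2: np.ndarray
    j_at_pmax: float
    p_max: float
    j_max: float
    ocp_V: float


@dataclass(frozen=True)
class OectSpec:
    """Small-signal OECT readout: constant transconductance at fixed V_sd."""

    v_sd_V: float = -0.6
    i_sd0_mA: float = 10.0
    g_m_mS: float = 11.29
    channel_L_um: float = 50.0
    channel_W_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.g_m_mS < 0:
            raise InvalidInputError("transconductance must be >= 0")
        if self.i_sd0_mA < 0:
            raise InvalidInputError("baseline drain current magnitude must be >= 0")


@dataclass(frozen=True)
class OectTrace:
    """Drain-current trace with connect/inject/disconnect markers."""

    times_s: np.ndarray
    i_sd_mA: np.ndarray
    events: tuple["ScheduleEvent", ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        i = np.asarray(self.i_sd_mA, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "i_sd_mA", i)
        object.__setattr__(self, "events", tuple(self.events))
        if t.shape != i.shape or t.ndim != 1:
            raise InvalidInputError("times and current must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")


@dataclass(frozen=True)
class ScheduleEvent:
    """One gate-circuit event: ``connect``, ``inject`` or ``disconnect``."""

    kind: str
    time_s: float
    glucose_mM: float = 0.0
    dose: LigandDose = NO_DOSE

    def __post_init__(self) -> None:
        if self.kind not in ("connect", "inject", "disconnect"):
            raise InvalidScheduleError(f"unknown event kind {self.kind!r}")
        if self.time_s < 0:
            raise InvalidInputError("event time must be >= 0")


def ocp_nernst(fc: FuelCellSpec, c_glucose: float, c_gluconolactone: float) -> float:
    """Equilibrium OCP (V) at given glucose/gluconolactone concentrations."""
    if c_glucose <= 0 or c_gluconolactone <= 0:
        raise DomainError("both concentrations must be > 0")
    return fc.k_total_V + nernst_slope_V(fc.t_K) * math.log(c_glucose / c_gluconolactone)


def _check_time_domain(c0: float, vmax: float, t: float) -> None:
    if vmax <= 0:
        raise DomainError("Vmax must be > 0")
    if c0 <= 0:
        raise DomainError("C0 glucose must be > 0")
    t_end = c0 / vmax
    if not 0.0 < t < t_end:
        raise DomainError(
            f"t = {t:g} s outside the valid interval (0, {t_end:g}) s "
            "(boundaries are singular: no product at t=0, no fuel at t=C0/Vmax)"
        )


def ocp_time_course(fc: FuelCellSpec, vmax_mM_per_s: float, t_s: float) -> float:
    """OCP(t) under zero-order glucose consumption; strictly decreasing.

    Valid strictly inside (0, C0/Vmax); both boundaries are logarithmic
    singularities (no gluconolactone yet / no glucose left).
    """
    _check_time_domain(fc.c0_glucose_mM, vmax_mM_per_s, t_s)
    c_glu = fc.c0_glucose_mM - vmax_mM_per_s * t_s
    c_lac = vmax_mM_per_s * t_s
    return fc.k_total_V + nernst_slope_V(fc.t_K) * math.log(c_glu / c_lac)


def polarization_curve(
    fc: FuelCellSpec,
    enzyme: EnzymeParams,
    glucose_mM: float,
    dose: LigandDose = NO_DOSE,
    n_points: int = 400,
    ocp_V: float | None = None,
) -> PolarizationCurve:
    """Discharge sweep V(j), P(j) from OCP to the short-circuit crossing.

    V(j) = OCP - R_int*j + (RT/2F) ln(1 - j/j_lim), with
    j_lim = j_lim_scale * catalytic_rate(enzyme, glucose, dose).  Reports
    j_max (the V = 0 crossing), the peak power density and its location.
    """
    ocp = fc.k_total_V if ocp_V is None else ocp_V
    j_lim = fc.j_lim_scale * catalytic_rate(enzyme, glucose_mM, dose)
    if j_lim <= 0:
        raise NoFuelError("limiting current density is <= 0 (no enzymatic turnover)")
    ns = nernst_slope_V(fc.t_K)

    def volts(j: np.ndarray | float) -> np.ndarray | float:
        return ocp - fc.r_int_ohm_cm2 * np.asarray(j) * 1e-6 + ns * np.log1p(-np.asarray(j) / j_lim)

    j_max = float(optimize.brentq(volts, 0.0, j_lim * (1.0 - 1e-12)))
    j = np.linspace(0.0, j_max, n_points)
    v = np.asarray(volts(j), dtype=float)
    v[-1] = max(v[-1], 0.0)  # clip the root's rounding residue
    p = v * j  # volts * uA cm^-2 == uW cm^-2
    k = int(np.argmax(p))
    return PolarizationCurve(j, v, p, float(j[k]), float(p[k]), j_max, ocp)


def oect_drain_current(oect: OectSpec, v_g: float) -> float:
    """Drain current (mA) at gate voltage v_g; sign follows V_sd.

    |I_sd| = max(0, I_sd0 - g_m * V_g): a positive gate voltage depletes
    the channel.
    """
    mag = max(0.0, oect.i_sd0_mA - oect.g_m_mS * v_g)
    return math.copysign(mag, oect.v_sd_V) if oect.v_sd_V != 0 else mag


def disd_dt(
    fc: FuelCellSpec,
    oect: OectSpec,
    vmax_mM_per_s: float,
    t_s: float,
    variant: str = "paper",
) -> float:
    """|dI_sd/dt| (mA/s) of the EFC-gated OECT during discharge.

    ``"exact"`` differentiates the composed OCP(t) -> I_sd model:
    g_m * (RT/2F) * |Vmax/(C0 - Vmax t) + 1/t|.  ``"paper"`` keeps only the
    glucose-consumption term, g_m * (RT/2F) * Vmax/(C0 - Vmax t); it is the
    statistic used for ligand discrimination and is monotone in Vmax at
    every valid t.
    """
    _check_time_domain(fc.c0_glucose_mM, vmax_mM_per_s, t_s)
    ns = nernst_slope_V(fc.t_K)
    consumption = vmax_mM_per_s / (fc.c0_glucose_mM - vmax_mM_per_s * t_s)
    if variant == "paper":
        return oect.g_m_mS * ns * consumption
    if variant == "exact":
        return oect.g_m_mS * ns * abs(-consumption - 1.0 / t_s)
    raise InvalidInputError(f"unknown variant {variant!r}; use 'paper' or 'exact'")


def percent_modulation(value_blank: float, value_ligand: float) -> float:
    """Signal modulation in percent, 100 * (1 - ligand/blank)."""
    if value_blank <= 0:
        raise InvalidInputError("blank value must be > 0")
    return 100.0 * (1.0 - value_ligand / value_blank)


def coupled_simulation(
    fc: FuelCellSpec,
    oect: OectSpec,
    enzyme: EnzymeParams,
    schedule: Sequence[ScheduleEvent],
    duration_s: float = 600.0,
    dt_s: float = 1.0,
    t_min_s: float = 1.0,
    noise_mA: float = 0.0,
    seed: int | None = 0,
) -> OectTrace:
    """Piecewise EFC-gated OECT drain-current trace.

    Gate voltage is 0 while disconnected, ``k_total_V`` while connected to
    a glucose-free EFC, and follows the OCP time course after a glucose
    injection (clamped below ``t_min_s`` to avoid the t -> 0 singularity;
    after fuel exhaustion it returns to the glucose-free level).  A warning
    is emitted when the injected glucose does not saturate the enzyme
    (C0 < 10 K_m), since consumption is modelled zero-order.
    """
    events = list(schedule)
    times_ev = [e.time_s for e in events]
    if any(t2 <= t1 for t1, t2 in zip(times_ev, times_ev[1:])):
        raise InvalidScheduleError("events must be strictly ordered in time")
    connected = False
    fueled = False
    for e in events:
        if e.kind == "connect":
            if connected:
                raise InvalidScheduleError("EFC already connected")
            connected = True
        elif e.kind == "disconnect":
            if not connected:
                raise InvalidScheduleError("disconnect before connect")
            connected = False
        elif e.kind == "inject":
            if not connected:
                raise InvalidScheduleError("injection requires a connected EFC")
            if fueled:
                raise InvalidScheduleError("only one glucose injection is supported")
            if e.glucose_mM <= 0:
                raise InvalidScheduleError("injection must add glucose")
            if e.glucose_mM < 10.0 * enzyme.km_mM:
                warnings.warn(
                    "injected glucose does not saturate the enzyme (C0 < 10 Km); "
                    "zero-order consumption is an approximation here",
                    stacklevel=2,
                )
            fueled = True

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    v_g = np.zeros_like(t)
    ns = nernst_slope_V(fc.t_K)
    on = False
    c0 = 0.0
    vmax = 0.0
    t_inject = math.inf
    ei = 0
    for k, tk in enumerate(t):
        while ei < len(events) and tk >= events[ei].time_s:
            e = events[ei]
            if e.kind == "connect":
                on = True
            elif e.kind == "disconnect":
                on = False
            else:
                c0 = e.glucose_mM
                vmax = fc.rate_to_mM_per_s * catalytic_rate(enzyme, e.glucose_mM, e.dose)
                t_inject = e.time_s
            ei += 1
        if not on:
            v_g[k] = 0.0
            continue
        tau = tk - t_inject
        if vmax <= 0 or tau < 0 or tau >= c0 / vmax:
            v_g[k] = fc.k_total_V  # glucose-free (or exhausted) EFC
        else:
            tau = max(tau, t_min_s)
            if tau >= c0 / vmax:
                v_g[k] = fc.k_total_V
            else:
                v_g[k] = fc.k_total_V + ns * math.log((c0 - vmax * tau) / (vmax * tau))
    i_sd = np.array([oect_drain_current(oect, v) for v in v_g])
    if noise_mA > 0:
        rng = np.random.default_rng(seed)
        i_sd = i_sd + noise_mA * rng.standard_normal(i_sd.shape)
    return OectTrace(t, i_sd, tuple(events))
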