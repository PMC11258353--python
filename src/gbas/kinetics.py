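"""Allosteric enzyme kinetics and the DCPIP colorimetric assay model.

The sensing enzyme is PQQ-dependent glucose dehydrogenase (GDH) carrying an
estrogen-receptor ligand-binding domain insertion.  Binding of the cognate
ligand (4-hydroxytamoxifen, 4-HT) allosterically represses glucose turnover.
The repression is modelled as a pure V_max effect: the apparent maximal rate
is scaled by an *inhibition factor* f in (0, 1] while the Michaelis constant
K_m is unchanged,

    v(S) = f * vmax_blank * S / (K_m + S),
    f    = dmso * (1 - alpha_max * w_species * h(c)),

where ``alpha_max`` is the maximal fractional inhibition at saturating
cognate ligand, ``w_species`` a per-ligand selectivity weight in [0, 1], and
``h(c)`` the occupancy-like dose response: flat (h = 1) across the enzyme's
operational ligand window (default 338 pM - 2 uM) and rolling off smoothly
below it.  A DMSO vehicle applies a single multiplicative factor.

The colorimetric readout follows dichlorophenolindophenol (DCPIP) reduction
at 600 nm: absorbance decreases linearly at a rate proportional to the
enzymatic rate, and the assay's replicate scatter is multiplicative with a
stated coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
from scipy import optimize

from .errors import FitError, InsufficientDataError, InvalidInputError

__all__ = [
    "COGNATE_LIGAND",
    "LigandDose",
    "EnzymeParams",
    "AssayTrace",
    "inhibition_factor",
    "catalytic_rate",
    "simulate_dcpip_trace",
    "activity_from_trace",
    "fit_michaelis_menten",
    "MichaelisMentenFit",
]

#: Species name of the sensed therapeutic.
COGNATE_LIGAND = "4-HT"

#: Default flat-response ligand window in molar (338 pM to 2 uM).
DEFAULT_LIGAND_RANGE_M = (338e-12, 2e-6)


@dataclass(frozen=True)
class LigandDose:
    """A ligand condition: species, molar concentration and DMSO vehicle.

    ``species`` of ``"none"`` means vehicle only (or nothing at all when
    ``vehicle_dmso`` is 0).
    """

    species: str = "none"
    concentration_M: float = 0.0
    vehicle_dmso: float = 0.0

    def __post_init__(self) -> None:
        if self.concentration_M < 0:
            raise InvalidInputError(
                f"ligand concentration must be >= 0, got {self.concentration_M}"
            )
        if not 0.0 <= self.vehicle_dmso <= 1.0:
            raise InvalidInputError(
                f"DMSO volume fraction must be in [0, 1], got {self.vehicle_dmso}"
            )


#: Convenience: no ligand, no vehicle.
NO_DOSE = LigandDose()


@dataclass(frozen=True)
class EnzymeParams:
    """Kinetic parameters of one enzyme variant.

    Parameters
    ----------
    name
        Free-text label (e.g. ``"GDH-5E+"``).
    vmax_blank
        Maximal rate without ligand or vehicle, in activity units per
        second (a.u./s; the assay's absorbance units are arbitrary).
    km_mM
        Michaelis constant for glucose, mM.
    holo
        Whether the PQQ cofactor is present.  The apo enzyme is inactive.
    alpha_max
        Maximal fractional inhibition at saturating cognate ligand
        (e.g. 0.18 for the engineered variant in solution).
    ligand_range_M
        ``(c_lo, c_hi)`` bounds of the flat-response ligand window, molar.
    selectivity
        Map species -> relative inhibition weight in [0, 1].  Species not
        listed do not inhibit.  Wild-type enzymes simply use an empty map
        (or ``alpha_max = 0``).
    dmso_factor
        Multiplicative vehicle effect in (0, 1], applied whenever the dose
        carries any DMSO.
    """

    name: str
    vmax_blank: float
    km_mM: float
    holo: bool = True
    alpha_max: float = 0.0
    ligand_range_M: tuple[float, float] = DEFAULT_LIGAND_RANGE_M
    selectivity: Mapping[str, float] = field(default_factory=dict)
    dmso_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.vmax_blank <= 0:
            raise InvalidInputError("vmax_blank must be > 0")
        if self.km_mM <= 0:
            raise InvalidInputError("km_mM must be > 0")
        if not 0.0 <= self.alpha_max < 1.0:
            raise InvalidInputError("alpha_max must be in [0, 1)")
        c_lo, c_hi = self.ligand_range_M
        if not 0 < c_lo < c_hi:
            raise InvalidInputError("ligand_range_M must satisfy 0 < c_lo < c_hi")
        for sp, w in self.selectivity.items():
            if not 0.0 <= w <= 1.0:
                raise InvalidInputError(f"selectivity weight for {sp!r} not in [0, 1]")
        if not 0.0 < self.dmso_factor <= 1.0:
            raise InvalidInputError("dmso_factor must be in (0, 1]")


@dataclass(frozen=True)
class AssayTrace:
    """A DCPIP absorbance-vs-time trace for one replicate and condition."""

    times_s: np.ndarray
    absorbance_600: np.ndarray
    glucose_mM: float
    dose: LigandDose
    replicate_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.absorbance_600, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "absorbance_600", a)
        if t.shape != a.shape or t.ndim != 1:
            raise InvalidInputError("times and absorbance must be equal-length 1-D")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(a < 0):
            raise InvalidInputError("absorbance must be >= 0")


def _dose_response(c: float, c_lo: float, c_hi: float) -> float:
    """Occupancy-like dose response h(c) in [0, 1].

    h = 1 on [c_lo, c_hi] and above c_hi (the response stays saturated);
    below c_lo it rolls off along a Hill curve (EC50 = c_lo/3, coefficient
    1) rescaled to reach exactly 1 at c_lo, keeping h continuous.
    """
    if c <= 0.0:
        return 0.0
    if c >= c_lo:
        return 1.0
    ec50 = c_lo / 3.0
    return (c / (c + ec50)) / (c_lo / (c_lo + ec50))


def inhibition_factor(params: EnzymeParams, dose: LigandDose) -> float:
    """Multiplicative rate factor f in (0, 1] for a ligand condition.

    ``f = dmso * (1 - alpha_max * w_species * h(c))``; the DMSO factor
    applies only when the dose actually carries vehicle.  Monotone
    non-increasing in the cognate ligand concentration.
    """
    vehicle = params.dmso_factor if dose.vehicle_dmso > 0 else 1.0
    w = float(params.selectivity.get(dose.species, 0.0))
    c_lo, c_hi = params.ligand_range_M
    h = _dose_response(dose.concentration_M, c_lo, c_hi)
    return vehicle * (1.0 - params.alpha_max * w * h)


def catalytic_rate(params: EnzymeParams, glucose_mM: float, dose: LigandDose = NO_DOSE) -> float:
    """Michaelis-Menten rate in a.u./s under a ligand condition.

    The apo enzyme (no PQQ) is catalytically dead and returns 0.
    """
    if glucose_mM < 0:
        raise InvalidInputError(f"glucose concentration must be >= 0, got {glucose_mM}")
    if not params.holo:
        return 0.0
    f = inhibition_factor(params, dose)
    return f * params.vmax_blank * glucose_mM / (params.km_mM + glucose_mM)


def simulate_dcpip_trace(
    params: EnzymeParams,
    glucose_mM: float,
    dose: LigandDose,
    duration_s: float = 600.0,
    dt_s: float = 15.0,
    cv: float = 0.0,
    seed: int | None = 0,
    *,
    a0: float = 1.0,
    k_abs: float = 1.0,
    replicate_id: int = 0,
) -> AssayTrace:
    """Simulate a DCPIP decolorization trace, A(t) = max(0, A0 - k_abs*v*t).

    Replicate noise is multiplicative Gaussian on the rate (one draw per
    trace, matching how assay CV is reported), with coefficient of
    variation ``cv``.  Deterministic for a fixed ``seed``.
    """
    if duration_s <= 0 or dt_s <= 0:
        raise InvalidInputError("duration_s and dt_s must be > 0")
    if cv < 0:
        raise InvalidInputError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    v = catalytic_rate(params, glucose_mM, dose)
    if cv > 0:
        v = max(0.0, v * (1.0 + cv * rng.standard_normal()))
    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    a = np.maximum(0.0, a0 - k_abs * v * t)
    return AssayTrace(t, a, glucose_mM, dose, replicate_id)


def activity_from_trace(trace: AssayTrace, window_s: tuple[float, float] | None = None) -> float:
    """Enzymatic activity (a.u./s) as minus the OLS slope of A(t).

    ``window_s`` restricts the fit to ``[t0, t1]``; the window must contain
    at least three samples.
    """
    t, a = trace.times_s, trace.absorbance_600
    if window_s is not None:
        t0, t1 = window_s
        mask = (t >= t0) & (t <= t1)
        t, a = t[mask], a[mask]
    if t.size < 3:
        raise InsufficientDataError(
            f"slope estimation needs >= 3 samples in the window, got {t.size}"
        )
    slope = np.polynomial.polynomial.polyfit(t, a, 1)[1]
    return -float(slope)


class MichaelisMentenFit(NamedTuple):
    """Result of a nonlinear Michaelis-Menten fit."""

    vmax: float
    km_mM: float
    vmax_stderr: float
    km_stderr: float


def _mm_model(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(S_mM: np.ndarray, v: np.ndarray) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of v = vmax*S/(km+S).

    Requires >= 4 points with >= 3 distinct glucose concentrations and
    non-negative rates.  Raises :class:`FitError` with a diagnostic when
    the optimizer fails or the covariance is undefined.
    """
    S = np.asarray(S_mM, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape or S.ndim != 1:
        raise InvalidInputError("S and v must be equal-length 1-D vectors")
    if S.size < 4:
        raise InsufficientDataError("Michaelis-Menten fit needs >= 4 points")
    if np.unique(S).size < 3:
        raise InsufficientDataError("need >= 3 distinct glucose concentrations")
    if np.any(v < 0) or np.any(S < 0):
        raise InvalidInputError("concentrations and rates must be >= 0")
    vmax0 = float(v.max()) or 1.0
    km0 = float(np.median(S[S > 0])) if np.any(S > 0) else 1.0
    try:
        popt, pcov = optimize.curve_fit(
            _mm_model, S, v, p0=(vmax0, km0), bounds=([0.0, 1e-12], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    if not np.all(np.isfinite(popt)):
        raise FitError("Michaelis-Menten fit returned non-finite parameters")
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    return MichaelisMentenFit(float(popt[0]), float(popt[1]), float(perr[0]), float(perr[1]))
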