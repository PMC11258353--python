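"""Ratiometric decoding of the 4-HT signal from dual-electrode currents.

The glucose current from the engineered electrode (GDH-5E+, WE-1) is
normalized by the current from a wild-type GDH electrode (WE-2) measured in
the same cell.  Above the operational glucose threshold (0.4 mM) the ratio
r = i_5E+ / i_wt is glucose-invariant, so its value carries only the ligand
information: r near the blank reference (6.37) means no 4-HT, r near the
positive reference (4.85) means 4-HT is present.  The decision is the
nearest reference (midpoint boundary 5.61), refused as INDETERMINATE when
the ratio is implausibly far from both references, and refused as
OUT_OF_RANGE when the glucose gate fails.

First-order (delta-method) error propagation supplies the ratio's
uncertainty; replicate comparisons use unpaired two-tailed t-tests
(pooled-variance by default, Welch available).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError, UndefinedRatioError
from .kinetics import EnzymeParams, LigandDose, catalytic_rate

__all__ = [
    "OPERATIONAL_GLUCOSE_MM",
    "GroupStats",
    "DualMeasurement",
    "RatioReference",
    "Call",
    "Decision",
    "current_ratio",
    "ratio_curve",
    "in_operational_range",
    "classify",
    "decode",
    "compare_groups",
    "compare_groups_from_stats",
    "TTestResult",
]

#: Strict lower glucose bound (mM) of the sensor's operational range.
OPERATIONAL_GLUCOSE_MM = 0.4


class GroupStats(NamedTuple):
    """Summary statistics of one replicate group."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class DualMeasurement:
    """Steady currents from the two working electrodes of one test."""

    i_5e: GroupStats
    i_wt: GroupStats
    glucose_mM_est: float | None = None

    def __post_init__(self) -> None:
        for g in (self.i_5e, self.i_wt):
            if g.sd < 0 or g.n < 1:
                raise InvalidInputError("group sd must be >= 0 and n >= 1")
        if self.glucose_mM_est is not None and self.glucose_mM_est < 0:
            raise InvalidInputError("glucose estimate must be >= 0")


@dataclass(frozen=True)
class RatioReference:
    """Reference ratios for the blank and 4-HT-positive states."""

    r_blank: GroupStats = GroupStats(6.37, 0.1, 8)
    r_positive: GroupStats = GroupStats(4.85, 0.1, 9)
    indeterminate_z: float = 3.0

    def __post_init__(self) -> None:
        if not self.r_blank.mean > self.r_positive.mean:
            raise InvalidInputError("blank reference ratio must exceed positive")
        if self.r_blank.sd <= 0 or self.r_positive.sd <= 0:
            raise InvalidInputError("reference sds must be > 0")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.r_blank.mean + self.r_positive.mean)


class Call(enum.Enum):
    """Binary 4-HT determination (with two refusal states)."""

    POSITIVE_4HT = "POSITIVE_4HT"
    NEGATIVE = "NEGATIVE"
    INDETERMINATE = "INDETERMINATE"
    OUT_OF_RANGE = "OUT_OF_RANGE"


@dataclass(frozen=True)
class Decision:
    """Outcome of the ratiometric decoding of one dual measurement."""

    call: Call
    ratio: float
    ratio_sd: float
    z_blank: float
    z_positive: float


def current_ratio(m: DualMeasurement) -> tuple[float, float]:
    """Ratio r = i_5E+/i_wt and its first-order propagated sd.

    sd_r = r * sqrt((sd_5e/mean_5e)^2 + (sd_wt/mean_wt)^2), assuming the
    two electrode currents are independent.
    """
    if m.i_5e.mean <= 0 or m.i_wt.mean <= 0:
        raise UndefinedRatioError("both electrode currents must be > 0 for a ratio")
    r = m.i_5e.mean / m.i_wt.mean
    sd_r = r * math.hypot(m.i_5e.sd / m.i_5e.mean, m.i_wt.sd / m.i_wt.mean)
    return r, sd_r


def ratio_curve(
    e5: EnzymeParams,
    ew: EnzymeParams,
    loadings: tuple[float, float],
    glucose_grid_mM: np.ndarray,
    dose: LigandDose,
) -> np.ndarray:
    """Model ratio r(S) = k1*v_5E+(S, dose) / (k2*v_wt(S, dose)) on a grid.

    The wild-type electrode sits in the same solution, so it sees the same
    dose; with an empty selectivity map only its vehicle factor responds.
    """
    grid = np.asarray(glucose_grid_mM, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(grid <= 0):
        raise InvalidInputError("glucose grid must be 1-D and positive")
    if np.any(np.diff(grid) <= 0):
        raise InvalidInputError("glucose grid must be strictly increasing")
    k1, k2 = loadings
    if k1 <= 0 or k2 <= 0:
        raise InvalidInputError("electrode loadings must be > 0")
    v5 = np.array([catalytic_rate(e5, s, dose) for s in grid])
    vw = np.array([catalytic_rate(ew, s, dose) for s in grid])
    return (k1 * v5) / (k2 * vw)


def in_operational_range(glucose_mM_est: float | None) -> bool:
    """Gate: glucose strictly above 0.4 mM.

    With no estimate the gate passes with a warning (whole blood is assumed
    to carry 4-6 mM glucose).
    """
    if glucose_mM_est is None:
        warnings.warn(
            "no glucose estimate supplied; assuming blood-range glucose (4-6 mM)",
            stacklevel=2,
        )
        return True
    if glucose_mM_est < 0:
        raise InvalidInputError("glucose estimate must be >= 0")
    return glucose_mM_est > OPERATIONAL_GLUCOSE_MM


def classify(
    r: float,
    sd_r: float,
    refs: RatioReference = RatioReference(),
    range_ok: bool = True,
) -> Decision:
    """Nearest-reference binary call with an indeterminate band.

    z-scores to each reference combine the measurement sd and the
    reference sd in quadrature.  If the gate failed -> OUT_OF_RANGE; if
    both |z| exceed ``indeterminate_z`` (or the ratio sits exactly on the
    midpoint) -> INDETERMINATE; otherwise the side of the midpoint decides.
    """
    if sd_r < 0:
        raise InvalidInputError("sd_r must be >= 0")
    z_b = (r - refs.r_blank.mean) / math.hypot(sd_r, refs.r_blank.sd)
    z_p = (r - refs.r_positive.mean) / math.hypot(sd_r, refs.r_positive.sd)
    if not range_ok:
        return Decision(Call.OUT_OF_RANGE, r, sd_r, z_b, z_p)
    if min(abs(z_b), abs(z_p)) > refs.indeterminate_z or r == refs.midpoint:
        return Decision(Call.INDETERMINATE, r, sd_r, z_b, z_p)
    call = Call.NEGATIVE if r > refs.midpoint else Call.POSITIVE_4HT
    return Decision(call, r, sd_r, z_b, z_p)


def decode(m: DualMeasurement, refs: RatioReference = RatioReference()) -> Decision:
    """End-to-end decoding: ratio, propagation, range gate, classification."""
    r, sd_r = current_ratio(m)
    return classify(r, sd_r, refs, in_operational_range(m.glucose_mM_est))


class TTestResult(NamedTuple):
    """Two-tailed unpaired t-test summary."""

    t: float
    p: float
    df: float


def compare_groups(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-tailed unpaired t-test on raw replicates (pooled by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 replicates")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.pvalue), float(res.df))


def compare_groups_from_stats(
    a: GroupStats, b: GroupStats, equal_var: bool = True
) -> TTestResult:
    """Two-tailed unpaired t-test from mean/sd/n summaries.

    Useful when only published summaries (mean +/- sd, n) are available.
    """
    if a.n < 2 or b.n < 2:
        raise InsufficientDataError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(float(res.statistic), float(res.pvalue), df)
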