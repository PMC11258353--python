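"""Two-round domain-insertion library screening statistics.

A ligand-binding domain is inserted after each of the 454 residues of GDH
and the library is screened colorimetrically.  Round 1 calls a position
*permissive* when its DCPIP decay rate clearly exceeds the empty-vector
control (a fold-threshold formalizes the by-eye comparison; reagent decay
is handled by comparing against the control rate).  Round 2 calls a
permissive position *allosteric* when triplicate activities under 4-HT
differ significantly from DMSO (two-tailed unpaired t-test, p < alpha).
Summary fractions, secondary-structure enrichment (chi-square against a
length-weighted null) and colony-picking coverage (coupon-collector
inclusion-exclusion) complete the analysis.

Tables are plain pandas DataFrames with the columns documented in
:data:`SCREEN_COLUMNS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AnnotationGapError,
    InsufficientDataError,
    InvalidInputError,
    MissingDataError,
)

__all__ = [
    "N_POSITIONS",
    "SCREEN_COLUMNS",
    "SS_CLASSES",
    "ProfileSummary",
    "EnrichmentResult",
    "CoverageResult",
    "round1_classify",
    "round2_allosteric",
    "classify_table",
    "profile_summary",
    "structural_enrichment",
    "coverage_probability",
    "coverage_from_reads",
    "classification_from_truth",
]

#: Number of insertion positions in GDH (one after each residue).
N_POSITIONS = 454

#: Expected columns of a screen table.
SCREEN_COLUMNS = (
    "position", "reads", "r1_rate", "r1_control_rate",
    "dmso_1", "dmso_2", "dmso_3", "ht_1", "ht_2", "ht_3",
)

#: Secondary-structure classes used for enrichment.
SS_CLASSES = ("loop", "helix", "sheet")


def round1_classify(
    r1_rate: float, neg_control_rate: float, fold_threshold: float = 3.0
) -> bool:
    """Permissive call: decay rate >= fold_threshold x control rate.

    The control (empty-vector cells) carries the reagent's intrinsic decay,
    so comparing against it removes that drift.
    """
    if r1_rate is None or (isinstance(r1_rate, float) and math.isnan(r1_rate)):
        raise MissingDataError("round-1 rate is missing")
    if neg_control_rate < 0:
        raise InvalidInputError("control rate must be >= 0")
    if fold_threshold <= 0:
        raise InvalidInputError("fold threshold must be > 0")
    return r1_rate >= fold_threshold * neg_control_rate


def round2_allosteric(
    dmso: Sequence[float],
    ht: Sequence[float],
    alpha: float = 0.05,
    permissive: bool = True,
    equal_var: bool = True,
) -> tuple[float, bool]:
    """Round-2 call: (p-value, allosteric flag).

    Two-tailed unpaired t-test on replicate activities with and without
    4-HT; a variant is allosteric only if it is permissive *and* p < alpha.
    """
    d = np.asarray(dmso, dtype=float)
    h = np.asarray(ht, dtype=float)
    if d.size < 2 or h.size < 2:
        raise InsufficientDataError("round-2 test needs >= 2 replicates per condition")
    if not 0 < alpha < 1:
        raise InvalidInputError("alpha must be in (0, 1)")
    p = float(stats.ttest_ind(d, h, equal_var=equal_var).pvalue)
    return p, bool(permissive and p < alpha)


def classify_table(
    table: pd.DataFrame,
    fold_threshold: float = 3.0,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Run both screening rounds over a whole table (vectorized).

    Returns a copy with ``permissive``, ``p_value`` and ``allosteric``
    columns added.  Round-2 p-values are computed for every row but gate
    only permissive rows.
    """
    missing = [c for c in SCREEN_COLUMNS if c not in table.columns]
    if missing:
        raise MissingDataError(f"screen table lacks columns: {missing}")
    out = table.copy()
    if out["r1_rate"].isna().any():
        raise MissingDataError("round-1 rates contain missing values")
    out["permissive"] = (
        out["r1_rate"].to_numpy() >= fold_threshold * out["r1_control_rate"].to_numpy()
    )
    d = out[["dmso_1", "dmso_2", "dmso_3"]].to_numpy(dtype=float)
    h = out[["ht_1", "ht_2", "ht_3"]].to_numpy(dtype=float)
    p = stats.ttest_ind(d, h, axis=1, equal_var=equal_var).pvalue
    out["p_value"] = p
    out["allosteric"] = out["permissive"] & (p < alpha)
    return out


def classification_from_truth(table: pd.DataFrame) -> pd.DataFrame:
    """Turn ground-truth labels into permissive/allosteric flag columns.

    For synthetic tables carrying a ``truth_label`` column; allosteric
    implies permissive.
    """
    if "truth_label" not in table.columns:
        raise MissingDataError("table has no truth_label column")
    out = table.copy()
    out["allosteric"] = out["truth_label"] == "allosteric"
    out["permissive"] = out["allosteric"] | (out["truth_label"] == "permissive")
    return out


@dataclass(frozen=True)
class ProfileSummary:
    """Library-level counts and fractions of permissive/allosteric sites."""

    n_total: int
    n_permissive: int
    n_allosteric: int
    frac_permissive: float
    frac_allosteric: float
    ss_counts: dict | None = None


def profile_summary(classified: pd.DataFrame, ss: pd.DataFrame | None = None) -> ProfileSummary:
    """Exact counts/fractions from a classified screen table.

    With a secondary-structure annotation, per-class counts of permissive
    and allosteric sites are included.
    """
    for col in ("permissive", "allosteric"):
        if col not in classified.columns:
            raise MissingDataError(f"table not classified: missing {col!r}")
    n = int(len(classified))
    n_perm = int(classified["permissive"].sum())
    n_allo = int(classified["allosteric"].sum())
    ss_counts = None
    if ss is not None and n > 0:
        lab = ss.set_index("residue")["ss_class"]
        ss_counts = {}
        for flag in ("permissive", "allosteric"):
            pos = classified.loc[classified[flag], "position"]
            ss_counts[flag] = pos.map(lab).value_counts().to_dict()
    return ProfileSummary(
        n_total=n,
        n_permissive=n_perm,
        n_allosteric=n_allo,
        frac_permissive=n_perm / n if n else 0.0,
        frac_allosteric=n_allo / n if n else 0.0,
        ss_counts=ss_counts,
    )


class EnrichmentResult(NamedTuple):
    """Secondary-structure distribution of a site set vs a length-weighted null."""

    counts: dict
    fractions: dict
    expected: dict
    chi2: float
    p: float


def structural_enrichment(sites: Sequence[int], ss: pd.DataFrame) -> EnrichmentResult:
    """Chi-square enrichment of sites across loop/helix/sheet classes.

    The null assigns sites proportionally to each class's residue count.
    Every site must be annotated.
    """
    sites = list(sites)
    if not sites:
        raise InsufficientDataError("no sites supplied")
    lab = ss.set_index("residue")["ss_class"]
    unknown = [s for s in sites if s not in lab.index]
    if unknown:
        raise AnnotationGapError(f"positions lack annotation: {unknown[:5]}")
    site_classes = lab.loc[sites]
    class_sizes = lab.value_counts()
    classes = [c for c in SS_CLASSES if c in class_sizes.index]
    counts = {c: int((site_classes == c).sum()) for c in classes}
    n = len(sites)
    total_res = int(class_sizes[classes].sum())
    expected = {c: n * class_sizes[c] / total_res for c in classes}
    obs = np.array([counts[c] for c in classes], dtype=float)
    exp = np.array([expected[c] for c in classes], dtype=float)
    chi2, p = stats.chisquare(obs, exp)
    fractions = {c: counts[c] / n for c in classes}
    return EnrichmentResult(counts, fractions, expected, float(chi2), float(p))


class CoverageResult(NamedTuple):
    """Coupon-collector coverage of a variant library by colony picking."""

    probability: float
    union_lower_bound: float


def coverage_probability(n_picks: int, n_variants: int) -> CoverageResult:
    """P(every variant sampled >= once) for N equiprobable picks of n variants.

    Inclusion-exclusion over the coupon-collector model,
    P = sum_k (-1)^k C(n,k) ((n-k)/n)^N, evaluated in log space; the
    Bonferroni/union lower bound 1 - n (1 - 1/n)^N is reported alongside.
    """
    if n_picks < 0 or n_variants < 1:
        raise InvalidInputError("need n_picks >= 0 and n_variants >= 1")
    n, N = n_variants, n_picks
    if N == 0:
        p = 1.0 if n == 0 else 0.0
        return CoverageResult(0.0 if n >= 1 else 1.0, 0.0)
    total = 0.0
    for k in range(0, n + 1):
        if n - k == 0:
            term = 0.0 if N > 0 else 1.0
        else:
            log_term = (
                math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
                + N * math.log((n - k) / n)
            )
            term = math.exp(log_term)
        if k > 0 and term < 1e-18:
            break
        total += term if k % 2 == 0 else -term
    prob = min(max(total, 0.0), 1.0)
    lower = max(0.0, 1.0 - n * (1.0 - 1.0 / n) ** N) if n > 1 else (1.0 if N >= 1 else 0.0)
    return CoverageResult(prob, lower)


def coverage_from_reads(
    read_counts: Sequence[int], n_positions: int = N_POSITIONS
) -> tuple[int, float]:
    """(positions with >= 1 read, completeness fraction) from per-position counts."""
    counts = np.asarray(read_counts)
    if counts.size != n_positions:
        raise InvalidInputError(
            f"expected {n_positions} per-position counts, got {counts.size}"
        )
    if np.any(counts < 0):
        raise InvalidInputError("read counts must be >= 0")
    covered = int((counts > 0).sum())
    return covered, covered / n_positions
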