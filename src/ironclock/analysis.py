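"""Cohort-level statistics: group comparisons, floor rule, trend fits.

Two-group comparisons follow a normality gate: both samples must pass a
Kolmogorov-Smirnov test against a normal with estimated moments
(Lilliefors-corrected p) at alpha = 0.05 for the pooled-variance t test
to apply; otherwise the Mann-Whitney U test (normal approximation with
tie correction) is used.  Viral loads below the 20 copies/mL assay
detection limit are replaced by 10, the midpoint of the undetectable
range, before any fit.  Age trends use ordinary least squares: a
quadratic for ferritin-vs-age, a line for biological-vs-chronological
age per group or regimen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .calibration import fit_normalized_slope
from .datamodel import SubjectRecord
from .io import subjects_to_frame

ALPHA = 0.05

#: assay lower detection limit (copies/mL) and the imputed midpoint
PVL_LIMIT = 20.0
PVL_IMPUTED = 10.0


def pvl_floor(pvl):
    """Map viral loads below the detection limit to the range midpoint.

    Values below 20 copies/mL become 10; detectable values pass through
    unchanged.  Idempotent; scalar or array input.
    """
    arr = np.asarray(pvl, dtype=float)
    if (arr < 0).any():
        raise ValueError("viral load cannot be negative")
    out = np.where(arr < PVL_LIMIT, PVL_IMPUTED, arr)
    return float(out) if np.ndim(pvl) == 0 else out


class Normality(str, Enum):
    normal = "normal"
    non_normal = "non_normal"


def normality_gate(sample, alpha: float = ALPHA) -> Normality:
    """Kolmogorov-Smirnov normality check with estimated mean and SD."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 4:
        raise ValueError(f"normality test needs n >= 4, got {sample.size}")
    if np.ptp(sample) == 0:
        warnings.warn("constant sample; treating as non-normal")
        return Normality.non_normal
    _, p = lilliefors(sample, dist="norm")
    return Normality.normal if p >= alpha else Normality.non_normal


class StatTest(str, Enum):
    t_test = "t_test"
    mann_whitney = "mann_whitney"


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    groups: tuple
    n: tuple
    test: StatTest
    statistic: float
    p_value: float
    df: Optional[float] = None
    #: (centre, spread) per group: mean/SD under t, median/IQR otherwise
    summary: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def compare_groups(
    a,
    b,
    variable: str = "",
    groups: tuple = ("a", "b"),
    gate: Optional[tuple] = None,
) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Pooled-variance two-sided t test (df = n_a + n_b - 2) when both
    samples pass the gate; Mann-Whitney U (asymptotic, tie-corrected)
    otherwise.  Pass precomputed ``gate`` results to skip re-testing.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise ValueError("both samples are a single constant; no test applies")
    if gate is None:
        gate = (normality_gate(a), normality_gate(b))
    both_normal = gate[0] is Normality.normal and gate[1] is Normality.normal
    if both_normal:
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        df = a.size + b.size - 2
        summary = (
            (float(np.mean(a)), float(np.std(a, ddof=1))),
            (float(np.mean(b)), float(np.std(b, ddof=1))),
        )
        return ComparisonResult(variable, groups, (a.size, b.size), StatTest.t_test,
                                float(stat), float(p), float(df), summary)
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    summary = (
        (float(np.median(a)), float(stats.iqr(a))),
        (float(np.median(b)), float(stats.iqr(b))),
    )
    return ComparisonResult(variable, groups, (a.size, b.size), StatTest.mann_whitney,
                            float(stat), float(p), None, summary)


@dataclass(frozen=True)
class PolyFit2:
    """Least-squares quadratic: value = c0 + c1*age + c2*age^2."""

    c0: float
    c1: float
    c2: float
    n: int
    residual_sd: float


def polyfit2(ages, values) -> PolyFit2:
    """Second-order polynomial fit of a biomarker on age."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.unique(ages).size < 3:
        raise ValueError("need at least 3 distinct ages for a quadratic fit")
    c2, c1, c0 = np.polyfit(ages, values, 2)
    resid = values - (c0 + c1 * ages + c2 * ages**2)
    dof = max(ages.size - 3, 1)
    return PolyFit2(float(c0), float(c1), float(c2), int(ages.size),
                    float(np.sqrt(np.sum(resid**2) / dof)))


@dataclass(frozen=True)
class LinFit:
    group: str
    slope: float
    intercept: float
    n: int


IDENTITY_LINE = LinFit(group="referent", slope=1.0, intercept=0.0, n=0)


def bioage_fits(
    bioage_frame: pd.DataFrame,
    cohort: Optional[Iterable[SubjectRecord]] = None,
    grouping: str = "hiv_status",
    include_identity: bool = True,
) -> list[LinFit]:
    """Linear fits of biological on chronological age, one per group.

    ``grouping`` is ``"hiv_status"`` or ``"regimen"`` (the latter needs
    ``cohort`` to label rows).  The referent identity line a_bio = a is
    prepended for reference.  Groups with fewer than 2 distinct ages are
    skipped with a warning.
    """
    frame = bioage_frame
    if grouping not in frame.columns:
        if cohort is None:
            raise ValueError(f"grouping {grouping!r} needs the cohort records")
        labels = subjects_to_frame(cohort)[["subject_id", grouping]]
        frame = frame.merge(labels, on="subject_id", how="left")
    fits: list[LinFit] = [IDENTITY_LINE] if include_identity else []
    for label, block in frame.groupby(grouping, sort=True):
        ages = block["age"].to_numpy(dtype=float)
        if np.unique(ages).size < 2:
            warnings.warn(f"group {label!r}: fewer than 2 distinct ages; skipped")
            continue
        fit = fit_normalized_slope(ages, block["a_bio"].to_numpy(dtype=float), str(label))
        fits.append(LinFit(str(label), fit.k_x, fit.n_x, len(block)))
    return fits


@dataclass(frozen=True)
class PairFit:
    """Exploratory linear relation between two cohort variables."""

    x: str
    y: str
    slope: float
    intercept: float
    r_value: float
    n: int


#: (x, y) pairs scanned for exploratory relations
_SCAN_PAIRS = [
    ("pvl", "rtl"),
    ("therapy_duration", "rtl"),
    ("pvl", "serum_iron"), ("pvl", "tibc"), ("pvl", "ferritin"),
    ("rtl", "serum_iron"), ("rtl", "tibc"), ("rtl", "ferritin"),
]


def relation_scan(cohort: Iterable[SubjectRecord]) -> list[PairFit]:
    """Pairwise linear fits among viral load, telomere length, iron panel.

    Viral loads pass through the detection-limit floor first.  Reports
    slopes and Pearson r only — no significance claims; pairs with
    fewer than 3 complete observations are skipped.
    """
    frame = subjects_to_frame(cohort)
    if "pvl" in frame.columns:
        detected = frame["pvl"].notna()
        frame.loc[detected, "pvl"] = pvl_floor(frame.loc[detected, "pvl"].to_numpy())
    fits: list[PairFit] = []
    for x, y in _SCAN_PAIRS:
        if x not in frame.columns or y not in frame.columns:
            continue
        block = frame[[x, y]].dropna()
        if len(block) < 3 or block[x].nunique() < 2:
            continue
        res = stats.linregress(block[x], block[y])
        fits.append(PairFit(x, y, float(res.slope), float(res.intercept),
                            float(res.rvalue), len(block)))
    return fits


def compare_cohort_variable(
    cohort: Iterable[SubjectRecord], variable: str, split: str = "hiv_status"
) -> ComparisonResult:
    """Convenience: gate-and-compare one biomarker across a two-level split."""
    frame = subjects_to_frame(cohort)
    levels = sorted(frame[split].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"split {split!r} must have exactly 2 levels, got {levels}")
    a = frame.loc[frame[split] == levels[0], variable].dropna().to_numpy()
    b = frame.loc[frame[split] == levels[1], variable].dropna().to_numpy()
    return compare_groups(a, b, variable=variable, groups=(str(levels[0]), str(levels[1])))
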