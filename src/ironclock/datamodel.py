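"""Domain types for the composite biological-age clock.

The clock combines relative telomere length (RTL, a dimensionless T/S
ratio) with three iron-metabolism biomarkers (serum iron, total
iron-binding capacity, serum ferritin) and chronological age into a
single biological-age estimate.  Calibration constants are derived from
a referent population in two age bands (19-35 and 50-77 years); the
built-in constants ship with the package and are exposed through
:func:`ironclock.io.load_reference_constants`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

#: The five formula variables, in canonical order: relative telomere
#: length, serum iron, total iron-binding capacity, serum ferritin,
#: chronological age.
VARIABLES = ("RTL", "Fe", "TIBC", "F", "a")

#: micrograms of iron per decilitre corresponding to 1 umol/L
#: (atomic mass of iron, 55.845 g/mol; 1 dL = 0.1 L).
UMOL_L_TO_UG_DL = 5.5845


class HIVStatus(str, Enum):
    negative = "negative"
    positive = "positive"


class Regimen(str, Enum):
    """Antiretroviral regimen class.

    ``none`` for uninfected subjects, ``naive`` for untreated HIV+
    subjects, and the two combined-therapy classes (two NRTIs plus
    either an NNRTI or a protease inhibitor).
    """

    none = "none"
    naive = "naive"
    nrti_nnrti = "nrti_nnrti"
    nrti_pi = "nrti_pi"


class BandLabel(str, Enum):
    younger = "younger"
    older = "older"


@dataclass(frozen=True)
class AgeBand:
    """Closed age interval used for calibration."""

    label: BandLabel
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"age band requires lower < upper, got [{self.lower}, {self.upper}]")

    def contains(self, age: float) -> bool:
        return self.lower <= age <= self.upper


YOUNGER_BAND = AgeBand(BandLabel.younger, 19.0, 35.0)
OLDER_BAND = AgeBand(BandLabel.older, 50.0, 77.0)

BANDS: Mapping[BandLabel, AgeBand] = {
    BandLabel.younger: YOUNGER_BAND,
    BandLabel.older: OLDER_BAND,
}


@dataclass
class SubjectRecord:
    """One subject's demographics and biomarker panel.

    Iron and TIBC are stored canonically in ug/dL; ferritin in ug/L;
    RTL is a dimensionless T/S ratio.  ``transferrin`` is in umol/L and
    ``transferrin_saturation`` in percent; neither enters the clock
    (saturation is iron/TIBC and transferrin tracks TIBC).
    """

    subject_id: str
    age: float
    hiv_status: HIVStatus
    regimen: Regimen = Regimen.none
    therapy_duration: Optional[float] = None  # months
    pvl: Optional[float] = None  # copies/mL
    cd4: Optional[float] = None  # cells/uL
    rtl: Optional[float] = None
    serum_iron: Optional[float] = None  # ug/dL
    tibc: Optional[float] = None  # ug/dL
    transferrin_saturation: Optional[float] = None  # percent
    transferrin: Optional[float] = None  # umol/L
    ferritin: Optional[float] = None  # ug/L

    def __post_init__(self) -> None:
        self.hiv_status = HIVStatus(self.hiv_status)
        self.regimen = Regimen(self.regimen)
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        for name in (
            "therapy_duration", "pvl", "cd4", "rtl", "serum_iron",
            "tibc", "transferrin_saturation", "transferrin", "ferritin",
        ):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if self.regimen in (Regimen.naive, Regimen.nrti_nnrti, Regimen.nrti_pi):
            if self.hiv_status is not HIVStatus.positive:
                raise ValueError(
                    f"regimen {self.regimen.value!r} requires hiv_status 'positive'"
                )

    def formula_inputs(self) -> Mapping[str, Optional[float]]:
        """The five clock inputs keyed by canonical variable name."""
        return {
            "RTL": self.rtl,
            "Fe": self.serum_iron,
            "TIBC": self.tibc,
            "F": self.ferritin,
            "a": self.age,
        }

    @property
    def clock_eligible(self) -> bool:
        """True when every clock input is present."""
        return all(v is not None for v in self.formula_inputs().values())


@dataclass(frozen=True)
class LifeExpectancySet:
    """Life expectancies that parameterize the adjustment terms.

    ``a_life_exp`` is the study population's life expectancy,
    ``a_ref_life_exp`` the referent (calibration) population's, and
    ``a_hiv_life_exp`` the life expectancy of HIV+ subjects whose
    treatment started at age 20.
    """

    a_life_exp: float = 72.9
    a_ref_life_exp: float = 76.1
    a_hiv_life_exp: float = 67.0

    def __post_init__(self) -> None:
        for name in ("a_life_exp", "a_ref_life_exp", "a_hiv_life_exp"):
            if not getattr(self, name) > 20:
                raise ValueError(f"{name} must exceed 20 years")


@dataclass
class CalibrationConstants:
    """Per-band normalization moments, age slopes, and clock constants.

    ``mu``/``sigma`` are the referent-population moments used for
    z-scoring; ``slope``/``intercept`` are the per-year OLS coefficients
    of each z-scored variable on age (k_X, n_X); ``k`` scales the summed
    signed z-scores so the clock tracks chronological age one-for-one in
    the referent population and ``C`` centres it; the two deltas are the
    per-year life-expectancy adjustments.
    """

    band: AgeBand
    mu: dict
    sigma: dict
    slope: dict
    intercept: dict
    k: float
    C: float
    delta_hiv_neg: float = 0.0
    delta_hiv_pos: float = 0.0

    def __post_init__(self) -> None:
        for mapping, label in ((self.mu, "mu"), (self.sigma, "sigma"),
                               (self.slope, "slope"), (self.intercept, "intercept")):
            if set(mapping) != set(VARIABLES):
                raise ValueError(
                    f"{label} must have exactly the keys {VARIABLES}, got {sorted(mapping)}"
                )
        for var, s in self.sigma.items():
            if not s > 0:
                raise ValueError(f"sigma[{var}] must be positive, got {s}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        abs_sum = sum(abs(v) for v in self.slope.values())
        # Printed-table constants are rounded to 4 dp, so allow a loose
        # consistency band; exactly derived constants satisfy this tightly.
        if abs_sum > 0 and abs(self.k - 1.0 / abs_sum) > 0.01:
            raise ValueError(
                f"k = {self.k} inconsistent with 1/sum|k_X| = {1.0 / abs_sum:.6f}"
            )

    def sign(self, var: str) -> float:
        """sgn(k_X); zero slopes map to +1 (degenerate, warned upstream)."""
        return math.copysign(1.0, self.slope[var]) if self.slope[var] != 0 else 1.0


@dataclass
class BioAgeResult:
    """Biological age with its per-term decomposition.

    ``term_contributions`` holds sgn(k_X) * X_norm per variable, so
    a_bio = k * sum(terms) + C + adjustment_neg + adjustment_pos.
    """

    subject_id: str
    band: BandLabel
    a_bio: float
    term_contributions: dict = field(default_factory=dict)
    adjustment_neg: float = 0.0
    adjustment_pos: float = 0.0


def umol_l_to_ug_dl(value: float) -> float:
    """Convert an iron concentration from umol/L to ug/dL."""
    return value * UMOL_L_TO_UG_DL


def ug_dl_to_umol_l(value: float) -> float:
    """Convert an iron concentration from ug/dL to umol/L."""
    return value / UMOL_L_TO_UG_DL
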