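"""Synthetic referent populations and HIV study cohorts.

Two generators back the test bed:

* :func:`generate_referent` draws a calibration sample in which each
  biomarker's z-score has unit variance and a prescribed OLS slope on
  age, so the calibration pipeline can be checked against known truth.
* :func:`generate_cohort` draws an HIV+/HIV- cross-sectional cohort
  whose per-group biomarker moments default to the published study's
  (telomere T/S ratios, ferritin, pooled iron panel, CD4, therapy
  duration), with regimen labels and a plasma-viral-load mixture that
  has a configurable undetectable fraction.

All randomness flows from one integer seed expanded into independent
per-group streams, so adding a group leaves the others' draws intact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .calibration import ReferentPopulation
from .datamodel import (
    BANDS,
    BandLabel,
    HIVStatus,
    Regimen,
    SubjectRecord,
    umol_l_to_ug_dl,
)
from .io import load_reference_constants

#: assay lower detection limit for plasma viral load, copies/mL
PVL_DETECTION_LIMIT = 20.0


def _group_rng(seed: int, group_key: str) -> np.random.Generator:
    """Independent stream per group, stable under adding other groups."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), zlib.crc32(group_key.encode())))
    )


def _truncated_normal(rng, mean, sd, lower, upper, size):
    if sd == 0:
        return np.full(size, float(mean))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _clipped_normal(rng, mean, sd, lower, size):
    """Normal draw floored at ``lower`` (point mass at the floor).

    Clipping, unlike resample-truncation, keeps the sample mean close
    to the target when the floor is within ~2 SD of it — the regime of
    the near-zero ferritin groups.
    """
    if sd == 0:
        return np.full(size, float(max(mean, lower)))
    return np.clip(rng.normal(mean, sd, size), lower, None)


@lru_cache(maxsize=64)
def _truncnorm_parent(mu: float, sigma: float, lower: float, upper: float) -> tuple:
    """Parent (loc, scale) whose band-truncated normal has moments ~(mu, sigma).

    Published band moments describe the band-restricted sample, so the
    truncated — not the parent — distribution must match them.  No
    distribution on [lower, upper] can exceed the uniform SD
    (width/sqrt(12)); when sigma sits at or above that bound the solver
    returns the closest achievable (near-uniform) member.
    """

    def truncated_moments(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lower - loc) / scale, (upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return float(m), float(np.sqrt(v))

    def residuals(params):
        m, s = truncated_moments(params)
        return [(m - mu) / sigma, (s - sigma) / sigma]

    # log-scale bounded above: beyond ~3x the band width the truncated
    # shape is indistinguishable from uniform and the fit is flat
    width = upper - lower
    result = optimize.least_squares(
        residuals,
        x0=[mu, np.log(sigma)],
        bounds=([lower - 3 * width, np.log(sigma) - 2], [upper + 3 * width, np.log(3 * width)]),
    )
    loc, log_scale = result.x
    return float(loc), float(np.exp(log_scale))


def _matched_truncated_normal(rng, mean, sd, lower, upper, size):
    """Truncated-normal draw whose in-band moments approximate (mean, sd)."""
    if sd == 0:
        return np.full(size, float(mean))
    loc, scale = _truncnorm_parent(float(mean), float(sd), float(lower), float(upper))
    a, b = (lower - loc) / scale, (upper - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# Referent populations


@dataclass(frozen=True)
class VariableTarget:
    """Target moments and normalized age-slope for one biomarker."""

    mu: float
    sigma: float
    k_x: float


def _band_defaults(band: BandLabel) -> dict:
    constants = load_reference_constants(band)
    return {
        var: VariableTarget(constants.mu[var], constants.sigma[var], constants.slope[var])
        for var in ("RTL", "Fe", "TIBC", "F")
    }


@dataclass(frozen=True)
class ReferentSpec:
    """Recipe for a synthetic calibration sample.

    Ages follow a normal (``age_mu``, ``age_sigma``) truncated to the
    band; each biomarker is ``mu + sigma * (k_x * (a - age_mu) + eps)``
    with ``eps ~ N(0, sqrt(1 - k_x^2 age_sigma^2))`` so its z-score has
    (asymptotically) mean 0, SD 1 and OLS slope ``k_x`` on age.
    Defaults reproduce the published referent moments per band.
    """

    band: BandLabel = BandLabel.younger
    n: int = 10_000
    age_mu: Optional[float] = None
    age_sigma: Optional[float] = None
    targets: Optional[Mapping[str, VariableTarget]] = None
    seed: int = 0

    def resolved(self) -> "ReferentSpec":
        constants = load_reference_constants(self.band)
        return replace(
            self,
            age_mu=self.age_mu if self.age_mu is not None else constants.mu["a"],
            age_sigma=self.age_sigma if self.age_sigma is not None else constants.sigma["a"],
            targets=dict(self.targets) if self.targets is not None else _band_defaults(self.band),
        )


def residual_sd(k_x: float, age_sigma: float) -> float:
    """SD of the z-score residual that keeps the marginal SD at 1."""
    variance = 1.0 - (k_x * age_sigma) ** 2
    if variance <= 0:
        raise ValueError(
            f"|k_x| * age_sigma = {abs(k_x) * age_sigma:.4f} >= 1; "
            "no real residual SD exists"
        )
    return float(np.sqrt(variance))


def generate_referent(spec: ReferentSpec) -> ReferentPopulation:
    """Draw a synthetic referent band sample (see :class:`ReferentSpec`).

    Biomarker values are clipped at zero; the clip count is recorded in
    ``population.records.attrs['truncated_at_zero']``.
    """
    spec = spec.resolved()
    if spec.n < 3:
        raise ValueError("need n >= 3 for a well-posed calibration sample")
    band = BANDS[BandLabel(spec.band)]
    rng = _group_rng(spec.seed, f"referent:{band.label.value}")
    ages = _matched_truncated_normal(rng, spec.age_mu, spec.age_sigma, band.lower, band.upper, spec.n)
    table = {"age": ages}
    truncated = 0
    pre_truncation_moments = {}
    for var in ("RTL", "Fe", "TIBC", "F"):
        target = spec.targets[var]
        eps = rng.normal(0.0, residual_sd(target.k_x, spec.age_sigma), spec.n)
        values = target.mu + target.sigma * (target.k_x * (ages - spec.age_mu) + eps)
        pre_truncation_moments[var] = (float(np.mean(values)), float(np.std(values, ddof=1)))
        truncated += int((values < 0).sum())
        table[var] = np.clip(values, 0.0, None)
    frame = pd.DataFrame(table)
    frame.attrs["truncated_at_zero"] = truncated
    frame.attrs["pre_truncation_moments"] = pre_truncation_moments
    return ReferentPopulation(frame, band)


# ---------------------------------------------------------------------------
# Study cohorts


@dataclass(frozen=True)
class GroupSpec:
    """Per-group draw parameters; (mean, SD) pairs, normal truncated at 0."""

    n: int
    hiv_status: HIVStatus
    band: BandLabel
    age: tuple  # (mean, sd); truncated to the band's enrolment window
    rtl: tuple
    ferritin: tuple  # ug/L
    serum_iron: tuple  # ug/dL
    tibc: tuple  # ug/dL
    transferrin: tuple  # umol/L
    cd4: Optional[tuple] = None
    therapy_duration: Optional[tuple] = None  # months, truncated at 0.8
    naive_fraction: float = 0.0
    regimen_mix: Mapping[str, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        for name in ("age", "rtl", "ferritin", "serum_iron", "tibc", "transferrin",
                     "cd4", "therapy_duration"):
            pair = getattr(self, name)
            if pair is not None and pair[1] < 0:
                raise ValueError(f"{name}: SD must be non-negative, got {pair[1]}")
        if not 0 <= self.naive_fraction <= 1:
            raise ValueError("naive_fraction must lie in [0, 1]")


def _umol(mean_sd: tuple) -> tuple:
    return (umol_l_to_ug_dl(mean_sd[0]), umol_l_to_ug_dl(mean_sd[1]))


# Published group moments.  Iron panel (umol/L in the source, converted
# here) is printed pooled per HIV status and applied to both bands.
_HIV_POS_IRON = dict(serum_iron=_umol((16.87, 5.91)), tibc=_umol((57.32, 15.57)),
                     transferrin=(29.54, 7.33))
_HIV_NEG_IRON = dict(serum_iron=_umol((19.68, 6.62)), tibc=_umol((62.82, 8.76)),
                     transferrin=(32.42, 4.66))

# Printed study ages ("29.2 +/- 0.5", "59.6 +/- 1.1") are read as mean
# +/- SEM: an SD of half a year is impossible across an 18-35 enrolment
# band.  Generator SDs are SEM * sqrt(n); uninfected donors get
# band-typical values (the study does not print their ages).
_DEFAULT_GROUPS = {
    ("positive", "younger"): GroupSpec(
        n=55, hiv_status=HIVStatus.positive, band=BandLabel.younger,
        age=(29.2, 3.7), rtl=(0.87, 0.37), ferritin=(13.4, 12.19),
        cd4=(461.9, 232.6), therapy_duration=(28.9, 32.3),
        naive_fraction=8 / 55, **_HIV_POS_IRON,
    ),
    ("positive", "older"): GroupSpec(
        n=50, hiv_status=HIVStatus.positive, band=BandLabel.older,
        age=(59.6, 7.8), rtl=(0.79, 0.32), ferritin=(16.16, 9.59),
        cd4=(567.0, 317.7), therapy_duration=(85.6, 61.1),
        naive_fraction=0.0, **_HIV_POS_IRON,
    ),
    ("negative", "younger"): GroupSpec(
        n=50, hiv_status=HIVStatus.negative, band=BandLabel.younger,
        age=(29.0, 4.0), rtl=(0.83, 0.36), ferritin=(7.03, 7.23),
        **_HIV_NEG_IRON,
    ),
    ("negative", "older"): GroupSpec(
        n=50, hiv_status=HIVStatus.negative, band=BandLabel.older,
        age=(60.0, 7.0), rtl=(0.69, 0.24), ferritin=(4.68, 3.82),
        **_HIV_NEG_IRON,
    ),
}

#: enrolment windows per band (study admits 18-35 and 50-77)
_ENROLMENT = {BandLabel.younger: (18.0, 35.0), BandLabel.older: (50.0, 77.0)}


@dataclass(frozen=True)
class PVLSpec:
    """Plasma viral load mixture: a point mass below the detection limit
    (simulated as exact zeros) plus a log10-normal detectable tail."""

    fraction_below_limit: float = 0.6
    log10_mean: float = 3.0
    log10_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_below_limit <= 1:
            raise ValueError("fraction_below_limit must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cross-sectional study cohort."""

    groups: Mapping[tuple, GroupSpec] = field(
        default_factory=lambda: dict(_DEFAULT_GROUPS)
    )
    pvl: PVLSpec = field(default_factory=PVLSpec)
    ferritin_lognormal: bool = False
    seed: int = 0


def _lognormal_params(mean: float, sd: float) -> tuple:
    # moment-match: if X ~ LogNormal(m, s), E X = exp(m + s^2/2),
    # Var X = (exp(s^2) - 1) exp(2m + s^2)
    s2 = np.log1p((sd / mean) ** 2)
    m = np.log(mean) - s2 / 2.0
    return m, np.sqrt(s2)


def _draw_regimens(rng, n: int, naive_fraction: float,
                   regimen_mix: Optional[Mapping[str, float]]) -> list:
    mix = dict(regimen_mix) if regimen_mix else {"nrti_nnrti": 0.5, "nrti_pi": 0.5}
    for key in mix:
        Regimen(key)  # validates
    labels = list(mix)
    probs = np.array([mix[k] for k in labels], dtype=float)
    probs = probs / probs.sum()
    n_naive = int(round(naive_fraction * n))
    treated = rng.choice(labels, size=n - n_naive, p=probs)
    regimens = [Regimen.naive] * n_naive + [Regimen(r) for r in treated]
    rng.shuffle(regimens)  # type: ignore[arg-type]
    return regimens


def generate_cohort(spec: CohortSpec = CohortSpec()) -> list[SubjectRecord]:
    """Draw a synthetic study cohort; deterministic per seed."""
    records: list[SubjectRecord] = []
    for (status, band_label), group in sorted(spec.groups.items(), key=lambda kv: kv[0]):
        group_key = f"cohort:{status}:{band_label}"
        rng = _group_rng(spec.seed, group_key)
        band = BandLabel(band_label)
        lo, hi = _ENROLMENT[band]
        n = group.n
        ages = _matched_truncated_normal(rng, group.age[0], group.age[1], lo, hi, n)
        rtl = _clipped_normal(rng, group.rtl[0], group.rtl[1], 0, n)
        if spec.ferritin_lognormal:
            m, s = _lognormal_params(*group.ferritin)
            ferritin = rng.lognormal(m, s, n)
        else:
            ferritin = _clipped_normal(rng, group.ferritin[0], group.ferritin[1], 0, n)
        iron = _clipped_normal(rng, group.serum_iron[0], group.serum_iron[1], 0, n)
        tibc = _clipped_normal(rng, group.tibc[0], group.tibc[1], 0, n)
        transferrin = _clipped_normal(rng, group.transferrin[0], group.transferrin[1], 0, n)

        hiv_positive = HIVStatus(group.hiv_status) is HIVStatus.positive
        if hiv_positive:
            cd4 = _clipped_normal(rng, group.cd4[0], group.cd4[1], 0, n)
            duration = _clipped_normal(
                rng, group.therapy_duration[0], group.therapy_duration[1], 0.8, n
            )
            regimens = _draw_regimens(rng, n, group.naive_fraction, group.regimen_mix)
            undetectable = rng.random(n) < spec.pvl.fraction_below_limit
            pvl = np.where(
                undetectable, 0.0, 10.0 ** rng.normal(spec.pvl.log10_mean, spec.pvl.log10_sd, n)
            )
        for i in range(n):
            common = dict(
                subject_id=f"{status[:3]}-{band_label}-{i:04d}",
                age=float(ages[i]),
                hiv_status=HIVStatus(group.hiv_status),
                rtl=float(rtl[i]),
                serum_iron=float(iron[i]),
                tibc=float(tibc[i]),
                transferrin=float(transferrin[i]),
                transferrin_saturation=(
                    float(100.0 * iron[i] / tibc[i]) if tibc[i] > 0 else None
                ),
                ferritin=float(ferritin[i]),
            )
            if hiv_positive:
                regimen = regimens[i]
                common.update(
                    regimen=regimen,
                    cd4=float(cd4[i]),
                    pvl=float(pvl[i]),
                    therapy_duration=(
                        None if regimen is Regimen.naive else float(duration[i])
                    ),
                )
            records.append(SubjectRecord(**common))
    return records


# ---------------------------------------------------------------------------
# Deterministic therapy-effect injection

_BIOMARKER_FIELDS = {"rtl", "serum_iron", "tibc", "ferritin", "transferrin",
                     "transferrin_saturation", "cd4"}


def inject_therapy_effect(
    cohort: Iterable[SubjectRecord],
    offsets: Optional[Mapping[str, Mapping[str, float]]] = None,
    slopes: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> list[SubjectRecord]:
    """Shift biomarkers of treated subjects per regimen, deterministically.

    ``offsets[regimen][biomarker]`` adds a constant; ``slopes`` adds a
    per-year-of-age term ``slope * age`` so downstream age-trend fits
    steepen for the affected regimen.  Values are floored at zero.
    """
    offsets = offsets or {}
    slopes = slopes or {}
    for mapping in (offsets, slopes):
        for regimen_key, shifts in mapping.items():
            Regimen(regimen_key)  # raises on unknown regimen
            unknown = set(shifts) - _BIOMARKER_FIELDS
            if unknown:
                raise ValueError(f"unknown biomarker field(s): {sorted(unknown)}")
    out = []
    for record in cohort:
        key = record.regimen.value
        shift_terms = {}
        for biomarker, off in offsets.get(key, {}).items():
            shift_terms[biomarker] = shift_terms.get(biomarker, 0.0) + off
        for biomarker, slope in slopes.get(key, {}).items():
            shift_terms[biomarker] = shift_terms.get(biomarker, 0.0) + slope * record.age
        if not shift_terms:
            out.append(record)
            continue
        updates = {}
        for biomarker, shift in shift_terms.items():
            current = getattr(record, biomarker)
            if current is not None:
                updates[biomarker] = max(0.0, current + shift)
        out.append(replace(record, **updates))
    return out
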