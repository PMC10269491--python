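"""Readers and writers: subject CSV tables and constants files.

Subject tables are plain CSV (UTF-8, comma separator, ``.`` decimal,
empty cell = missing).  Iron and TIBC columns default to ug/dL, the
canonical internal unit; a header suffix ``(umol/L)`` or an explicit
``units`` mapping triggers conversion on read.  Constants files are
flat ``key = value`` text written at full precision.
"""

from __future__ import annotations

import sys
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .datamodel import (
    BANDS,
    VARIABLES,
    AgeBand,
    BandLabel,
    CalibrationConstants,
    HIVStatus,
    Regimen,
    SubjectRecord,
    umol_l_to_ug_dl,
)

# ---------------------------------------------------------------------------
# Built-in referent-population constants, both age bands, as printed.

_YOUNGER_CONSTANTS = dict(
    mu={"RTL": 1.1674, "Fe": 106.701, "TIBC": 350.4698, "F": 141.099, "a": 27.4770},
    sigma={"RTL": 0.2699, "Fe": 40.65551, "TIBC": 48.50848, "F": 87.18172, "a": 4.7178},
    slope={"RTL": -0.0432, "Fe": -0.0270, "TIBC": -0.0183, "F": 0.0608, "a": 0.2120},
    k=2.7681,
    C=27.4907,
    delta_hiv_neg=-0.044,
    delta_hiv_pos=0.194,
)

_OLDER_CONSTANTS = dict(
    mu={"RTL": 0.9310, "Fe": 92.84552, "TIBC": 340.4459, "F": 195.7973, "a": 64.0432},
    sigma={"RTL": 0.2211, "Fe": 34.4174, "TIBC": 51.6161, "F": 171.4354, "a": 7.9415},
    slope={"RTL": -0.0327, "Fe": -0.0086, "TIBC": -0.0096, "F": 0.0058, "a": 0.1259},
    k=5.4744,
    C=68.1219,
    delta_hiv_neg=-0.044,
    delta_hiv_pos=0.194,
)


def _intercepts_from(mu_a: float, slopes: Mapping[str, float]) -> dict:
    # The referent OLS lines pass through (mean age, 0) for z-scored
    # variables, so n_X = -k_X * mu_a.  The printed table omits the
    # intercepts; reconstruct them from that identity.
    return {var: -k_x * mu_a for var, k_x in slopes.items()}


def load_reference_constants(band: BandLabel | str) -> CalibrationConstants:
    """Return the built-in calibration constants for one age band.

    Values are the published referent-population (NHANES-derived)
    moments, normalized age slopes, scaling factor ``k``, constant
    ``C``, and the two life-expectancy adjustments, exactly as printed.
    """
    band = BandLabel(band)
    raw = {BandLabel.younger: _YOUNGER_CONSTANTS, BandLabel.older: _OLDER_CONSTANTS}[band]
    return CalibrationConstants(
        band=BANDS[band],
        mu=dict(raw["mu"]),
        sigma=dict(raw["sigma"]),
        slope=dict(raw["slope"]),
        intercept=_intercepts_from(raw["mu"]["a"], raw["slope"]),
        k=raw["k"],
        C=raw["C"],
        delta_hiv_neg=raw["delta_hiv_neg"],
        delta_hiv_pos=raw["delta_hiv_pos"],
    )


# ---------------------------------------------------------------------------
# Subject CSV

#: columns convertible from umol/L, with conversion applied on read
_IRON_COLUMNS = ("serum_iron", "tibc")

_OPTIONAL_NUMERIC = (
    "therapy_duration", "pvl", "cd4", "rtl", "serum_iron", "tibc",
    "transferrin_saturation", "transferrin", "ferritin",
)


class SchemaError(ValueError):
    """The CSV is missing a required column or is otherwise unusable."""


def _normalize_columns(columns: Sequence[str]) -> tuple[dict, dict]:
    """Split unit suffixes like ``serum_iron (umol/L)`` off header names.

    Returns (rename mapping, per-column declared unit).
    """
    rename, units = {}, {}
    for col in columns:
        name = col.strip()
        unit = None
        if "(" in name and name.endswith(")"):
            name, _, unit = name.partition("(")
            name = name.strip()
            unit = unit[:-1].strip()
        rename[col] = name
        if unit:
            units[name] = unit
    return rename, units


def read_subjects(
    path,
    units: Optional[Mapping[str, str]] = None,
    diagnostics: Optional[list] = None,
) -> list[SubjectRecord]:
    """Read and validate a subject table from CSV.

    Rows violating a record invariant are dropped; a row-indexed message
    is appended to ``diagnostics`` (and echoed to stderr when no list is
    supplied).  ``units`` may declare ``"umol/L"`` for ``serum_iron`` or
    ``tibc``; a parenthesized header suffix does the same.
    """
    frame = pd.read_csv(path, dtype={"subject_id": str})
    rename, header_units = _normalize_columns(frame.columns)
    frame = frame.rename(columns=rename)
    declared = dict(header_units)
    if units:
        declared.update(units)

    required = {"subject_id", "age", "hiv_status"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")

    sink = diagnostics if diagnostics is not None else None
    records: list[SubjectRecord] = []
    for idx, row in frame.iterrows():
        try:
            records.append(_row_to_record(row, declared))
        except (ValueError, TypeError) as exc:
            message = f"row {idx}: {exc}"
            if sink is not None:
                sink.append(message)
            else:
                print(message, file=sys.stderr)
    return records


def _parse_optional(row, name: str):
    if name not in row.index or pd.isna(row[name]):
        return None
    value = float(row[name])
    return value


def _row_to_record(row, declared_units: Mapping[str, str]) -> SubjectRecord:
    kwargs = {
        "subject_id": str(row["subject_id"]),
        "age": float(row["age"]),
        "hiv_status": HIVStatus(str(row["hiv_status"]).strip().lower()),
    }
    if "regimen" in row.index and not pd.isna(row["regimen"]):
        kwargs["regimen"] = Regimen(str(row["regimen"]).strip().lower())
    for name in _OPTIONAL_NUMERIC:
        value = _parse_optional(row, name)
        if value is None:
            continue
        unit = declared_units.get(name, "").replace("µ", "u").lower()
        if name in _IRON_COLUMNS and unit in ("umol/l", "umol_l"):
            value = umol_l_to_ug_dl(value)
        kwargs[name] = value
    return SubjectRecord(**kwargs)


def subjects_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Flatten records into a DataFrame in canonical (ug/dL) units."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "age": r.age,
            "hiv_status": r.hiv_status.value,
            "regimen": r.regimen.value,
            "therapy_duration": r.therapy_duration,
            "pvl": r.pvl,
            "cd4": r.cd4,
            "rtl": r.rtl,
            "serum_iron": r.serum_iron,
            "tibc": r.tibc,
            "transferrin_saturation": r.transferrin_saturation,
            "transferrin": r.transferrin,
            "ferritin": r.ferritin,
        })
    columns = ["subject_id", "age", "hiv_status", "regimen", "therapy_duration",
               "pvl", "cd4", "rtl", "serum_iron", "tibc",
               "transferrin_saturation", "transferrin", "ferritin"]
    return pd.DataFrame(rows, columns=columns)


def write_subjects(records: Iterable[SubjectRecord], path) -> None:
    subjects_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Constants files: flat "key = value" text, full precision.

def write_constants(constants: CalibrationConstants, path) -> None:
    lines = [
        f"band.label = {constants.band.label.value}",
        f"band.lower = {constants.band.lower!r}",
        f"band.upper = {constants.band.upper!r}",
    ]
    for group, mapping in (("mu", constants.mu), ("sigma", constants.sigma),
                           ("slope", constants.slope), ("intercept", constants.intercept)):
        for var in VARIABLES:
            lines.append(f"{group}.{var} = {mapping[var]!r}")
    lines.append(f"k = {constants.k!r}")
    lines.append(f"C = {constants.C!r}")
    lines.append(f"delta_hiv_neg = {constants.delta_hiv_neg!r}")
    lines.append(f"delta_hiv_pos = {constants.delta_hiv_pos!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


class ConstantsParseError(ValueError):
    pass


def read_constants(path) -> CalibrationConstants:
    """Parse a constants file; inverse of :func:`write_constants`."""
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConstantsParseError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()

    def require(key: str) -> str:
        if key not in entries:
            raise ConstantsParseError(f"missing key {key!r}")
        return entries[key]

    band = AgeBand(
        BandLabel(require("band.label")),
        float(require("band.lower")),
        float(require("band.upper")),
    )
    groups = {}
    for group in ("mu", "sigma", "slope", "intercept"):
        groups[group] = {var: float(require(f"{group}.{var}")) for var in VARIABLES}
    return CalibrationConstants(
        band=band,
        mu=groups["mu"],
        sigma=groups["sigma"],
        slope=groups["slope"],
        intercept=groups["intercept"],
        k=float(require("k")),
        C=float(require("C")),
        delta_hiv_neg=float(require("delta_hiv_neg")),
        delta_hiv_pos=float(require("delta_hiv_pos")),
    )
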