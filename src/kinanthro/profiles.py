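"""Athlete anthropometric records: domain types, validation, CSV I/O, summaries.

A restricted-profile record holds 26 surface-anthropometry measurements taken
with standard ISAK technique — body mass, three lengths/heights, six bone
breadths, eight girths and eight skinfolds — plus chronological age and a
playing-position label.  Everything downstream (tissue fractionation,
somatotype, proportionality indices, positional statistics) consumes these
records, so validation is strict by default: a profile with a missing or
impossible measurement is rejected rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger("kinanthro")

#: The seven playing positions, in canonical order.
POSITIONS: tuple[str, ...] = ("DB", "DL", "LB", "OL", "QB", "RB", "WR")

#: The 26 measurements in canonical column order (kg for mass, cm for
#: lengths/breadths/girths, mm for skinfolds).
MEASUREMENTS: tuple[str, ...] = (
    "body_mass",
    "stretch_stature",
    "sitting_height",
    "arm_span",
    # breadths (cm)
    "biacromial",
    "transverse_chest",
    "ap_chest_depth",
    "biiliocristal",
    "humerus",
    "femur",
    # girths (cm)
    "head_girth",
    "arm_relaxed",
    "arm_flexed_tensed",
    "forearm_girth",
    "chest_girth",
    "waist_girth",
    "thigh_girth",
    "calf_girth",
    # skinfolds (mm)
    "triceps_sf",
    "subscapular_sf",
    "biceps_sf",
    "iliac_crest_sf",
    "supraspinale_sf",
    "abdominal_sf",
    "thigh_sf",
    "calf_sf",
)

SKINFOLDS: tuple[str, ...] = tuple(m for m in MEASUREMENTS if m.endswith("_sf"))

#: Canonical CSV column order.
COLUMNS: tuple[str, ...] = ("athlete_id", "position", "age") + MEASUREMENTS

#: Accepted header aliases -> canonical name.  The canonical set is snake_case;
#: aliases cover common spreadsheet spellings.
HEADER_ALIASES: dict[str, str] = {
    "id": "athlete_id",
    "player_id": "athlete_id",
    "mass": "body_mass",
    "weight": "body_mass",
    "stature": "stretch_stature",
    "height": "stretch_stature",
    "antero_posterior_chest_depth": "ap_chest_depth",
    "arm_flexed": "arm_flexed_tensed",
    "arm_flexed_and_tensed": "arm_flexed_tensed",
    "thigh_1cm_gluteal": "thigh_girth",
    "forearm": "forearm_girth",
    "chest": "chest_girth",
    "waist": "waist_girth",
    "calf": "calf_girth",
    "head": "head_girth",
    "triceps": "triceps_sf",
    "subscapular": "subscapular_sf",
    "biceps": "biceps_sf",
    "iliac_crest": "iliac_crest_sf",
    "supraspinale": "supraspinale_sf",
    "abdominal": "abdominal_sf",
    "front_thigh": "thigh_sf",
    "medial_calf": "calf_sf",
}


class CohortSchemaError(ValueError):
    """A cohort table is missing required columns or contains unparsable cells."""


class ProfileValidationError(ValueError):
    """One or more profile invariants are violated."""


class DuplicateIdError(ValueError):
    """Two rows in a cohort share an athlete_id."""


@dataclass
class AnthroProfile:
    """One athlete's restricted anthropometric profile.

    Units follow field convention: kg (mass), cm (lengths, breadths, girths),
    mm (skinfolds), years (age).
    """

    athlete_id: str
    position: str
    age: float
    body_mass: float
    stretch_stature: float
    sitting_height: float
    arm_span: float
    biacromial: float
    transverse_chest: float
    ap_chest_depth: float
    biiliocristal: float
    humerus: float
    femur: float
    head_girth: float
    arm_relaxed: float
    arm_flexed_tensed: float
    forearm_girth: float
    chest_girth: float
    waist_girth: float
    thigh_girth: float
    calf_girth: float
    triceps_sf: float
    subscapular_sf: float
    biceps_sf: float
    iliac_crest_sf: float
    supraspinale_sf: float
    abdominal_sf: float
    thigh_sf: float
    calf_sf: float

    def violations(self, relax_age: bool = False) -> list[str]:
        """Return a list of human-readable invariant violations (empty if valid)."""
        problems: list[str] = []
        if self.position not in POSITIONS:
            problems.append(f"unknown position {self.position!r}")
        for name in ("age",) + MEASUREMENTS:
            v = getattr(self, name)
            if not np.isfinite(v):
                problems.append(f"{name} is not finite")
            elif v <= 0:
                problems.append(f"{name} must be strictly positive (got {v})")
        if self.sitting_height >= self.stretch_stature:
            problems.append(
                f"sitting_height ({self.sitting_height}) must be below "
                f"stretch_stature ({self.stretch_stature})"
            )
        # A flexed-and-tensed arm girth grossly below the relaxed girth is a
        # recording error, not biology.
        if self.arm_flexed_tensed < self.arm_relaxed - 2.0:
            problems.append(
                "arm_flexed_tensed more than 2 cm below arm_relaxed "
                f"({self.arm_flexed_tensed} vs {self.arm_relaxed})"
            )
        if self.humerus >= self.femur + 5.0:
            problems.append(
                f"humerus breadth ({self.humerus}) implausibly large relative "
                f"to femur breadth ({self.femur})"
            )
        if not relax_age and not (15.0 <= self.age <= 60.0):
            problems.append(f"age {self.age} outside [15, 60]")
        return problems

    def validate(self, relax_age: bool = False) -> "AnthroProfile":
        problems = self.violations(relax_age=relax_age)
        if problems:
            raise ProfileValidationError(
                f"profile {self.athlete_id!r}: " + "; ".join(problems)
            )
        return self

    def as_row(self) -> dict[str, object]:
        return {c: getattr(self, c) for c in COLUMNS}


@dataclass
class Cohort:
    """An ordered collection of :class:`AnthroProfile` with unique ids."""

    profiles: list[AnthroProfile] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[AnthroProfile]:
        return iter(self.profiles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.profiles == other.profiles

    @property
    def positions(self) -> list[str]:
        return [p.position for p in self.profiles]

    def position_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.profiles:
            counts[p.position] = counts.get(p.position, 0) + 1
        return counts

    def check_unique_ids(self) -> None:
        seen: set[str] = set()
        for p in self.profiles:
            if p.athlete_id in seen:
                raise DuplicateIdError(f"duplicate athlete_id {p.athlete_id!r}")
            seen.add(p.athlete_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_row() for p in self.profiles], columns=COLUMNS)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        strict: bool = True,
        provenance: str = "",
        relax_age: bool = False,
    ) -> "Cohort":
        df = _canonicalize_columns(df)
        numeric_cols = [c for c in COLUMNS if c not in ("athlete_id", "position")]
        for col in numeric_cols:
            values = []
            # python's float() is correctly rounded, so CSV round-trips are
            # bit-exact (pandas' own string parser is not)
            for i, cell in enumerate(df[col]):
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise CohortSchemaError(
                        f"missing value in column {col!r} at row {i}")
                try:
                    values.append(float(cell))
                except (TypeError, ValueError):
                    raise CohortSchemaError(
                        f"non-numeric value {cell!r} in column {col!r} at row {i}"
                    ) from None
            df[col] = values

        profiles: list[AnthroProfile] = []
        for i, rec in enumerate(df[list(COLUMNS)].to_dict("records")):
            rec["athlete_id"] = str(rec["athlete_id"])
            rec["position"] = str(rec["position"])
            prof = AnthroProfile(**rec)
            problems = prof.violations(relax_age=relax_age)
            if problems:
                msg = f"row {i} (athlete {prof.athlete_id!r}): " + "; ".join(problems)
                if strict:
                    raise ProfileValidationError(msg)
                logger.warning("dropping invalid profile: %s", msg)
                continue
            profiles.append(prof)
        cohort = cls(profiles=profiles, provenance=provenance)
        cohort.check_unique_ids()
        return cohort


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "_").replace("-", "_")
        key = HEADER_ALIASES.get(key, key)
        rename[col] = key
    df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def read_cohort(path: str | Path, strict: bool = True, relax_age: bool = False) -> Cohort:
    """Read a cohort CSV (one athlete per row, '.' decimal separator).

    In strict mode any row violating a profile invariant aborts the read; in
    non-strict mode offending rows are dropped with a logged warning.  Row
    order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    return Cohort.from_dataframe(
        df, strict=strict, provenance=str(path), relax_age=relax_age
    )


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as CSV in canonical column order (round-trip safe)."""
    if len(cohort) == 0:
        raise ValueError("refusing to write an empty cohort")
    path = Path(path)
    cohort.to_dataframe().to_csv(path, index=False, float_format="%.17g")
    return path


def position_summary(cohort: Cohort, variable: str) -> pd.DataFrame:
    """Per-position mean and SD (n-1 denominator) plus a pooled 'Total' row."""
    df = cohort.to_dataframe()
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    out = []
    for pos in POSITIONS:
        vals = df.loc[df["position"] == pos, variable].to_numpy(float)
        if vals.size:
            out.append(
                {
                    "position": pos,
                    "n": vals.size,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                }
            )
    allv = df[variable].to_numpy(float)
    out.append(
        {
            "position": "Total",
            "n": allv.size,
            "mean": float(np.mean(allv)),
            "sd": float(np.std(allv, ddof=1)) if allv.size > 1 else 0.0,
        }
    )
    return pd.DataFrame(out)


def summarize(cohort: Cohort, variables: Iterable[str] | None = None) -> pd.DataFrame:
    """Stacked :func:`position_summary` over several variables."""
    variables = list(variables) if variables is not None else list(MEASUREMENTS)
    frames = []
    for v in variables:
        t = position_summary(cohort, v)
        t.insert(0, "variable", v)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
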