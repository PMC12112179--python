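"""Individual and cohort data model for age-stage two-sex life tables.

A life-table study follows a cohort of eggs, one individual per record, with
daily observation: the age (in integer days, day 0 = first day of the egg
stage) at which each individual enters each developmental stage, the last day
it was alive, its sex (revealed at adult emergence), and — for females — the
number of eggs laid on each day of adult life.

Conventions
-----------
* An individual "at age x" means alive on day x; lifespan is ``death_age + 1``
  days.
* On a transition day the individual is attributed to the *new* stage, so the
  stages partition the interval ``[0, death_age]``.
* The adult stage is split by sex into ``female_adult`` and ``male_adult``,
  both branching from the pupal stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEMALE_ADULT = "female_adult"
MALE_ADULT = "male_adult"

#: Default stage order: egg, four larval instars, pupa, then sexed adults.
DEFAULT_STAGE_ORDER: tuple[str, ...] = (
    "egg", "L1", "L2", "L3", "L4", "pupa", FEMALE_ADULT, MALE_ADULT,
)

SEXES = ("f", "m", "u")


class CohortValidationError(ValueError):
    """Raised when a cohort violates the data-model invariants."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        lines = [f"[{rid}] {rule}: {msg}" for rid, rule, msg in report.issues]
        super().__init__("cohort validation failed:\n" + "\n".join(lines))


@dataclass
class ValidationReport:
    """Collected invariant violations; empty iff the cohort is valid."""

    issues: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, record_id: str, rule: str, message: str) -> None:
        self.issues.append((record_id, rule, message))

    def __bool__(self) -> bool:  # truthy when there ARE issues
        return bool(self.issues)


@dataclass
class IndividualRecord:
    """One insect's complete life history.

    Parameters
    ----------
    id : str
        Unique label within the cohort.
    sex : {"f", "m", "u"}
        "u" (undetermined) is permitted only for individuals that died
        before adult emergence.
    stage_entry : dict[str, int]
        Stage name -> age (day) of entry. Egg entry is day 0.
    death_age : int
        Last day the individual was alive.
    fecundity : dict[int, int]
        Day -> eggs laid that day; non-empty only for females.
    """

    id: str
    sex: str
    stage_entry: dict[str, int]
    death_age: int
    fecundity: dict[int, int] = field(default_factory=dict)

    @property
    def adult_entry(self) -> int | None:
        for stage in (FEMALE_ADULT, MALE_ADULT):
            if stage in self.stage_entry:
                return self.stage_entry[stage]
        return None

    @property
    def lifespan(self) -> int:
        """Days alive (death day inclusive)."""
        return self.death_age + 1

    def stage_on_day(self, day: int, stage_order: tuple[str, ...]) -> str:
        """Stage occupied on ``day`` (new stage on transition days)."""
        current = None
        for stage in stage_order:
            entry = self.stage_entry.get(stage)
            if entry is not None and entry <= day:
                current = stage
        if current is None:
            raise ValueError(f"{self.id}: no stage entered by day {day}")
        return current

    def total_fecundity(self) -> int:
        return sum(self.fecundity.values())

    def first_oviposition_day(self) -> int | None:
        laying = [d for d, n in self.fecundity.items() if n > 0]
        return min(laying) if laying else None


@dataclass
class Cohort:
    """An ordered stage list plus the individual records; the resampling unit
    of all downstream bootstrap inference is the individual."""

    individuals: list[IndividualRecord]
    stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER

    @property
    def n_01(self) -> int:
        """Initial egg-cohort size (no censoring: one record per egg)."""
        return len(self.individuals)

    @property
    def max_age(self) -> int:
        return max(r.death_age for r in self.individuals)

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        order = {s: i for i, s in enumerate(self.stage_order)}
        if FEMALE_ADULT not in order or MALE_ADULT not in order:
            report.add("<cohort>", "stage_order",
                       "stage order must contain female_adult and male_adult")
            return report
        seen_ids: set[str] = set()
        for rec in self.individuals:
            if rec.id in seen_ids:
                report.add(rec.id, "unique-id", "duplicate individual id")
            seen_ids.add(rec.id)
            if rec.sex not in SEXES:
                report.add(rec.id, "sex", f"unknown sex code {rec.sex!r}")
                continue
            for stage in rec.stage_entry:
                if stage not in order:
                    report.add(rec.id, "stage-name",
                               f"stage {stage!r} not in stage order")
            if rec.stage_entry.get(self.stage_order[0]) != 0:
                report.add(rec.id, "egg-entry",
                           "first-stage entry must be at age 0")
            known = [(order[s], a) for s, a in rec.stage_entry.items() if s in order]
            ages = [a for _, a in sorted(known)]
            if any(b <= a for a, b in zip(ages, ages[1:])):
                report.add(rec.id, "stage-ordering",
                           "stage entry ages must strictly increase along the stage order")
            if rec.stage_entry and rec.death_age < max(rec.stage_entry.values()):
                report.add(rec.id, "death-age",
                           "death age precedes the last stage entry")
            adult = rec.adult_entry
            if rec.sex == "u" and adult is not None:
                report.add(rec.id, "sex-undetermined",
                           "sex must be recorded at adult emergence")
            if rec.sex == "f" and MALE_ADULT in rec.stage_entry:
                report.add(rec.id, "sex-stage", "female with male_adult entry")
            if rec.sex == "m" and FEMALE_ADULT in rec.stage_entry:
                report.add(rec.id, "sex-stage", "male with female_adult entry")
            if rec.fecundity:
                if rec.sex != "f":
                    report.add(rec.id, "fecundity-sex",
                               "fecundity recorded for a non-female")
                elif adult is not None:
                    days = rec.fecundity.keys()
                    if min(days) < adult or max(days) > rec.death_age:
                        report.add(rec.id, "fecundity-days",
                                   "egg-laying days outside [adult entry, death age]")
                if any(n < 0 for n in rec.fecundity.values()):
                    report.add(rec.id, "fecundity-negative", "negative egg count")
        return report

    def require_valid(self) -> "Cohort":
        report = self.validate()
        if report:
            raise CohortValidationError(report)
        return self

    def females(self) -> list[IndividualRecord]:
        return [r for r in self.individuals if r.sex == "f"]

    def males(self) -> list[IndividualRecord]:
        return [r for r in self.individuals if r.sex == "m"]


def _entry_columns(stage_order: tuple[str, ...]) -> list[str]:
    cols = [f"entry_{s}" for s in stage_order
            if s not in (FEMALE_ADULT, MALE_ADULT)]
    return cols + ["entry_adult"]


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV: one row per individual, sparse day-indexed
    ``egg_day:<d>`` fecundity columns, blank cells for missing entries."""
    cohort.require_valid()
    entry_cols = _entry_columns(cohort.stage_order)
    egg_days = sorted({d for r in cohort.individuals for d in r.fecundity})
    header = ["id", "sex"] + entry_cols + ["death_age"] + [
        f"egg_day:{d}" for d in egg_days]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec in cohort.individuals:
            row: list[str] = [rec.id, rec.sex]
            for col in entry_cols:
                stage = col.removeprefix("entry_")
                if stage == "adult":
                    age = rec.adult_entry
                else:
                    age = rec.stage_entry.get(stage)
                row.append("" if age is None else str(age))
            row.append(str(rec.death_age))
            for d in egg_days:
                n = rec.fecundity.get(d)
                row.append("" if n is None else str(n))
            writer.writerow(row)


def read_cohort(path, stage_order: tuple[str, ...] = DEFAULT_STAGE_ORDER) -> Cohort:
    """Read and validate a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    ValueError
        On a malformed row (names the row and column).
    CohortValidationError
        If the parsed cohort violates any data-model invariant.
    """
    entry_cols = _entry_columns(stage_order)
    individuals: list[IndividualRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in ["id", "sex", "death_age"] + entry_cols
                   if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        egg_cols = [(c, int(c.split(":", 1)[1]))
                    for c in reader.fieldnames if c.startswith("egg_day:")]
        for i, row in enumerate(reader, start=2):
            rid = row["id"]
            sex = row["sex"].strip()
            stage_entry: dict[str, int] = {}
            for col in entry_cols:
                raw = (row.get(col) or "").strip()
                if not raw:
                    continue
                try:
                    age = int(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}: row {i}, column {col}: not an integer: {raw!r}")
                stage = col.removeprefix("entry_")
                if stage == "adult":
                    stage = {"f": FEMALE_ADULT, "m": MALE_ADULT}.get(sex)
                    if stage is None:
                        raise ValueError(
                            f"{path}: row {i}: adult entry given but sex is {sex!r}")
                stage_entry[stage] = age
            try:
                death_age = int(row["death_age"])
            except ValueError:
                raise ValueError(
                    f"{path}: row {i}, column death_age: not an integer: "
                    f"{row['death_age']!r}")
            fecundity: dict[int, int] = {}
            for col, day in egg_cols:
                raw = (row.get(col) or "").strip()
                if raw and int(raw) > 0:
                    fecundity[day] = int(raw)
            individuals.append(IndividualRecord(
                id=rid, sex=sex, stage_entry=stage_entry,
                death_age=death_age, fecundity=fecundity))
    return Cohort(individuals=individuals, stage_order=stage_order).require_valid()


def individual_summaries(cohort: Cohort) -> pd.DataFrame:
    """Per-individual life-history summaries.

    Columns: one duration per stage (``dur_<stage>``, days spent in the
    stage), ``preadult`` (egg entry to adult entry), ``adult_longevity``,
    ``lifespan``, ``total_fecundity``, ``oviposition_days`` (days with at
    least one egg), ``APOP`` (adult entry to first oviposition day) and
    ``TPOP`` (age 0 to first oviposition day). Quantities undefined for an
    individual (APOP for males, durations of unreached stages) are NaN.
    """
    cohort.require_valid()
    order = cohort.stage_order
    rows = []
    for rec in cohort.individuals:
        row: dict[str, float | str] = {"id": rec.id, "sex": rec.sex}
        entered = [(s, rec.stage_entry[s]) for s in order if s in rec.stage_entry]
        for (stage, age), nxt in zip(entered, entered[1:] + [(None, None)]):
            end = rec.death_age + 1 if nxt[0] is None else nxt[1]
            row[f"dur_{stage}"] = end - age
        for stage in order:
            row.setdefault(f"dur_{stage}", np.nan)
        adult = rec.adult_entry
        row["preadult"] = np.nan if adult is None else adult
        row["adult_longevity"] = (
            np.nan if adult is None else rec.death_age - adult + 1)
        row["lifespan"] = rec.lifespan
        row["total_fecundity"] = (
            rec.total_fecundity() if rec.sex == "f" else np.nan)
        ovi_days = sum(1 for n in rec.fecundity.values() if n > 0)
        row["oviposition_days"] = ovi_days if rec.sex == "f" else np.nan
        first = rec.first_oviposition_day()
        if first is not None and adult is not None:
            row["APOP"] = first - adult
            row["TPOP"] = first
        else:
            row["APOP"] = np.nan
            row["TPOP"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")
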