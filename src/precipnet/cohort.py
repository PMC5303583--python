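"""Case records, cohort file I/O and the cohort summary table.

A cohort is one row per hospitalized case: an opaque case id, gender, age,
the poisoning substance, and the set of precipitating-problem subcategories
abstracted from the chart (possibly empty — many charts record no problem,
and a large share record exactly one).

Files are UTF-8 delimited text with columns ``case_id, gender, age,
substance, problems``; the problems cell packs leaf codes with ``|``.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .taxonomy import ProblemTaxonomy

__all__ = [
    "CaseRecord",
    "Cohort",
    "CohortSummary",
    "CohortFormatError",
    "CohortValidationError",
    "load_cohort",
    "write_cohort",
    "filter_stratum",
    "summarize_cohort",
    "round_half_up",
]

REQUIRED_COLUMNS = ("case_id", "gender", "age", "substance", "problems")
GENDERS = ("male", "female")
STRATA = ("total", "male", "female")


class CohortFormatError(ValueError):
    """Raised when a cohort file lacks the required layout."""


class CohortValidationError(ValueError):
    """Raised when records violate the taxonomy or uniqueness invariants."""


@dataclass(frozen=True)
class CaseRecord:
    """One case: stratum covariates plus the set of reported problems."""

    case_id: str
    gender: str | None = None  # "male" | "female" | None (missing)
    age: int | None = None
    substance: str | None = None
    problems: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.gender is not None and self.gender not in GENDERS:
            raise CohortValidationError(
                f"case {self.case_id!r}: gender must be one of {GENDERS} or missing, "
                f"got {self.gender!r}"
            )
        if self.age is not None and self.age <= 0:
            raise CohortValidationError(f"case {self.case_id!r}: age must be positive")
        object.__setattr__(self, "problems", frozenset(self.problems))


@dataclass(frozen=True)
class Cohort:
    """A validated list of case records under one taxonomy."""

    taxonomy: ProblemTaxonomy
    cases: tuple[CaseRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))
        seen: set[str] = set()
        leaves = set(self.taxonomy.subcategories)
        for case in self.cases:
            if case.case_id in seen:
                raise CohortValidationError(f"duplicate case_id {case.case_id!r}")
            seen.add(case.case_id)
            unknown = case.problems - leaves
            if unknown:
                raise CohortValidationError(
                    f"case {case.case_id!r}: unknown problem code(s) {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.cases)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (ties like 0.25 -> 0.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _parse_problems(cell: str) -> frozenset[str]:
    codes = [c.strip() for c in cell.split("|")] if cell.strip() else []
    return frozenset(c for c in codes if c)


def load_cohort(path, taxonomy: ProblemTaxonomy, delimiter: str = ",") -> Cohort:
    """Read a cohort file and validate it against the taxonomy.

    Raises
    ------
    CohortFormatError
        If a required column is missing from the header.
    CohortValidationError
        For unknown problem codes (named with their 1-based data row number)
        or duplicate case ids.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise CohortFormatError(f"{path}: missing required column(s) {missing}")
        leaves = set(taxonomy.subcategories)
        cases: list[CaseRecord] = []
        for rownum, row in enumerate(reader, start=1):
            problems = _parse_problems(row["problems"] or "")
            unknown = problems - leaves
            if unknown:
                raise CohortValidationError(
                    f"{path} row {rownum}: unknown problem code(s) {sorted(unknown)}"
                )
            gender = (row["gender"] or "").strip() or None
            age_cell = (row["age"] or "").strip()
            cases.append(
                CaseRecord(
                    case_id=row["case_id"],
                    gender=gender,
                    age=int(age_cell) if age_cell else None,
                    substance=(row["substance"] or "").strip() or None,
                    problems=problems,
                )
            )
    return Cohort(taxonomy, tuple(cases))


def write_cohort(cohort: Cohort, path, delimiter: str = ",") -> None:
    """Write a cohort file that ``load_cohort`` reads back identically.

    Problem codes are written in taxonomy order so output is canonical.
    """
    order = {leaf: i for i, leaf in enumerate(cohort.taxonomy.subcategories)}
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(REQUIRED_COLUMNS)
    for case in cohort.cases:
        problems = "|".join(sorted(case.problems, key=order.__getitem__))
        writer.writerow(
            [
                case.case_id,
                case.gender or "",
                "" if case.age is None else case.age,
                case.substance or "",
                problems,
            ]
        )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def filter_stratum(cohort: Cohort, gender: str) -> Cohort:
    """Sub-cohort of cases with the given gender; taxonomy unchanged."""
    if gender not in GENDERS:
        raise ValueError(f"gender must be one of {GENDERS}, got {gender!r}")
    return replace(cohort, cases=tuple(c for c in cohort.cases if c.gender == gender))


@dataclass(frozen=True)
class CohortSummary:
    """Per-category report counts and percentages by stratum.

    ``table`` has one row per class (class rows carry the sum of their leaves)
    and per leaf, in taxonomy order, with columns
    ``(stratum)_count`` / ``(stratum)_pct`` for total/male/female.
    Percentages are shares of the stratum's total problem reports, rounded
    half-up to one decimal; they are NaN when the stratum has no reports.
    """

    table: pd.DataFrame
    report_totals: dict[str, int]  # stratum -> total problem reports
    n_cases: int
    n_zero_problem: int
    n_single_problem: int
    n_multi_problem: int


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Tally problem reports per subcategory and class, overall and by gender."""
    tax = cohort.taxonomy
    counts = {s: {leaf: 0 for leaf in tax.subcategories} for s in STRATA}
    n_zero = n_single = n_multi = 0
    for case in cohort.cases:
        k = len(case.problems)
        if k == 0:
            n_zero += 1
        elif k == 1:
            n_single += 1
        else:
            n_multi += 1
        strata = ["total"] + ([case.gender] if case.gender in GENDERS else [])
        for leaf in case.problems:
            for s in strata:
                counts[s][leaf] += 1
    totals = {s: sum(counts[s].values()) for s in STRATA}

    rows = []
    for cls in tax.classes:
        leaves = tax.leaves_of(cls)
        rows.append((cls, cls, True, {s: sum(counts[s][l] for l in leaves) for s in STRATA}))
        for leaf in leaves:
            rows.append((leaf, cls, False, {s: counts[s][leaf] for s in STRATA}))

    data: dict[str, list] = {"category": [], "class": [], "is_class": []}
    for s in STRATA:
        data[f"{s}_count"] = []
        data[f"{s}_pct"] = []
    for code, cls, is_class, cnt in rows:
        data["category"].append(code)
        data["class"].append(cls)
        data["is_class"].append(is_class)
        for s in STRATA:
            data[f"{s}_count"].append(cnt[s])
            pct = (
                round_half_up(100.0 * cnt[s] / totals[s]) if totals[s] > 0 else np.nan
            )
            data[f"{s}_pct"].append(pct)
    table = pd.DataFrame(data).set_index("category")
    return CohortSummary(
        table=table,
        report_totals=totals,
        n_cases=len(cohort),
        n_zero_problem=n_zero,
        n_single_problem=n_single,
        n_multi_problem=n_multi,
    )
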