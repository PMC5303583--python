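"""Published per-subcategory report margins of the motivating hospital cohort.

The study cohort (357 deliberate self-poisoning admissions, 579 problem
reports) is not deposited; what is public are its marginal counts — reports
per problem subcategory, split by gender. Those margins are recorded here
both as fixture material and as the prevalence weights the synthetic
generator defaults to.
"""

from __future__ import annotations

from .cohort import CaseRecord, Cohort
from .taxonomy import ProblemTaxonomy, default_taxonomy

__all__ = ["REFERENCE_LEAF_COUNTS", "REFERENCE_COHORT_SHAPE", "cohort_from_counts"]

# leaf -> (male reports, female reports); totals: male 265, female 314, all 579
REFERENCE_LEAF_COUNTS: dict[str, tuple[int, int]] = {
    "physical_illness": (13, 36),
    "depression": (15, 34),
    "alcoholism": (23, 2),
    "drug_addiction": (59, 10),
    "other_mental_problems": (30, 37),
    "surgery": (6, 11),
    "family_conflicts": (56, 100),
    "marital_problems": (4, 18),
    "divorce": (4, 11),
    "death_of_family_member": (0, 5),
    "physical_violence": (0, 3),
    "other_family_problems": (2, 9),
    "financial_problems": (20, 3),
    "unemployment": (2, 0),
    "other_economic_problems": (4, 0),
    "romantic_problems": (5, 11),
    "educational_problems": (3, 2),
    "others": (19, 22),
}

# case-level shape of the study cohort
REFERENCE_COHORT_SHAPE = {
    "n_cases": 357,
    "n_zero_problem": 93,
    "n_single_problem": 107,
    "n_multi_problem": 157,
    "n_reports": 579,
    "female_share": 0.574,
}


def cohort_from_counts(
    counts: dict[str, tuple[int, int]] | None = None,
    taxonomy: ProblemTaxonomy | None = None,
) -> Cohort:
    """Deterministic cohort whose per-leaf, per-gender report tallies equal ``counts``.

    Each report becomes one single-problem case, so the summary's count and
    percentage columns reproduce the given margins exactly. Case-level
    structure (multi-problem cases) is deliberately not emulated here; use
    the synthetic generator for that.
    """
    counts = REFERENCE_LEAF_COUNTS if counts is None else counts
    taxonomy = default_taxonomy() if taxonomy is None else taxonomy
    cases: list[CaseRecord] = []
    for leaf in taxonomy.subcategories:
        male, female = counts.get(leaf, (0, 0))
        for gender, n in (("male", male), ("female", female)):
            for i in range(n):
                cases.append(
                    CaseRecord(
                        case_id=f"{leaf}-{gender}-{i}",
                        gender=gender,
                        problems=frozenset({leaf}),
                    )
                )
    return Cohort(taxonomy, tuple(cases))
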