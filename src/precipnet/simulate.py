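"""Synthetic cohort generator with planted co-occurrence block structure.

Emulates the statistical shape of a self-poisoning admissions cohort: each
case draws a gender, then a number of problems ``k`` (many cases have zero or
one), then ``k`` distinct problem subcategories by sequential weighted
sampling without replacement. A planted partition of the leaves into blocks,
with a within-block boost factor ``beta`` >= 1, multiplies the weight of any
candidate leaf that shares a block with an already-drawn leaf — the ground
truth used to validate co-occurrence construction and blockmodel recovery.

For specs whose problem-count distribution is supported on {0, 1, 2} the
pair-count expectation has a closed form (``expected_cooccurrence``), giving
an analytic oracle for the generator and the network builder jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import CaseRecord, Cohort, GENDERS
from .reference import REFERENCE_COHORT_SHAPE, REFERENCE_LEAF_COUNTS
from .taxonomy import ProblemTaxonomy, default_taxonomy

__all__ = [
    "SyntheticCohortSpec",
    "SpecError",
    "default_spec",
    "generate_cohort",
    "expected_cooccurrence",
    "load_spec",
    "write_spec",
]


class SpecError(ValueError):
    """Raised for invalid or infeasible generator specifications."""


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the generative model.

    Attributes
    ----------
    n_cases : int
        Number of cases to draw.
    gender_split : float
        Probability a case is female.
    problem_count_dist : dict[int, float]
        Distribution of the per-case problem count k (must sum to 1).
    base_prevalence : dict[str, dict[str, float]]
        Per-gender, per-leaf sampling weights (non-negative, at least one
        positive per gender).
    blocks : tuple[frozenset[str], ...]
        Planted partition of (a subset of) the leaves; leaves absent from
        every block are unboosted singletons.
    beta : float
        Within-block co-occurrence boost factor, >= 1 (1 = no planted
        structure).
    seed : int
        Seed of the single random stream.
    taxonomy : ProblemTaxonomy
    """

    n_cases: int
    gender_split: float = REFERENCE_COHORT_SHAPE["female_share"]
    problem_count_dist: dict[int, float] = field(default_factory=dict)
    base_prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    blocks: tuple[frozenset[str], ...] = ()
    beta: float = 1.0
    seed: int = 0
    taxonomy: ProblemTaxonomy = field(default_factory=default_taxonomy)

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise SpecError("n_cases must be >= 0")
        if not 0.0 <= self.gender_split <= 1.0:
            raise SpecError("gender_split must lie in [0, 1]")
        if self.beta < 1.0:
            raise SpecError("beta must be >= 1")
        object.__setattr__(self, "blocks", tuple(frozenset(b) for b in self.blocks))
        leaves = set(self.taxonomy.subcategories)
        seen: set[str] = set()
        for block in self.blocks:
            if block - leaves:
                raise SpecError(f"block leaves not in taxonomy: {sorted(block - leaves)}")
            if block & seen:
                raise SpecError("planted blocks must be disjoint")
            seen |= block
        dist = self.problem_count_dist
        if not dist:
            raise SpecError("problem_count_dist is empty")
        if any(k < 0 or p < 0 for k, p in dist.items()):
            raise SpecError("problem counts and masses must be non-negative")
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise SpecError("problem_count_dist must sum to 1")
        k_max = max(k for k, p in dist.items() if p > 0)
        for gender in GENDERS:
            weights = self.base_prevalence.get(gender, {})
            if any(w < 0 for w in weights.values()):
                raise SpecError(f"negative prevalence weight for {gender}")
            n_positive = sum(1 for w in weights.values() if w > 0)
            if n_positive == 0:
                raise SpecError(f"no positive prevalence weight for {gender}")
            if k_max > n_positive:
                raise SpecError(
                    f"infeasible draw: k={k_max} exceeds the {n_positive} "
                    f"positive-weight leaves for {gender}"
                )


def default_spec(seed: int = 0, beta: float = 1.0,
                 blocks: tuple[frozenset[str], ...] = ()) -> SyntheticCohortSpec:
    """Spec emulating the study cohort's shape.

    357 cases, 57.4% female, zero/single/multi case mass 93:107:157 with the
    multi-problem count spread over {2, 3, 4} around its observed mean of 3,
    and per-gender leaf weights proportional to the published report margins.
    """
    shape = REFERENCE_COHORT_SHAPE
    n = shape["n_cases"]
    p_multi = shape["n_multi_problem"] / n
    dist = {
        0: shape["n_zero_problem"] / n,
        1: shape["n_single_problem"] / n,
        2: p_multi * 0.25,
        3: p_multi * 0.50,
        4: p_multi * 0.25,
    }
    prevalence = {
        "male": {leaf: float(m) for leaf, (m, f) in REFERENCE_LEAF_COUNTS.items()},
        "female": {leaf: float(f) for leaf, (m, f) in REFERENCE_LEAF_COUNTS.items()},
    }
    return SyntheticCohortSpec(
        n_cases=n,
        gender_split=shape["female_share"],
        problem_count_dist=dist,
        base_prevalence=prevalence,
        blocks=blocks,
        beta=beta,
        seed=seed,
    )


def _block_index(spec: SyntheticCohortSpec) -> dict[str, int]:
    return {leaf: i for i, block in enumerate(spec.blocks) for leaf in block}


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Draw a cohort; deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    leaves = list(spec.taxonomy.subcategories)
    block_of = _block_index(spec)
    ks = sorted(spec.problem_count_dist)
    k_probs = np.array([spec.problem_count_dist[k] for k in ks], dtype=float)
    k_probs = k_probs / k_probs.sum()
    base = {
        g: np.array([spec.base_prevalence[g].get(l, 0.0) for l in leaves])
        for g in GENDERS
    }
    cases: list[CaseRecord] = []
    for i in range(spec.n_cases):
        gender = "female" if rng.random() < spec.gender_split else "male"
        k = int(ks[rng.choice(len(ks), p=k_probs)])
        weights = base[gender].copy()
        chosen: list[int] = []
        chosen_blocks: set[int] = set()
        for _ in range(k):
            w = weights.copy()
            w[chosen] = 0.0
            if chosen_blocks:
                boost = np.array(
                    [block_of.get(l, -1) in chosen_blocks for l in leaves]
                )
                w = np.where(boost, w * spec.beta, w)
            total = w.sum()
            if total <= 0:  # exhausted positive-weight leaves mid-draw
                raise SpecError("infeasible draw: ran out of positive-weight leaves")
            j = int(rng.choice(len(leaves), p=w / total))
            chosen.append(j)
            if leaves[j] in block_of:
                chosen_blocks.add(block_of[leaves[j]])
        cases.append(
            CaseRecord(
                case_id=f"S{i:05d}",
                gender=gender,
                problems=frozenset(leaves[j] for j in chosen),
            )
        )
    return Cohort(spec.taxonomy, tuple(cases))


def expected_cooccurrence(spec: SyntheticCohortSpec) -> dict[frozenset[str], float]:
    """Analytic expected pair counts; defined only when k is supported on {0,1,2}.

    For a case of gender g with k=2 the probability of ending with the
    unordered pair {a, b} is P(first=a)P(second=b | a) + P(first=b)P(second=a | b)
    where the second draw reweights remaining leaves by beta if they share a
    planted block with the first. The expectation sums over genders and
    multiplies by n_cases.
    """
    unsupported = [k for k, p in spec.problem_count_dist.items() if p > 0 and k > 2]
    if unsupported:
        raise NotImplementedError(
            f"closed form requires k <= 2; spec has mass on k={sorted(unsupported)}"
        )
    p2 = spec.problem_count_dist.get(2, 0.0)
    leaves = list(spec.taxonomy.subcategories)
    block_of = _block_index(spec)
    p_gender = {"female": spec.gender_split, "male": 1.0 - spec.gender_split}

    def mult(a: str, b: str) -> float:
        same = a in block_of and b in block_of and block_of[a] == block_of[b]
        return spec.beta if same else 1.0

    out: dict[frozenset[str], float] = {}
    for gender in GENDERS:
        w = {l: spec.base_prevalence[gender].get(l, 0.0) for l in leaves}
        total = sum(w.values())
        if total <= 0 or p_gender[gender] == 0:
            continue
        denom = {
            a: sum(w[j] * mult(a, j) for j in leaves if j != a) for a in leaves
        }
        for i, a in enumerate(leaves):
            for b in leaves[i + 1:]:
                prob = 0.0
                if w[a] > 0 and denom[a] > 0:
                    prob += (w[a] / total) * (w[b] * mult(a, b) / denom[a])
                if w[b] > 0 and denom[b] > 0:
                    prob += (w[b] / total) * (w[a] * mult(a, b) / denom[b])
                key = frozenset({a, b})
                out[key] = out.get(key, 0.0) + spec.n_cases * p_gender[gender] * p2 * prob
    return out


def _spec_to_dict(spec: SyntheticCohortSpec) -> dict:
    return {
        "n_cases": spec.n_cases,
        "gender_split": spec.gender_split,
        "problem_count_dist": {int(k): float(v) for k, v in spec.problem_count_dist.items()},
        "base_prevalence": {g: dict(w) for g, w in spec.base_prevalence.items()},
        "blocks": [sorted(b) for b in spec.blocks],
        "beta": spec.beta,
        "seed": spec.seed,
    }


def write_spec(spec: SyntheticCohortSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_spec_to_dict(spec), fh, sort_keys=False)


def load_spec(path, taxonomy: ProblemTaxonomy | None = None) -> SyntheticCohortSpec:
    """Read a generator spec from YAML; omitted fields fall back to defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = _spec_to_dict(default_spec())
    base.update(raw)
    return SyntheticCohortSpec(
        n_cases=int(base["n_cases"]),
        gender_split=float(base["gender_split"]),
        problem_count_dist={int(k): float(v) for k, v in base["problem_count_dist"].items()},
        base_prevalence=base["base_prevalence"],
        blocks=tuple(frozenset(b) for b in base["blocks"]),
        beta=float(base["beta"]),
        seed=int(base["seed"]),
        taxonomy=taxonomy or default_taxonomy(),
    )
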