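"""Problem taxonomy: six classes of precipitating problems and their 18 subcategories.

The taxonomy mirrors the classification used in hospital chart abstraction of
deliberate self-poisoning cases: each reported problem is one of 18 leaf
subcategories, each belonging to exactly one of 6 classes (health, family,
economic, romantic, educational, other).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["ProblemTaxonomy", "default_taxonomy", "load_taxonomy", "write_taxonomy"]

# class -> [(leaf_code, human label), ...]
_DEFAULT = {
    "health": [
        ("physical_illness", "Physical illness"),
        ("depression", "Depression"),
        ("alcoholism", "Alcoholism"),
        ("drug_addiction", "Drug addiction"),
        ("other_mental_problems", "Other mental problems"),
        ("surgery", "Surgery"),
    ],
    "family": [
        ("family_conflicts", "Family conflicts"),
        ("marital_problems", "Marital problems"),
        ("divorce", "Divorce"),
        ("death_of_family_member", "Death of family member"),
        ("physical_violence", "Physical violence"),
        ("other_family_problems", "Other family problems"),
    ],
    "economic": [
        ("financial_problems", "Financial problems"),
        ("unemployment", "Unemployment"),
        ("other_economic_problems", "Other economic problems"),
    ],
    "romantic": [("romantic_problems", "Romantic problems")],
    "educational": [("educational_problems", "Educational problems")],
    "other": [("others", "Others")],
}


@dataclass(frozen=True)
class ProblemTaxonomy:
    """Ordered two-level taxonomy of precipitating problems.

    Attributes
    ----------
    classes : tuple of str
        Ordered class codes.
    subcategories : tuple of str
        Ordered leaf codes (order follows class order).
    leaf_to_class : dict
        Total mapping leaf code -> class code.
    labels : dict
        Leaf code -> human-readable name.
    """

    classes: tuple[str, ...]
    subcategories: tuple[str, ...]
    leaf_to_class: dict[str, str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class codes")
        if len(set(self.subcategories)) != len(self.subcategories):
            raise ValueError("duplicate leaf codes")
        if set(self.leaf_to_class) != set(self.subcategories):
            raise ValueError("leaf_to_class must map every leaf and nothing else")
        bad = set(self.leaf_to_class.values()) - set(self.classes)
        if bad:
            raise ValueError(f"leaf mapped to unknown class: {sorted(bad)}")

    def class_of(self, leaf: str) -> str:
        return self.leaf_to_class[leaf]

    def leaves_of(self, cls: str) -> tuple[str, ...]:
        return tuple(l for l in self.subcategories if self.leaf_to_class[l] == cls)

    def label(self, leaf: str) -> str:
        return self.labels.get(leaf, leaf)


def default_taxonomy() -> ProblemTaxonomy:
    """The standard 6-class / 18-subcategory problem taxonomy."""
    classes = tuple(_DEFAULT)
    leaves: list[str] = []
    leaf_to_class: dict[str, str] = {}
    labels: dict[str, str] = {}
    for cls, items in _DEFAULT.items():
        for code, label in items:
            leaves.append(code)
            leaf_to_class[code] = cls
            labels[code] = label
    return ProblemTaxonomy(classes, tuple(leaves), leaf_to_class, labels)


def load_taxonomy(path) -> ProblemTaxonomy:
    """Read a taxonomy from a YAML/JSON mapping ``class -> [leaves]``.

    Leaves may be plain codes or one-entry ``{code: label}`` mappings.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ValueError(f"taxonomy file {path} must be a non-empty class->leaves mapping")
    classes = tuple(raw)
    leaves: list[str] = []
    leaf_to_class: dict[str, str] = {}
    labels: dict[str, str] = {}
    for cls, entries in raw.items():
        for entry in entries or []:
            if isinstance(entry, dict):
                (code, label), = entry.items()
            else:
                code, label = str(entry), str(entry)
            leaves.append(code)
            leaf_to_class[code] = cls
            labels[code] = label
    return ProblemTaxonomy(classes, tuple(leaves), leaf_to_class, labels)


def write_taxonomy(taxonomy: ProblemTaxonomy, path) -> None:
    """Write a taxonomy as a YAML class->leaves mapping (round-trips with load)."""
    doc = {
        cls: [{leaf: taxonomy.label(leaf)} for leaf in taxonomy.leaves_of(cls)]
        for cls in taxonomy.classes
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
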