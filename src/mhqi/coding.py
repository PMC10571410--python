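"""Code lists and classification maps for diagnoses, drugs and services.

Administrative mental-healthcare data arrive coded: diagnoses as ICD-9-CM or
ICD-10 strings, drug dispensations as ATC codes, outpatient interventions and
laboratory services as catalogue entries.  This module holds the editable
:class:`CodingMaps` bundle that the rest of the pipeline consults, together
with prefix-matching classifiers.  The shipped defaults cover the standard
psychotropic classes; every list can be overridden from a YAML file so that
study-specific code lists can be dropped in without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

# Drug-class labels used throughout the pipeline.
ANTIPSYCHOTIC = "antipsychotic"
LITHIUM = "lithium"
VALPROATE_CARBAMAZEPINE = "valproate_carbamazepine"
LAMOTRIGINE = "lamotrigine"
OTHER_MOOD_STABILIZER = "other_mood_stabilizer"
ANTIDEPRESSANT = "antidepressant"

#: classes whose union constitutes "mood stabilizers"
MOOD_STABILIZER_CLASSES = frozenset(
    {LITHIUM, VALPROATE_CARBAMAZEPINE, LAMOTRIGINE, OTHER_MOOD_STABILIZER}
)
#: aggregate label for any mood-stabilizing agent
MOOD_STABILIZER = "mood_stabilizer"
#: aggregate label for any psychotropic agent (used by the washout rule)
PSYCHOTROPIC = "psychotropic"

DRUG_CLASSES = frozenset(
    {
        ANTIPSYCHOTIC,
        LITHIUM,
        VALPROATE_CARBAMAZEPINE,
        LAMOTRIGINE,
        OTHER_MOOD_STABILIZER,
        ANTIDEPRESSANT,
    }
)

INTERVENTION_CATALOGUE = (
    "psychiatric_visit",
    "standardized_assessment",
    "psychosocial_intervention",
    "psychotherapy",
    "psychoeducation",
    "family_intervention",
    "other",
)

MONITORING_SERVICES = (
    "lithaemia",
    "electrolytes",
    "glycaemia",
    "lipid_panel",
    "transaminases",
    "blood_count",
)

# Default ATC prefix -> drug class.  ``None`` marks an exclusion carve-out:
# lithium salts (N05AN) are not counted as antipsychotics even though they sit
# inside ATC N05A.  Longest-prefix matching makes carve-outs compose.
_DEFAULT_DRUG_PREFIXES: dict[str, Optional[str]] = {
    "N05A": ANTIPSYCHOTIC,
    "N05AN": None,
    "N05AN01": LITHIUM,
    "N03A": OTHER_MOOD_STABILIZER,
    "N03AG01": VALPROATE_CARBAMAZEPINE,
    "N03AF01": VALPROATE_CARBAMAZEPINE,
    "N03AX09": LAMOTRIGINE,
    "N06A": ANTIDEPRESSANT,
}

# Personality disorders: ICD-10 F60-F61, ICD-9-CM 301.* (prefix semantics).
_DEFAULT_PD_CODES = ("F60", "F61", "301")

_DEFAULT_MONITORING_SETS: dict[str, tuple[str, ...]] = {
    ANTIPSYCHOTIC: ("glycaemia", "lipid_panel"),
    LITHIUM: ("lithaemia", "electrolytes"),
    VALPROATE_CARBAMAZEPINE: ("blood_count", "transaminases"),
    LAMOTRIGINE: ("blood_count",),
}


class InvalidCodeError(ValueError):
    """Raised for structurally invalid codes (e.g. an empty ATC string)."""


@dataclass(frozen=True)
class CodingMaps:
    """Bundle of code lists driving classification decisions.

    Parameters
    ----------
    personality_disorder_codes
        ICD prefixes identifying a personality-disorder diagnosis; a prefix
        matches any more specific code (``"F60"`` matches ``"F60.3"``).
    drug_classes
        ATC prefix -> drug-class label; a ``None`` value carves the prefix
        out of any enclosing class.  Codes are resolved by longest prefix.
    monitoring_sets
        Drug class -> the laboratory/specialist service codes that together
        form the recommended monitoring panel for that class.
    intervention_catalogue
        Admissible ``intervention_type`` values for outpatient contacts.
    """

    personality_disorder_codes: tuple[str, ...] = _DEFAULT_PD_CODES
    drug_classes: Mapping[str, Optional[str]] = field(
        default_factory=lambda: dict(_DEFAULT_DRUG_PREFIXES)
    )
    monitoring_sets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_MONITORING_SETS)
    )
    intervention_catalogue: tuple[str, ...] = INTERVENTION_CATALOGUE

    def __post_init__(self) -> None:
        if not self.personality_disorder_codes:
            raise ValueError("personality_disorder_codes must be non-empty")
        if not self.drug_classes:
            raise ValueError("drug_classes must be non-empty")
        for prefix, cls in self.drug_classes.items():
            if cls is not None and cls not in DRUG_CLASSES:
                raise ValueError(f"unknown drug class {cls!r} for prefix {prefix!r}")

    # -- classification ----------------------------------------------------

    def classify_drug(self, atc_code: str) -> Optional[str]:
        """Return the drug class of an ATC code, or ``None`` if unclassified.

        Resolution is by longest configured prefix, so molecule-level entries
        override class-level ones and exclusion carve-outs override both.
        """
        if not atc_code or not atc_code.strip():
            raise InvalidCodeError("empty ATC code")
        code = atc_code.strip().upper()
        best: Optional[str] = None
        best_len = -1
        for prefix, cls in self.drug_classes.items():
            if code.startswith(prefix) and len(prefix) > best_len:
                best, best_len = cls, len(prefix)
        return best

    def drug_memberships(self, atc_code: str) -> frozenset[str]:
        """All class labels an ATC code belongs to, including aggregates.

        A lithium dispensation, for instance, is simultaneously ``lithium``,
        ``mood_stabilizer`` and ``psychotropic``.
        """
        cls = self.classify_drug(atc_code)
        if cls is None:
            return frozenset()
        labels = {cls, PSYCHOTROPIC}
        if cls in MOOD_STABILIZER_CLASSES:
            labels.add(MOOD_STABILIZER)
        return frozenset(labels)

    def is_personality_disorder(self, icd_code: str) -> bool:
        """Prefix-membership test against the personality-disorder list.

        Unknown or malformed codes simply test false.
        """
        if not icd_code:
            return False
        code = icd_code.strip().upper()
        return any(code.startswith(p.upper()) for p in self.personality_disorder_codes)

    def monitoring_panel(self, drug_class: str) -> frozenset[str]:
        """Required monitoring service codes for a drug class (may be empty)."""
        return frozenset(self.monitoring_sets.get(drug_class, ()))

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "personality_disorder_codes": list(self.personality_disorder_codes),
            "drug_classes": {
                p: (c if c is not None else "none") for p, c in self.drug_classes.items()
            },
            "monitoring_sets": {k: list(v) for k, v in self.monitoring_sets.items()},
            "intervention_catalogue": list(self.intervention_catalogue),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CodingMaps":
        raw = dict(d.get("drug_classes", _DEFAULT_DRUG_PREFIXES))
        drug_classes = {p: (None if c in (None, "none") else c) for p, c in raw.items()}
        return cls(
            personality_disorder_codes=tuple(
                d.get("personality_disorder_codes", _DEFAULT_PD_CODES)
            ),
            drug_classes=drug_classes,
            monitoring_sets={
                k: tuple(v)
                for k, v in dict(d.get("monitoring_sets", _DEFAULT_MONITORING_SETS)).items()
            },
            intervention_catalogue=tuple(
                d.get("intervention_catalogue", INTERVENTION_CATALOGUE)
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CodingMaps":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


#: module-level default maps, shared by the generator and the pipeline
DEFAULT_MAPS = CodingMaps()
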