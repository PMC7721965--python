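"""The coding dictionary: concepts, value sets and units.

Everything semantic in the emitted DICOM objects — what a segment
represents, which attribute a qualitative evaluation rates, what each
ordinal rating means, what a measurement measures and in what unit — is a
coded concept: a (CodeValue, CodingSchemeDesignator, CodeMeaning) triplet.
Standard schemes (SRT/SCT for SNOMED, UCUM for units, IBSI for radiomics
nomenclature, DCM for DICOM-defined terms) are used where a matching
concept exists; collection-specific rating scales use a private scheme,
99LIDCQIICR, flagged nonstandard by its "99" prefix.

The dictionary ships as a human-editable YAML file
(``lidckit/data/codes.yaml``, schema documented in its header) and is
loaded once per process; an alternative dictionary file may be supplied for
any loader-backed operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml

from lidckit.lidc_xml import CHARACTERISTIC_NAMES

__all__ = [
    "CodedConcept",
    "CodeDictionary",
    "load_dictionary",
    "segmentation_semantics",
    "measurement_codes",
    "evaluation_code",
    "MEASUREMENT_NAMES",
]

MEASUREMENT_NAMES = ("diameter", "surface_area", "volume")

_ALLOWED_SCHEMES = {"SRT", "SCT", "UCUM", "IBSI", "DCM", "99LIDCQIICR", "RFC5646"}


@dataclass(frozen=True)
class CodedConcept:
    """A (CodeValue, CodingSchemeDesignator, CodeMeaning) triplet."""

    value: str
    scheme: str
    meaning: str

    def __post_init__(self) -> None:
        if not (self.value and self.scheme and self.meaning):
            raise ValueError("coded concept fields must all be non-empty")

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.value, self.scheme, self.meaning)


def _concept(node: dict) -> CodedConcept:
    c = CodedConcept(str(node["value"]), str(node["scheme"]), str(node["meaning"]))
    if c.scheme not in _ALLOWED_SCHEMES:
        raise ValueError(f"unexpected coding scheme {c.scheme!r} in dictionary")
    return c


class CodeDictionary:
    """Parsed, validated coding dictionary."""

    def __init__(self, raw: dict):
        sem = raw["segmentation_semantics"]
        self._semantics = {
            role: {form: _concept(node) for form, node in forms.items()}
            for role, forms in sem.items()
        }
        self._measurements = {
            name: (_concept(node["concept"]), _concept(node["unit"]))
            for name, node in raw["measurements"].items()
        }
        self._characteristics: dict[str, tuple[CodedConcept, dict[int, CodedConcept]]] = {}
        for attr, node in raw["characteristics"].items():
            values = {int(k): _concept(v) for k, v in node["values"].items()}
            self._characteristics[attr] = (_concept(node["concept"]), values)
        self._validate()

    def _validate(self) -> None:
        missing = set(CHARACTERISTIC_NAMES) - set(self._characteristics)
        if missing:
            raise ValueError(f"dictionary lacks characteristics: {sorted(missing)}")
        seen: dict[tuple[str, str], str] = {}
        for c in self.all_concepts():
            key = (c.value, c.scheme)
            if key in seen and seen[key] != c.meaning:
                raise ValueError(
                    f"code {key} appears with two meanings: "
                    f"{seen[key]!r} vs {c.meaning!r}"
                )
            seen[key] = c.meaning

    def all_concepts(self) -> list[CodedConcept]:
        out = [c for forms in self._semantics.values() for c in forms.values()]
        for concept, unit in self._measurements.values():
            out += [concept, unit]
        for concept, values in self._characteristics.values():
            out.append(concept)
            out += list(values.values())
        return out

    def segmentation_semantics(
        self, scheme: str = "SRT"
    ) -> tuple[CodedConcept, CodedConcept, CodedConcept]:
        """(category, type, anatomy) triple, constant for every segment.

        ``scheme`` selects the SRT identifiers (as published) or the SCT
        numeric codes for the same SNOMED concepts.
        """
        form = scheme.lower()
        if form not in ("srt", "sct"):
            raise ValueError("scheme must be 'SRT' or 'SCT'")
        return tuple(self._semantics[role][form] for role in ("category", "type", "anatomy"))

    def measurement_codes(self, name: str) -> tuple[CodedConcept, CodedConcept]:
        """(concept, unit) pair for one of the three measurement names."""
        try:
            return self._measurements[name]
        except KeyError:
            raise KeyError(
                f"unknown measurement {name!r}; expected one of "
                f"{sorted(self._measurements)}"
            ) from None

    def all_measurement_codes(self) -> dict[str, tuple[CodedConcept, CodedConcept]]:
        return dict(self._measurements)

    def evaluation_code(
        self, attribute: str, rating: int
    ) -> tuple[CodedConcept, CodedConcept]:
        """(concept, value) pair for one characteristic rating."""
        if attribute not in self._characteristics:
            raise KeyError(
                f"unknown characteristic {attribute!r}; expected one of "
                f"{sorted(self._characteristics)}"
            )
        concept, values = self._characteristics[attribute]
        rating = int(rating)
        if rating not in values:
            raise ValueError(
                f"{attribute} rating {rating} out of range; valid ratings: "
                f"{sorted(values)}"
            )
        return concept, values[rating]

    def value_set(self, attribute: str) -> dict[int, CodedConcept]:
        return dict(self._characteristics[attribute][1])

    def is_known_pair(self, concept: CodedConcept, value: CodedConcept) -> bool:
        """True when (concept, value) is a dictionary evaluation pair."""
        for attr_concept, values in self._characteristics.values():
            if attr_concept.as_tuple() == concept.as_tuple():
                return any(v.as_tuple() == value.as_tuple() for v in values.values())
        return False

    def concept_to_attribute(self, concept: CodedConcept) -> str | None:
        for attr, (attr_concept, _) in self._characteristics.items():
            if attr_concept.as_tuple() == concept.as_tuple():
                return attr
        return None

    def rating_for_value(self, attribute: str, value: CodedConcept) -> int:
        for rating, v in self._characteristics[attribute][1].items():
            if v.as_tuple() == value.as_tuple():
                return rating
        raise ValueError(f"value code {value} not in {attribute} value set")


@lru_cache(maxsize=4)
def _load_cached(path_str: str | None) -> CodeDictionary:
    if path_str is None:
        text = (resources.files("lidckit") / "data" / "codes.yaml").read_text()
    else:
        text = Path(path_str).read_text()
    return CodeDictionary(yaml.safe_load(text))


def load_dictionary(path: str | Path | None = None) -> CodeDictionary:
    """Load the shipped dictionary, or an alternative YAML file."""
    return _load_cached(str(path) if path is not None else None)


def segmentation_semantics(scheme: str = "SRT"):
    """Module-level convenience over the shipped dictionary."""
    return load_dictionary().segmentation_semantics(scheme)


def measurement_codes(name: str):
    return load_dictionary().measurement_codes(name)


def evaluation_code(attribute: str, rating: int):
    return load_dictionary().evaluation_code(attribute, rating)
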