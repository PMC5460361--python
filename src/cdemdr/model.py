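"""Core ISO 11179-style domain types and the registry container.

The data-description subset modelled here is the classic decomposition of a
common data element (CDE): an *object class* (the thing being described, e.g.
"Pharmacologic Substance"), a *property* (the aspect described, e.g. "Begin
Occurrence") and a *value domain* (the representation, e.g. "Event Month
Number", possibly enumerated with permissible values).  Components may carry
concept annotations from a standard terminology such as the NCI Thesaurus,
either a single pre-coordinated code or a colon-joined post-coordinated code
("C25431:C25275").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ConceptRef",
    "ObjectClass",
    "PropertyDef",
    "PermissibleValue",
    "ValueDomain",
    "DataElement",
    "DomainVariable",
    "ClinicalDomain",
    "Registry",
    "ModelError",
    "DuplicateElementError",
    "parse_concept_code",
    "dedup_key",
    "build_registry",
]

_NCIT_CODE = re.compile(r"^C\d+$")
_WS = re.compile(r"\s+")


class ModelError(ValueError):
    """Invalid domain object or operation input."""


class DuplicateElementError(ModelError):
    """Two data elements share the same (public_id, version) identity."""

    def __init__(self, first: "DataElement", second: "DataElement"):
        self.first = first
        self.second = second
        super().__init__(
            f"duplicate data element identity ({first.public_id!r}, "
            f"{first.version!r}): {first.long_name!r} vs {second.long_name!r}"
        )


@dataclass(frozen=True)
class ConceptRef:
    """A terminology code, possibly post-coordinated (colon-joined atoms)."""

    code: str
    source: str = "NCIt"

    def __post_init__(self) -> None:
        if not self.code:
            raise ModelError("concept code must be non-empty")

    @property
    def parts(self) -> tuple[str, ...]:
        return tuple(self.code.split(":"))

    @property
    def is_postcoordinated(self) -> bool:
        return len(self.parts) > 1


def parse_concept_code(code: str, source: str = "NCIt") -> ConceptRef:
    """Parse a (possibly post-coordinated) terminology code.

    The code is preserved verbatim; ``parts`` is its colon-split.  NCI
    Thesaurus atoms are checked against the ``C<digits>`` pattern.
    """
    if not code:
        raise ModelError("concept code must be non-empty")
    ref = ConceptRef(code=code, source=source)
    if source == "NCIt":
        for atom in ref.parts:
            if not _NCIT_CODE.match(atom):
                raise ModelError(
                    f"atom {atom!r} of code {code!r} does not match the "
                    "NCI Thesaurus pattern C<digits>"
                )
    return ref


def _normalize_name(name: str) -> str:
    return _WS.sub(" ", name.strip()).lower()


@dataclass(frozen=True)
class ObjectClass:
    name: str
    public_id: str | None = None
    concepts: tuple[ConceptRef, ...] = ()

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ModelError("object class name must be non-empty")


@dataclass(frozen=True)
class PropertyDef:
    name: str
    public_id: str | None = None
    concepts: tuple[ConceptRef, ...] = ()

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ModelError("property name must be non-empty")


@dataclass(frozen=True)
class PermissibleValue:
    value: str
    meaning: str = ""
    concept: ConceptRef | None = None

    def __post_init__(self) -> None:
        if not self.value:
            raise ModelError("permissible value must be non-empty")


@dataclass(frozen=True)
class ValueDomain:
    name: str
    public_id: str | None = None
    datatype: str = "string"
    permissible_values: tuple[PermissibleValue, ...] = ()

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ModelError("value domain name must be non-empty")

    @property
    def kind(self) -> str:
        """``enumerated`` iff the domain carries permissible values."""
        return "enumerated" if self.permissible_values else "non_enumerated"


def dedup_key(item: ObjectClass | PropertyDef | ValueDomain) -> str:
    """Distinctness key for registry components.

    The registry counts *distinct* object classes, properties and value
    domains.  The key is the public registry identifier when present,
    otherwise the lowercase, whitespace-collapsed display name.  Idempotent
    and invariant under case and extra whitespace.
    """
    if item.public_id:
        return item.public_id
    return _normalize_name(item.name)


@dataclass(frozen=True)
class DataElement:
    """An ISO 11179 common data element."""

    public_id: str
    version: str
    long_name: str
    object_class: ObjectClass
    property: PropertyDef
    value_domain: ValueDomain
    preferred_name: str | None = None
    definition: str = ""
    workflow_status: str = "RELEASED"

    def __post_init__(self) -> None:
        if not self.public_id:
            raise ModelError("data element public_id must be non-empty")
        if not self.long_name or not self.long_name.strip():
            raise ModelError("data element long_name must be non-empty")

    @property
    def identity(self) -> tuple[str, str]:
        return (self.public_id, self.version)


@dataclass(frozen=True)
class DomainVariable:
    """A data-dictionary variable, optionally annotated with a CDE."""

    variable_name: str
    cde_ref: str | None
    position: int

    @property
    def annotated(self) -> bool:
        return self.cde_ref is not None


@dataclass(frozen=True)
class ClinicalDomain:
    """A clinical study domain: an ordered list of dictionary variables."""

    name: str
    variables: tuple[DomainVariable, ...] = ()

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variables]
        if positions != list(range(len(positions))):
            raise ModelError(
                f"domain {self.name!r}: variable positions must be "
                f"0..{len(positions) - 1} in order, got {positions}"
            )


@dataclass
class Registry:
    """Container of data elements indexed by object-class dedup key."""

    data_elements: tuple[DataElement, ...] = ()
    index_by_object_class: dict[str, tuple[DataElement, ...]] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.data_elements)

    def get(self, public_id: str, version: str | None = None) -> DataElement | None:
        for de in self.data_elements:
            if de.public_id == public_id and (
                version is None or de.version == version
            ):
                return de
        return None

    def by_long_name(self, name: str) -> DataElement | None:
        """Case-insensitive, whitespace-normalized long-name lookup."""
        key = _normalize_name(name)
        for de in self.data_elements:
            if _normalize_name(de.long_name) == key:
                return de
        return None


def build_registry(elements: list[DataElement] | tuple[DataElement, ...]) -> Registry:
    """Build a registry, partitioning elements by object-class dedup key.

    Rejects duplicate (public_id, version) identities.  Every element lands
    in exactly one index bucket; bucket sizes sum to the element count.
    """
    seen: dict[tuple[str, str], DataElement] = {}
    for de in elements:
        if de.identity in seen:
            raise DuplicateElementError(seen[de.identity], de)
        seen[de.identity] = de
    buckets: dict[str, list[DataElement]] = {}
    for de in elements:
        buckets.setdefault(dedup_key(de.object_class), []).append(de)
    return Registry(
        data_elements=tuple(elements),
        index_by_object_class={k: tuple(v) for k, v in buckets.items()},
    )
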