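"""ISO 11179 schema subset and harmonization with a converted UML ontology.

The ISO side is a fixed, versioned axiom set in the ``mms`` namespace (the
data-description subset: AdministeredItem at the top, DataElement,
ObjectClass, Property, ValueDomain, PermissibleValue and their linking
properties).  Harmonization asserts every class of the converted reference
model as a subclass of ``mms:AdministeredItem``, adding nothing else.
"""

from __future__ import annotations

from .rdf import MMS
from .uml2owl import (
    ClassDecl,
    DatatypePropertyDecl,
    ObjectPropertyDecl,
    OntologySchema,
    SubClassOf,
)
from .rdf import XSD

__all__ = ["iso11179_schema", "harmonize", "HarmonizationError", "ADMINISTERED_ITEM"]

ADMINISTERED_ITEM = MMS + "AdministeredItem"


class HarmonizationError(ValueError):
    """IRI collision between the two input schemas."""


def iso11179_schema() -> OntologySchema:
    """The embedded ISO 11179 data-description schema subset (prefix mms)."""
    c = {
        name: MMS + name
        for name in (
            "AdministeredItem",
            "DataElement",
            "ObjectClass",
            "Property",
            "ValueDomain",
            "PermissibleValue",
        )
    }
    axioms = {
        *(ClassDecl(iri) for iri in c.values()),
        SubClassOf(c["DataElement"], c["AdministeredItem"]),
        SubClassOf(c["ObjectClass"], c["AdministeredItem"]),
        SubClassOf(c["Property"], c["AdministeredItem"]),
        SubClassOf(c["ValueDomain"], c["AdministeredItem"]),
        ObjectPropertyDecl(MMS + "objectClass", c["DataElement"], c["ObjectClass"]),
        ObjectPropertyDecl(MMS + "property", c["DataElement"], c["Property"]),
        ObjectPropertyDecl(MMS + "valueDomain", c["DataElement"], c["ValueDomain"]),
        ObjectPropertyDecl(
            MMS + "permissibleValue", c["ValueDomain"], c["PermissibleValue"]
        ),
        DatatypePropertyDecl(MMS + "publicId", c["AdministeredItem"], XSD + "string"),
        DatatypePropertyDecl(MMS + "version", c["AdministeredItem"], XSD + "string"),
        DatatypePropertyDecl(MMS + "longName", c["AdministeredItem"], XSD + "string"),
    }
    return OntologySchema(
        axioms=frozenset(axioms),
        iri_map={name: iri for name, iri in c.items()},
    )


def harmonize(
    cimi: OntologySchema, iso: OntologySchema | None = None
) -> OntologySchema:
    """Merge a converted reference-model ontology into the ISO schema.

    Output = all input axioms plus ``C subClassOf mms:AdministeredItem``
    for every reference-model class C; nothing else added or removed.
    Classes already in the ISO (mms) namespace are not re-asserted, which
    makes the operation idempotent.  Raises on class-IRI collision.
    """
    if iso is None:
        iso = iso11179_schema()
    collisions = cimi.classes() & iso.classes()
    # a previously harmonized input legitimately carries the ISO axioms
    if collisions and not iso.axioms <= cimi.axioms:
        raise HarmonizationError(
            f"class IRIs declared on both sides: {sorted(collisions)}"
        )
    new_subclass = {
        SubClassOf(iri, ADMINISTERED_ITEM)
        for iri in cimi.classes()
        if not iri.startswith(MMS)
    }
    iri_map = dict(iso.iri_map)
    iri_map.update(cimi.iri_map)
    return OntologySchema(
        axioms=frozenset(cimi.axioms | iso.axioms | new_subclass),
        iri_map=iri_map,
    )
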