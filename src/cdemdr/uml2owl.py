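"""Parse UML models from XMI and convert them to an OWL schema.

The conversion follows the classic ODM-style mapping: a UML class becomes an
OWL class, a generalization a subclass axiom, a primitive-typed attribute a
datatype property, a class-typed attribute or association end an object
property, and multiplicities become cardinality restrictions on the owning
class.  Only the subset exercised by clinical reference models (classes,
attributes, associations, generalizations, packages) is supported — no
stereotypes, no OCL.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .rdf import IRI, Literal, RDFGraph, RDF_TYPE, XSD, RDFS_NS, OWL_NS

__all__ = [
    "UMLAttribute",
    "UMLClass",
    "UMLAssociationEnd",
    "UMLAssociation",
    "UMLModel",
    "Axiom",
    "ClassDecl",
    "SubClassOf",
    "ObjectPropertyDecl",
    "DatatypePropertyDecl",
    "MaxCardinality",
    "MinCardinality",
    "OntologySchema",
    "XmiError",
    "UnsupportedDialectError",
    "ConversionError",
    "parse_xmi",
    "uml_to_owl",
    "PRIMITIVE_TO_XSD",
]

XMI_NS = "http://www.omg.org/XMI"
UML_NS = "http://www.omg.org/spec/UML"

#: Fixed UML-primitive to XSD datatype table; unknown primitives map to
#: xsd:string with a warning.
PRIMITIVE_TO_XSD = {
    "String": XSD + "string",
    "Integer": XSD + "integer",
    "Boolean": XSD + "boolean",
    "Real": XSD + "double",
    "Decimal": XSD + "decimal",
    "Date": XSD + "date",
    "Time": XSD + "time",
    "DateTime": XSD + "dateTime",
    "Uri": XSD + "anyURI",
    "Byte": XSD + "byte",
    "Count": XSD + "nonNegativeInteger",
}

UNBOUNDED = None  # upper multiplicity "*"


class XmiError(ValueError):
    """Malformed or unresolvable XMI content."""


class UnsupportedDialectError(XmiError):
    """The file is not in the supported XMI dialect/version."""


class ConversionError(ValueError):
    """UML model cannot be converted (e.g. unresolvable attribute type)."""


@dataclass(frozen=True)
class UMLAttribute:
    name: str
    type_name: str
    lower: int = 0
    upper: int | None = 1  # None == unbounded ("*")


@dataclass(frozen=True)
class UMLClass:
    name: str
    package: str = ""
    abstract: bool = False
    attributes: tuple[UMLAttribute, ...] = ()
    generalizations: tuple[str, ...] = ()  # parent class names


@dataclass(frozen=True)
class UMLAssociationEnd:
    role: str | None
    type_name: str
    lower: int = 0
    upper: int | None = None


@dataclass(frozen=True)
class UMLAssociation:
    name: str | None
    ends: tuple[UMLAssociationEnd, UMLAssociationEnd]


@dataclass
class UMLModel:
    name: str = ""
    packages: dict[str, tuple[str, ...]] = field(default_factory=dict)
    classes: dict[str, UMLClass] = field(default_factory=dict)
    associations: tuple[UMLAssociation, ...] = ()
    primitives: set[str] = field(default_factory=set)

    def validate(self) -> list[str]:
        """Return a list of unresolved-reference problems (empty if valid)."""
        problems = []
        for cls in self.classes.values():
            for parent in cls.generalizations:
                if parent not in self.classes:
                    problems.append(
                        f"class {cls.name!r}: unresolved generalization "
                        f"target {parent!r}"
                    )
            for attr in cls.attributes:
                if (
                    attr.upper is not None
                    and attr.lower > attr.upper
                ):
                    problems.append(
                        f"{cls.name}.{attr.name}: lower {attr.lower} > "
                        f"upper {attr.upper}"
                    )
        for assoc in self.associations:
            for end in assoc.ends:
                if end.type_name not in self.classes:
                    problems.append(
                        f"association {assoc.name!r}: unresolved end type "
                        f"{end.type_name!r}"
                    )
        return problems


# ---------------------------------------------------------------------------
# XMI parsing (documented minimal subset)
# ---------------------------------------------------------------------------

def _attr(elem: ET.Element, name: str) -> str | None:
    v = elem.get(f"{{{XMI_NS}}}{name}")
    if v is None:
        v = elem.get(name)
    return v


def _mult(elem: ET.Element) -> tuple[int, int | None]:
    lower_s = elem.get("lower", "0")
    upper_s = elem.get("upper", "1")
    lv = elem.find("lowerValue")
    uv = elem.find("upperValue")
    if lv is not None and lv.get("value") is not None:
        lower_s = lv.get("value")
    if uv is not None and uv.get("value") is not None:
        upper_s = uv.get("value")
    lower = int(lower_s)
    upper = UNBOUNDED if upper_s in ("*", "-1") else int(upper_s)
    return lower, upper


def parse_xmi(path_or_text) -> UMLModel:
    """Parse an XMI file (path or XML text) into a :class:`UMLModel`.

    The supported dialect: ``xmi:XMI`` root with an ``xmi:version``
    attribute (2.x), ``uml:Model`` containing nested ``packagedElement``
    nodes with ``xmi:type`` of ``uml:Package``, ``uml:Class``,
    ``uml:PrimitiveType`` or ``uml:Association``; class children
    ``ownedAttribute`` and ``generalization``.  Attribute/end types refer
    either to an ``xmi:id`` or to a primitive type name.
    """
    text = str(path_or_text)
    if "<" not in text:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise XmiError(f"malformed XMI: {exc}") from exc

    tag = root.tag.rsplit("}", 1)[-1]
    if tag not in ("XMI", "Model"):
        raise UnsupportedDialectError(f"unexpected root element {root.tag!r}")
    version = _attr(root, "version")
    if tag == "XMI":
        if version is None:
            raise UnsupportedDialectError("missing xmi:version attribute")
        if not version.startswith("2"):
            raise UnsupportedDialectError(
                f"unsupported XMI version {version!r} (2.x required)"
            )
        model_elem = next(
            (c for c in root if c.tag.rsplit("}", 1)[-1] == "Model"), None
        )
        if model_elem is None:
            raise UnsupportedDialectError("no uml:Model element found")
    else:
        model_elem = root

    model = UMLModel(name=model_elem.get("name", ""))
    id_to_name: dict[str, str] = {}
    pending_generals: list[tuple[str, str]] = []  # (class name, target ref)
    pending_attr_types: list[tuple[str, str, UMLAttribute]] = []

    def walk(elem: ET.Element, package: str) -> None:
        for child in elem.findall("packagedElement"):
            xtype = (_attr(child, "type") or "").rsplit(":", 1)[-1]
            name = child.get("name", "")
            xid = _attr(child, "id")
            if xtype == "Package":
                model.packages.setdefault(name, ())
                walk(child, name)
            elif xtype == "PrimitiveType":
                model.primitives.add(name)
                if xid:
                    id_to_name[xid] = name
            elif xtype == "Class":
                if xid:
                    id_to_name[xid] = name
                attrs = []
                for oa in child.findall("ownedAttribute"):
                    lower, upper = _mult(oa)
                    type_ref = oa.get("type", "")
                    attr = UMLAttribute(
                        name=oa.get("name", ""),
                        type_name=type_ref,  # resolved after full walk
                        lower=lower,
                        upper=upper,
                    )
                    attrs.append(attr)
                for gen in child.findall("generalization"):
                    target = gen.get("general", "")
                    pending_generals.append((name, target))
                model.classes[name] = UMLClass(
                    name=name,
                    package=package,
                    abstract=child.get("isAbstract", "false") == "true",
                    attributes=tuple(attrs),
                )
                model.packages[package] = model.packages.get(package, ()) + (
                    name,
                )
            elif xtype == "Association":
                ends = []
                for oe in child.findall("ownedEnd"):
                    lower, upper = _mult(oe)
                    ends.append(
                        UMLAssociationEnd(
                            role=oe.get("name") or None,
                            type_name=oe.get("type", ""),
                            lower=lower,
                            upper=upper,
                        )
                    )
                if len(ends) != 2:
                    raise XmiError(
                        f"association {name!r}: expected 2 ownedEnd, "
                        f"got {len(ends)}"
                    )
                model.associations = model.associations + (
                    UMLAssociation(name=name or None, ends=(ends[0], ends[1])),
                )

    model.packages.setdefault("", ())
    walk(model_elem, "")

    def resolve(ref: str) -> str:
        return id_to_name.get(ref, ref)

    # second pass: resolve id references to names
    model.classes = {
        cname: UMLClass(
            name=cls.name,
            package=cls.package,
            abstract=cls.abstract,
            attributes=tuple(
                UMLAttribute(a.name, resolve(a.type_name), a.lower, a.upper)
                for a in cls.attributes
            ),
            generalizations=tuple(
                resolve(t) for c, t in pending_generals if c == cname
            ),
        )
        for cname, cls in model.classes.items()
    }
    model.associations = tuple(
        UMLAssociation(
            name=assoc.name,
            ends=tuple(  # type: ignore[arg-type]
                UMLAssociationEnd(e.role, resolve(e.type_name), e.lower, e.upper)
                for e in assoc.ends
            ),
        )
        for assoc in model.associations
    )
    if not model.packages.get(""):
        model.packages.pop("", None)
    return model


# ---------------------------------------------------------------------------
# OWL schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassDecl:
    iri: str


@dataclass(frozen=True)
class SubClassOf:
    sub: str
    sup: str


@dataclass(frozen=True)
class ObjectPropertyDecl:
    iri: str
    domain: str
    range: str


@dataclass(frozen=True)
class DatatypePropertyDecl:
    iri: str
    domain: str
    range: str


@dataclass(frozen=True)
class MaxCardinality:
    cls: str
    prop: str
    n: int


@dataclass(frozen=True)
class MinCardinality:
    cls: str
    prop: str
    n: int


Axiom = (
    ClassDecl
    | SubClassOf
    | ObjectPropertyDecl
    | DatatypePropertyDecl
    | MaxCardinality
    | MinCardinality
)


@dataclass
class OntologySchema:
    """An OWL axiom set with a name->IRI map."""

    axioms: frozenset[Axiom] = frozenset()
    iri_map: dict[str, str] = field(default_factory=dict)

    def classes(self) -> set[str]:
        return {a.iri for a in self.axioms if isinstance(a, ClassDecl)}

    def subclass_pairs(self) -> set[tuple[str, str]]:
        return {
            (a.sub, a.sup) for a in self.axioms if isinstance(a, SubClassOf)
        }

    def __len__(self) -> int:
        return len(self.axioms)

    def to_rdf(self, namespaces: dict[str, str] | None = None) -> RDFGraph:
        """Render the axiom set as an RDF graph (restrictions get skolem IRIs)."""
        g = RDFGraph(namespaces)
        a = IRI(RDF_TYPE)
        sub = IRI(RDFS_NS + "subClassOf")
        restr_count = 0
        for ax in sorted(self.axioms, key=repr):
            if isinstance(ax, ClassDecl):
                g.add(IRI(ax.iri), a, IRI(OWL_NS + "Class"))
            elif isinstance(ax, SubClassOf):
                g.add(IRI(ax.sub), sub, IRI(ax.sup))
            elif isinstance(ax, ObjectPropertyDecl):
                g.add(IRI(ax.iri), a, IRI(OWL_NS + "ObjectProperty"))
                g.add(IRI(ax.iri), IRI(RDFS_NS + "domain"), IRI(ax.domain))
                g.add(IRI(ax.iri), IRI(RDFS_NS + "range"), IRI(ax.range))
            elif isinstance(ax, DatatypePropertyDecl):
                g.add(IRI(ax.iri), a, IRI(OWL_NS + "DatatypeProperty"))
                g.add(IRI(ax.iri), IRI(RDFS_NS + "domain"), IRI(ax.domain))
                g.add(IRI(ax.iri), IRI(RDFS_NS + "range"), IRI(ax.range))
            else:
                node = IRI(f"{ax.cls}/restriction/{restr_count}")
                restr_count += 1
                g.add(node, a, IRI(OWL_NS + "Restriction"))
                g.add(node, IRI(OWL_NS + "onProperty"), IRI(ax.prop))
                pred = (
                    "maxCardinality"
                    if isinstance(ax, MaxCardinality)
                    else "minCardinality"
                )
                g.add(
                    node,
                    IRI(OWL_NS + pred),
                    Literal(str(ax.n), XSD + "nonNegativeInteger"),
                )
                g.add(IRI(ax.cls), sub, node)
        return g


def uml_to_owl(model: UMLModel, base_iri: str) -> OntologySchema:
    """Convert a UML model to an OWL schema by the fixed mapping rules.

    Class -> owl:Class; generalization -> subclass axiom; primitive-typed
    attribute -> datatype property; class-typed attribute and association
    end -> object property; upper multiplicity 1 -> max-cardinality-1 on
    the owner, lower >= 1 -> min-cardinality.  Deterministic and total on
    valid models: #class axioms == #UML classes, #subclass axioms ==
    #generalizations.
    """
    problems = model.validate()
    if problems:
        raise ConversionError("; ".join(problems))
    base = base_iri.rstrip("#/")
    iri_map: dict[str, str] = {}
    axioms: set[Axiom] = set()

    def class_iri(name: str) -> str:
        iri = f"{base}#{name}"
        iri_map.setdefault(name, iri)
        return iri

    for cls in model.classes.values():
        axioms.add(ClassDecl(class_iri(cls.name)))
    for cls in model.classes.values():
        for parent in cls.generalizations:
            axioms.add(SubClassOf(class_iri(cls.name), class_iri(parent)))
        for attr in cls.attributes:
            prop_iri = f"{base}#{cls.name}.{attr.name}"
            if attr.type_name in model.classes:
                axioms.add(
                    ObjectPropertyDecl(
                        prop_iri, class_iri(cls.name), class_iri(attr.type_name)
                    )
                )
            elif attr.type_name in PRIMITIVE_TO_XSD:
                axioms.add(
                    DatatypePropertyDecl(
                        prop_iri,
                        class_iri(cls.name),
                        PRIMITIVE_TO_XSD[attr.type_name],
                    )
                )
            elif attr.type_name in model.primitives:
                warnings.warn(
                    f"unknown primitive {attr.type_name!r} mapped to "
                    "xsd:string",
                    stacklevel=2,
                )
                axioms.add(
                    DatatypePropertyDecl(
                        prop_iri, class_iri(cls.name), XSD + "string"
                    )
                )
            else:
                raise ConversionError(
                    f"attribute {cls.name}.{attr.name}: unresolvable "
                    f"type {attr.type_name!r}"
                )
            iri_map.setdefault(f"{cls.name}.{attr.name}", prop_iri)
            if attr.upper == 1:
                axioms.add(MaxCardinality(class_iri(cls.name), prop_iri, 1))
            if attr.lower >= 1:
                axioms.add(
                    MinCardinality(class_iri(cls.name), prop_iri, attr.lower)
                )
    def add_assoc_property(
        prop_name: str, owner: UMLAssociationEnd, target: UMLAssociationEnd
    ) -> None:
        prop_iri = f"{base}#{prop_name}"
        axioms.add(
            ObjectPropertyDecl(
                prop_iri, class_iri(owner.type_name), class_iri(target.type_name)
            )
        )
        iri_map.setdefault(prop_name, prop_iri)
        if target.upper == 1:
            axioms.add(MaxCardinality(class_iri(owner.type_name), prop_iri, 1))
        if target.lower >= 1:
            axioms.add(
                MinCardinality(class_iri(owner.type_name), prop_iri, target.lower)
            )

    for assoc in model.associations:
        e1, e2 = assoc.ends
        if e1.role or e2.role:
            # a named end yields a property navigable from the opposite class
            if e2.role:
                add_assoc_property(e2.role, e1, e2)
            if e1.role:
                add_assoc_property(e1.role, e2, e1)
        else:
            add_assoc_property(f"{e1.type_name}_{e2.type_name}".lower(), e1, e2)
    return OntologySchema(axioms=frozenset(axioms), iri_map=iri_map)
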