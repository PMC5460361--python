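"""Mini-archetype pattern instances: recursive ITEM_GROUP/ELEMENT trees.

Two reusable patterns are built per clinical domain:

* **Pattern 1 (asserted)** mirrors the data dictionary: the domain is an
  ITEM_GROUP whose children are one ELEMENT per dictionary variable, in
  document order, each bound to its annotating CDE.
* **Pattern 2 (post-coordinated)** dissects the same CDEs into their
  registry metadata: domain ITEM_GROUP → one ITEM_GROUP per distinct
  object class → one ITEM_GROUP per distinct (object class, property) →
  one ELEMENT per distinct (object class, property, value domain) path.
  Value-domain leaves dedupe only within their property group, so the same
  value domain may legitimately recur under different properties.  Sibling
  order is order of first appearance in Pattern 1 order.

Trees are emitted as RDF instances of the harmonized schema (ITEM_GROUP /
ELEMENT classes) with explicit child-order indices, and can be parsed back.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

from .model import ClinicalDomain, ConceptRef, Registry, dedup_key
from .rdf import IRI, Literal, MDRS, RDFGraph, RDF_TYPE, XSD
from .uml2owl import OntologySchema

__all__ = [
    "ArchetypeNode",
    "StructureError",
    "build_pattern1",
    "build_pattern2",
    "archetype_to_rdf",
    "archetype_from_rdf",
]


class StructureError(ValueError):
    """A CDE lacks a component required by the pattern."""


@dataclass(frozen=True)
class ArchetypeNode:
    """One node of an ITEM_GROUP/ELEMENT instance tree.

    An ELEMENT is a leaf (no recursion); an ITEM_GROUP holds an ordered
    list of children.  ``bindings`` lists the public ids of the CDEs the
    node captures; ``unbound`` marks a dictionary variable whose CDE
    reference did not resolve.
    """

    kind: str  # "ITEM_GROUP" | "ELEMENT"
    label: str
    children: tuple["ArchetypeNode", ...] = ()
    bindings: tuple[str, ...] = ()
    concepts: tuple[ConceptRef, ...] = ()
    variant: str = "asserted"  # "asserted" | "postcoordinated"
    unbound: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("ITEM_GROUP", "ELEMENT"):
            raise ValueError(f"bad node kind {self.kind!r}")
        if self.kind == "ELEMENT" and self.children:
            raise ValueError("an ELEMENT is a leaf and carries no children")

    def leaves(self) -> list["ArchetypeNode"]:
        if self.kind == "ELEMENT":
            return [self]
        out: list[ArchetypeNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def normalized(self) -> "ArchetypeNode":
        """Copy with bindings/concepts sorted (graph emission does not keep
        their order, so round-trip comparisons use the normalized form)."""
        return replace(
            self,
            bindings=tuple(sorted(self.bindings)),
            concepts=tuple(sorted(self.concepts, key=lambda c: (c.code, c.source))),
            children=tuple(c.normalized() for c in self.children),
        )

    def to_json(self) -> str:
        def conv(node: ArchetypeNode) -> dict:
            d = {
                "kind": node.kind,
                "label": node.label,
                "variant": node.variant,
                "bindings": list(node.bindings),
                "concepts": [
                    {"code": c.code, "source": c.source} for c in node.concepts
                ],
            }
            if node.unbound:
                d["unbound"] = True
            if node.kind == "ITEM_GROUP":
                d["children"] = [conv(c) for c in node.children]
            return d

        return json.dumps(conv(self), indent=2)


def build_pattern1(domain: ClinicalDomain, registry: Registry) -> ArchetypeNode:
    """Asserted pattern: root ITEM_GROUP labelled with the domain name, one
    ELEMENT per dictionary variable in document order, bound to its CDE.
    Unresolved references yield unbound, flagged ELEMENTs."""
    known = {de.public_id: de for de in registry.data_elements}
    children = []
    for var in domain.variables:
        de = known.get(var.cde_ref) if var.cde_ref else None
        children.append(
            ArchetypeNode(
                kind="ELEMENT",
                label=var.variable_name,
                bindings=(de.public_id,) if de else (),
                variant="asserted",
                unbound=de is None,
            )
        )
    return ArchetypeNode(
        kind="ITEM_GROUP",
        label=domain.name,
        children=tuple(children),
        variant="asserted",
    )


def build_pattern2(domain: ClinicalDomain, registry: Registry) -> ArchetypeNode:
    """Post-coordinated pattern: group the domain's resolved CDEs by object
    class, then property, then value domain (all by dedup key), preserving
    first-appearance order; each leaf binds all contributing CDEs and each
    level carries its component's concept annotations."""
    known = {de.public_id: de for de in registry.data_elements}
    resolved = []
    seen_ids: set[str] = set()
    for var in domain.variables:
        if var.cde_ref and var.cde_ref in known and var.cde_ref not in seen_ids:
            resolved.append(known[var.cde_ref])
            seen_ids.add(var.cde_ref)
    for de in resolved:
        if not (de.object_class and de.property and de.value_domain):
            raise StructureError(
                f"CDE {de.public_id} is missing a metadata component"
            )

    # nested first-appearance-ordered grouping: oc key -> prop key -> vd key
    oc_order: dict[str, dict] = {}
    for de in resolved:
        oc_k = dedup_key(de.object_class)
        oc_bucket = oc_order.setdefault(
            oc_k, {"component": de.object_class, "props": {}, "bindings": []}
        )
        oc_bucket["bindings"].append(de.public_id)
        pr_k = dedup_key(de.property)
        pr_bucket = oc_bucket["props"].setdefault(
            pr_k, {"component": de.property, "vds": {}, "bindings": []}
        )
        pr_bucket["bindings"].append(de.public_id)
        vd_k = dedup_key(de.value_domain)
        vd_bucket = pr_bucket["vds"].setdefault(
            vd_k, {"component": de.value_domain, "bindings": []}
        )
        vd_bucket["bindings"].append(de.public_id)

    oc_nodes = []
    for oc_bucket in oc_order.values():
        prop_nodes = []
        for pr_bucket in oc_bucket["props"].values():
            vd_nodes = [
                ArchetypeNode(
                    kind="ELEMENT",
                    label=vd_bucket["component"].name,
                    bindings=tuple(vd_bucket["bindings"]),
                    variant="postcoordinated",
                )
                for vd_bucket in pr_bucket["vds"].values()
            ]
            prop_nodes.append(
                ArchetypeNode(
                    kind="ITEM_GROUP",
                    label=pr_bucket["component"].name,
                    children=tuple(vd_nodes),
                    bindings=tuple(pr_bucket["bindings"]),
                    concepts=tuple(pr_bucket["component"].concepts),
                    variant="postcoordinated",
                )
            )
        oc_nodes.append(
            ArchetypeNode(
                kind="ITEM_GROUP",
                label=oc_bucket["component"].name,
                children=tuple(prop_nodes),
                bindings=tuple(oc_bucket["bindings"]),
                concepts=tuple(oc_bucket["component"].concepts),
                variant="postcoordinated",
            )
        )
    return ArchetypeNode(
        kind="ITEM_GROUP",
        label=domain.name,
        children=tuple(oc_nodes),
        variant="postcoordinated",
    )


# ---------------------------------------------------------------------------
# RDF instance emission / parsing
# ---------------------------------------------------------------------------

def _require_classes(schema: OntologySchema) -> dict[str, str]:
    classes = {iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]: iri
               for iri in schema.classes()}
    missing = [k for k in ("ITEM_GROUP", "ELEMENT") if k not in classes]
    if missing:
        raise ValueError(
            f"schema lacks required classes: {', '.join(missing)}"
        )
    return classes


def archetype_to_rdf(
    node: ArchetypeNode,
    schema: OntologySchema,
    base_iri: str = "http://purl.example.org/cdemdr/instance",
) -> RDFGraph:
    """Emit one archetype tree as typed instances of the schema's
    ITEM_GROUP/ELEMENT classes, with child links carrying order indices,
    CDE bindings and concept annotations."""
    classes = _require_classes(schema)
    base = base_iri.rstrip("/")
    g = RDFGraph()
    a = IRI(RDF_TYPE)
    counter = [0]

    def emit(n: ArchetypeNode) -> IRI:
        iri = IRI(f"{base}/node/{counter[0]}")
        counter[0] += 1
        g.add(iri, a, IRI(classes[n.kind]))
        g.add(iri, IRI(MDRS + "label"), Literal(n.label))
        g.add(iri, IRI(MDRS + "variant"), Literal(n.variant))
        if n.unbound:
            g.add(iri, IRI(MDRS + "unbound"), Literal("true", XSD + "boolean"))
        for pid in n.bindings:
            g.add(iri, IRI(MDRS + "binds"), Literal(pid))
        for ref in n.concepts:
            g.add(iri, IRI(MDRS + "conceptCode"), Literal(ref.code))
        for idx, child in enumerate(n.children):
            child_iri = emit(child)
            g.add(iri, IRI(MDRS + "item"), child_iri)
            g.add(
                child_iri,
                IRI(MDRS + "index"),
                Literal(str(idx), XSD + "integer"),
            )
        return iri

    root_iri = emit(node)
    g.add(root_iri, a, IRI(MDRS + "ArchetypeRoot"))
    return g


def archetype_from_rdf(graph: RDFGraph, schema: OntologySchema) -> ArchetypeNode:
    """Rebuild the archetype tree from an emitted instance graph (inverse of
    :func:`archetype_to_rdf` up to structural equality)."""
    classes = _require_classes(schema)
    kind_of: dict[IRI, str] = {}
    for kind in ("ITEM_GROUP", "ELEMENT"):
        for s in graph.subjects_of_type(IRI(classes[kind])):
            kind_of[s] = kind
    roots = graph.subjects_of_type(IRI(MDRS + "ArchetypeRoot"))
    if len(roots) != 1:
        raise ValueError(f"expected exactly 1 archetype root, got {len(roots)}")
    (root,) = roots

    def rebuild(iri: IRI) -> ArchetypeNode:
        label = str(next(iter(graph.objects(iri, IRI(MDRS + "label"))), ""))
        variant = str(
            next(iter(graph.objects(iri, IRI(MDRS + "variant"))), "asserted")
        )
        unbound = any(
            str(o) == "true" for o in graph.objects(iri, IRI(MDRS + "unbound"))
        )
        bindings = tuple(
            sorted(str(o) for o in graph.objects(iri, IRI(MDRS + "binds")))
        )
        concepts = tuple(
            ConceptRef(str(o))
            for o in graph.objects(iri, IRI(MDRS + "conceptCode"))
        )
        children_with_idx = []
        for child in graph.objects(iri, IRI(MDRS + "item")):
            idx = int(
                str(next(iter(graph.objects(child, IRI(MDRS + "index"))), "0"))
            )
            children_with_idx.append((idx, child))
        children = tuple(
            rebuild(c) for _, c in sorted(children_with_idx, key=lambda t: t[0])
        )
        return ArchetypeNode(
            kind=kind_of[iri],
            label=label,
            children=children,
            bindings=bindings,
            concepts=concepts,
            variant=variant,
            unbound=unbound,
        )

    return rebuild(root)
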