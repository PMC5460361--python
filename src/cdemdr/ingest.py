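"""Readers for the CDE-registry and data-dictionary XML dialect, a link
checker, and a deterministic synthetic fixture generator.

The XML dialect (element names ``DataElement``, ``PublicId``, ``LongName``,
``ObjectClass``, ``Property``, ``ValueDomain``, ``PermissibleValue``,
``ConceptCode``, ``WorkflowStatus``; dictionary side ``Domain``,
``Variable``, ``CDERef``) is artifact-defined and documented in the shipped
XSD (``data/cde_dialect.xsd``).  Records with workflow status ``RETIRED``
are excluded at ingest, mirroring the registry-download convention of
keeping only non-retired production elements.
"""

from __future__ import annotations

import json
import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

from .model import (
    ClinicalDomain,
    ConceptRef,
    DataElement,
    DomainVariable,
    ObjectClass,
    PermissibleValue,
    PropertyDef,
    Registry,
    ValueDomain,
    build_registry,
    dedup_key,
)

__all__ = [
    "IngestError",
    "IngestReport",
    "IngestResult",
    "LinkReport",
    "FixtureConfig",
    "FixturePaths",
    "read_cde_registry",
    "load_cde_registry",
    "read_data_dictionary",
    "link_dictionary",
    "generate_fixture",
]


class IngestError(ValueError):
    """Malformed input file."""


@dataclass
class IngestReport:
    n_loaded: int = 0
    n_retired_excluded: int = 0
    record_errors: list[str] = field(default_factory=list)


@dataclass
class IngestResult:
    registry: Registry
    report: IngestReport


@dataclass
class LinkReport:
    """Per-domain resolution of dictionary CDE references."""

    per_domain: dict[str, dict[str, int]] = field(default_factory=dict)
    dangling: list[tuple[str, str, str]] = field(default_factory=list)
    unannotated: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_dangling(self) -> int:
        return len(self.dangling)


def _text(elem: ET.Element, tag: str, default: str | None = None) -> str | None:
    child = elem.find(tag)
    if child is None or child.text is None:
        return default
    return child.text.strip()


def _parse_component(elem: ET.Element) -> tuple[str, str | None, tuple[ConceptRef, ...]]:
    name = _text(elem, "Name", "")
    public_id = _text(elem, "PublicId")
    concepts = tuple(
        ConceptRef(code=c.text.strip(), source=c.get("source", "NCIt"))
        for c in elem.findall("ConceptCode")
        if c.text and c.text.strip()
    )
    return name or "", public_id, concepts


def _parse_data_element(elem: ET.Element) -> DataElement:
    public_id = _text(elem, "PublicId")
    long_name = _text(elem, "LongName")
    if not public_id:
        raise IngestError("record missing PublicId")
    if not long_name:
        raise IngestError(f"record {public_id!r} missing LongName")

    oc_elem = elem.find("ObjectClass")
    prop_elem = elem.find("Property")
    vd_elem = elem.find("ValueDomain")
    if oc_elem is None or prop_elem is None or vd_elem is None:
        raise IngestError(
            f"record {public_id!r} missing ObjectClass/Property/ValueDomain"
        )
    oc_name, oc_id, oc_concepts = _parse_component(oc_elem)
    pr_name, pr_id, pr_concepts = _parse_component(prop_elem)
    vd_name = _text(vd_elem, "Name", "") or ""
    vd_id = _text(vd_elem, "PublicId")
    pvs = []
    for pv in vd_elem.findall("PermissibleValue"):
        code = pv.find("ConceptCode")
        concept = None
        if code is not None and code.text and code.text.strip():
            concept = ConceptRef(code.text.strip(), code.get("source", "NCIt"))
        pvs.append(
            PermissibleValue(
                value=_text(pv, "Value", "") or "",
                meaning=_text(pv, "Meaning", "") or "",
                concept=concept,
            )
        )
    return DataElement(
        public_id=public_id,
        version=_text(elem, "Version", "1.0") or "1.0",
        long_name=long_name,
        preferred_name=_text(elem, "PreferredName"),
        definition=_text(elem, "Definition", "") or "",
        workflow_status=_text(elem, "WorkflowStatus", "RELEASED") or "RELEASED",
        object_class=ObjectClass(oc_name, oc_id, oc_concepts),
        property=PropertyDef(pr_name, pr_id, pr_concepts),
        value_domain=ValueDomain(
            name=vd_name,
            public_id=vd_id,
            datatype=_text(vd_elem, "Datatype", "string") or "string",
            permissible_values=tuple(pvs),
        ),
    )


def _parse_xml_file(path) -> ET.Element:
    try:
        return ET.parse(path).getroot()
    except ET.ParseError as exc:
        line, col = exc.position
        raise IngestError(
            f"{path}: malformed XML at line {line}, column {col}: {exc.msg}"
        ) from exc


def load_cde_registry(path) -> IngestResult:
    """Read a CDE-registry XML file; RETIRED records are excluded and
    counted, records missing required fields are collected as errors and
    skipped."""
    root = _parse_xml_file(path)
    report = IngestReport()
    elements: list[DataElement] = []
    for record in root.findall("DataElement"):
        try:
            de = _parse_data_element(record)
        except IngestError as exc:
            report.record_errors.append(str(exc))
            continue
        if de.workflow_status.upper() == "RETIRED":
            report.n_retired_excluded += 1
            continue
        elements.append(de)
    report.n_loaded = len(elements)
    return IngestResult(registry=build_registry(elements), report=report)


def read_cde_registry(path) -> Registry:
    return load_cde_registry(path).registry


def read_data_dictionary(path) -> list[ClinicalDomain]:
    """Read a data-dictionary XML file into ordered clinical domains.

    Variables keep document order (0-based positions); unannotated
    variables (no ``CDERef``) are retained with ``cde_ref=None``.
    """
    root = _parse_xml_file(path)
    domains: list[ClinicalDomain] = []
    for d in root.findall("Domain"):
        name = d.get("name", "")
        variables = []
        for pos, v in enumerate(d.findall("Variable")):
            variables.append(
                DomainVariable(
                    variable_name=_text(v, "Name", "") or "",
                    cde_ref=_text(v, "CDERef"),
                    position=pos,
                )
            )
        domains.append(ClinicalDomain(name=name, variables=tuple(variables)))
    return domains


def link_dictionary(
    domains: list[ClinicalDomain] | tuple[ClinicalDomain, ...],
    registry: Registry,
) -> LinkReport:
    """Resolve every dictionary CDE reference against the registry.

    Report-only: dangling references and unannotated variables are listed,
    nothing is dropped.
    """
    known = {de.public_id for de in registry.data_elements}
    report = LinkReport()
    for domain in domains:
        resolved = unresolved = 0
        for var in domain.variables:
            if var.cde_ref is None:
                report.unannotated.append((domain.name, var.variable_name))
            elif var.cde_ref in known:
                resolved += 1
            else:
                unresolved += 1
                report.dangling.append(
                    (domain.name, var.variable_name, var.cde_ref)
                )
        report.per_domain[domain.name] = {
            "resolved": resolved,
            "unresolved": unresolved,
            "unannotated": sum(
                1 for v in domain.variables if v.cde_ref is None
            ),
        }
    return report


# ---------------------------------------------------------------------------
# Synthetic fixture generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic registry/dictionary world.

    Defaults are sized like a single-study slice of a production registry:
    a handful of domains of 10-25 variables each, drawing on a component
    pool small enough that object classes are shared across data elements
    (which is what makes enrichment non-trivial).
    """

    n_domains: int = 5
    n_cdes_per_domain: tuple[int, int] = (10, 25)
    n_object_classes: int = 12
    props_per_class: tuple[int, int] = (2, 6)
    enumerated_fraction: float = 0.4
    retired_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 0 or self.n_object_classes < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.enumerated_fraction <= 1.0:
            raise ValueError("enumerated_fraction must be in [0, 1]")
        if not 0.0 <= self.retired_fraction <= 1.0:
            raise ValueError("retired_fraction must be in [0, 1]")
        for lo, hi in (self.n_cdes_per_domain, self.props_per_class):
            if lo < 0 or hi < lo:
                raise ValueError("count ranges must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class FixturePaths:
    cde_xml: Path
    dict_xml: Path
    manifest_json: Path


_ADJ = [
    "Primary", "Secondary", "Baseline", "Followup", "Adjuvant", "Initial",
    "Prior", "Current", "Reported", "Derived",
]
_NOUN = [
    "Specimen", "Tumor", "Therapy", "Agent", "Lesion", "Biopsy", "Marker",
    "Regimen", "Outcome", "Procedure",
]
_PROP = [
    "Begin Occurrence", "End Occurrence", "Continue Occurrence", "Count",
    "Status", "Type", "Grade", "Measurement", "Identifier", "Description",
]
_VD = [
    "Event Year Number", "Event Month Number", "Event Day Number",
    "Yes No Character Indicator", "Text Name", "Integer Count",
    "Code Identifier", "Decimal Measurement",
]


def _indent(elem: ET.Element, level: int = 0) -> None:
    pad = "\n" + "  " * level
    if len(elem):
        if not elem.text or not elem.text.strip():
            elem.text = pad + "  "
        for child in elem:
            _indent(child, level + 1)
            child.tail = pad + "  "
        elem[-1].tail = pad
    if level == 0:
        elem.tail = "\n"


def _write_xml(root: ET.Element, path: Path) -> None:
    _indent(root)
    data = ET.tostring(root, encoding="unicode")
    path.write_text('<?xml version="1.0" encoding="UTF-8"?>\n' + data, "utf-8")


def generate_fixture(config: FixtureConfig, out_dir) -> FixturePaths:
    """Generate a registry + dictionary XML pair and a manifest of true
    counts (the oracle for round-trip tests).  Byte-identical for the same
    config (seed included)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)

    # component pools
    oc_names = []
    while len(oc_names) < config.n_object_classes:
        name = f"{rng.choice(_ADJ)} {rng.choice(_NOUN)}"
        if name not in oc_names:
            oc_names.append(name)
    oc_pool = [
        ObjectClass(
            name=name,
            public_id=f"OC{2000 + i}" if rng.random() < 0.5 else None,
            concepts=(ConceptRef(f"C{rng.randrange(1000, 99999)}"),),
        )
        for i, name in enumerate(oc_names)
    ]
    props_for_oc: dict[int, list[PropertyDef]] = {}
    for i in range(len(oc_pool)):
        k = rng.randint(*config.props_per_class)
        chosen = rng.sample(_PROP, min(k, len(_PROP)))
        props_for_oc[i] = [
            PropertyDef(
                name=p,
                concepts=(
                    ConceptRef(
                        f"C{rng.randrange(1000, 99999)}:C{rng.randrange(1000, 99999)}"
                    )
                    if rng.random() < 0.3
                    else ConceptRef(f"C{rng.randrange(1000, 99999)}")
                ,),
            )
            for p in chosen
        ]
    vd_pool = []
    for i, name in enumerate(_VD):
        enumerated = rng.random() < config.enumerated_fraction
        pvs = (
            tuple(
                PermissibleValue(value=v, meaning=m)
                for v, m in (("YES", "Yes"), ("NO", "No"))
            )
            if enumerated
            else ()
        )
        vd_pool.append(
            ValueDomain(
                name=name,
                public_id=f"VD{3000 + i}",
                datatype="string" if enumerated else "number",
                permissible_values=pvs,
            )
        )

    # data elements per domain
    domains: list[ClinicalDomain] = []
    all_elements: list[DataElement] = []
    retired_ids: list[str] = []
    next_id = 10000
    for d in range(config.n_domains):
        n_vars = rng.randint(*config.n_cdes_per_domain)
        variables = []
        for pos in range(n_vars):
            oc_idx = rng.randrange(len(oc_pool))
            oc = oc_pool[oc_idx]
            prop = rng.choice(props_for_oc[oc_idx])
            vd = rng.choice(vd_pool)
            public_id = str(next_id)
            next_id += 1
            retired = rng.random() < config.retired_fraction
            de = DataElement(
                public_id=public_id,
                version="1.0",
                long_name=f"{oc.name} {prop.name} {vd.name} {public_id}",
                definition=f"Synthetic data element {public_id}.",
                workflow_status="RETIRED" if retired else "RELEASED",
                object_class=oc,
                property=prop,
                value_domain=vd,
            )
            all_elements.append(de)
            if retired:
                retired_ids.append(public_id)
            variables.append(
                DomainVariable(
                    variable_name=f"Domain {d} Variable {pos}",
                    cde_ref=public_id if not retired else None,
                    position=pos,
                )
            )
        domains.append(
            ClinicalDomain(name=f"synthetic domain {d}", variables=tuple(variables))
        )

    cde_path = out / "cde_registry.xml"
    dict_path = out / "data_dictionary.xml"
    manifest_path = out / "manifest.json"
    _write_registry_xml(all_elements, cde_path)
    _write_dictionary_xml(domains, dict_path)

    live = [de for de in all_elements if de.workflow_status != "RETIRED"]
    manifest = {
        "seed": config.seed,
        "n_domains": len(domains),
        "n_cde_records": len(all_elements),
        "n_retired": len(retired_ids),
        "n_live_cdes": len(live),
        "n_distinct_object_classes": len({dedup_key(d.object_class) for d in live}),
        "n_distinct_properties": len({dedup_key(d.property) for d in live}),
        "n_distinct_value_domains": len({dedup_key(d.value_domain) for d in live}),
        "n_distinct_enumerated_value_domains": len(
            {
                dedup_key(d.value_domain)
                for d in live
                if d.value_domain.kind == "enumerated"
            }
        ),
        "variables_per_domain": {
            d.name: len(d.variables) for d in domains
        },
        "distinct_cdes_per_domain": {
            d.name: len({v.cde_ref for v in d.variables if v.cde_ref})
            for d in domains
        },
    }
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", "utf-8"
    )
    return FixturePaths(cde_path, dict_path, manifest_path)


def _component_xml(parent: ET.Element, tag: str, name, public_id, concepts) -> None:
    e = ET.SubElement(parent, tag)
    ET.SubElement(e, "Name").text = name
    if public_id:
        ET.SubElement(e, "PublicId").text = public_id
    for ref in concepts:
        c = ET.SubElement(e, "ConceptCode")
        c.text = ref.code
        if ref.source != "NCIt":
            c.set("source", ref.source)


def _write_registry_xml(elements: list[DataElement], path: Path) -> None:
    root = ET.Element("CDERegistry")
    for de in elements:
        rec = ET.SubElement(root, "DataElement")
        ET.SubElement(rec, "PublicId").text = de.public_id
        ET.SubElement(rec, "Version").text = de.version
        ET.SubElement(rec, "LongName").text = de.long_name
        if de.preferred_name:
            ET.SubElement(rec, "PreferredName").text = de.preferred_name
        if de.definition:
            ET.SubElement(rec, "Definition").text = de.definition
        ET.SubElement(rec, "WorkflowStatus").text = de.workflow_status
        _component_xml(
            rec, "ObjectClass", de.object_class.name,
            de.object_class.public_id, de.object_class.concepts,
        )
        _component_xml(
            rec, "Property", de.property.name,
            de.property.public_id, de.property.concepts,
        )
        vd = ET.SubElement(rec, "ValueDomain")
        ET.SubElement(vd, "Name").text = de.value_domain.name
        if de.value_domain.public_id:
            ET.SubElement(vd, "PublicId").text = de.value_domain.public_id
        ET.SubElement(vd, "Datatype").text = de.value_domain.datatype
        for pv in de.value_domain.permissible_values:
            pve = ET.SubElement(vd, "PermissibleValue")
            ET.SubElement(pve, "Value").text = pv.value
            if pv.meaning:
                ET.SubElement(pve, "Meaning").text = pv.meaning
            if pv.concept is not None:
                c = ET.SubElement(pve, "ConceptCode")
                c.text = pv.concept.code
                if pv.concept.source != "NCIt":
                    c.set("source", pv.concept.source)
    _write_xml(root, path)


def _write_dictionary_xml(
    domains: list[ClinicalDomain] | tuple[ClinicalDomain, ...], path: Path
) -> None:
    root = ET.Element("DataDictionary")
    for domain in domains:
        d = ET.SubElement(root, "Domain", name=domain.name)
        for var in domain.variables:
            v = ET.SubElement(d, "Variable")
            ET.SubElement(v, "Name").text = var.variable_name
            if var.cde_ref is not None:
                ET.SubElement(v, "CDERef").text = var.cde_ref
    _write_xml(root, path)
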