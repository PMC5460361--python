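"""Domain analytics: object-class enrichment and template alignment.

*Enrichment* asks: given the data elements a dictionary asserts for a
clinical domain, what else does the registry know about the same object
classes?  All registry elements sharing an asserted object class form the
*global* pool; the pool minus the asserted set is the *enrichment* — extra
properties and value domains a modeler could draw on.

*Alignment* classifies the rows of an external data-collection template
(e.g. a medication template) against the domain: a row whose mapped element
resolves into the dictionary-asserted CDE set is ``asserted``; failing
that, into the enrichment set is ``enriched``; otherwise ``unmatched``.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field

from .model import ClinicalDomain, DataElement, Registry, dedup_key

__all__ = [
    "EnrichmentReport",
    "AlignmentRow",
    "AlignmentSpec",
    "RowClassification",
    "AlignmentResult",
    "enrich_domain",
    "align_template",
    "suggest_mappings",
    "read_alignment_spec",
]

_WS = re.compile(r"\s+")


def _norm(name: str) -> str:
    return _WS.sub(" ", name.strip()).lower()


@dataclass
class EnrichmentCounts:
    data_elements: int = 0
    object_classes: int = 0
    properties: int = 0
    value_domains: int = 0
    enumerated_value_domains: int = 0
    #: value-domain count including enumerated ones (the inclusive convention)
    value_domains_inclusive: int = 0


@dataclass
class EnrichmentReport:
    domain: str
    asserted: EnrichmentCounts
    global_: EnrichmentCounts
    enriched: EnrichmentCounts
    asserted_elements: tuple[DataElement, ...] = ()
    enriched_elements: tuple[DataElement, ...] = ()
    warnings: list[str] = field(default_factory=list)

    def enriched_names(self) -> set[str]:
        return {_norm(de.long_name) for de in self.enriched_elements}

    def to_dict(self) -> dict:
        def counts(c: EnrichmentCounts) -> dict:
            return {
                "data_elements": c.data_elements,
                "object_classes": c.object_classes,
                "properties": c.properties,
                "value_domains": c.value_domains,
                "enumerated_value_domains": c.enumerated_value_domains,
                "value_domains_inclusive": c.value_domains_inclusive,
            }

        return {
            "domain": self.domain,
            "asserted": counts(self.asserted),
            "global": counts(self.global_),
            "enriched": counts(self.enriched),
            "enriched_element_names": sorted(
                de.long_name for de in self.enriched_elements
            ),
            "warnings": list(self.warnings),
        }


def _count(elements) -> EnrichmentCounts:
    elements = list(elements)
    vds = {dedup_key(de.value_domain) for de in elements}
    enum_vds = {
        dedup_key(de.value_domain)
        for de in elements
        if de.value_domain.kind == "enumerated"
    }
    return EnrichmentCounts(
        data_elements=len(elements),
        object_classes=len({dedup_key(de.object_class) for de in elements}),
        properties=len({dedup_key(de.property) for de in elements}),
        value_domains=len(vds - enum_vds),
        enumerated_value_domains=len(enum_vds),
        value_domains_inclusive=len(vds),
    )


def enrich_domain(domain: ClinicalDomain, registry: Registry) -> EnrichmentReport:
    """Compute the object-class enrichment report for one domain.

    The asserted set is the domain's resolved CDEs; the global set is every
    registry element whose object-class dedup key occurs in the asserted
    set; enrichment is the per-category set difference.
    """
    known = {de.public_id: de for de in registry.data_elements}
    asserted = []
    seen_ids: set[str] = set()
    for var in domain.variables:
        if var.cde_ref and var.cde_ref in known and var.cde_ref not in seen_ids:
            asserted.append(known[var.cde_ref])
            seen_ids.add(var.cde_ref)
    warnings = []
    if not asserted:
        warnings.append(
            f"domain {domain.name!r} has no resolved CDEs; report is empty"
        )
    oc_keys = {dedup_key(de.object_class) for de in asserted}
    global_elements = [
        de
        for de in registry.data_elements
        if dedup_key(de.object_class) in oc_keys
    ]
    asserted_idset = {de.identity for de in asserted}
    enriched_elements = [
        de for de in global_elements if de.identity not in asserted_idset
    ]
    return EnrichmentReport(
        domain=domain.name,
        asserted=_count(asserted),
        global_=_count(global_elements),
        enriched=_count_delta(asserted, global_elements, enriched_elements),
        asserted_elements=tuple(asserted),
        enriched_elements=tuple(enriched_elements),
        warnings=warnings,
    )


def _count_delta(asserted, global_elements, enriched_elements) -> EnrichmentCounts:
    """Per-category |global set \\ asserted set| (deltas, not differences of
    counts — a property seen in both sets is not 'enriched')."""
    def keys(elements, getter):
        return {dedup_key(getter(de)) for de in elements}

    a_oc = keys(asserted, lambda d: d.object_class)
    g_oc = keys(global_elements, lambda d: d.object_class)
    a_pr = keys(asserted, lambda d: d.property)
    g_pr = keys(global_elements, lambda d: d.property)
    a_vd = keys(asserted, lambda d: d.value_domain)
    g_vd = keys(global_elements, lambda d: d.value_domain)
    a_evd = {
        dedup_key(d.value_domain)
        for d in asserted
        if d.value_domain.kind == "enumerated"
    }
    g_evd = {
        dedup_key(d.value_domain)
        for d in global_elements
        if d.value_domain.kind == "enumerated"
    }
    return EnrichmentCounts(
        data_elements=len(enriched_elements),
        object_classes=len(g_oc - a_oc),
        properties=len(g_pr - a_pr),
        value_domains=len((g_vd - g_evd) - (a_vd - a_evd)),
        enumerated_value_domains=len(g_evd - a_evd),
        value_domains_inclusive=len(g_vd - a_vd),
    )


# ---------------------------------------------------------------------------
# Template alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRow:
    question_text: str
    prompt: str
    mapped_names: tuple[str, ...] = ()


@dataclass
class AlignmentSpec:
    rows: tuple[AlignmentRow, ...]

    def __post_init__(self) -> None:
        prompts = [r.prompt for r in self.rows]
        if len(prompts) != len(set(prompts)):
            dupes = sorted({p for p in prompts if prompts.count(p) > 1})
            raise ValueError(f"duplicate prompts in alignment spec: {dupes}")


@dataclass
class RowClassification:
    prompt: str
    category: str  # asserted | enriched | unmatched
    matched_names: tuple[str, ...] = ()
    unknown_names: tuple[str, ...] = ()


@dataclass
class AlignmentResult:
    classifications: tuple[RowClassification, ...]

    @property
    def total(self) -> int:
        return len(self.classifications)

    def count(self, category: str) -> int:
        return sum(1 for c in self.classifications if c.category == category)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "asserted": self.count("asserted"),
            "enriched": self.count("enriched"),
            "unmatched": self.count("unmatched"),
            "total": self.total,
        }

    def unmatched_prompts(self) -> list[str]:
        return [
            c.prompt for c in self.classifications if c.category == "unmatched"
        ]

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "rows": [
                {
                    "prompt": c.prompt,
                    "category": c.category,
                    "matched_names": list(c.matched_names),
                    "unknown_names": list(c.unknown_names),
                }
                for c in self.classifications
            ],
        }


def _asserted_name_set(
    domain: ClinicalDomain, report: EnrichmentReport
) -> set[str]:
    # A template row may name an asserted element either by its dictionary
    # variable name (the name the domain publishes) or by the underlying
    # registry long name; both resolve into the asserted set.
    names = {_norm(de.long_name) for de in report.asserted_elements}
    resolved_ids = {de.public_id for de in report.asserted_elements}
    for var in domain.variables:
        if var.cde_ref in resolved_ids:
            names.add(_norm(var.variable_name))
    return names


def align_template(
    spec: AlignmentSpec, domain: ClinicalDomain, report: EnrichmentReport
) -> AlignmentResult:
    """Classify each template row as asserted / enriched / unmatched.

    Resolution is case-insensitive exact match on normalized names;
    asserted takes precedence over enriched when a row matches both.  A
    mapped name resolving to no known element is recorded separately from
    an empty mapping, but both leave the row unmatched.
    """
    if report.domain != domain.name:
        raise ValueError(
            f"enrichment report is for domain {report.domain!r}, "
            f"not {domain.name!r}"
        )
    asserted_names = _asserted_name_set(domain, report)
    enriched_names = report.enriched_names()
    out = []
    for row in spec.rows:
        hits_asserted, hits_enriched, unknown = [], [], []
        for name in row.mapped_names:
            key = _norm(name)
            if key in asserted_names:
                hits_asserted.append(name)
            elif key in enriched_names:
                hits_enriched.append(name)
            else:
                unknown.append(name)
        if hits_asserted:
            cat, matched = "asserted", hits_asserted
        elif hits_enriched:
            cat, matched = "enriched", hits_enriched
        else:
            cat, matched = "unmatched", []
        out.append(
            RowClassification(
                prompt=row.prompt,
                category=cat,
                matched_names=tuple(matched),
                unknown_names=tuple(unknown),
            )
        )
    return AlignmentResult(classifications=tuple(out))


# ---------------------------------------------------------------------------
# Advisory mapping suggestions
# ---------------------------------------------------------------------------

def _tokens(name: str) -> frozenset[str]:
    return frozenset(re.findall(r"[a-z0-9]+", name.lower()))


def suggest_mappings(
    prompts: list[str], candidate_names: list[str], top_k: int = 5
) -> dict[str, list[tuple[str, float]]]:
    """Rank candidate element names per prompt by token Jaccard overlap.

    Purely advisory (the authoritative alignment is curated by hand);
    scores are |token intersection| / |token union| in [0, 1], ties broken
    lexicographically.
    """
    out: dict[str, list[tuple[str, float]]] = {}
    for prompt in prompts:
        pt = _tokens(prompt)
        scored = []
        for cand in candidate_names:
            ct = _tokens(cand)
            union = pt | ct
            score = len(pt & ct) / len(union) if union else 0.0
            scored.append((cand, score))
        scored.sort(key=lambda x: (-x[1], x[0]))
        out[prompt] = scored[:top_k]
    return out


def read_alignment_spec(path_or_text, delimiter: str = "\t") -> AlignmentSpec:
    """Read an alignment spec from TSV/CSV text or file.

    Columns: ``question_text``, ``prompt``, ``mapped_names``
    (semicolon-separated, may be empty).
    """
    text = str(path_or_text)
    if "\n" not in text and "\t" not in text:
        with open(path_or_text, encoding="utf-8") as fh:
            text = fh.read()
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    required = {"question_text", "prompt", "mapped_names"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ValueError(
            f"alignment spec must have columns {sorted(required)}"
        )
    rows = []
    for rec in reader:
        mapped = tuple(
            n.strip() for n in (rec["mapped_names"] or "").split(";") if n.strip()
        )
        rows.append(
            AlignmentRow(
                question_text=rec["question_text"],
                prompt=rec["prompt"],
                mapped_names=mapped,
            )
        )
    return AlignmentSpec(rows=tuple(rows))
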