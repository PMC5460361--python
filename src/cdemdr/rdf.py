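"""Minimal RDF layer: triples, Turtle/N-Triples I/O, XML lifting, BGP query.

The graph model is deliberately small: a set of (subject, predicate, object)
triples over IRIs and typed literals, with a prefix map.  Blank nodes are
never produced — every anonymous node gets a skolem IRI — so graphs are
diffable and distinct-counting is well defined.

Two routes produce graphs:

* :func:`lift_xml` — a generic, schema-agnostic XML-to-RDF lifting with a
  documented deterministic convention (one resource per element, one triple
  per attribute and non-whitespace text node, child links with order
  indices).
* :func:`registry_to_rdf` — a typed mapping of a CDE registry and data
  dictionary onto the ISO 11179 schema classes, with shared components
  (same dedup key) mapped to the same IRI.

Querying is restricted to conjunctive basic graph patterns with DISTINCT
semantics, which is all that domain retrieval needs.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from urllib.parse import quote

from .model import (
    ClinicalDomain,
    DataElement,
    Registry,
    dedup_key,
)

__all__ = [
    "IRI",
    "Literal",
    "Var",
    "RDFGraph",
    "QueryError",
    "RDF_TYPE",
    "XSD",
    "MMS",
    "MDRS",
    "lift_xml",
    "registry_to_rdf",
    "query_graph",
    "parse_sparql_bgp",
]

XSD = "http://www.w3.org/2001/XMLSchema#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
OWL_NS = "http://www.w3.org/2002/07/owl#"
#: ISO 11179 subset schema namespace (metadata model schema, prefix "mms").
MMS = "http://rdf.cdisc.org/mms#"
#: Artifact vocabulary for dictionary/domain structure and archetype instances.
MDRS = "http://purl.example.org/cdemdr/schema#"

RDF_TYPE = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"


@dataclass(frozen=True)
class IRI:
    value: str

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Literal:
    lexical: str
    datatype: str | None = None

    def __str__(self) -> str:
        return self.lexical


@dataclass(frozen=True)
class Var:
    """A query variable in a basic graph pattern."""

    name: str


Term = IRI | Literal
Triple = tuple[IRI, IRI, Term]

_DEFAULT_NAMESPACES = {
    "rdf": RDF_NS,
    "rdfs": RDFS_NS,
    "owl": OWL_NS,
    "xsd": XSD,
    "mms": MMS,
    "mdrs": MDRS,
}


class QueryError(ValueError):
    """Malformed basic graph pattern or query text."""


class RDFGraph:
    """A set of triples with a prefix map (no blank nodes)."""

    def __init__(self, namespaces: dict[str, str] | None = None):
        self.triples: set[Triple] = set()
        self.namespaces: dict[str, str] = dict(_DEFAULT_NAMESPACES)
        if namespaces:
            self.namespaces.update(namespaces)

    def bind(self, prefix: str, iri: str) -> None:
        self.namespaces[prefix] = iri

    def add(self, s: IRI, p: IRI, o: Term) -> None:
        if not isinstance(s, IRI) or not isinstance(p, IRI):
            raise TypeError("subject and predicate must be IRIs")
        if not isinstance(o, (IRI, Literal)):
            raise TypeError("object must be an IRI or Literal")
        self.triples.add((s, p, o))

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, triple: Triple) -> bool:
        return triple in self.triples

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RDFGraph) and self.triples == other.triples

    def subjects_of_type(self, cls: IRI) -> set[IRI]:
        t = IRI(RDF_TYPE)
        return {s for (s, p, o) in self.triples if p == t and o == cls}

    def objects(self, s: IRI, p: IRI) -> list[Term]:
        return sorted(
            (o for (s2, p2, o) in self.triples if s2 == s and p2 == p),
            key=_term_sort_key,
        )

    # -- serialization ----------------------------------------------------

    def _qname(self, iri: str) -> str | None:
        for prefix, ns in self.namespaces.items():
            if iri.startswith(ns):
                local = iri[len(ns):]
                if local and re.fullmatch(r"[A-Za-z_][\w.\-]*", local):
                    return f"{prefix}:{local}"
        return None

    def _term_ttl(self, term: Term) -> str:
        if isinstance(term, IRI):
            q = self._qname(term.value)
            return q if q else f"<{term.value}>"
        lex = _escape_literal(term.lexical)
        if term.datatype is None or term.datatype == XSD + "string":
            return f'"{lex}"'
        dq = self._qname(term.datatype)
        dt = dq if dq else f"<{term.datatype}>"
        return f'"{lex}"^^{dt}'

    def to_turtle(self) -> str:
        """Serialize to Turtle, one statement per line, deterministic order."""
        lines = [
            f"@prefix {p}: <{ns}> ."
            for p, ns in sorted(self.namespaces.items())
        ]
        lines.append("")
        for s, p, o in sorted(self.triples, key=_triple_sort_key):
            pred = "a" if p.value == RDF_TYPE else self._term_ttl(p)
            lines.append(f"{self._term_ttl(s)} {pred} {self._term_ttl(o)} .")
        return "\n".join(lines) + "\n"

    def to_ntriples(self) -> str:
        out = []
        for s, p, o in sorted(self.triples, key=_triple_sort_key):
            if isinstance(o, IRI):
                obj = f"<{o.value}>"
            elif o.datatype:
                obj = f'"{_escape_literal(o.lexical)}"^^<{o.datatype}>'
            else:
                obj = f'"{_escape_literal(o.lexical)}"'
            out.append(f"<{s.value}> <{p.value}> {obj} .")
        return "\n".join(out) + ("\n" if out else "")

    @classmethod
    def from_turtle(cls, text: str) -> "RDFGraph":
        """Parse the line-oriented Turtle subset emitted by :meth:`to_turtle`."""
        g = cls()
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@prefix"):
                m = re.match(r"@prefix\s+([\w\-]*):\s*<([^>]*)>\s*\.", line)
                if not m:
                    raise QueryError(f"line {lineno}: bad @prefix: {raw!r}")
                g.namespaces[m.group(1)] = m.group(2)
                continue
            terms = _tokenize_statement(line, lineno)
            if len(terms) != 3:
                raise QueryError(
                    f"line {lineno}: expected 3 terms, got {len(terms)}"
                )
            s, p, o = (_resolve_token(t, g.namespaces, lineno) for t in terms)
            if isinstance(s, Literal) or isinstance(p, Literal):
                raise QueryError(f"line {lineno}: literal in subject/predicate")
            g.add(s, p, o)
        return g

    @classmethod
    def from_ntriples(cls, text: str) -> "RDFGraph":
        return cls.from_turtle(text)


def _escape_literal(s: str) -> str:
    return (
        s.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


def _unescape_literal(s: str) -> str:
    out, i = [], 0
    while i < len(s):
        c = s[i]
        if c == "\\" and i + 1 < len(s):
            nxt = s[i + 1]
            out.append({"n": "\n", "r": "\r", "t": "\t", '"': '"', "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


_TOKEN = re.compile(
    r"""
    "(?:[^"\\]|\\.)*"(?:\^\^(?:<[^>]*>|[\w\-]*:[\w.\-]+))?   # literal
    | <[^>]*>                                                 # IRI
    | \?[\w]+                                                 # variable
    | [\w\-]*:[\w.\-]*                                        # prefixed name
    | \ba\b                                                   # rdf:type kw
    """,
    re.VERBOSE,
)


def _tokenize_statement(line: str, lineno: int) -> list[str]:
    body = line.rstrip()
    if body.endswith("."):
        body = body[:-1].rstrip()
    tokens = [m.group(0) for m in _TOKEN.finditer(body)]
    if not tokens:
        raise QueryError(f"line {lineno}: cannot tokenize {line!r}")
    return tokens


def _resolve_token(
    tok: str, namespaces: dict[str, str], lineno: int, allow_vars: bool = False
) -> Term | Var:
    if tok == "a":
        return IRI(RDF_TYPE)
    if tok.startswith("<"):
        return IRI(tok[1:-1])
    if tok.startswith("?"):
        if not allow_vars:
            raise QueryError(f"line {lineno}: variable {tok!r} not allowed here")
        return Var(tok[1:])
    if tok.startswith('"'):
        m = re.match(r'^"((?:[^"\\]|\\.)*)"(?:\^\^(.+))?$', tok)
        lex = _unescape_literal(m.group(1))
        dt = m.group(2)
        if dt is None:
            return Literal(lex)
        if dt.startswith("<"):
            return Literal(lex, dt[1:-1])
        prefix, _, local = dt.partition(":")
        if prefix not in namespaces:
            raise QueryError(f"line {lineno}: unbound prefix {prefix!r}")
        return Literal(lex, namespaces[prefix] + local)
    prefix, _, local = tok.partition(":")
    if prefix not in namespaces:
        raise QueryError(f"line {lineno}: unbound prefix {prefix!r}")
    return IRI(namespaces[prefix] + local)


def _term_sort_key(t: Term) -> tuple[int, str, str]:
    if isinstance(t, IRI):
        return (0, t.value, "")
    return (1, t.lexical, t.datatype or "")


def _triple_sort_key(tr: Triple):
    return (_term_sort_key(tr[0]), _term_sort_key(tr[1]), _term_sort_key(tr[2]))


# ---------------------------------------------------------------------------
# Generic XML -> RDF lifting
# ---------------------------------------------------------------------------

def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def lift_xml(doc: str | ET.Element, base_iri: str) -> RDFGraph:
    """Lift an XML document into RDF with a fixed deterministic convention.

    Per element node: one skolem resource ``{base}/node/{i}`` (document
    preorder) typed ``{base}/vocab/{tag}``.  Per attribute: one triple with
    predicate ``{base}/vocab/{attname}`` and a plain-literal object.  Per
    non-whitespace text node: one ``{base}/vocab/text`` triple.  Per
    parent-child element edge: a ``child`` link plus an ``index`` literal on
    the child (0-based document order).

    Triple count is therefore E + A + T + 2*C for E elements, A attributes,
    T non-whitespace text nodes and C parent-child edges.
    """
    if isinstance(doc, str):
        try:
            root = ET.fromstring(doc)
        except ET.ParseError as exc:
            raise ValueError(f"malformed XML: {exc}") from exc
    else:
        root = doc
    base = base_iri.rstrip("/")
    g = RDFGraph({"lift": base + "/vocab/"})
    vocab = base + "/vocab/"
    counter = [0]

    def visit(elem: ET.Element) -> IRI:
        node = IRI(f"{base}/node/{counter[0]}")
        counter[0] += 1
        g.add(node, IRI(RDF_TYPE), IRI(vocab + _localname(elem.tag)))
        for name, value in elem.attrib.items():
            g.add(node, IRI(vocab + _localname(name)), Literal(value))
        if elem.text and elem.text.strip():
            g.add(node, IRI(vocab + "text"), Literal(elem.text.strip()))
        for idx, child in enumerate(elem):
            child_node = visit(child)
            g.add(node, IRI(vocab + "child"), child_node)
            g.add(
                child_node,
                IRI(vocab + "index"),
                Literal(str(idx), XSD + "integer"),
            )
            if child.tail and child.tail.strip():
                g.add(node, IRI(vocab + "text"), Literal(child.tail.strip()))
        return node

    visit(root)
    return g


# ---------------------------------------------------------------------------
# Typed ISO 11179 mapping
# ---------------------------------------------------------------------------

def _enc(key: str) -> str:
    return quote(key, safe="")


def registry_to_rdf(
    registry: Registry,
    domains: list[ClinicalDomain] | tuple[ClinicalDomain, ...] = (),
    base_iri: str = "http://purl.example.org/cdemdr",
) -> RDFGraph:
    """Map a registry (and optional dictionary domains) onto the ISO schema.

    Every data element, object class, property, value domain, permissible
    value and domain becomes one typed resource.  Components sharing a dedup
    key share an IRI, so distinct-counting over the graph matches the
    registry's component counting.  Concept codes become annotation triples.
    """
    base = base_iri.rstrip("/")
    g = RDFGraph()
    a = IRI(RDF_TYPE)

    def component_iri(kind: str, key: str) -> IRI:
        return IRI(f"{base}/{kind}/{_enc(key)}")

    def annotate(node: IRI, concepts) -> None:
        for ref in concepts:
            g.add(node, IRI(MMS + "conceptCode"), Literal(ref.code))
            if ref.source != "NCIt":
                g.add(node, IRI(MMS + "conceptSource"), Literal(ref.source))

    de_iris: dict[str, IRI] = {}
    for de in registry.data_elements:
        de_iri = IRI(f"{base}/de/{_enc(de.public_id)}-v{_enc(de.version)}")
        de_iris[de.public_id] = de_iri
        g.add(de_iri, a, IRI(MMS + "DataElement"))
        g.add(de_iri, IRI(MMS + "publicId"), Literal(de.public_id))
        g.add(de_iri, IRI(MMS + "version"), Literal(de.version))
        g.add(de_iri, IRI(MMS + "longName"), Literal(de.long_name))
        if de.definition:
            g.add(de_iri, IRI(MMS + "definition"), Literal(de.definition))
        g.add(de_iri, IRI(MMS + "workflowStatus"), Literal(de.workflow_status))

        oc = component_iri("oc", dedup_key(de.object_class))
        g.add(oc, a, IRI(MMS + "ObjectClass"))
        g.add(oc, IRI(MMS + "name"), Literal(de.object_class.name))
        annotate(oc, de.object_class.concepts)
        g.add(de_iri, IRI(MMS + "objectClass"), oc)

        prop = component_iri("prop", dedup_key(de.property))
        g.add(prop, a, IRI(MMS + "Property"))
        g.add(prop, IRI(MMS + "name"), Literal(de.property.name))
        annotate(prop, de.property.concepts)
        g.add(de_iri, IRI(MMS + "property"), prop)

        vd = component_iri("vd", dedup_key(de.value_domain))
        g.add(vd, a, IRI(MMS + "ValueDomain"))
        g.add(vd, IRI(MMS + "name"), Literal(de.value_domain.name))
        g.add(vd, IRI(MMS + "datatype"), Literal(de.value_domain.datatype))
        g.add(de_iri, IRI(MMS + "valueDomain"), vd)
        for i, pv in enumerate(de.value_domain.permissible_values):
            pv_iri = IRI(f"{vd.value}/pv/{i}")
            g.add(pv_iri, a, IRI(MMS + "PermissibleValue"))
            g.add(pv_iri, IRI(MMS + "value"), Literal(pv.value))
            if pv.meaning:
                g.add(pv_iri, IRI(MMS + "meaning"), Literal(pv.meaning))
            if pv.concept is not None:
                annotate(pv_iri, [pv.concept])
            g.add(vd, IRI(MMS + "permissibleValue"), pv_iri)

    for domain in domains:
        d_iri = IRI(f"{base}/domain/{_enc(domain.name)}")
        g.add(d_iri, a, IRI(MDRS + "ClinicalDomain"))
        g.add(d_iri, IRI(MDRS + "hasName"), Literal(domain.name))
        for var in domain.variables:
            v_iri = IRI(f"{d_iri.value}/var/{var.position}")
            g.add(v_iri, a, IRI(MDRS + "Variable"))
            g.add(v_iri, IRI(MDRS + "variableName"), Literal(var.variable_name))
            g.add(
                v_iri,
                IRI(MDRS + "position"),
                Literal(str(var.position), XSD + "integer"),
            )
            g.add(d_iri, IRI(MDRS + "hasVariable"), v_iri)
            if var.cde_ref is not None and var.cde_ref in de_iris:
                g.add(v_iri, IRI(MDRS + "annotatedBy"), de_iris[var.cde_ref])
    return g


# ---------------------------------------------------------------------------
# Basic graph pattern query
# ---------------------------------------------------------------------------

PatternTerm = Term | Var
Pattern = list[tuple[PatternTerm, PatternTerm, PatternTerm]]


def query_graph(graph: RDFGraph, pattern: Pattern) -> list[dict[str, Term]]:
    """Evaluate a conjunctive basic graph pattern with DISTINCT semantics.

    Returns all solutions as a list of variable->term dicts, duplicates
    removed, in deterministic (lexicographic by binding) order.
    """
    if not pattern:
        return []
    for tp in pattern:
        if len(tp) != 3:
            raise QueryError(f"pattern triple must have 3 terms: {tp!r}")

    solutions: list[dict[str, Term]] = [{}]
    for s_t, p_t, o_t in pattern:
        next_solutions: list[dict[str, Term]] = []
        for binding in solutions:
            for s, p, o in graph.triples:
                b = _match(binding, [(s_t, s), (p_t, p), (o_t, o)])
                if b is not None:
                    next_solutions.append(b)
        solutions = next_solutions
    names = sorted({v.name for tp in pattern for v in tp if isinstance(v, Var)})
    distinct = {
        tuple(sol[n] for n in names): sol for sol in solutions
    }
    ordered = sorted(
        distinct.values(),
        key=lambda sol: tuple(_term_sort_key(sol[n]) for n in names),
    )
    return [{n: sol[n] for n in names} for sol in ordered]


def _match(
    binding: dict[str, Term], pairs: list[tuple[PatternTerm, Term]]
) -> dict[str, Term] | None:
    out = dict(binding)
    for pat, actual in pairs:
        if isinstance(pat, Var):
            if pat.name in out:
                if out[pat.name] != actual:
                    return None
            else:
                out[pat.name] = actual
        elif pat != actual:
            return None
    return out


def parse_sparql_bgp(text: str, namespaces: dict[str, str] | None = None) -> Pattern:
    """Parse a restricted SPARQL SELECT into a basic graph pattern.

    Supported: ``PREFIX`` declarations, ``SELECT`` (projection is ignored —
    DISTINCT over all variables is always applied), a ``WHERE`` block of
    dot-separated triple patterns using IRIs, prefixed names, plain or typed
    literals and ``?var`` variables.  Nothing else (no OPTIONAL, FILTER or
    property paths).
    """
    ns = dict(_DEFAULT_NAMESPACES)
    if namespaces:
        ns.update(namespaces)
    for m in re.finditer(r"(?i)\bPREFIX\s+([\w\-]*):\s*<([^>]*)>", text):
        ns[m.group(1)] = m.group(2)
    m = re.search(r"\{(.*)\}", text, re.DOTALL)
    if not m:
        raise QueryError("no { ... } pattern block found")
    body = m.group(1)
    pattern: Pattern = []
    for lineno, stmt in enumerate(re.split(r"[.;]\s*(?=\n|$)|\.\s+", body), 1):
        stmt = stmt.strip().rstrip(".")
        if not stmt:
            continue
        toks = [t.group(0) for t in _TOKEN.finditer(stmt)]
        if len(toks) != 3:
            raise QueryError(f"pattern statement {stmt!r}: expected 3 terms")
        s, p, o = (
            _resolve_token(t, ns, lineno, allow_vars=True) for t in toks
        )
        pattern.append((s, p, o))
    if not pattern:
        raise QueryError("empty pattern block")
    return pattern
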