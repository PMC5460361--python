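# Methods

## The metadata model

The unit of content is the ISO/IEC 11179 data element: an object class
plus a property give the *data element concept*, and a value domain gives
its representation.  Components may carry concept annotations from a
standard terminology (NCI Thesaurus in the packaged material); a
post-coordinated annotation is a colon-joined sequence of atomic codes
(`C25431:C25275`), and the parser enforces the `C<digits>` atom pattern
only when the source is NCIt.

**Distinctness.** Registries report *distinct* object classes, properties
and value domains, but the counting key is rarely stated.  Here the key is
the component's public registry identifier when present, otherwise its
lowercase, whitespace-collapsed display name.  The key is idempotent on
name-derived keys and invariant under case and spacing; all grouping
(registry index buckets, Pattern 2, enrichment, IRI minting) uses it, so
every count in the package is consistent with every other.

**Dictionary side.** A clinical domain is an ordered list of variables;
a variable may reference a CDE by public id or be unannotated.
Unannotated and dangling references are retained and flagged, never
dropped — Pattern 1 still renders them as unbound ELEMENTs, and the link
report lists them.

## RDF layer

No RDF library is a runtime dependency, so the package carries a small,
purpose-built layer: a graph is a *set* of (IRI, IRI, IRI-or-literal)
triples with a prefix map.  Blank nodes are never minted — anonymous
nodes get skolem IRIs — so graphs are diffable, serialization round-trips
are exact on the triple set, and distinct counting over a graph is well
defined.  Turtle output is one statement per line in deterministic sorted
order; the reader parses exactly that subset (plus N-Triples).

**Generic lifting convention** (artifact-defined, since generic XML→RDF
tools differ): per element one skolem resource typed by its tag name; per
attribute one literal triple; per non-whitespace text node one `text`
triple; per parent–child element edge a `child` link plus an `index`
literal (0-based document order).  The triple count is then exactly
`E + A + T + 2C`, which the property suite checks on random documents.
Because the graph is a set, two *identical* text chunks under one parent
collapse into one triple; the generator used by the tests therefore emits
unique chunks.

**Typed mapping.** The supported path into analytics is the typed ISO
11179 mapping: data elements get IRIs `{base}/de/{public_id}-v{version}`;
components get IRIs from their dedup key (percent-encoded), so shared
components share a resource and graph-level counting equals registry
counting.  Record order never changes the emitted triple set.

**Query.** Retrieval needs only conjunctive basic graph patterns with
DISTINCT semantics, so that is all `query_graph` implements (nested-loop
join, deduplicated, lexicographically ordered bindings; verified against
a brute-force join oracle).  A restricted SPARQL `SELECT` text form is
parsed for convenience; OPTIONAL/FILTER/paths are out of scope.

## UML → OWL and harmonization

The XMI parser supports a documented minimal 2.x dialect (packages,
classes, attributes with multiplicities, binary associations,
generalizations); anything else raises an unsupported-dialect error
rather than guessing.  Conversion follows the classic ODM-style table:

| UML | OWL |
|---|---|
| class | `owl:Class` |
| generalization | `rdfs:subClassOf` |
| attribute of primitive type | datatype property (fixed primitive→XSD table; unknown declared primitives map to `xsd:string` with a warning) |
| attribute of class type, association end | object property with domain/range |
| upper multiplicity 1 | max-cardinality-1 restriction on the owner |
| lower multiplicity ≥ 1 | min-cardinality restriction |

Unnamed association ends yield a single `{classa}_{classb}` lowercase
property — the model is silent, and determinism matters more than taste.
Two count identities hold by construction and are property-tested:
`#class axioms == #UML classes` and `#subclass axioms ==
#generalizations` (the subclass graph is isomorphic to the generalization
graph).

The packaged reference-model fixture is a hand-built reconstruction of
the recursive clinical-content pattern — an abstract ITEM under a
LOCATABLE root, ITEM_GROUP as the ordered grouping variant, ELEMENT as
the recursion-free leaf — plus data-value, primitive and party packages.
It is synthetic: structurally faithful to the published class diagram
subset, not a copy of any released model file.

**Harmonization** adds, for every reference-model class `C`, the single
axiom `C ⊑ mms:AdministeredItem` on top of the union of both axiom sets —
nothing else.  This is applied to *all* classes, including datatype-like
ones, which is ontologically debatable but matches the stated
harmonization rule; fidelity wins.  Classes already in the `mms`
namespace are skipped, which is what makes `harmonize ∘ harmonize =
harmonize`; with disjoint inputs the count identity
`|out| = |cimi| + |iso| + #cimi classes` holds exactly.  The embedded ISO
schema is the data-description subset only (AdministeredItem at the top;
DataElement, ObjectClass, Property, ValueDomain administered beneath it;
PermissibleValue deliberately not administered).

## Archetype patterns

Pattern 1 is the dictionary view: domain ITEM_GROUP, one ELEMENT per
variable in document order, each bound to its CDE.  Pattern 2 dissects
the same CDEs: object-class groups, property groups within them,
value-domain ELEMENTs within those.  Three choices matter:

- **Sibling order is first appearance in Pattern 1 order**, not
  alphabetical: the published pattern keeps start before end before
  ongoing, and ITEM_GROUP is defined as an *ordered* list.
- **Value-domain leaves dedupe only within their property group**: the
  same value domain (e.g. *Event Year Number*) legitimately recurs under
  both the begin and end properties, i.e. the distinctness key is the
  full (object class, property, value domain) path.
- **Unbound ELEMENTs count in Pattern 1 but are excluded from
  Pattern 2**, which only has meaning for resolved metadata.

Two invariants are property-tested: leaf conservation (every resolved
domain CDE is bound to exactly one Pattern 2 leaf) and monotone collapse
(`#P2 leaves ≤ #P1 leaves`, with equality iff all component paths are
distinct).  Instance emission types each node with the harmonized
schema's ITEM_GROUP/ELEMENT classes and keeps child order as index
literals; parsing the graph back rebuilds the tree up to the (unordered)
binding/concept sets.

## Analytics

Enrichment: the asserted set is the domain's resolved CDEs; the global
set is every registry element whose object-class key occurs in the
asserted set; the enriched set is the difference.  Reported counts are
per-category *set* deltas (`|global \ asserted|`), not differences of
counts — "37 more properties" style reporting.  Because the convention
for the value-domain bar of an enrichment chart is ambiguous, the report
exposes both: enumerated and non-enumerated separately, and the inclusive
total.

Alignment: a template row is `asserted` if any mapped name resolves into
the asserted set, else `enriched` if any resolves into the enriched set,
else `unmatched`.  Resolution is case-insensitive exact match on
normalized names; an asserted element can be named either by its
dictionary variable name (the name a domain publishes, e.g. *Therapy
Ongoing*) or by its registry long name — published alignment tables use
the former, so both resolve.  Asserted takes precedence over enriched for
rows matching both (deterministic, and mixed rows do not occur in the
source material).  A mapped name that resolves to nothing is flagged
separately from an empty mapping, but both leave the row unmatched.
`suggest_mappings` is a purely advisory token-Jaccard ranking; it never
feeds classification.

## Synthetic data

`generate_fixture` emulates a registry slice: a pool of object classes
each carrying a few properties, a shared value-domain pool (default 40%
enumerated), domains of 10–25 variables, and a 5% retired fraction —
sized so that object classes are shared across elements (otherwise
enrichment is trivially empty) while a desk-scale run stays under a
second.  Output is byte-identical for a given config; a manifest records
the true counts, which is the oracle for reader round-trip tests.  What
it does **not** emulate: real registry name collisions across versions,
terminology-aware annotations, or corpus-scale magnitudes — so a green
property suite establishes structural correctness of the pipeline, not
agreement with any production registry's totals (those depend on external
snapshots and are explicitly out of scope).

The packaged clinical-pharmaceutical fixture reconstructs the published
worked example: the seven drug-therapy CDEs
with their published component names and codes, the other fourteen
template-target elements, and the twenty-row medication template.  Public
ids are synthetic.  Object-class assignments for elements whose
decomposition is not printed were chosen once to be registry-plausible
and such that every enriched element shares an object class with an
asserted CDE (the precondition for enrichment to discover it); they were
not adjusted afterwards.  The full domain carries 14 variables — the
published 18-CDE domain is only partially reconstructible from printed
tables — and the drug-therapy *extract* (`clinpharm_table2_extract`) is
the published two-pattern example exactly.

## Numerical / procedural choices

- All randomness flows through explicit seeds (`random.Random(seed)`);
  there is no global-state dependence, and pipeline outputs are
  byte-deterministic for fixed inputs.
- Turtle/JSON outputs are sorted; manifests are `sort_keys=True`.
- Pipeline stages write atomically (temp file + rename), so a failed run
  never leaves a truncated bundle member.
- Degenerate inputs are defined, not errors: empty registry → empty
  graph; empty domain → zero-leaf patterns and a zero-count enrichment
  report with a warning; empty dictionary → empty bundle with a warning.

## Known limitations

- The XML dialect is artifact-defined (documented by the shipped XSD);
  production registry exports would need a thin adapter.
- The XSD documents the dialect but is not enforced at runtime (no XSD
  validator without heavier dependencies); readers validate structurally.
- The query surface is conjunctive BGPs only; the Turtle reader handles
  the package's own line-oriented output subset, not arbitrary Turtle.
- No DL reasoning or shape validation over the emitted OWL/RDF; the
  harmonized hierarchy is checked by graph traversal only.
- Alignment matching is exact (normalized); semantic matching via
  terminology hierarchies is out of scope.
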