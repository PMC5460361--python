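# cdemdr

A semantic-web metadata-repository toolkit for clinical-study **common data
elements (CDEs)**, aimed at clinical research informaticists who curate
ISO 11179-style metadata registries and build detailed clinical models from
them.

## What it does

Cancer genome studies collect clinical data against dictionaries of CDEs.
Each CDE decomposes, per ISO/IEC 11179, into an **object class** (what is
described, e.g. *Pharmacologic Substance*), a **property** (the aspect,
e.g. *Begin Occurrence*, possibly post-coordinated from NCI Thesaurus codes
such as `C25431:C25275`) and a **value domain** (the representation, e.g.
*Event Month Number*; enumerated domains carry permissible values).
A data dictionary groups a preferred set of CDEs into clinical study
domains such as *clinical pharmaceutical*.

The package wires this metadata into a semantic-web pipeline:

1. **Ingest** — readers for a documented CDE-registry and data-dictionary
   XML dialect (XSD shipped in `src/cdemdr/data/`); retired records are
   excluded at ingest; a seeded synthetic fixture generator supplies test
   worlds with a manifest of true counts.
2. **RDF lifting** — a generic XML→RDF lifting with a fixed deterministic
   convention, plus a typed ISO 11179 mapping of registry content where
   components sharing a distinctness key share one IRI.  Conjunctive
   basic-graph-pattern queries (DISTINCT semantics) retrieve, e.g., all
   CDEs of a domain.
3. **UML→OWL** — an XMI parser and ODM-style converter (class → OWL class,
   generalization → subclass, attribute/association → property,
   multiplicity → cardinality restriction) applied to the recursive
   ITEM / ITEM_GROUP / ELEMENT pattern of a CIMI-style clinical reference
   model, then **harmonized** with the ISO 11179 schema by asserting every
   reference-model class under `mms:AdministeredItem`.
4. **Archetype patterns** — per domain, two mini-archetype instance trees:
   *Pattern 1* (asserted) mirrors the dictionary as one ELEMENT per
   variable under a domain ITEM_GROUP; *Pattern 2* (post-coordinated)
   dissects the same CDEs into object-class → property → value-domain
   groups, the dissection style used for reusable terminologies.
5. **Analytics** — object-class **enrichment** (all registry elements
   sharing a domain's object classes, minus the asserted set) and
   **template alignment**, classifying the rows of an external
   data-collection template (e.g. a CDASH-style medication template) as
   `asserted`, `enriched` or `unmatched`.

## Worked example

The packaged `clinical pharmaceutical` fixture reconstructs the drug-therapy
worked example: seven start/end/ongoing CDEs sharing the object class
*Pharmacologic Substance*, seven further dictionary-asserted medication
CDEs, fourteen enriched registry CDEs and a twenty-row medication template.

```python
from cdemdr import (build_pattern1, build_pattern2, enrich_domain,
                    align_template, load_clinpharm_fixture)
from cdemdr.clinpharm import clinpharm_table2_extract

fx = load_clinpharm_fixture()
extract = clinpharm_table2_extract()          # the 7 drug-therapy variables

p1 = build_pattern1(extract, fx.registry)
print(len(p1.leaves()))                        # 7

p2 = build_pattern2(extract, fx.registry)
(oc,) = p2.children
print(oc.label)                                # Pharmacologic Substance
print([g.label for g in oc.children])          # ['Begin Occurrence', 'End Occurrence', 'Continue Occurrence']
print(len({l.label for l in oc.leaves()}))     # 4

report = enrich_domain(fx.domain, fx.registry)
result = align_template(fx.alignment_spec, fx.domain, report)
print(result.counts)                           # {'asserted': 9, 'enriched': 10, 'unmatched': 1, 'total': 20}
```

The Pattern 1 tree has 7 ELEMENT leaves (the asserted drug-therapy
variables).  Pattern 2 collapses them under one object-class group with 3
property groups and 4 distinct value domains.  Of the 20 template rows, 9
align with dictionary-asserted CDEs, 10 with enriched elements discovered
through shared object classes, and 1 has no counterpart.

## Command line

```sh
mdr fixture clinpharm --out fx/            # export the packaged fixture as XML/TSV
mdr run --config config.yaml               # full pipeline -> Turtle graphs + JSON reports
mdr archetype build --cde fx/cde_registry.xml --dict fx/data_dictionary.xml \
    --domain "clinical pharmaceutical" --pattern 2
mdr analyze align --cde fx/cde_registry.xml --dict fx/data_dictionary.xml \
    --domain "clinical pharmaceutical" --spec fx/alignment_spec.tsv
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the worked example end to end — Pattern 1/Pattern 2 construction on
the drug-therapy extract and enrichment + template alignment on the full
domain — and writes the four summary quantities (Pattern 1 leaf count,
distinct value domains under the object-class group, asserted and enriched
row counts) as JSON.

See `docs/methods.md` for the model, design choices and limitations.
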