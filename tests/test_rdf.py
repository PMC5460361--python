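import random

import pytest

from cdemdr.ingest import FixtureConfig, generate_fixture, read_cde_registry
from cdemdr.rdf import (
    IRI,
    Literal,
    MDRS,
    MMS,
    QueryError,
    RDFGraph,
    RDF_TYPE,
    Var,
    XSD,
    lift_xml,
    parse_sparql_bgp,
    query_graph,
    registry_to_rdf,
)

BASE = "http://example.org/b"


def random_xml(rng: random.Random) -> tuple[str, int]:
    """Build a random XML tree and return (text, expected triple count)."""
    counts = {"E": 0, "A": 0, "T": 0, "C": 0}

    def node(depth: int) -> str:
        counts["E"] += 1
        n_attrs = rng.randint(0, 3)
        counts["A"] += n_attrs
        attrs = " ".join(f'a{i}="v{rng.randint(0, 9)}"' for i in range(n_attrs))
        tag = f"t{rng.randint(0, 5)}"
        parts = [f"<{tag} {attrs}>" if attrs else f"<{tag}>"]
        # text chunks carry a global counter so no two triples collide in
        # the set-based graph (identical chunks under one parent collapse)
        if rng.random() < 0.4:
            counts["T"] += 1
            parts.append(f"text{counts['T']}")
        if depth < 3:
            for _ in range(rng.randint(0, 3)):
                counts["C"] += 1
                parts.append(node(depth + 1))
                if rng.random() < 0.3:
                    counts["T"] += 1
                    parts.append(f"tail{counts['T']}")
        parts.append(f"</{tag}>")
        return "".join(parts)

    text = node(0)
    expected = counts["E"] + counts["A"] + counts["T"] + 2 * counts["C"]
    return text, expected


class TestLiftXml:
    def test_single_empty_element_one_type_triple(self):
        g = lift_xml("<a/>", BASE)
        assert len(g) == 1
        assert (IRI(f"{BASE}/node/0"), IRI(RDF_TYPE), IRI(f"{BASE}/vocab/a")) in g

    def test_two_attributes_three_triples(self):
        assert len(lift_xml('<a x="1" y="2"/>', BASE)) == 3

    def test_child_indices_in_document_order(self):
        g = lift_xml("<a><b/><c/></a>", BASE)
        idx = IRI(f"{BASE}/vocab/index")
        assert g.objects(IRI(f"{BASE}/node/1"), idx) == [
            Literal("0", XSD + "integer")
        ]
        assert g.objects(IRI(f"{BASE}/node/2"), idx) == [
            Literal("1", XSD + "integer")
        ]

    def test_malformed_xml(self):
        with pytest.raises(ValueError, match="malformed"):
            lift_xml("<a><b></a>", BASE)

    @pytest.mark.parametrize("seed", range(20))
    def test_triple_count_formula_on_random_trees(self, seed):
        """len(graph) == E + A + T + 2C, counted independently while the
        random document is being generated."""
        text, expected = random_xml(random.Random(seed))
        assert len(lift_xml(text, BASE)) == expected


class TestRegistryToRdf:
    def test_shared_object_class_single_resource(self, clinpharm):
        drug = [de for de in clinpharm.registry.data_elements
                if de.public_id.startswith("1000")]
        from cdemdr.model import build_registry
        g = registry_to_rdf(build_registry(drug[:7]), [], BASE)
        assert len(g.subjects_of_type(IRI(MMS + "ObjectClass"))) == 1

    def test_empty_registry(self):
        from cdemdr.model import build_registry
        g = registry_to_rdf(build_registry([]), [], BASE)
        assert len(g) == 0

    def test_data_element_count_matches_manifest(self, tmp_path):
        import json
        paths = generate_fixture(FixtureConfig(seed=2), tmp_path)
        manifest = json.loads(paths.manifest_json.read_text())
        registry = read_cde_registry(paths.cde_xml)
        g = registry_to_rdf(registry, [], BASE)
        assert len(g.subjects_of_type(IRI(MMS + "DataElement"))) == (
            manifest["n_live_cdes"]
        )

    def test_iri_stability_under_record_permutation(self, clinpharm):
        from cdemdr.model import build_registry
        elements = list(clinpharm.registry.data_elements)
        g1 = registry_to_rdf(build_registry(elements), clinpharm.domains, BASE)
        rng = random.Random(0)
        shuffled = elements[:]
        rng.shuffle(shuffled)
        g2 = registry_to_rdf(build_registry(shuffled), clinpharm.domains, BASE)
        assert g1 == g2


class TestSerialization:
    @pytest.mark.parametrize("seed", range(5))
    def test_turtle_roundtrip_random_graphs(self, seed):
        text, _ = random_xml(random.Random(seed))
        g = lift_xml(text, BASE)
        assert RDFGraph.from_turtle(g.to_turtle()).triples == g.triples

    def test_turtle_roundtrip_clinpharm(self, clinpharm):
        g = registry_to_rdf(clinpharm.registry, clinpharm.domains, BASE)
        assert RDFGraph.from_turtle(g.to_turtle()).triples == g.triples

    def test_ntriples_roundtrip(self, clinpharm):
        g = registry_to_rdf(clinpharm.registry, clinpharm.domains, BASE)
        assert RDFGraph.from_ntriples(g.to_ntriples()).triples == g.triples

    def test_literal_escaping(self):
        g = RDFGraph()
        g.add(IRI("http://x/s"), IRI("http://x/p"),
              Literal('tricky "quote"\nand\ttab\\'))
        assert RDFGraph.from_turtle(g.to_turtle()).triples == g.triples


def brute_force_join(graph, pattern):
    """Nested-loop join oracle: enumerate every triple combination."""
    import itertools

    names = sorted({v.name for tp in pattern for v in tp if isinstance(v, Var)})
    solutions = set()
    for combo in itertools.product(graph.triples, repeat=len(pattern)):
        binding = {}
        ok = True
        for (ps, pp, po), (s, p, o) in zip(pattern, combo):
            for pat, actual in ((ps, s), (pp, p), (po, o)):
                if isinstance(pat, Var):
                    if binding.get(pat.name, actual) != actual:
                        ok = False
                        break
                    binding[pat.name] = actual
                elif pat != actual:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            solutions.add(tuple(binding[n] for n in names))
    return solutions


class TestQueryGraph:
    def test_domain_retrieval_includes_fig4_cde(self, clinpharm):
        g = registry_to_rdf(clinpharm.registry, clinpharm.domains, BASE)
        pattern = [
            (Var("d"), IRI(MDRS + "hasName"), Literal("clinical pharmaceutical")),
            (Var("d"), IRI(MDRS + "hasVariable"), Var("v")),
            (Var("v"), IRI(MDRS + "annotatedBy"), Var("cde")),
            (Var("cde"), IRI(MMS + "longName"), Var("name")),
        ]
        names = {str(sol["name"]) for sol in query_graph(g, pattern)}
        assert "Pharmacologic Substance Begin Occurrence Month Number" in names

    def test_no_match_empty_table(self, clinpharm):
        g = registry_to_rdf(clinpharm.registry, clinpharm.domains, BASE)
        pattern = [(Var("d"), IRI(MDRS + "hasName"), Literal("no such domain"))]
        assert query_graph(g, pattern) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_equivalent_to_nested_loop_oracle(self, seed):
        rng = random.Random(seed)
        g = RDFGraph()
        nodes = [IRI(f"http://x/n{i}") for i in range(4)]
        preds = [IRI(f"http://x/p{i}") for i in range(3)]
        for _ in range(rng.randint(3, 12)):
            g.add(rng.choice(nodes), rng.choice(preds),
                  rng.choice(nodes + [Literal(str(rng.randint(0, 3)))]))
        pattern = []
        for _ in range(rng.randint(1, 3)):
            pattern.append((
                rng.choice([Var("a"), Var("b"), rng.choice(nodes)]),
                rng.choice([Var("p"), rng.choice(preds)]),
                rng.choice([Var("b"), Var("c"), rng.choice(nodes)]),
            ))
        names = sorted({v.name for tp in pattern for v in tp
                        if isinstance(v, Var)})
        got = {tuple(sol[n] for n in names) for sol in query_graph(g, pattern)}
        assert got == brute_force_join(g, pattern)

    def test_deterministic_order(self, clinpharm):
        g = registry_to_rdf(clinpharm.registry, clinpharm.domains, BASE)
        pattern = [(Var("de"), IRI(RDF_TYPE), IRI(MMS + "DataElement"))]
        sols = query_graph(g, pattern)
        assert sols == sorted(sols, key=lambda s: str(s["de"]))

    def test_sparql_text_parsing(self, clinpharm):
        g = registry_to_rdf(clinpharm.registry, clinpharm.domains, BASE)
        query = """
        PREFIX mdrs: <http://purl.example.org/cdemdr/schema#>
        SELECT ?v WHERE {
          ?d mdrs:hasName "clinical pharmaceutical" .
          ?d mdrs:hasVariable ?v .
        }
        """
        pattern = parse_sparql_bgp(query)
        assert len(query_graph(g, pattern)) == 14

    def test_unbound_prefix_is_error(self):
        with pytest.raises(QueryError, match="unbound prefix"):
            parse_sparql_bgp("SELECT ?x WHERE { ?x nope:pred ?y . }")
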