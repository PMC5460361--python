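import random

import pytest

from cdemdr.analytics import (
    AlignmentRow,
    AlignmentSpec,
    align_template,
    enrich_domain,
    read_alignment_spec,
    suggest_mappings,
)
from cdemdr.model import (
    ClinicalDomain,
    DataElement,
    PropertyDef,
    ValueDomain,
    build_registry,
    dedup_key,
)
from conftest import random_registry_and_domain


class TestEnrichDomain:
    def test_saturation_global_equals_whole_registry(self, clinpharm):
        # the full fixture domain covers every object class in the registry
        report = enrich_domain(clinpharm.domain, clinpharm.registry)
        assert report.global_.data_elements == len(clinpharm.registry)

    def test_enriched_includes_dosage_form_code(self, clinpharm):
        report = enrich_domain(clinpharm.domain, clinpharm.registry)
        assert "Pharmaceutical Dosage Form Code" in {
            de.long_name for de in report.enriched_elements
        }

    def test_empty_asserted_set_warns(self, clinpharm):
        report = enrich_domain(ClinicalDomain(name="void"), clinpharm.registry)
        assert report.asserted.data_elements == 0
        assert report.global_.data_elements == 0
        assert report.warnings

    @pytest.mark.parametrize("seed", range(10))
    def test_counts_equal_exhaustive_scan(self, seed):
        """Report counts replicated by an independent brute-force scan of
        the registry."""
        registry, domain = random_registry_and_domain(seed)
        report = enrich_domain(domain, registry)
        asserted_ids = {v.cde_ref for v in domain.variables if v.cde_ref}
        asserted = [de for de in registry.data_elements
                    if de.public_id in asserted_ids]
        oc_keys = {dedup_key(de.object_class) for de in asserted}
        global_ = [de for de in registry.data_elements
                   if dedup_key(de.object_class) in oc_keys]
        assert report.asserted.data_elements == len(asserted)
        assert report.global_.data_elements == len(global_)
        assert report.enriched.data_elements == len(global_) - len(asserted)
        assert report.global_.properties == len(
            {dedup_key(de.property) for de in global_}
        )
        assert report.enriched.properties == len(
            {dedup_key(de.property) for de in global_}
            - {dedup_key(de.property) for de in asserted}
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_monotonicity_under_registry_growth(self, seed):
        """Adding registry elements never decreases any global count, and
        removing a non-asserted element never changes asserted counts."""
        registry, domain = random_registry_and_domain(seed, n_elements=10)
        before = enrich_domain(domain, registry)
        extra = DataElement(
            public_id="99999", version="1.0", long_name="Extra Element",
            object_class=registry.data_elements[0].object_class,
            property=PropertyDef("Brand New Property"),
            value_domain=ValueDomain("Brand New Domain"),
        )
        grown = build_registry(list(registry.data_elements) + [extra])
        after = enrich_domain(domain, grown)
        for attr in ("data_elements", "object_classes", "properties",
                     "value_domains_inclusive"):
            assert getattr(after.global_, attr) >= getattr(before.global_, attr)
        asserted_ids = {v.cde_ref for v in domain.variables}
        keep = [de for de in registry.data_elements
                if de.public_id in asserted_ids]
        if len(keep) < len(registry.data_elements):
            shrunk = enrich_domain(domain, build_registry(keep))
            assert shrunk.asserted == before.asserted

    def test_both_value_domain_conventions_exposed(self, clinpharm):
        report = enrich_domain(clinpharm.domain, clinpharm.registry)
        c = report.global_
        assert c.value_domains_inclusive == (
            c.value_domains + c.enumerated_value_domains
        )


def random_spec(rng: random.Random, names: list[str]) -> AlignmentSpec:
    rows = []
    for i in range(rng.randint(0, 12)):
        mapped = tuple(
            rng.choice(names + ["No Such Element"])
            for _ in range(rng.randint(0, 3))
        )
        rows.append(AlignmentRow(
            question_text=f"Q{i}?", prompt=f"P{i}", mapped_names=mapped
        ))
    return AlignmentSpec(rows=tuple(rows))


class TestAlignTemplate:
    def test_worked_example_rows(self, clinpharm):
        report = enrich_domain(clinpharm.domain, clinpharm.registry)
        result = align_template(clinpharm.alignment_spec,
                                clinpharm.domain, report)
        by_prompt = {c.prompt: c for c in result.classifications}
        assert by_prompt["Ongoing"].category == "asserted"
        assert by_prompt["MH ID"].category == "unmatched"
        assert by_prompt["End Time"].category == "enriched"
        assert result.counts == {
            "asserted": 9, "enriched": 10, "unmatched": 1, "total": 20,
        }

    def test_unknown_mapped_name_flagged_distinctly(self, clinpharm):
        report = enrich_domain(clinpharm.domain, clinpharm.registry)
        spec = AlignmentSpec(rows=(
            AlignmentRow("Q?", "ghost", ("Totally Unknown Element",)),
            AlignmentRow("Q2?", "empty", ()),
        ))
        result = align_template(spec, clinpharm.domain, report)
        ghost, empty = result.classifications
        assert ghost.category == "unmatched" and ghost.unknown_names
        assert empty.category == "unmatched" and not empty.unknown_names

    def test_wrong_domain_report_rejected(self, clinpharm):
        report = enrich_domain(ClinicalDomain(name="other"),
                               clinpharm.registry)
        with pytest.raises(ValueError, match="other"):
            align_template(clinpharm.alignment_spec, clinpharm.domain, report)

    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_on_random_specs(self, seed):
        """asserted + enriched + unmatched == total rows."""
        registry, domain = random_registry_and_domain(seed)
        report = enrich_domain(domain, registry)
        rng = random.Random(seed + 100)
        names = [de.long_name for de in registry.data_elements]
        spec = random_spec(rng, names)
        result = align_template(spec, domain, report)
        c = result.counts
        assert c["asserted"] + c["enriched"] + c["unmatched"] == c["total"]
        assert c["total"] == len(spec.rows)

    def test_row_order_permutation_invariance(self, clinpharm):
        report = enrich_domain(clinpharm.domain, clinpharm.registry)
        rows = list(clinpharm.alignment_spec.rows)
        random.Random(0).shuffle(rows)
        shuffled = AlignmentSpec(rows=tuple(rows))
        a = align_template(clinpharm.alignment_spec, clinpharm.domain, report)
        b = align_template(shuffled, clinpharm.domain, report)
        assert a.counts == b.counts
        assert {c.prompt: c.category for c in a.classifications} == {
            c.prompt: c.category for c in b.classifications
        }

    def test_duplicate_prompts_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            AlignmentSpec(rows=(
                AlignmentRow("Q?", "same", ()),
                AlignmentRow("Q2?", "same", ()),
            ))


class TestSuggestMappings:
    def test_token_containment_top_ranked(self):
        out = suggest_mappings(
            ["Route"],
            ["Route Of Administration", "Prescribed Dose", "Drug Name"],
        )
        top_name, top_score = out["Route"][0]
        assert top_name == "Route Of Administration" and top_score > 0

    def test_disjoint_tokens_score_zero(self):
        out = suggest_mappings(["alpha"], ["beta gamma"])
        assert out["alpha"][0][1] == 0.0

    @pytest.mark.parametrize(
        "prompt,candidate,expected",
        [
            ("Dose Unit", "Prescribed Dose Units", 1 / 4),  # {dose}/{dose,unit,units,prescribed}
            ("Start Date", "Start Date", 1.0),
            ("End Time", "Agent Administered End Time", 2 / 4),
        ],
    )
    def test_hand_computed_jaccard(self, prompt, candidate, expected):
        out = suggest_mappings([prompt], [candidate])
        assert out[prompt][0][1] == pytest.approx(expected)

    def test_ties_broken_lexicographically(self):
        out = suggest_mappings(["x"], ["x b", "x a"])
        assert [n for n, _ in out["x"]] == ["x a", "x b"]


class TestReadAlignmentSpec:
    def test_tsv_roundtrip(self, tmp_path, clinpharm):
        lines = ["question_text\tprompt\tmapped_names"]
        for row in clinpharm.alignment_spec.rows:
            lines.append(
                f"{row.question_text}\t{row.prompt}\t"
                + ";".join(row.mapped_names)
            )
        path = tmp_path / "spec.tsv"
        path.write_text("\n".join(lines) + "\n", "utf-8")
        spec = read_alignment_spec(path)
        assert spec.rows == clinpharm.alignment_spec.rows

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1\t2\n", "utf-8")
        with pytest.raises(ValueError, match="columns"):
            read_alignment_spec(path)
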