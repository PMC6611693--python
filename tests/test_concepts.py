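"""Dictionary recognition, PheCode rollup, and ambiguity accounting."""

import pytest

from patmine.concepts import (
    Lexicon,
    MappingBundle,
    annotate_corpus,
    mapping_audit,
    recognize,
    rollup,
)
from patmine import synth

from conftest import make_doc


class TestRecognize:
    def test_longest_match_wins(self, diabetes_lexicon):
        doc = make_doc(title="treating type 2 diabetes mellitus")
        mentions = recognize(doc, diabetes_lexicon)
        assert len(mentions) == 1
        m = mentions[0]
        assert m.surface == "type 2 diabetes mellitus"
        assert m.cui == "C0011860"
        assert m.token_span == (1, 5)

    def test_no_lexicon_terms_in_text(self, diabetes_lexicon):
        doc = make_doc(title="a rotary combustion engine")
        assert recognize(doc, diabetes_lexicon) == []

    def test_case_insensitive_token_boundaries(self, diabetes_lexicon):
        doc = make_doc(title="OBESITY and Diabetes Mellitus,")
        cuis = [m.cui for m in recognize(doc, diabetes_lexicon)]
        assert cuis == ["C0028754", "C0011849"]

    def test_mentions_never_overlap(self, diabetes_lexicon):
        doc = make_doc(
            title="type 2 diabetes mellitus",
            abstract="diabetes mellitus obesity diabetes mellitus",
        )
        for section in ("title", "abstract"):
            spans = sorted(
                m.token_span for m in recognize(doc, diabetes_lexicon)
                if m.section == section
            )
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_empty_lexicon_rejected(self):
        with pytest.raises(ValueError):
            recognize(make_doc(), Lexicon())

    def test_planted_mentions_recovered_exactly(self, tmp_path):
        """With overlap-free terms, recognition finds exactly the planted
        mention count across the biomedical corpus."""
        from patmine.corpus import read_corpus, filter_corpus

        config = synth.GeneratorConfig(seed=3, years=(2001, 2002), docs_per_year=150,
                                       n_diseases=5, mention_prob=0.3,
                                       biomedical_fraction=1.0, n_bait=0)
        paths = synth.simulate(config, tmp_path)
        gt = synth.GroundTruth.load(paths["ground_truth"])
        lex = Lexicon.from_tsv(paths["lexicon"])
        docs = list(read_corpus(paths["corpus"], "records"))
        total = sum(len(recognize(d, lex)) for d in docs)
        assert total == gt.n_mentions


class TestRollup:
    def test_one_to_one_definitive(self, simple_bundle):
        roots, definitive = rollup("C0011849", simple_bundle)
        assert roots == {"250"} and definitive

    def test_multiple_to_one_definitive(self, simple_bundle):
        # two ICD-9 codes, both landing on root 250
        roots, definitive = rollup("C0011860", simple_bundle)
        assert roots == {"250"} and definitive

    def test_one_to_multiple_ambiguous(self, simple_bundle):
        roots, definitive = rollup("C0028754", simple_bundle)
        assert roots == {"278", "279"} and not definitive

    def test_unmapped_cui(self, simple_bundle):
        assert rollup("C0999999", simple_bundle) == (frozenset(), False)

    def test_dangling_phecode_is_configuration_error(self):
        bundle = MappingBundle(
            cui_to_icd9={"C1": {"001"}},
            icd9_to_phecode={"001": {"008"}},
            phecode_to_root={},
        )
        with pytest.raises(ValueError):
            rollup("C1", bundle)

    def test_invariant_to_table_iteration_order(self, simple_bundle):
        reordered = MappingBundle(
            cui_to_icd9={k: set(sorted(v, reverse=True))
                         for k, v in reversed(list(simple_bundle.cui_to_icd9.items()))},
            icd9_to_phecode=dict(reversed(list(simple_bundle.icd9_to_phecode.items()))),
            phecode_to_root=dict(reversed(list(simple_bundle.phecode_to_root.items()))),
        )
        for cui in simple_bundle.cui_to_icd9:
            assert rollup(cui, simple_bundle) == rollup(cui, reordered)


class TestAnnotate:
    def test_union_under_all_policy(self, diabetes_lexicon, simple_bundle):
        doc = make_doc(title="diabetes mellitus", abstract="obesity treatment")
        (ann,) = annotate_corpus([doc], diabetes_lexicon, simple_bundle, "all")
        assert ann.root_phecodes == {"250", "278", "279"}
        assert ann.ambiguous

    def test_drop_policy_excludes_ambiguous(self, diabetes_lexicon, simple_bundle):
        doc = make_doc(title="diabetes mellitus", abstract="obesity treatment")
        (ann,) = annotate_corpus([doc], diabetes_lexicon, simple_bundle, "drop")
        assert ann.root_phecodes == {"250"}

    def test_drop_is_subset_of_all(self, diabetes_lexicon, simple_bundle):
        docs = [
            make_doc("U1", title="obesity"),
            make_doc("U2", title="type 2 diabetes mellitus and obesity"),
            make_doc("U3", title="nothing relevant"),
        ]
        all_anns = list(annotate_corpus(docs, diabetes_lexicon, simple_bundle, "all"))
        drop_anns = list(annotate_corpus(docs, diabetes_lexicon, simple_bundle, "drop"))
        for a, d in zip(all_anns, drop_anns):
            assert d.root_phecodes <= a.root_phecodes

    def test_no_mention_yields_empty_set(self, diabetes_lexicon, simple_bundle):
        (ann,) = annotate_corpus(
            [make_doc(title="gearbox")], diabetes_lexicon, simple_bundle, "all"
        )
        assert ann.root_phecodes == frozenset()


class TestMappingAudit:
    def test_nine_of_ten_definitive(self, rng):
        config = synth.GeneratorConfig(seed=0, n_diseases=10, ambiguity_fraction=0.0)
        lex, bundle, gt = synth.make_lexicon_and_mappings(config)
        # make exactly one CUI ambiguous by hand
        cui = sorted(lex.cuis)[0]
        bundle.cui_to_icd9[cui].add("999.0")
        bundle.icd9_to_phecode["999.0"] = {"999.1"}
        bundle.phecode_to_root["999.1"] = "999"
        bundle.phecode_to_root["999"] = "999"
        audit = mapping_audit(bundle, lex.cuis)
        assert audit.definitive_pct == pytest.approx(90.0)
        assert audit.n_unmapped == 0

    def test_all_unmapped_is_undefined(self, simple_bundle):
        audit = mapping_audit(simple_bundle, {"C0111111", "C0222222"})
        assert audit.definitive_pct is None
        assert audit.n_unmapped == audit.n_total == 2

    def test_percentages_sum_to_100_over_mapped(self, simple_bundle):
        audit = mapping_audit(
            simple_bundle, {"C0011849", "C0011860", "C0028754", "C0999999"}
        )
        assert audit.definitive_pct + audit.ambiguous_pct == pytest.approx(100.0)
        assert audit.n_unmapped == 1

    def test_empty_cui_set_rejected(self, simple_bundle):
        with pytest.raises(ValueError):
            mapping_audit(simple_bundle, set())
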