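"""Generator determinism, planted ground truth, and measure construction."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from patmine import synth
from patmine.concepts import Lexicon, MappingBundle, annotate_corpus, mapping_audit
from patmine.corpus import filter_corpus, read_corpus
from patmine.coverage import tabulate
from patmine.indices import MeasureTable, normalize, phi, roi


def _dir_hashes(d: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
        if p.is_file()
    }


class TestLexiconAndMappings:
    def test_zero_ambiguity_audits_fully_definitive(self):
        config = synth.GeneratorConfig(seed=0, n_diseases=10, ambiguity_fraction=0.0)
        lex, bundle, gt = synth.make_lexicon_and_mappings(config)
        audit = mapping_audit(bundle, lex.cuis)
        assert audit.definitive_pct == 100.0
        assert gt.ambiguous_cuis == []

    def test_audit_matches_constructed_ambiguous_set_exactly(self):
        config = synth.GeneratorConfig(seed=5, n_diseases=200, ambiguity_fraction=0.3)
        lex, bundle, gt = synth.make_lexicon_and_mappings(config)
        audit = mapping_audit(bundle, lex.cuis)
        assert audit.n_ambiguous == len(gt.ambiguous_cuis)
        assert audit.n_definitive == 200 - len(gt.ambiguous_cuis)

    def test_invalid_ambiguity_fraction_rejected(self):
        with pytest.raises(ValueError):
            synth.make_lexicon_and_mappings(
                synth.GeneratorConfig(ambiguity_fraction=1.5)
            )


class TestDeterminism:
    def test_fixed_seed_byte_identical_files(self, tmp_path):
        config = synth.GeneratorConfig(seed=9, years=(2000, 2001), docs_per_year=50)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        synth.simulate(config, d1)
        synth.simulate(config, d2)
        h1, h2 = _dir_hashes(d1), _dir_hashes(d2)
        assert h1 == h2

    def test_different_seeds_differ(self, tmp_path):
        synth.simulate(synth.GeneratorConfig(seed=1, docs_per_year=30), tmp_path / "a")
        synth.simulate(synth.GeneratorConfig(seed=2, docs_per_year=30), tmp_path / "b")
        assert _dir_hashes(tmp_path / "a") != _dir_hashes(tmp_path / "b")


class TestGeneratedFilesValidate:
    def test_readers_accept_generated_files_with_zero_skips(self, tmp_path):
        paths = synth.simulate(synth.demo_config(2), tmp_path)
        skipped = []
        docs = list(read_corpus(paths["corpus"], "records", skipped=skipped))
        assert skipped == []
        Lexicon.from_tsv(paths["lexicon"])
        MappingBundle.from_files(
            paths["cui2icd9"], paths["icd92phe"], paths["phe2root"]
        ).validate()
        MeasureTable.from_csv(paths["measures"])

    def test_mention_prob_one_reaches_every_biomedical_doc(self, tmp_path):
        config = synth.GeneratorConfig(
            seed=4, years=(2000,), docs_per_year=60, n_diseases=2,
            mention_prob=1.0, biomedical_fraction=1.0, n_bait=0,
        )
        paths = synth.simulate(config, tmp_path)
        gt = synth.GroundTruth.load(paths["ground_truth"])
        lex = Lexicon.from_tsv(paths["lexicon"])
        bundle = MappingBundle.from_files(
            paths["cui2icd9"], paths["icd92phe"], paths["phe2root"]
        )
        docs = list(read_corpus(paths["corpus"], "records"))
        docs, _ = filter_corpus(docs, synth.default_criteria(config.years))
        roots = set(gt.disease_root.values())
        for ann in annotate_corpus(docs, lex, bundle, "all"):
            assert ann.root_phecodes == roots

    def test_incidence_ground_truth_predicts_tabulation(self, tmp_path):
        config = synth.GeneratorConfig(seed=6, years=(2000, 2001), docs_per_year=120,
                                       n_diseases=6, mention_prob=0.2,
                                       biomedical_fraction=0.6)
        paths = synth.simulate(config, tmp_path)
        gt = synth.GroundTruth.load(paths["ground_truth"])
        lex = Lexicon.from_tsv(paths["lexicon"])
        bundle = MappingBundle.from_files(
            paths["cui2icd9"], paths["icd92phe"], paths["phe2root"]
        )
        docs, _ = filter_corpus(
            read_corpus(paths["corpus"], "records"),
            synth.default_criteria(config.years),
        )
        anns = list(annotate_corpus(docs, lex, bundle, "all"))
        matrix = tabulate(anns, {d.doc_id: d.year for d in docs})
        for root, per_year in gt.incidence.items():
            for year, count in per_year.items():
                assert matrix.counts.at[root, int(year)] == count


class TestMeasures:
    def test_unit_folds_give_aligned_indices(self, tmp_path):
        spec = synth.MeasureSpec(
            years=(2000,), folds={f"D{i}": {2000: 1.0} for i in range(4)}
        )
        gt = synth.GroundTruth()
        synth.make_measures(spec, gt, tmp_path / "m.csv")
        X = normalize(MeasureTable.from_csv(tmp_path / "m.csv"))
        assert np.allclose(roi(X).wide()[2000], 1.0)
        assert phi(X)[2000] == pytest.approx(0.0, abs=1e-15)

    def test_single_planted_fold_recovered_exactly(self, tmp_path):
        folds = {"D0": {2000: 3.0}, "D1": {2000: 1.0}, "D2": {2000: 0.5},
                 "D3": {2000: 1.0}}
        spec = synth.MeasureSpec(years=(2000,), folds=folds)
        synth.make_measures(spec, synth.GroundTruth(), tmp_path / "m.csv")
        X = normalize(MeasureTable.from_csv(tmp_path / "m.csv"))
        wide = roi(X).wide()
        assert wide.at["D0", 2000] == pytest.approx(3.0, rel=1e-12)
        assert wide.at["D2", 2000] == pytest.approx(-2.0, rel=1e-12)

    def test_infeasible_fold_patterns_rejected(self, tmp_path):
        spec = synth.MeasureSpec(
            years=(2000,), folds={"D0": {2000: 2.0}, "D1": {2000: 3.0}}
        )
        with pytest.raises(ValueError, match="infeasible"):
            synth.make_measures(spec, synth.GroundTruth(), tmp_path / "m.csv")

    def test_shrinking_folds_monotone_toward_one(self):
        folds = synth.shrinking_folds({"D0": 4.0, "D1": 0.25}, range(2000, 2005))
        vals = [folds["D0"][y] for y in range(2000, 2005)]
        assert all(a > b > 1.0 for a, b in zip(vals, vals[1:]))
        vals = [folds["D1"][y] for y in range(2000, 2005)]
        assert all(a < b < 1.0 for a, b in zip(vals, vals[1:]))
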