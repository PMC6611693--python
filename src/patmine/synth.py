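"""Synthetic corpus, lexicon, mapping-table and measure-table generator.

Every stage of the pipeline is exercised against data with planted, exported
ground truth: patent-like documents with year stamps and classification
codes, embedded multiword disease terms, per-topic filler-word distributions
that can drift across year slices, mapping bundles with a controlled
ambiguous fraction, and measure tables with planted fold-imbalances between
burden share and resource share.  All randomness flows from the config seed;
a fixed seed reproduces byte-identical files.

The generator writes real files in the pipeline's external formats so the
I/O code is exercised by every recovery test.  It emulates the shape of the
real inputs (bulk patent archives, claims-derived burden tables, publication
and trial counts), not their vocabulary statistics or legal prose.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .concepts import Lexicon, MappingBundle
from .corpus import FilterCriteria, PatentDocument, write_corpus
from .indices import MEASURES, RESOURCES

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "MeasureSpec",
    "GroundTruth",
    "default_allowlist",
    "default_criteria",
    "make_lexicon_and_mappings",
    "make_corpus",
    "make_measures",
    "shrinking_folds",
    "simulate",
    "demo_config",
]

#: illustrative biomedical classification prefixes (the real list is config)
BIOMED_CPC = ("A61K", "A61B", "A61F", "C12N", "G01N33")
OFFLIST_CPC = ("H04L", "B60K", "E04B", "F16H", "G06F")
BIOMED_USPC = ("424", "514", "600")
OFFLIST_USPC = ("704", "340")


def default_allowlist() -> tuple[frozenset[str], frozenset[str]]:
    return frozenset(BIOMED_USPC), frozenset(BIOMED_CPC)


def default_criteria(years: Sequence[int]) -> FilterCriteria:
    uspc, cpc = default_allowlist()
    return FilterCriteria(
        date_start=dt.date(min(years), 1, 1),
        date_end=dt.date(max(years), 12, 31),
        uspc_allowlist=uspc,
        cpc_allowlist=cpc,
        match_mode="prefix",
    )


@dataclass
class GeneratorConfig:
    seed: int = 0
    years: tuple[int, ...] = (2000, 2001, 2002)
    docs_per_year: int = 200
    n_diseases: int = 8
    mention_prob: float | Mapping[str, float] = 0.25
    ambiguity_fraction: float = 0.0
    biomedical_fraction: float = 0.11
    n_topics: int = 3
    filler_vocab_size: int = 60
    doc_length: int = 60
    drift_total: float = 0.0  # extra probability the drift keyword gains by the last slice
    n_bait: int = 10  # in-allowlist docs dated outside the window
    dialect: str = "records"

    def disease_ids(self) -> list[str]:
        return [f"D{i:03d}" for i in range(self.n_diseases)]

    def mention_prob_for(self, disease: str) -> float:
        if isinstance(self.mention_prob, Mapping):
            return float(self.mention_prob[disease])
        return float(self.mention_prob)


@dataclass
class MeasureSpec:
    """Planted fold-imbalances f_d per year: X_burden = f_d * R_resource."""

    years: tuple[int, ...]
    folds: dict[str, dict[int, float]]  # phecode -> year -> fold
    totals: dict[str, float] = field(
        default_factory=lambda: {m: 1e5 for m in MEASURES}
    )
    noise: str = "none"  # none | poisson | lognormal
    lognormal_sigma: float = 0.25  # log-scale sd for multiplicative cost noise

    def fold_vector(self, phecodes: Sequence[str], year: int) -> np.ndarray:
        return np.array([self.folds[p][year] for p in phecodes])


@dataclass
class GroundTruth:
    """Planted parameters sufficient to predict every stage's output."""

    doc_biomedical: dict[str, bool] = field(default_factory=dict)
    doc_year: dict[str, int] = field(default_factory=dict)
    doc_topic: dict[str, int] = field(default_factory=dict)
    doc_diseases: dict[str, list[str]] = field(default_factory=dict)
    disease_root: dict[str, str] = field(default_factory=dict)
    disease_cui: dict[str, str] = field(default_factory=dict)
    ambiguous_cuis: list[str] = field(default_factory=list)
    incidence: dict[str, dict[str, int]] = field(default_factory=dict)  # root -> year -> count
    n_mentions: int = 0
    topic_term_dists: list[list[list[float]]] = field(default_factory=list)  # T x K x V
    filler_vocab: list[str] = field(default_factory=list)
    drift_keyword: str = ""
    true_shares: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    folds: dict[str, dict[str, float]] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def make_lexicon_and_mappings(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[Lexicon, MappingBundle, GroundTruth]:
    """One unique multiword surface term per disease CUI; an
    ``ambiguity_fraction`` of CUIs is wired to two root PheCodes through
    divergent ICD-9 codes, the remainder one-to-one."""
    if not 0.0 <= config.ambiguity_fraction <= 1.0:
        raise ValueError("ambiguity_fraction must be in [0, 1]")
    if config.n_diseases < 2:
        raise ValueError("need at least 2 diseases")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    gt = GroundTruth()
    lex = Lexicon()
    bundle = MappingBundle()
    for i, disease in enumerate(config.disease_ids()):
        cui = f"C{1000001 + i:07d}"
        term = f"chronic cond{i:03d} syndrome"
        root = f"{100 + i}"
        icd9 = f"{100 + i}.0"
        phecode = f"{100 + i}.1"
        lex.add(term, cui)
        bundle.cui_to_icd9[cui] = {icd9}
        bundle.icd9_to_phecode[icd9] = {phecode}
        bundle.phecode_to_root[phecode] = root
        bundle.phecode_to_root[root] = root
        ambiguous = bool(rng.random() < config.ambiguity_fraction)
        if ambiguous:
            # second ICD-9 branch landing on a different root
            icd9b = f"{900 + i}.0"
            pheb = f"{900 + i}.1"
            rootb = f"{900 + i}"
            bundle.cui_to_icd9[cui].add(icd9b)
            bundle.icd9_to_phecode[icd9b] = {pheb}
            bundle.phecode_to_root[pheb] = rootb
            bundle.phecode_to_root[rootb] = rootb
            gt.ambiguous_cuis.append(cui)
        gt.disease_cui[disease] = cui
        gt.disease_root[disease] = root
    bundle.validate()
    return lex, bundle, gt


def _topic_distributions(config: GeneratorConfig) -> tuple[list[str], np.ndarray, str]:
    """Block-structured topic-term distributions over the filler vocabulary,
    with an optional linearly ramping drift keyword in topic 0.

    Returns (vocab, dists[T, K, V], drift_keyword).
    """
    V, K, T = config.filler_vocab_size, config.n_topics, len(config.years)
    vocab = [f"w{i:03d}" for i in range(V)]
    blocks = np.array_split(np.arange(V), K)
    static = np.full((K, V), 0.15 / V)
    for k, block in enumerate(blocks):
        static[k, block] += 0.85 / len(block)
    dists = np.tile(static[None], (T, 1, 1))
    keyword = ""
    if config.drift_total > 0:
        kw_idx = int(blocks[0][0])
        keyword = vocab[kw_idx]
        for t in range(T):
            frac = t / (T - 1) if T > 1 else 1.0
            target = static[0, kw_idx] + config.drift_total * frac
            row = static[0].copy()
            others = np.delete(np.arange(V), kw_idx)
            row[others] *= (1.0 - target) / row[others].sum()
            row[kw_idx] = target
            dists[t, 0] = row
    return vocab, dists, keyword


def make_corpus(
    config: GeneratorConfig,
    lexicon: Lexicon,
    gt: GroundTruth,
    path: str | Path,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Write a corpus file and extend ``gt`` with per-document truth.

    Documents are filler tokens sampled from planted per-slice topic
    distributions; each disease's surface term is inserted with its mention
    probability into biomedical documents.  A ``biomedical_fraction`` of
    documents receives allowlisted codes, the rest off-list codes; ``n_bait``
    extra allowlisted documents are dated outside the year window.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    vocab, dists, keyword = _topic_distributions(config)
    gt.filler_vocab = vocab
    gt.topic_term_dists = dists.tolist()
    gt.drift_keyword = keyword
    diseases = config.disease_ids()
    cui_to_term = {cui: " ".join(key) for key, cui in lexicon.entries.items()}
    surface = {d: cui_to_term[gt.disease_cui[d]] for d in diseases}
    docs: list[PatentDocument] = []
    n_mentions = 0
    serial = 0
    for t, year in enumerate(config.years):
        for _ in range(config.docs_per_year):
            serial += 1
            doc_id = f"US{serial:07d}"
            biomedical = bool(rng.random() < config.biomedical_fraction)
            topic = int(rng.integers(config.n_topics))
            tokens = list(
                rng.choice(vocab, size=config.doc_length, p=dists[t, topic])
            )
            mentioned: list[str] = []
            if biomedical:
                for d in diseases:
                    if rng.random() < config.mention_prob_for(d):
                        pos = int(rng.integers(len(tokens) + 1))
                        tokens.insert(pos, surface[d])
                        mentioned.append(d)
                        n_mentions += 1
            n_title = 5
            doc = PatentDocument(
                doc_id=doc_id,
                grant_date=dt.date(year, 1, 1)
                + dt.timedelta(days=int(rng.integers(365))),
                title=" ".join(tokens[:n_title]),
                abstract=" ".join(tokens[n_title:]),
                claims=f"claim for device {serial}",
                uspc_codes=(
                    [str(rng.choice(BIOMED_USPC))]
                    if biomedical
                    else [str(rng.choice(OFFLIST_USPC))]
                ),
                cpc_codes=(
                    [str(rng.choice(BIOMED_CPC)) + "31/00"]
                    if biomedical
                    else [str(rng.choice(OFFLIST_CPC)) + "1/00"]
                ),
            )
            docs.append(doc)
            gt.doc_biomedical[doc_id] = biomedical
            gt.doc_year[doc_id] = year
            gt.doc_topic[doc_id] = topic
            gt.doc_diseases[doc_id] = mentioned
            if biomedical:
                for d in mentioned:
                    root = gt.disease_root[d]
                    gt.incidence.setdefault(root, {})
                    gt.incidence[root][str(year)] = (
                        gt.incidence[root].get(str(year), 0) + 1
                    )
    # filter bait: allowlisted codes but outside the date window
    bait_year = min(config.years) - 2
    for _ in range(config.n_bait):
        serial += 1
        doc_id = f"US{serial:07d}"
        docs.append(
            PatentDocument(
                doc_id=doc_id,
                grant_date=dt.date(bait_year, 6, 15),
                title="out of window bait",
                abstract=" ".join(rng.choice(vocab, size=10, p=dists[0, 0])),
                claims="",
                uspc_codes=[str(rng.choice(BIOMED_USPC))],
                cpc_codes=[str(rng.choice(BIOMED_CPC)) + "31/00"],
            )
        )
        gt.doc_biomedical[doc_id] = False
        gt.doc_year[doc_id] = bait_year
    gt.n_mentions = n_mentions
    write_corpus(docs, path, dialect=config.dialect)
    return gt


def make_topic_documents(
    config: GeneratorConfig, rng: np.random.Generator | None = None
):
    """Tokenized documents sampled directly from the planted topic model.

    Each document draws one topic uniformly and ``doc_length`` tokens from
    that topic's slice distribution — the well-separated regime used by the
    topic-recovery tests.  Returns (docs, dists[T,K,V], vocab, drift_keyword).
    """
    from .preprocess import TokenizedDoc

    if rng is None:
        rng = np.random.default_rng(config.seed)
    vocab, dists, keyword = _topic_distributions(config)
    docs = []
    for t, year in enumerate(config.years):
        for i in range(config.docs_per_year):
            z = int(rng.integers(config.n_topics))
            tokens = list(rng.choice(vocab, size=config.doc_length, p=dists[t, z]))
            docs.append(
                TokenizedDoc(doc_id=f"T{t}_{i:04d}", year=year, tokens=tokens)
            )
    return docs, dists, vocab, keyword


def _solve_resource_shares(f: np.ndarray) -> np.ndarray:
    """Resource shares R on the simplex with sum(f * R) = 1, so that
    X_b = f * R is itself a share vector.

    Feasible iff folds > 1 and < 1 balance (or all are exactly 1)."""
    above = f > 1
    below = f < 1
    u = np.ones_like(f)
    if above.any() and not below.any():
        raise ValueError(
            "infeasible fold pattern: every disease understudied (all folds > 1); "
            "shares cannot renormalize"
        )
    if below.any() and not above.any():
        raise ValueError(
            "infeasible fold pattern: every disease overstudied (all folds < 1)"
        )
    if above.any():
        surplus = float(((f - 1)[above] * u[above]).sum())
        deficit = float(((1 - f)[below] * u[below]).sum())
        u[below] *= surplus / deficit
    R = u / u.sum()
    assert abs(float((f * R).sum()) - 1.0) < 1e-9
    return R


def make_measures(
    spec: MeasureSpec,
    gt: GroundTruth,
    path: str | Path,
    truth_path: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Write a tidy measure CSV with planted fold relations.

    True shares satisfy X_burden = f_d * R with R the common share of the
    three resource measures; values are scaled by per-measure totals and
    optionally Poisson-sampled.  A noiseless truth table is written next to
    the noisy one when ``truth_path`` is given.
    """
    if spec.noise not in ("none", "poisson", "lognormal"):
        raise ValueError(f"unknown noise model {spec.noise!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    phecodes = sorted(spec.folds)
    rows = []
    truth_rows = []
    for year in spec.years:
        f = spec.fold_vector(phecodes, year)
        R = _solve_resource_shares(f)
        Xb = f * R
        shares = {"burden": Xb}
        for m in RESOURCES:
            shares[m] = R
        for m in MEASURES:
            scaled = shares[m] * spec.totals[m]
            if spec.noise == "poisson":
                values = rng.poisson(scaled).astype(float)
            elif spec.noise == "lognormal":
                values = scaled * rng.lognormal(
                    0.0, spec.lognormal_sigma, size=scaled.shape
                )
            else:
                values = scaled
            for p, v_true, v in zip(phecodes, scaled, values):
                rows.append((m, p, year, v))
                truth_rows.append((m, p, year, v_true))
        for p, fold, xb, r in zip(phecodes, f, Xb, R):
            gt.folds.setdefault(p, {})[str(year)] = float(fold)
            gt.true_shares.setdefault(str(year), {})[p] = {
                "burden": float(xb),
                "resource": float(r),
            }
    header = "measure,phecode,year,value\n"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        for m, p, y, v in rows:
            fh.write(f"{m},{p},{y},{v:.17g}\n")
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write(header)
            for m, p, y, v in truth_rows:
                fh.write(f"{m},{p},{y},{v:.17g}\n")
    return gt


def shrinking_folds(
    initial: Mapping[str, float], years: Sequence[int], decay: float = 0.7
) -> dict[str, dict[int, float]]:
    """Fold schedules converging geometrically toward 1 (alignment), so the
    planted misalignment shrinks strictly along the year sequence."""
    out: dict[str, dict[int, float]] = {}
    for p, f0 in initial.items():
        out[p] = {}
        for i, year in enumerate(years):
            out[p][year] = 1.0 + (float(f0) - 1.0) * decay**i
    return out


def demo_config(seed: int = 0) -> GeneratorConfig:
    """Small preset: full pipeline end-to-end in well under a minute."""
    return GeneratorConfig(
        seed=seed,
        years=(2000, 2001, 2002),
        docs_per_year=200,
        n_diseases=8,
        mention_prob=0.25,
        ambiguity_fraction=0.0,
        biomedical_fraction=0.5,
        n_topics=3,
        drift_total=0.2,
    )


def simulate(
    config: GeneratorConfig,
    outdir: str | Path,
    measure_spec: MeasureSpec | None = None,
) -> dict[str, Path]:
    """Generate every pipeline input under ``outdir``; returns file paths.

    Deterministic: a fixed config seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    lexicon, bundle, gt = make_lexicon_and_mappings(config, rng)
    paths = {
        "corpus": outdir / ("corpus.xml" if config.dialect != "records" else "corpus.jsonl"),
        "lexicon": outdir / "lexicon.tsv",
        "cui2icd9": outdir / "cui2icd9.tsv",
        "icd92phe": outdir / "icd92phe.tsv",
        "phe2root": outdir / "phe2root.tsv",
        "measures": outdir / "measures.csv",
        "measures_true": outdir / "measures_true.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    lexicon.to_tsv(paths["lexicon"])
    _write_pairs(bundle.cui_to_icd9, paths["cui2icd9"])
    _write_pairs(bundle.icd9_to_phecode, paths["icd92phe"])
    _write_pairs({p: {r} for p, r in bundle.phecode_to_root.items()}, paths["phe2root"])
    gt = make_corpus(config, lexicon, gt, paths["corpus"], rng)
    if measure_spec is None:
        roots = sorted(gt.disease_root.values())
        half = len(roots) // 2
        folds = {
            p: {y: (3.0 if i < half else 0.5) for y in config.years}
            for i, p in enumerate(roots)
        }
        measure_spec = MeasureSpec(
            years=tuple(config.years), folds=folds, noise="lognormal"
        )
    gt = make_measures(
        measure_spec, gt, paths["measures"], paths["measures_true"], rng
    )
    gt.save(paths["ground_truth"])
    return paths


def _write_pairs(mapping: Mapping[str, set[str]], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# source\ttarget\n")
        for src in sorted(mapping):
            for dst in sorted(mapping[src]):
                fh.write(f"{src}\t{dst}\n")
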