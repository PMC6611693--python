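"""End-to-end pipeline orchestration.

One declarative YAML config drives filter -> annotate -> coverage ->
indices -> topics; each stage reads only the previous stage's declared
outputs, all randomness flows from named seeds in the config, and a run
manifest (config snapshot, per-stage row counts, timestamps, warnings) is
written even on partial failure.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .concepts import (
    Lexicon,
    MappingBundle,
    annotate_corpus,
    mapping_audit,
    write_annotations,
)
from .corpus import FilterCriteria, filter_corpus, read_corpus, write_corpus
from .coverage import coverage, diseases_covered_per_year, tabulate, top_k
from .dtm import DTMParams, build_matrix, fit_dtm, top_words
from .coherence import select_topic_number, umass_coherence
from .indices import MeasureTable, normalize, phi, roi, vif
from .preprocess import preprocess_docs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_all"]

STAGES = ("filter", "annotate", "coverage", "indices", "topics")


@dataclass
class RunConfig:
    corpus: Path
    dialect: str
    lexicon: Path
    cui2icd9: Path
    icd92phe: Path
    phe2root: Path
    measures: Path
    output_dir: Path
    criteria: FilterCriteria
    ambiguity_policy: str = "all"
    coverage_top_k: int = 24
    coverage_denominator: str = "mentioning"
    index_weights: dict[str, float] | None = None
    index_window: tuple[int, int] | None = None
    topic_disease: str | None = None
    topic_k: int = 10
    topic_select_grid: tuple[int, ...] | None = None
    topic_alpha: float = 0.01
    topic_sigma: float = 0.005
    topic_n_iter: int = 40
    topic_seed: int = 0
    topic_min_df: int = 2
    topic_max_df_frac: float = 0.95

    def snapshot(self) -> dict[str, Any]:
        return {
            "corpus": str(self.corpus),
            "dialect": self.dialect,
            "lexicon": str(self.lexicon),
            "measures": str(self.measures),
            "output_dir": str(self.output_dir),
            "date_start": self.criteria.date_start.isoformat(),
            "date_end": self.criteria.date_end.isoformat(),
            "match_mode": self.criteria.match_mode,
            "uspc_allowlist": sorted(self.criteria.uspc_allowlist),
            "cpc_allowlist": sorted(self.criteria.cpc_allowlist),
            "ambiguity_policy": self.ambiguity_policy,
            "index_weights": self.index_weights,
            "index_window": list(self.index_window) if self.index_window else None,
            "topic_disease": self.topic_disease,
            "topic_k": self.topic_k,
            "topic_select_grid": (
                list(self.topic_select_grid) if self.topic_select_grid else None
            ),
            "topic_alpha": self.topic_alpha,
            "topic_sigma": self.topic_sigma,
            "topic_n_iter": self.topic_n_iter,
            "topic_seed": self.topic_seed,
        }


@dataclass
class RunManifest:
    config: dict[str, Any]
    version: str = __version__
    started: str = ""
    finished: str = ""
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def save(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "config": self.config,
            "stages": self.stages,
            "warnings": self.warnings,
            "failed_stage": self.failed_stage,
            "error": self.error,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def _as_date(value: Any, errors: list[str], label: str) -> dt.date | None:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value))
    except (TypeError, ValueError):
        errors.append(f"{label}: cannot parse date {value!r}")
        return None


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config, collecting every error.

    Raises ``ValueError`` whose message lists all problems at once.
    """
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except (OSError, yaml.YAMLError) as exc:
        raise ValueError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    errors: list[str] = []
    paths_sec = raw.get("paths", {})
    resolved: dict[str, Path] = {}
    for key in ("corpus", "lexicon", "cui2icd9", "icd92phe", "phe2root", "measures"):
        value = paths_sec.get(key)
        if value is None:
            errors.append(f"paths.{key}: missing")
            continue
        p = Path(value)
        if not p.exists():
            errors.append(f"paths.{key}: file not found: {p}")
        resolved[key] = p
    filt = raw.get("filter", {})
    start = _as_date(filt.get("date_start"), errors, "filter.date_start")
    end = _as_date(filt.get("date_end"), errors, "filter.date_end")
    if start and end and start > end:
        errors.append("filter: date_start is after date_end")
    uspc = frozenset(filt.get("uspc_allowlist") or [])
    cpc = frozenset(filt.get("cpc_allowlist") or [])
    if not (uspc or cpc):
        errors.append("filter: both allowlists are empty")
    match_mode = filt.get("match_mode", "prefix")
    if match_mode not in ("exact", "prefix"):
        errors.append(f"filter.match_mode: unknown mode {match_mode!r}")
    ann = raw.get("annotate", {})
    policy = ann.get("ambiguity_policy", "all")
    if policy not in ("all", "drop"):
        errors.append(f"annotate.ambiguity_policy: unknown policy {policy!r}")
    idx = raw.get("indices", {})
    window = idx.get("window")
    if window is not None:
        try:
            window = (int(window[0]), int(window[1]))
            if window[0] > window[1]:
                errors.append("indices.window: start year is after end year")
        except (TypeError, ValueError, IndexError):
            errors.append(f"indices.window: expected [start, end], got {window!r}")
            window = None
    topics = raw.get("topics", {})
    output_dir = raw.get("output_dir")
    if output_dir is None:
        errors.append("output_dir: missing")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    criteria = FilterCriteria(
        date_start=start,
        date_end=end,
        uspc_allowlist=uspc,
        cpc_allowlist=cpc,
        match_mode=match_mode,
    )
    grid = topics.get("select_k")
    return RunConfig(
        corpus=resolved["corpus"],
        dialect=paths_sec.get("dialect", "records"),
        lexicon=resolved["lexicon"],
        cui2icd9=resolved["cui2icd9"],
        icd92phe=resolved["icd92phe"],
        phe2root=resolved["phe2root"],
        measures=resolved["measures"],
        output_dir=Path(output_dir),
        criteria=criteria,
        ambiguity_policy=policy,
        coverage_top_k=int(raw.get("coverage", {}).get("top_k", 24)),
        coverage_denominator=raw.get("coverage", {}).get("denominator", "mentioning"),
        index_weights=idx.get("weights"),
        index_window=window,
        topic_disease=topics.get("disease"),
        topic_k=int(topics.get("k", 10)),
        topic_select_grid=tuple(grid) if grid else None,
        topic_alpha=float(topics.get("alpha", 0.01)),
        topic_sigma=float(topics.get("sigma", 0.005)),
        topic_n_iter=int(topics.get("n_iter", 40)),
        topic_seed=int(topics.get("seed", 0)),
        topic_min_df=int(topics.get("min_df", 2)),
        topic_max_df_frac=float(topics.get("max_df_frac", 0.95)),
    )


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage in order, writing outputs under the run directory.

    Rerunning with an identical config and seeds reproduces identical
    outputs.  A stage failure halts the chain; the manifest records the
    failed stage and cause, and earlier outputs stay intact.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot())
    manifest.started = dt.datetime.now(dt.timezone.utc).isoformat()
    manifest_path = out / "manifest.json"
    current = ""
    try:
        current = "filter"
        t0 = time.monotonic()
        skipped: list[str] = []
        docs = list(read_corpus(config.corpus, config.dialect, skipped=skipped))
        filtered, report = filter_corpus(docs, config.criteria)
        write_corpus(filtered, out / "filtered.jsonl", dialect="records")
        report.to_json(out / "filter_report.json")
        report.per_year_csv(out / "filter_per_year.csv")
        manifest.stages["filter"] = {
            "n_total": report.n_total,
            "n_biomedical": report.n_biomedical,
            "n_skipped": len(skipped),
            "seconds": round(time.monotonic() - t0, 3),
        }

        current = "annotate"
        t0 = time.monotonic()
        lexicon = Lexicon.from_tsv(config.lexicon)
        bundle = MappingBundle.from_files(
            config.cui2icd9, config.icd92phe, config.phe2root
        )
        annotations = list(
            annotate_corpus(filtered, lexicon, bundle, config.ambiguity_policy)
        )
        write_annotations(annotations, out / "annotations.tsv")
        audit = mapping_audit(bundle, lexicon.cuis)
        (out / "mapping_audit.json").write_text(
            json.dumps(
                {
                    "n_total": audit.n_total,
                    "n_definitive": audit.n_definitive,
                    "n_ambiguous": audit.n_ambiguous,
                    "n_unmapped": audit.n_unmapped,
                    "definitive_pct": audit.definitive_pct,
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )
        manifest.stages["annotate"] = {
            "n_docs": len(annotations),
            "n_with_disease": sum(1 for a in annotations if a.root_phecodes),
            "seconds": round(time.monotonic() - t0, 3),
        }

        current = "coverage"
        t0 = time.monotonic()
        doc_years = {d.doc_id: d.year for d in filtered}
        matrix = tabulate(annotations, doc_years)
        table = coverage(matrix, denominator=config.coverage_denominator)
        table.to_csv(out / "coverage.csv")
        diseases_covered_per_year(matrix).to_csv(
            out / "diseases_per_year.csv", index_label="year", header=["count"]
        )
        top_k(table, config.coverage_top_k).to_csv(out / "top_k.csv", index=False)
        manifest.stages["coverage"] = {
            "n_diseases": int(len(matrix.counts)),
            "n_years": int(len(matrix.counts.columns)),
            "seconds": round(time.monotonic() - t0, 3),
        }

        current = "indices"
        t0 = time.monotonic()
        measures = MeasureTable.from_csv(config.measures)
        if config.index_window:
            measures = measures.window(*config.index_window)
        X = normalize(measures)
        roi_series = roi(X, config.index_weights)
        roi_series.to_csv(out / "roi.csv")
        phi(X, config.index_weights).to_csv(out / "phi.csv", index_label="year")
        vif(X).to_csv(out / "vif.csv", index_label="measure")
        manifest.stages["indices"] = {
            "n_diseases": len(X.phecodes),
            "n_years": len(X.years),
            "seconds": round(time.monotonic() - t0, 3),
        }

        current = "topics"
        t0 = time.monotonic()
        disease = config.topic_disease
        if disease is None:
            by_doc_count = matrix.counts.sum(axis=1)
            disease = sorted(
                by_doc_count.items(), key=lambda kv: (-kv[1], kv[0])
            )[0][0]
        doc_ids = {
            a.doc_id for a in annotations if disease in a.root_phecodes
        }
        subcorpus = [d for d in filtered if d.doc_id in doc_ids]
        tokenized = preprocess_docs(subcorpus, lexicon=lexicon)
        dtm_matrix = build_matrix(
            tokenized, min_df=config.topic_min_df, max_df_frac=config.topic_max_df_frac
        )
        params = DTMParams(
            K=config.topic_k,
            alpha=config.topic_alpha,
            sigma=config.topic_sigma,
            n_iter=config.topic_n_iter,
            seed=config.topic_seed,
        )
        topic_dir = out / "topics"
        topic_dir.mkdir(exist_ok=True)
        stage: dict[str, Any] = {"disease": disease, "n_docs": dtm_matrix.n_docs}
        if config.topic_select_grid:
            best_k, curve = select_topic_number(
                dtm_matrix, grid=config.topic_select_grid, params=params
            )
            params = DTMParams(
                K=best_k,
                alpha=config.topic_alpha,
                sigma=config.topic_sigma,
                n_iter=config.topic_n_iter,
                seed=config.topic_seed,
            )
            with open(topic_dir / "coherence_curve.csv", "w", encoding="utf-8") as fh:
                fh.write("k,mean_coherence\n")
                for k_val in sorted(curve):
                    fh.write(f"{k_val},{curve[k_val]:.8g}\n")
            stage["selected_k"] = best_k
        fit = fit_dtm(dtm_matrix, params)
        fit.save(topic_dir)
        _, mean_coh = umass_coherence(fit, dtm_matrix)
        with open(topic_dir / "top_words.csv", "w", encoding="utf-8") as fh:
            fh.write("slice_year,topic,rank,term,beta\n")
            term_id = {t: i for i, t in enumerate(fit.vocab)}
            for t, year in enumerate(fit.slice_years):
                for k_idx in range(params.K):
                    for rank, term in enumerate(top_words(fit, t, k_idx), 1):
                        beta_v = fit.beta[t, k_idx, term_id[term]]
                        fh.write(f"{year},{k_idx},{rank},{term},{beta_v:.8g}\n")
        stage.update(
            {
                "k": params.K,
                "mean_coherence": mean_coh,
                "converged": fit.converged,
                "seconds": round(time.monotonic() - t0, 3),
            }
        )
        manifest.stages["topics"] = stage
    except Exception as exc:  # manifest must record partial failure
        manifest.failed_stage = current
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.finished = dt.datetime.now(dt.timezone.utc).isoformat()
        manifest.save(manifest_path)
        raise
    manifest.finished = dt.datetime.now(dt.timezone.utc).isoformat()
    manifest.save(manifest_path)
    return manifest
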