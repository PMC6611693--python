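"""UMass topic coherence and coherence-driven topic-number selection.

The UMass score for a topic's ranked top-N terms is

    sum over ranked pairs i < j of log[(D(w_i, w_j) + 1) / D(w_j)]

where D(w) and D(w_i, w_j) are document occurrence and co-occurrence counts
from the modeled corpus itself.  Scores are <= 0 in practice; values nearer
0 mean the top terms genuinely co-occur.  Per-slice scores are averaged with
equal weights, then averaged over topics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse

from .dtm import DocTermMatrix, DTMFit, DTMParams, fit_dtm, top_words

logger = logging.getLogger(__name__)

__all__ = ["umass_coherence", "select_topic_number"]


def _doc_occurrence(matrix: DocTermMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Document frequency vector and co-occurrence matrix (binary counts)."""
    binary = (matrix.counts > 0).astype(np.float64)
    df = np.asarray(binary.sum(axis=0)).ravel()
    co = (binary.T @ binary).toarray()
    return df, co


def _pair_score(df_j: float, co_ij: float) -> float:
    # a term absent from every document gets denominator 1 (the +1 smoothing
    # convention extended to the denominator), giving a 0 pair score
    denom = df_j if df_j > 0 else 1.0
    return float(np.log((co_ij + 1.0) / denom))


def umass_coherence(
    fit: DTMFit, matrix: DocTermMatrix, top_n: int = 10
) -> tuple[np.ndarray, float]:
    """Per-topic UMass coherence (slices averaged equally) and the mean.

    The fit and matrix must share a vocabulary; top terms are ordered by
    beta descending with lexicographic tie-breaks.
    """
    if fit.vocab != matrix.vocab:
        raise ValueError("fit and matrix vocabularies differ")
    term_id = {t: i for i, t in enumerate(matrix.vocab)}
    df, co = _doc_occurrence(matrix)
    T, K, _ = fit.beta.shape
    per_topic = np.zeros(K)
    for k in range(K):
        slice_scores = []
        for t in range(T):
            terms = top_words(fit, t, k, top_n)
            ids = [term_id[w] for w in terms]
            score = 0.0
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    score += _pair_score(df[ids[j]], co[ids[i], ids[j]])
            slice_scores.append(score)
        per_topic[k] = float(np.mean(slice_scores))
    return per_topic, float(per_topic.mean())


def select_topic_number(
    matrix: DocTermMatrix,
    grid: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20),
    params: DTMParams | None = None,
    seeds_per_k: int = 1,
    top_n: int = 10,
) -> tuple[int, dict[int, float]]:
    """Fit the model at each K on the grid and pick the coherence maximizer.

    Coherence is averaged over ``seeds_per_k`` refits; ties break toward the
    smaller K.  A K whose fit fails is skipped with a warning; the curve
    contains one value per successful K.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if params is None:
        params = DTMParams()
    curve: dict[int, float] = {}
    for K in grid:
        scores = []
        try:
            for s in range(seeds_per_k):
                p = replace(params, K=K, seed=params.seed + 1000 * s)
                fit = fit_dtm(matrix, p)
                _, mean_score = umass_coherence(fit, matrix, top_n=top_n)
                scores.append(mean_score)
        except ValueError as exc:
            warnings.warn(f"skipping K={K}: {exc}")
            continue
        curve[K] = float(np.mean(scores))
    if not curve:
        raise ValueError("no K on the grid produced a successful fit")
    best_k = min(curve, key=lambda k: (-curve[k], k))
    return best_k, curve
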