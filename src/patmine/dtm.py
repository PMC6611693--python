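"""Dynamic topic model over calendar-year slices.

The model family: K topics, each with per-slice term distributions
``beta[t, k] = softmax(eta[t, k])`` whose natural parameters ``eta`` evolve
between adjacent slices as a Gaussian random walk with chain variance
``sigma``; per-document topic proportions ``theta[d]`` smoothed by a
Dirichlet-style pseudo-count ``alpha``.  ``sigma -> 0`` collapses every
slice to a single shared topic-term distribution; a large ``sigma``
decouples the slices.

Inference is a generalized EM on the penalized log likelihood

    L = sum_dv n_dv log sum_k theta_dk beta_{s(d),k,v}
        + alpha * sum_dk log theta_dk
        - 1/(2 sigma) * sum_tk ||eta_{t,k} - eta_{t-1,k}||^2

with an exact M-step for theta and backtracking gradient ascent for eta,
so the recorded objective trace is nondecreasing (within float noise) and
the whole fit is reproducible from the seed.  This is a self-contained
reimplementation of the model contract, not of any particular historical
inference code.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.io import mmread, mmwrite
from scipy.special import logsumexp

from .preprocess import TokenizedDoc

logger = logging.getLogger(__name__)

__all__ = [
    "DocTermMatrix",
    "DTMParams",
    "DTMFit",
    "build_matrix",
    "fit_dtm",
    "top_words",
    "top_word_drift",
]

#: pseudo-count used wherever a closed-form multinomial estimate needs smoothing
SMOOTH = 1e-3


@dataclass
class DocTermMatrix:
    """Sparse bag-of-words counts with a year slice per document."""

    counts: sparse.csr_matrix  # D x V
    vocab: list[str]
    doc_ids: list[str]
    slice_index: np.ndarray  # document -> slice ordinal
    slice_years: list[int]  # ordered calendar years

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    @property
    def n_slices(self) -> int:
        return len(self.slice_years)

    def save(self, prefix: str | Path) -> None:
        """Write <prefix>.mtx, <prefix>.terms.txt, <prefix>.docs.csv."""
        prefix = Path(prefix)
        mmwrite(str(prefix) + ".mtx", self.counts)
        Path(str(prefix) + ".terms.txt").write_text(
            "\n".join(self.vocab) + "\n", encoding="utf-8"
        )
        with open(str(prefix) + ".docs.csv", "w", encoding="utf-8") as fh:
            fh.write("doc_id,year,slice\n")
            for i, doc_id in enumerate(self.doc_ids):
                s = int(self.slice_index[i])
                fh.write(f"{doc_id},{self.slice_years[s]},{s}\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "DocTermMatrix":
        prefix = Path(prefix)
        counts = sparse.csr_matrix(mmread(str(prefix) + ".mtx"))
        vocab = Path(str(prefix) + ".terms.txt").read_text(encoding="utf-8").split()
        doc_ids, years = [], []
        with open(str(prefix) + ".docs.csv", encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                doc_id, year, _ = line.strip().split(",")
                doc_ids.append(doc_id)
                years.append(int(year))
        slice_years = sorted(set(years))
        year_to_slice = {y: i for i, y in enumerate(slice_years)}
        slice_index = np.array([year_to_slice[y] for y in years], dtype=int)
        return cls(counts, vocab, doc_ids, slice_index, slice_years)


def build_matrix(
    tokenized: Iterable[TokenizedDoc],
    min_df: int = 1,
    max_df_frac: float = 1.0,
) -> DocTermMatrix:
    """Convert tokenized documents into a D x V count matrix.

    Vocabulary keeps terms whose document frequency lies in
    ``[min_df, max_df_frac * D]``.  Documents left empty after filtering are
    dropped with a logged count; slices are the sorted calendar years present
    among retained documents.
    """
    docs = [d for d in tokenized]
    nonempty = [d for d in docs if d.tokens]
    if len(docs) - len(nonempty):
        logger.info("dropping %d empty documents", len(docs) - len(nonempty))
    if len(nonempty) < 2:
        raise ValueError("need at least 2 non-empty documents")
    df: dict[str, int] = {}
    for d in nonempty:
        for term in set(d.tokens):
            df[term] = df.get(term, 0) + 1
    max_df = max_df_frac * len(nonempty)
    vocab = sorted(t for t, c in df.items() if min_df <= c <= max_df)
    if not vocab:
        raise ValueError("vocabulary empty after document-frequency filtering")
    term_id = {t: i for i, t in enumerate(vocab)}
    rows, cols, vals = [], [], []
    kept: list[TokenizedDoc] = []
    n_dropped = 0
    for d in nonempty:
        counts: dict[int, int] = {}
        for term in d.tokens:
            j = term_id.get(term)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if not counts:
            n_dropped += 1
            continue
        i = len(kept)
        kept.append(d)
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    if n_dropped:
        logger.info("dropping %d documents emptied by vocabulary filter", n_dropped)
    if len(kept) < 2:
        raise ValueError("need at least 2 non-empty documents after filtering")
    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(kept), len(vocab)), dtype=np.float64
    )
    slice_years = sorted({d.year for d in kept})
    year_to_slice = {y: i for i, y in enumerate(slice_years)}
    slice_index = np.array([year_to_slice[d.year] for d in kept], dtype=int)
    return DocTermMatrix(
        counts=counts,
        vocab=vocab,
        doc_ids=[d.doc_id for d in kept],
        slice_index=slice_index,
        slice_years=slice_years,
    )


@dataclass(frozen=True)
class DTMParams:
    """K topics, document-topic concentration alpha, chain variance sigma."""

    K: int = 10
    alpha: float = 0.01
    sigma: float = 0.005
    n_iter: int = 60
    seed: int = 0
    tol_per_token: float = 1e-8  # early-stop threshold on the objective

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class DTMFit:
    beta: np.ndarray  # T x K x V, rows sum to 1, strictly positive
    theta: np.ndarray  # D x K, rows sum to 1
    trace: list[float]  # penalized objective per epoch (nondecreasing)
    params: DTMParams
    vocab: list[str]
    slice_years: list[int]
    doc_ids: list[str]
    converged: bool = True

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for t, year in enumerate(self.slice_years):
            mmwrite(str(outdir / f"beta_slice_{year}.mtx"), sparse.coo_matrix(self.beta[t]))
        with open(outdir / "theta.csv", "w", encoding="utf-8") as fh:
            fh.write("doc_id," + ",".join(f"topic_{k}" for k in range(self.params.K)) + "\n")
            for i, doc_id in enumerate(self.doc_ids):
                fh.write(doc_id + "," + ",".join(f"{v:.8g}" for v in self.theta[i]) + "\n")
        Path(outdir / "vocab.txt").write_text("\n".join(self.vocab) + "\n", encoding="utf-8")


def _eta_objective(eta: np.ndarray, C: np.ndarray, M: np.ndarray, sigma: float) -> float:
    """Expected complete-data term + chain penalty for one topic.

    eta, C: T x V; M: per-slice responsibility mass (T,).
    """
    lse = logsumexp(eta, axis=1)
    val = float((C * eta).sum() - (M * lse).sum())
    if sigma > 0 and eta.shape[0] > 1:
        d = np.diff(eta, axis=0)
        val -= float((d * d).sum()) / (2.0 * sigma)
    return val


def _eta_gradient(eta: np.ndarray, C: np.ndarray, M: np.ndarray, sigma: float) -> np.ndarray:
    p = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    grad = C - M[:, None] * p
    if sigma > 0 and eta.shape[0] > 1:
        lap = np.zeros_like(eta)
        d = np.diff(eta, axis=0)
        lap[:-1] -= d
        lap[1:] += d
        grad -= lap / sigma
    return grad


def _update_eta(
    eta: np.ndarray, C: np.ndarray, M: np.ndarray, sigma: float, n_steps: int = 8
) -> np.ndarray:
    """Backtracking gradient ascent; never decreases the objective."""
    lipschitz = float(M.max()) + (4.0 / sigma if sigma > 0 else 0.0) + 1e-9
    step = 1.0 / lipschitz
    f = _eta_objective(eta, C, M, sigma)
    for _ in range(n_steps):
        g = _eta_gradient(eta, C, M, sigma)
        s = step
        for _ in range(30):
            cand = eta + s * g
            f_new = _eta_objective(cand, C, M, sigma)
            if f_new >= f:
                eta, f = cand, f_new
                break
            s *= 0.5
        else:
            break  # no improving step found; stationary enough
    return eta


def fit_dtm(matrix: DocTermMatrix, params: DTMParams) -> DTMFit:
    """Fit the Gaussian-chained topic model by generalized EM.

    Identical (matrix, params) inputs produce bitwise-identical fits.  If the
    objective has not stabilized after ``n_iter`` epochs the best fit so far
    is returned with ``converged=False`` and a warning.
    """
    D, V = matrix.counts.shape
    K, T = params.K, matrix.n_slices
    if K > V:
        raise ValueError(f"K={K} exceeds vocabulary size {V}")
    if K > D:
        raise ValueError(f"K={K} exceeds document count {D}")
    rng = np.random.default_rng(params.seed)

    X = [np.asarray(matrix.counts[matrix.slice_index == t].todense()) for t in range(T)]
    doc_order = np.concatenate([np.flatnonzero(matrix.slice_index == t) for t in range(T)])
    n_tokens = float(matrix.counts.sum())

    corpus_freq = np.asarray(matrix.counts.sum(axis=0)).ravel()
    base = np.log(corpus_freq + SMOOTH)
    # identical across slices at init so the chain penalty starts at zero
    eta = np.tile(base[None, None, :], (T, K, 1)) + np.tile(
        0.5 * rng.standard_normal((1, K, V)), (T, 1, 1)
    )
    thetas = [np.full((x.shape[0], K), 1.0 / K) for x in X]

    def slice_beta(t: int) -> np.ndarray:
        return np.exp(eta[t] - logsumexp(eta[t], axis=1, keepdims=True))

    def objective() -> float:
        val = 0.0
        for t in range(T):
            B = slice_beta(t)
            p = thetas[t] @ B
            nz = X[t] > 0
            val += float((X[t][nz] * np.log(p[nz])).sum())
            val += params.alpha * float(np.log(thetas[t]).sum())
        if params.sigma > 0 and T > 1:
            d = np.diff(eta, axis=0)
            val -= float((d * d).sum()) / (2.0 * params.sigma)
        return val

    trace: list[float] = []
    converged = False
    for epoch in range(params.n_iter):
        C = np.zeros((T, K, V))
        M = np.zeros((T, K))
        for t in range(T):
            B = slice_beta(t)  # K x V
            p = thetas[t] @ B  # Ds x V
            ratio = np.divide(X[t], p, out=np.zeros_like(X[t]), where=p > 0)
            N = thetas[t] * (ratio @ B.T)  # Ds x K expected counts
            C[t] = B * (thetas[t].T @ ratio)
            M[t] = C[t].sum(axis=1)
            new_theta = N + params.alpha
            thetas[t] = new_theta / new_theta.sum(axis=1, keepdims=True)
        if params.sigma == 0.0:
            # shared topic-term distribution: closed-form smoothed estimate
            pooled = C.sum(axis=0) + SMOOTH  # K x V
            eta = np.tile(
                np.log(pooled / pooled.sum(axis=1, keepdims=True))[None], (T, 1, 1)
            )
        else:
            for k in range(K):
                eta[:, k, :] = _update_eta(
                    eta[:, k, :], C[:, k, :], M[:, k], params.sigma
                )
        trace.append(objective())
        if (
            epoch > 0
            and abs(trace[-1] - trace[-2]) <= params.tol_per_token * n_tokens
        ):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"DTM did not converge in {params.n_iter} epochs; returning best fit"
        )

    beta = np.stack([slice_beta(t) for t in range(T)])
    theta = np.zeros((D, K))
    theta[doc_order] = np.vstack(thetas)
    return DTMFit(
        beta=beta,
        theta=theta,
        trace=trace,
        params=params,
        vocab=matrix.vocab,
        slice_years=matrix.slice_years,
        doc_ids=matrix.doc_ids,
        converged=converged,
    )


def top_words(fit: DTMFit, t: int, k: int, n: int = 10) -> list[str]:
    """The n highest-probability terms of topic k in slice t; ties break
    lexicographically.  n beyond the vocabulary returns all terms."""
    row = fit.beta[t, k]
    order = sorted(range(len(row)), key=lambda j: (-row[j], fit.vocab[j]))
    return [fit.vocab[j] for j in order[: min(n, len(row))]]


def top_word_drift(fit: DTMFit, k: int, n: int = 10) -> list[dict]:
    """For each term ever in topic k's top-n, the first and last slice year
    of its top-n membership (a keyword-drift table)."""
    membership: dict[str, list[int]] = {}
    for t, year in enumerate(fit.slice_years):
        for term in top_words(fit, t, k, n):
            membership.setdefault(term, []).append(year)
    return [
        {"term": term, "first_year": ys[0], "last_year": ys[-1], "n_slices": len(ys)}
        for term, ys in sorted(membership.items())
    ]
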