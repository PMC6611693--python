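# Methods

This note documents the models and procedures implemented in `patmine`, the
parameters that matter, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## Corpus filtering

A patent document carries an identifier, grant date, three text sections
(title, abstract, claims), and USPC/CPC classification codes.  The
biomedical filter keeps a document when (a) its grant date lies inside the
configured window, inclusive on both ends, and (b) at least one USPC *or*
CPC code matches the union of the two allowlists.  Matching defaults to
prefix mode because CPC codes are hierarchical (`A61K31/00` is a
subdivision of `A61K`); exact mode is available for flat lists.  The
allowlist is data, not algorithm: it is a required input, and the packaged
illustrative list (`A61K`, `A61B`, `C12N`, …) exists for tests and demos
only.  Malformed records in a multi-million-document stream are skipped
with a logged warning rather than aborting the run; a file yielding zero
parseable records is an error.

Two dialects are supported: a simplified patent XML (one `<patent>` element
with `doc-number`, `date` as YYYYMMDD, text sections, repeated `uspc`/`cpc`
children) and a JSON-lines record dialect with the same field names.
Historical bulk-archive formats are out of scope.

## Concept recognition and PheCode rollup

Disease mentions are found by deterministic dictionary matching: greedy
longest match, left to right, case-insensitive, on token boundaries, in
title, abstract, and claims (the three sections weighted equally).  A
shorter term inside an accepted longer match is suppressed, so
"type 2 diabetes mellitus" yields one mention even when the lexicon also
contains "type 2 diabetes" and "diabetes mellitus".  The lexicon is an
input file (term → CUI), so a thesaurus-derived lexicon can be dropped in.

Each CUI rolls up through CUI → ICD-9-CM → PheCode → root PheCode tables.
A rollup is *definitive* when exactly one root PheCode remains (one-to-one
or many-to-one) and *ambiguous* otherwise.  The default annotation policy
keeps every candidate root of an ambiguous rollup (`all`); `drop` discards
ambiguous mentions for sensitivity analysis.  The mapping audit reports the
definitive percentage over mapped CUIs, with unmapped CUIs counted
separately (an all-unmapped set has an undefined percentage, reported as
such).  An optional ICD-10-CM → ICD-9-CM bridge supports claims-derived
tables that switched coding systems.

## Coverage

Coverage of disease *d* in year *t* is the number of documents mentioning
*d* divided by the number of documents mentioning at least one disease that
year.  Counting is document-level: ten mentions in one document count once.
The denominator reading "documents mentioning any disease" keeps a
single-disease coverage ≤ 1 and makes shares behave like percentages; the
alternative reading (all biomedical documents in the year) is available via
`denominator="all"`.  Zero-denominator years are dropped rather than
divided by zero.  Top-k rankings order by mean-over-years (or final-year)
coverage with lexicographic tie-breaks for determinism.

## ROI and PHI

Raw measures Y (burden as treatment cost per million people; publication,
trial, and patent counts) are inflation-prone and unit-incommensurate, so
each measure-year is normalized to shares: `X_nd(t) = Y_nd(t) / Σ_d'
Y_nd'(t)`.  This share normalization is invariant to rescaling any
measure-year by a positive constant, which is the point.

The composite resource share is `R_d = w_r X_rd + w_c X_cd + w_p X_pd`,
equal weights by default (weights are config and must sum to 1).

**ROI** is the signed fold ratio ρ = X_bd / R_d: `+ρ` when ρ ≥ 1
(understudied; burden share exceeds resource share) and `−1/ρ` when ρ < 1
(overstudied).  The form satisfies: +1 at exact alignment, |ROI| ≥ 1,
sign(ROI) = sign(X_b − R), antisymmetry under swapping burden with
resources, and magnitude growing with misalignment.  Zero shares produce
explicit sentinels (`overstudied-unbounded`, `understudied-unbounded`,
`undefined`) with NaN values rather than infinities, keeping tabular
exports well defined.  The functional form is isolated in `roi()` /
`phi()` so an alternative index definition can be substituted without
touching callers.

**PHI(t) = ½ Σ_d |X_bd(t) − R_d(t)|** is the total-variation distance
between the burden share distribution and the composite resource share
distribution: 0 iff perfectly aligned, at most 1, monotone under any
transport of resource share toward the burden distribution, and comparable
across years because both arguments are normalized within the year.

**VIF** regresses each measure's cross-disease share vector (with
intercept) on the other three and reports 1/(1 − R²).  Disease-year rows
are pooled over years by default, with a per-year option.  A constant
vector reports VIF 1 (nothing to inflate); perfect collinearity reports
infinity with a warning.

## Dynamic topic model

The model: K topics; per slice t (calendar years), topic k emits terms from
`beta[t,k] = softmax(eta[t,k])`, and the natural parameters evolve as a
Gaussian random walk, `eta[t,k] ~ Normal(eta[t-1,k], sigma·I)`.  Documents
mix topics with proportions `theta[d]` smoothed by a Dirichlet-style
pseudo-count `alpha`.  Defaults `alpha = 0.01`, `sigma = 0.005`, `K = 10`
(with per-disease overrides; coherence-selected optima differ by disease).
A smaller sigma ties the slices together; sigma = 0 is handled as an exact
special case in which all slices share one closed-form smoothed topic-term
distribution (pseudo-count 1e-3), and K = 1 with sigma = 0 degenerates to
the corpus-wide term distribution.

Inference is a generalized EM on the penalized objective

    L = Σ_dv n_dv log Σ_k theta_dk beta_{s(d),k,v}
        + alpha Σ_dk log theta_dk
        − 1/(2 sigma) Σ_tk ||eta_tk − eta_{t−1,k}||²

E-step: exact token-level responsibilities.  M-step: `theta ∝ N_dk +
alpha` in closed form; `eta` by up to 8 backtracking gradient-ascent steps
per topic per epoch with initial step 1/(max slice mass + 4/sigma), which
never decreases the objective.  The recorded trace is therefore
nondecreasing up to float noise, and identical inputs plus seed give
bitwise-identical fits (initialization draws one per-topic perturbation
shared across slices so the chain penalty starts at zero).  Early stop when
the objective changes by less than `tol_per_token` per token; otherwise the
best fit is returned with `converged=False` and a warning.  This is a
self-contained implementation of the model family, not a port of any
particular variational Kalman-filter code; the drift contract (monotone
between-slice divergence in sigma, collapse as sigma → 0) is what the tests
pin down.

**Coherence.** UMass intrinsic coherence over a topic's ranked top-N terms:
`Σ_{i<j} log[(D(w_i,w_j) + 1)/D(w_j)]`, with D(·) document occurrence and
co-occurrence counts from the modeled corpus.  Per-slice scores are
averaged with equal weights, then over topics.  A term absent from every
document takes denominator 1 (extending the +1 smoothing), rather than
dividing by zero.  Topic-number selection fits each K on a grid (default
2–20 step 2), averages mean coherence over `seeds_per_k` refits, and picks
the maximizer, ties toward smaller K; a failing K is skipped with a
warning.  Model selection uses 60 EM epochs and 3 seeds per K by default —
averaging over restarts is what makes the coherence curve stable enough to
rank neighboring K values.

**Preprocessing** order is fixed and deterministic: (1) concept recognition
and CUI substitution (so multiword concepts survive as atomic tokens),
(2) tokenization on non-alphanumeric boundaries, (3) lowercasing,
(4) stop-word removal, (5) suffix-rule lemmatization.  The lemmatizer is a
small ordered rewrite table (e.g. `ing→`, `ed→`, `ies→y`, identity guards
like `ss→ss`) with a 3-character minimum stem, chosen over a statistical
lemmatizer for reproducibility; the rule file is swappable.  CUI tokens are
exempt from lowercasing and lemmatization.  Documents emptied by
preprocessing or vocabulary filtering are dropped with a logged count.

## Synthetic data and what the tests show

The generator writes real files in the pipeline's external formats so I/O
code is exercised by every recovery test, and exports the planted truth
needed to predict each stage's output without rerunning the generator.

- **Corpus**: filler tokens drawn from block-structured per-slice topic
  distributions (0.85 of each topic's mass on its own vocabulary block,
  0.15 uniform — the well-separated regime); one unique three-word disease
  term per CUI inserted per document with its mention probability;
  allowlisted codes with probability `biomedical_fraction` (0.11 in the
  filter experiments, echoing the roughly one-in-nine biomedical share of
  granted patents); bait documents dated outside the window.  An optional
  drift schedule ramps one keyword's probability linearly across slices.
- **Mappings**: each CUI maps through one ICD-9 branch to one root; an
  `ambiguity_fraction` of CUIs (Bernoulli-sampled) gets a second branch to
  a different root.  The audit experiment uses fraction 0.016 at 10,000
  CUIs, i.e. a 98.4% definitive rate at the construction level.
- **Measures**: planted folds f_d are realized by solving for resource
  shares R on the simplex with Σ f_d R_d = 1 (a two-group reweighting), so
  X_b = f·R is itself a share vector and the pipeline ROI recovers ±f_d
  exactly in the noiseless case.  All-understudied or all-overstudied fold
  patterns cannot renormalize and raise.  Noise models: Poisson for
  count-like sampling, log-normal multiplicative (sd 0.25 on the log
  scale) for cost-like measures; the demo preset uses log-normal noise so
  its VIF audit reflects partially correlated rather than duplicated
  measures.
- **Demo preset**: 3 years × 200 documents × 8 diseases × 3 topics; the
  full pipeline runs end to end in seconds.

Problem sizes in the test suite (5,000 documents for the filter experiment,
10,000 CUIs for the audit, 150–300 documents and vocabularies of 60–80
terms for topic experiments, 20 seeds for every stochastic claim) are
chosen so the statistical claims have the stated power while the whole
suite stays fast.

Passing these tests shows the machinery is correct on data matching the
generator's assumptions: disease terms that never collide with filler text,
noise exactly Poisson/log-normal, topics genuinely block-separated.  Real
patent text has none of these guarantees — recognition misses name
variants, topics overlap heavily, and measure noise is structured — so the
recovery rates here are upper bounds on behavior, not field performance.

## Known limitations

- The dictionary recognizer does no word-sense disambiguation, negation
  handling, or abbreviation expansion.
- ROI is undefined (sentinel) when either share is zero; downstream
  consumers must handle the sentinel column.
- The DTM is fitted with dense per-slice matrices; corpora beyond roughly
  10⁵ documents × 10⁴ terms per slice need a sparser E-step.
- UMass coherence is the only built-in coherence flavor; sliding-window
  variants would need a tokenized corpus, which the fit does not retain.
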