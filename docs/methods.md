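# Methods

## Problem and model

Coded electronic-health-record (EHR) data — diagnosis, procedure, lab and
medication codes recorded on patient-days — carry rich information about
which clinical concepts are related, but patient-level records cannot be
shared across institutions. This package implements a pipeline that (i)
compresses patient-level event streams into code embeddings that contain no
patient data, and (ii) extracts clinical knowledge from the embeddings
alone by sparse regression, so that multi-center analyses can run on
shareable summaries.

### From events to embeddings

Events are deduplicated to one record per (patient, code, day). For each
patient, every occurrence of a target code on day *t* is paired with every
code occurrence in the forward window [*t*, *t* + *w*] (default *w* = 30
days; 7 and 60 are supported for sensitivity analysis). The directed tally
plus its transpose gives the symmetric co-occurrence matrix ℂ = [C(w,c)] —
identical to counting within ±*w* days. Same-day unordered pairs are
counted once before symmetrization so that each contributes one unit to
C(w,c) and C(c,w); same-code pairs on different days fall on the diagonal
under the literal "directed + transpose" rule (two units per pair), and
the diagonal participates in the marginals but is never a regression
candidate.

The shifted positive pointwise mutual information of a pair is

    SPPMI(w,c) = max{ log[ C(w,c)·|D| / (C(w,·)·C(c,·)) ] − log k, 0 }

with C(w,·) the row sum, |D| the grand total, and shift k ≥ 1 (default 1,
i.e. no shift; the shift corresponds to the negative-sample count of
skip-gram training, for which this factorization is an efficient
surrogate). Zero-count cells map to 0, never −∞.

The embedding of code *w* is the *w*-th row of V_d = U_d·diag(√λ_1…√λ_d),
where U_d holds the top-d singular vectors of the SPPMI matrix. Because
the matrix is symmetric, singular triplets are computed from a full dense
symmetric eigendecomposition ordered by |eigenvalue| (stable sort), with
each vector's sign fixed by making its largest-magnitude entry positive.
This choice — rather than an iterative sparse solver — makes the output
bit-for-bit reproducible and makes truncation exact: the d′-dimensional
embedding is literally the first d′ columns of the d-dimensional one, so a
single high-dimensional factorization serves every downstream task.
Vocabularies here are at most a few thousand codes, where the dense
decomposition is cheap. The SPPMI matrix may be indefinite; V·diag(s)·Vᵀ
with the recorded eigenvalue signs s reconstructs it exactly at full rank,
while V·Vᵀ is only an approximation when negative eigenvalues are present.

Embedding dimension can be chosen three ways: smallest d retaining 95% of
spectral variation (cumulative squared singular values by default; an
unsquared convention is available by flag since either reading is
defensible), or maximizing SNR(d) = W_d/S_d (mean known-pair over mean
random-pair cosine) or the AUC of known vs. random pairs on a grid, with
ties going to the smallest d.

### Sparse embedding regression

The statistical model treats the embedding vectors as a Gaussian graphical
model: the vector of code *w*, conditional on all other code vectors at
site *m*, is Gaussian with mean Σ_c B_wc^(m) V_c^(m) and isotropic
variance σ_m². The support of the symmetric B^(m) encodes conditional
dependency, so selecting nonzero B_wc identifies the codes related to *w*.

Candidates are pre-screened by marginal cosine: code *c* enters Ω^(m) only
if cos(V_w, V_c) reaches ρ, the upper-5% quantile of cosines among random
pairs of the same relation type (PheCode–PheCode, PheCode–RXNORM, …),
computed globally per type (not per target) from a seeded null sample of
1000 pairs by default. `alpha=None` disables screening, which is the right
choice for vocabularies too small to estimate null quantiles. When
multiple PheCode granularity levels coexist, the one-digit level can be
retained (`filter_phecode_levels`) to reduce collinearity among
candidates.

Single-site objective (exactly as the model states it — no ½ or 1/n
factors, so penalty grids are on the model's own scale):

    ‖V_w/‖V_w‖ − Σ_c B_wc V_c/‖V_c‖‖²
      + λ₁ Σ_c |B_wc| / |cos(V_w,V_c)| + λ₂ Σ_c B_wc²

solved by cyclic coordinate descent on the Gram form 1 − 2bᵀr + bᵀGb,
where r is the target–candidate cosine vector and G the candidate cosine
Gram matrix. Each coordinate update is the exact scalar minimizer
(soft-threshold over an elastic-net denominator), so the objective is
non-increasing per sweep; convergence is declared when the largest
coordinate step falls below 1e-10 (cap 2000 sweeps, non-convergence
returned with a flag and warning). The adaptive weights 1/|cos| are capped
at 1/ρ_min as a safety net against division blow-up on unscreened
candidate sets (screening normally keeps |cos| ≥ ρ).

Multi-site objective: per-site losses of the same form plus, per candidate
code c,

    λ₁ · ‖(B_wc^(m))_m‖₂ / ( max_m |cos_m(V_w,V_c)| · √(#sites with c) )
      + λ₂ Σ_m (B_wc^(m))² ,

with B_wc^(m) structurally zero where c failed site m's screen. The group
lasso pools evidence across sites — a code selected when its cross-site
coefficient group has nonzero norm — while per-site coefficients absorb
magnitude heterogeneity. Solved by block coordinate descent over cross-site
groups; each block update is an exact group soft-threshold. With M = 1
the penalty reduces algebraically to the single-site form, and the two
solvers agree to 1e-6 (tested).

### Penalty tuning

Embedding coordinates are not independent replicates, so cross-validation
over coordinates would be invalid. Instead, a second embedding set is
built from held-out patients (disjoint-patient split of the events), and
the penalties minimize the basis-free validation loss 1 − 2bᵀr_v + bᵀG_v b
computed from validation cosines only — the two factorizations need not
share a basis. The grid defaults to 20 log-spaced λ₁ values spanning three
decades down from the data-derived λ₁_max (the smallest penalty that
zeroes everything, from the KKT threshold) × 5 log-spaced λ₂ in [1e-4, 1],
solved warm-started along the λ₁ path.

Selection rule: among grid points whose validation loss is within 1% of
the minimum, the sparsest fit wins, then the smaller λ₂. This is a
one-standard-error-style rule adapted to a deterministic loss: a spurious
noise-level coefficient moves the validation loss by O(1/d) — well inside
the tolerance — while a genuine signal moves it by its squared
coefficient, well outside. Without it, prediction-optimal tuning keeps
noise-level coefficients and the node-wise network acquires spurious
transitive edges.

### Networks, evaluation, translation

The knowledge network runs the tuned (integrative) regression with every
code in a chosen subset as target and aggregates selected neighborhoods.
Node-wise fits can disagree on an edge's two directions; edges are
symmetrized by union by default (the "OR" neighborhood-selection
convention — the model assumes symmetric support, so either direction is
evidence), with "AND" available. Per-target randomness is keyed by a hash
of the target code, so the edge set is invariant to iteration order;
per-node failures are recorded in a manifest instead of aborting.

Embedding quality is scored against curated relation pairs by cosine
similarity: AUC (Mann–Whitney, ties one-half) and sensitivity at FPR ∈
{0.01, 0.05, 0.10} against random same-type pairs (default 10× the known
count). The null-quantile threshold uses "higher" interpolation with
strict exceedance, guaranteeing realized FPR ≤ nominal on the null
sample. Unresolvable curated pairs are counted and reported, not silently
dropped.

Cross-site code translation fits the orthogonal Procrustes minimizer
Q = argmin ‖V_tgt − V_src·Q‖_F over row-normalized shared-code matrices
(closed form via SVD) and ranks target codes by cosine with the mapped
query, restricted to the query's code-type namespace by default (a
medication query ranks against medications; full-vocabulary ranking by
flag), ties broken lexicographically.

## Synthetic data

The generators produce the dependency structure the method consumes, with
ground truth recorded:

* **GGM embeddings** — a random regular support graph (exactly
  `n_neighbors` planted neighbors per code) with constant positive edge
  weight; precision Ω = (I − B)/σ², positive definite whenever
  `n_neighbors × edge_magnitude < 1` (checked, with a constructive error
  otherwise). Columns are sampled i.i.d. through the Cholesky factor of
  Ω⁻¹, computed once. Defaults: p = 100 codes, d = 1000 dimensions, 5
  neighbors, edge 0.15, σ² = 1 — edge magnitude three to five standard
  errors (≈ 1/√d) above the noise floor, the regime where recovery is
  expected but not trivial. Positive edge weights are used because the
  screening step is one-sided in cosine.
* **Two-site embeddings** — shared support, each edge strong (0.2) at one
  randomly chosen site and weak (0.04, near the d = 800 noise floor) at
  the other, so neither site alone sees all edges clearly and pooling
  pays; p = 60, 4 neighbors keeps every configuration positive definite.
  A `site_vocab_fraction` knob drops codes per site to exercise
  site-specific availability.
* **Patient events** — 20 codes in 4 latent conditions; each of 2000
  patients activates each condition with probability 0.4, an active
  condition emits Poisson(2) events per member code within 30 days of a
  uniform onset, on top of Poisson(0.3) uniform background events over a
  360-day horizon. Condition-mates therefore co-occur within the counting
  window at elevated rates.

What these generators do **not** emulate: realistic code-frequency skew,
visit/encounter structure, billing semantics, non-Gaussian embedding
noise, or negative conditional dependencies. Passing tests show the
pipeline recovers the structure it models, at desk scale — not that it
reproduces any particular institution's numbers, which require
patient-level data of a different order of magnitude.

## Verification scale and results computed

The test suite and `scripts/acceptance.py` run everything from scratch at
the scales above: support recovery averaged over 10 seeds × 30 targets
(sensitivity ≥ 0.8 at FPR ≤ 0.05 is the bar; observed ≈ 0.95 at ≈ 0.003),
integrative-vs-single-site over 20 replicates × 15 targets (integrative
sensitivity at least each site's in ≥ 15/20; observed 20/20), the
events-to-embedding pipeline over 10 seeds (within-group AUC ≥ 0.9;
observed 1.0), and 3-code chain network recovery over 20 replicates
(exactly the two planted edges, no transitive edge, in ≥ 18/20; observed
20/20). Exact primitives (SPPMI hand value, reconstruction, truncation,
closed-form and optimizer-checked solver solutions, KKT residuals,
Procrustes recovery, rank statistics) are held to 1e-6–1e-12.

## Numerical choices and edge cases

* Eigenvalue ties in the factorization resolve by stable sort order;
  zero singular vectors get sign +1.
* Codes with zero marginal count yield all-zero SPPMI rows with a
  warning, not an error; zero-norm vectors make cosine undefined and
  raise, naming the code.
* `frequency_filter` is strict (count > threshold) by default, matching
  thresholds quoted as ">1000"; counts are over deduplicated patient-day
  records (raw-row counting is available by ingesting with
  `deduplicate=False`).
* The patient split ranks a keyed hash of patient ids, so it is exact in
  size, deterministic in the seed, and independent of row order.
* Null-pair sampling is without replacement with an explicit error when
  the request exceeds the number of distinct pairs.

## Known limitations

* Dense factorization bounds the practical vocabulary at ~10⁴ codes on a
  laptop; the co-occurrence and SPPMI stages are sparse throughout and do
  not share this bound.
* The tuning procedure (grid + validation loss + 1% sparsity tolerance)
  is this package's documented choice; other tuning recipes for the same
  objectives would select slightly different supports.
* Screening is one-sided: codes related through strong negative marginal
  cosine are not admitted as candidates.
* The group weight treats sites symmetrically; with grossly unbalanced
  site qualities a site-weighted loss would be preferable.
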