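# keser — clinical knowledge extraction via sparse embedding regression

Coded electronic-health-record data (PheCode diagnoses, RxNorm
medications, CCS procedures, lab codes) contain rich signal about which
clinical concepts are related, but the patient-level records carrying that
signal cannot be shared across institutions. This package compresses
longitudinal event streams into **code embeddings** that contain no
patient data, then extracts relatedness from the embeddings alone by
**sparse embedding regression** — per site, or integratively across sites
— and assembles the results into a clinical knowledge network. It is
aimed at EHR methodologists and phenotyping teams who need candidate
feature lists and code-relatedness graphs without moving patient data.

## The model

1. **Co-occurrence → SPPMI → SVD.** Events are deduplicated to one record
   per (patient, code, day); codes co-occurring within a 30-day window are
   counted into a symmetric matrix ℂ = [C(w,c)], from which the shifted
   positive pointwise mutual information is

   SPPMI(w,c) = max{ log[ C(w,c)·|D| / (C(w,·)·C(c,·)) ] − log k, 0 },

   with k = 1 by default. Embeddings are rows of
   V_d = U_d·diag(√λ₁,…,√λ_d) from the top-d singular triplets of the
   SPPMI matrix — an efficient surrogate for skip-gram training with
   negative sampling. Lower dimensions are exact truncations of higher
   ones, so one factorization serves every task.

2. **Sparse embedding regression.** Embedding vectors are modeled as a
   Gaussian graphical model: V_w | {V_c} ~ N(Σ_c B_wc V_c, σ²I). After
   screening candidates by marginal cosine against the upper-5% quantile
   ρ of random same-type pairs, the single-site fit solves an adaptive
   elastic net

   min_B ‖V_w/‖V_w‖ − Σ_c B_wc V_c/‖V_c‖‖² + λ₁ Σ |B_wc|/|cos(V_w,V_c)| + λ₂ Σ B_wc²,

   and the multi-site fit adds a cross-site group-lasso penalty
   λ₁·‖(B_wc^(m))_m‖₂ / (max_m|cos_m|·√#sites) + ridge, pooling evidence
   across sites while letting magnitudes differ. Nonzero coefficients are
   the codes related to the target; running every code as target and
   symmetrizing the selected neighborhoods yields the knowledge network.
   Penalties are tuned on embeddings built from held-out patients.

3. **Cross-site translation.** An orthogonal Procrustes map fitted over
   shared codes aligns two sites' embedding spaces, translating
   site-specific codes with top-k accuracy reporting.

## Worked example

Everything below runs in seconds from a fresh checkout; the synthetic
module supplies data with known ground truth.

```python
import warnings; warnings.simplefilter("ignore")
from keser import screen, tune_single_site
from keser import synthetic

# Embeddings drawn from a Gaussian graphical model: 100 codes, 1000
# dimensions, 5 planted neighbors per code; a second, independent draw
# from the same model plays the held-out-patient validation set.
emb_train, truth = synthetic.simulate_ggm_embeddings(
    p=100, d=1000, n_neighbors=5, edge_magnitude=0.15, seed=7)
emb_valid, _ = synthetic.simulate_ggm_embeddings(d=1000, seed=8, spec=truth.ggm)

target = "PheCode:000"
s = screen(emb_train, target, alpha=0.05, n_null=1000, seed=0)
res = tune_single_site(emb_train, emb_valid, target, screen_set=s)
print(res.summary())
print("planted neighbors:", sorted(truth.neighbor_codes(target)))
```

```
Sparse embedding regression (single site)
=============================================
target:       PheCode:000
candidates:   4  (selected: 4)
lam1, lam2:   0.000752771, 0.1
objective:    0.863315
converged:    True (6 sweeps)
valid. loss:  0.875203
---------------------------------------------
code                                  coef
PheCode:007                        0.18424
PheCode:082                        0.18225
PheCode:046                        0.14382
PheCode:044                        0.12609

planted neighbors: ['PheCode:007', 'PheCode:019', 'PheCode:044', 'PheCode:046', 'PheCode:082']
```

Four of the five planted neighbors pass the cosine screen and all four
are selected with no false positives; the coefficients estimate the
planted conditional-dependency weights (0.15 each, up to sampling noise).
The missed neighbor fell below the screening threshold in this draw.

The front half of the pipeline — events to validated embeddings — runs
the same way:

```python
from keser import count_cooccurrence, compute_sppmi, factorize, evaluate
events, truth = synthetic.simulate_patient_events(n_patients=2000, seed=7)
C = count_cooccurrence(events, window_days=30, vocab=truth.vocab)
emb = factorize(compute_sppmi(C, k=1.0), d=20)
report = evaluate(emb, truth.known_pairs, seed=0)[0]
print(f"{report.pair_type} ({report.relation_class}): AUC {report.auc:.3f}, "
      f"sensitivity at 5% FPR {report.sensitivity_at[0.05]:.3f}")
```

```
PheCode-PheCode (similar): AUC 1.000, sensitivity at 5% FPR 1.000
```

Codes belonging to the same latent condition co-occur within the window
at elevated rates, and their embedding cosines separate them perfectly
from random pairs at this signal strength.

A `keser` command-line tool mirrors the library
(`keser ingest`, `cooccur`, `embed`, `eval`, `fit`, `integrate`,
`network`, `translate-fit`/`translate-eval`, `simulate`); every artifact
is plain text (TSV, MatrixMarket, JSON) so the commands compose.

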