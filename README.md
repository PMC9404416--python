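# herdfert

Genetic parameters for dairy-cattle fertility traits derived from on-farm
artificial-insemination (AI) service records.

Dairy herds that record every AI event, calving and pregnancy diagnosis can
measure female fertility far earlier and more directly than the
calving-interval traits used in many national evaluations.  `herdfert`
implements the full pipeline for such data:

1. **Trait derivation** — nine heifer/cow fertility traits from raw
   service-event tables, with the standard biological edit rules:

   | trait | class | definition |
   |-------|-------|------------|
   | AFS   | heifer | age at first service (months) |
   | AFC   | heifer | age at first calving (months) |
   | SPCh  | heifer | services per conception |
   | CFS   | cow | calving to first service (days), kept in [21, 250] |
   | DO    | cow | days open: calving to conception (days), kept in [21, 435] |
   | SPC   | cow | services per conception |
   | FS80d | cow | served within 80 d post-partum (1 = no, 2 = yes) |
   | PD100d| cow | pregnant within 100 d post-partum (1 = no, 2 = yes) |
   | PD200d| cow | pregnant within 200 d post-partum (1 = no, 2 = yes) |

2. **Pedigree algebra** — inbreeding coefficients (Meuwissen–Luo recursion),
   the dense numerator relationship matrix **A** (tabular method) and sparse
   **A⁻¹** (Henderson's rules with inbreeding).

3. **Multi-trait animal models** — for traits *y*, the mixed model
   `y = Xb + Za + Wpe + e` with contemporary-group (herd-year-season),
   parity and age fixed effects, additive values `a ~ N(0, A ⊗ G₀)`,
   permanent-environment effects `pe ~ N(0, I ⊗ P₀)` for repeated cow
   records, and residuals `e ~ N(0, I ⊗ R₀)`.  Binary success traits are
   modelled on a latent liability with a threshold at zero.  Estimation is
   Bayesian via a compiled single-site Gibbs sampler that handles linear and
   threshold traits simultaneously; an AI-REML fitter is provided as an
   independent cross-check for all-linear models.  Heritability is
   `h² = σ²ₐ/(σ²ₐ + σ²ₚₑ + σ²ₑ)` (the σ²ₚₑ term only for repeated-record
   traits); genetic correlations come from `G₀` and phenotypic correlations
   from `G₀ + P₀ + R₀`.

4. **Synthetic herds** — an event-level reproduction simulator (21-day heat
   cycles, heat-detection failures, per-service conception linked to a
   heritable fertility liability, 260–302 d gestation) with a truth ledger,
   so every pipeline stage is testable without farm data.

## Worked example

```python
from herdfert import HerdSimConfig, simulate_herd, derive_phenotypes, AnimalModel

cfg = HerdSimConfig(n_founders=300, n_generations=3, generation_size=600,
                    n_sires=30, seed=7)
ped, records, truth = simulate_herd(cfg)
phenotypes, edit_log = derive_phenotypes(records)
model = AnimalModel(phenotypes, ped, traits=["CFS", "DO", "PD100d"])
result = model.fit(method="gibbs", n_iter=30_000, burn_in=8_000, thin=10, seed=1)
print(result.summary())
```

prints

```
Multi-trait animal model (Gibbs)
  traits: CFS, DO, PD100d  (threshold: PD100d)
  records: 2256   animals in pedigree: 1443
  chain: 30000 cycles, burn-in 8000, thinning 10, seed 1

  trait          h2       sd
  CFS         0.035    0.011
  DO          0.119    0.006
  PD100d      0.126    0.007

  genetic (above) / phenotypic (below) correlations:
                CFS       DO   PD100d
  CFS             .    0.801   -0.798
  DO          0.389        .   -1.000
  PD100d     -0.384   -1.000        .
```

Heritabilities of fertility traits are low, as expected for this trait
class: here conception carries a heritable liability, so days open (DO) and
pregnancy-by-100-days (PD100d) show moderate h², while calving-to-first-
service (CFS) — driven by heat detection and the voluntary waiting period in
the simulator — is barely heritable.  PD100d is defined by thresholding DO
at 100 days on the same records, so their correlations approach −1 (yes is
coded 2, and small DO means early pregnancy).  The same analysis runs from
the command line: `herdfert simulate / derive / fit / report`, each step
writing a manifest (config snapshot, input checksums, seed, record counts)
that makes the run exactly reproducible.

`result.diagnostics()` gives effective sample sizes and Geweke scores per
variance component; `tables.write_results(result.summarize(), ...)` writes
the trait-by-trait matrix (h² on the diagonal, genetic correlations above,
phenotypic below) plus a long-format table.

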