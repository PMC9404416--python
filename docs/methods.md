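# Methods

## Trait derivation

Raw data are per-animal reproductive event histories: services (AI events),
calvings with lactation numbers, and veterinary pregnancy diagnoses.  A
*service episode* is the run of services before the first calving (the
heifer episode) or between consecutive calvings.  Conception is attributed
to the **last service of an episode**, confirmed either by the next calving
falling 260–302 days later (the biological gestation window for Holsteins)
or, when no later calving exists, by a pregnant diagnosis after that service
with no later service in the episode.  Unconfirmed conceptions leave
SPCh/SPC/DO and the pregnancy success traits missing — censoring, never
zero-filling.  This attribution rule is a convention: service outcome codes
on farm software are not reliable enough to define conception on their own,
and the gestation-window check is the standard fallback.

Ages are reported in months as `days / 30.4375` (the mean Gregorian month)
rounded to one decimal; all day intervals are exact integer-day arithmetic
on proleptic-Gregorian ordinals.  Success traits are coded 1 = no, 2 = yes
with inclusive windows (`CFS ≤ 80`, `DO ≤ 100`, `DO ≤ 200`).

Editing removes: values outside the biological bounds (CFS 21–250 d,
DO 21–435 d, and descriptive-range limits AFS 10–30 mo, AFC 20–48 mo,
SPCh/SPC 1–8 for the remaining traits); rows of animals with an unknown sire
or dam (their additive effect would be confounded with the base population);
and contemporary groups smaller than `min_size` (default 3, so that no group
is identified by a single animal's record).  Seasons are summer =
October–March, winter = April–September (southern hemisphere); contemporary
groups are herd-year-season of birth for heifer traits and of calving for
cow traits.  Every removed row or value appears exactly once in the edit
log with a machine-readable reason.

One cow row is produced per calving; its parity is the lactation number of
the initiating calving plus one (the parity being created), so cow rows have
parity ≥ 2 and heifer rows parity 1.

## Pedigree algebra

Inbreeding uses the Meuwissen–Luo ancestor-tracing recursion
(`F_i = Σ_j L²_ij d_j − 1`); the dense numerator relationship matrix A uses
the tabular method; sparse A⁻¹ uses Henderson's rules with
inbreeding-adjusted Mendelian-sampling variances
(`d_i = 0.5 − 0.25(F_s + F_d)`, with 0.75 − 0.25 F for one known parent and
1 for founders).  Unknown parents are unrelated base-population founders; no
genetic groups are fitted.  Dense A is limited to ~6,000 animals; the
mixed-model path only ever forms sparse A⁻¹.  `a_inverse(assume_noninbred=True)`
is provided as an oracle toggle.

## The animal model and its sampler

Per trait the fixed effects are the contemporary group (always; the CG
factor carries all levels and doubles as the intercept), a parity class
(2, 3, 4, 5+; cow traits only), and an age covariate (age at first
insemination for the heifer conception count, age at calving for cow
traits), centred.  Records map to animals through the pruned pedigree;
repeated cow records share a permanent-environment (pe) level.

A single compiled Gibbs kernel runs the whole chain under one seeded random
stream (bitwise reproducibility).  Per cycle:

1. **Augmentation.**  Missing trait values are drawn from their Gaussian
   conditionals given the record's other traits under R₀; binary records'
   latent liabilities are drawn from one-sided truncated normals (category
   1 below the zero threshold, 2 above), using normal rejection in the body
   and exponential rejection in the tail.  Records are kept, never dropped,
   across the heifer/cow trait split.
2. **Locations.**  Fixed-effect factors are updated level-by-level (levels
   are disjoint, so a factor is one exact block draw); additive and pe
   effects are single-site draws over the sparse A⁻¹ and identity priors.
3. **Covariances.**  G₀ | a is inverse-Wishart with scale `a' A⁻¹ a` over
   all pedigree animals; P₀ | pe likewise with `pe' pe`.
4. **Residuals.**  With no threshold traits, R₀ | e is inverse-Wishart on
   `e'e`.  With threshold traits, their residual variances are fixed at 1
   (liability identifiability) and their residual covariances with each
   other at 0; the free elements are drawn exactly through the conjugate
   regression factorization `e_lin | e_thr ~ N(Γ' e_thr, Ω)` (Γ
   matrix-normal, Ω inverse-Wishart), and R₀ is reassembled as
   `[[Ω + Γ'Γ, Γ'], [Γ, I]]`.  The factorized form is used instead of the
   sample-then-rescale device because naive rescaling is not a valid Gibbs
   move — in testing it made the liability scale drift without bound.  The
   price is that residual covariances *among* binary traits are pinned to
   zero; their phenotypic correlations then come from G₀ and P₀ only.

Priors default to **flat** on all covariance matrices (the convention of the
established Gibbs samplers in this field), under which posterior means track
REML closely; a proper weakly-informative inverse-Wishart option
(df = dim + 1, scale 0.1 × phenotypic variances) is available for small
datasets.  Chains default to 300,000 cycles with a 50,000-cycle burn-in and
thinning 10; the validation studies use 20,000/4,000 (40,000/10,000 where a
pe effect must separate from the additive effect, a direction that
single-site updates traverse slowly).

A known property of threshold **animal** models, reproduced here and
verified independently with JAGS on identical data, is that one binary
record per animal leaves the liability scale so weakly anchored that the
additive-variance posterior is effectively unusable (it wanders to extreme
values).  Repeated binary records with a pe effect — the structure fertility
data actually have, since success traits recur across lactations — anchor
the scale well, and all binary-trait validation studies use that structure.

## AI-REML cross-check

For all-linear models on complete records, `fit(method="reml")` maximizes
the restricted likelihood on the dense phenotypic covariance
`V = A_rec ⊗ G₀ + Pe ⊗ P₀ + I ⊗ R₀` with average-information updates,
step-halving back into the parameter space, and convergence at a relative
log-likelihood change below 1e−8.  Asymptotic standard errors come from the
inverse AI matrix; a near-singular AI matrix triggers an identifiability
warning (e.g. unrelated founders with single records in one group).  The
dense formulation is deliberately simple — it is the *oracle* for the Gibbs
sampler, capped at ~8,000 record-trait cells, not a production REML.

When comparing the two fits, note that the Gibbs posterior mean and the REML
maximizer are different estimators: for a variance with effective degrees of
freedom ν their gap is ≈ 3/√(2ν) posterior SDs (posterior skewness).  The
validation study therefore asserts agreement within 2 posterior SDs — the
scale at which the estimators are exchangeable — and reports the
Monte-Carlo-SE ratios alongside (they exceed 2 whenever the chain's ESS
grows past ~ν, for any exact sampler).

## Synthetic herds

The pedigree generator produces discrete generations with a small male pool
per generation, giving paternal half-sib families plus parent–offspring
links across generations.  Breeding values follow the Mendelian-sampling
recursion (founders ~ N(0, G₀); offspring = parent mean + deviation with
variance d_i·G₀), so `cov(a) = A ⊗ G₀` without ever forming dense A.

`simulate_phenotypes` generates records under the exact estimation model —
CG effect + additive + pe + residual, binary traits by thresholding the
latent liability at 0 — and is what the recovery studies invert.

`simulate_service_records` is event-level: first service at a rearing-policy
age (default 16.5 months ± 60 d); heats every 21 ± 3 d, each detected with
probability 0.55; conception per service is Bernoulli with probability
Φ(Φ⁻¹(p₀) + u), p₀ = 0.65 for heifers and 0.45 for cows, where u is an
animal fertility liability (SD 0.3, 30% of its variance transmitted through
the pedigree); gestation is truncated-normal 280 ± 5 d within [260, 302];
the voluntary waiting period is 60 d; episodes stop at 8 services (cull
cap).  These defaults were set once to produce Holstein-like descriptive
statistics (AFS ≈ 16.5 mo, SPCh ≈ 1.6, SPC ≈ 2.2, CFS ≈ 88 ± 26 d,
DO ≈ 132 ± 70 d, about half of cows served by 80 d).  The simulator
bookkeeps every derivable trait value in a truth ledger, and the derivation
stage must reproduce the ledger exactly — this identity is an acceptance
check, not a statistical comparison.

What the event simulator does **not** emulate: seasonal fertility
depression, culling-for-infertility selection bias, herd-level management
differences in the reproduction parameters, recording errors, or a
fertility liability that differs between traits.  Passing tests on
synthetic herds therefore demonstrate algorithmic correctness and
recoverability under the model's own assumptions, not robustness to the
messiness of real farm data.

## Validation study design

Recovery studies use pedigrees of 3,000 animals (2,000 phenotyped) with 100
sires per generation.  The number of sire families dominates the sampling
noise of the *realized* genetic variance (relative SD ≈ √(2/n_families)),
so small sire pools make any single replicate's estimate deviate from the
generating parameter by design, not by error; 100 families keep that noise
near 0.03 in h² units, and each study averages three independent data
seeds.  The oracle-equivalence study uses h² = 0.5, where the additive
variance is strongly identified and both estimators are well conditioned.

## Numerical choices and degenerate inputs

Dates that fail to parse, out-of-order events, unknown event types and bad
lactation numbers reject the row to the edit log, never silently.  Ties in
conception attribution cannot arise (the candidate is unique).  The
inverse-Wishart sampler uses the Bartlett decomposition; a non-positive-
definite scale matrix aborts the chain with its cycle index.  Records are
canonically sorted before design construction, so permuting input rows
leaves results bit-identical under the same seed.  Correlations are computed
per saved iteration and then averaged (ratio-then-average), making the
reported SDs posterior SDs of the derived quantities.

## Known limitations

* Residual covariances among binary traits are fixed at zero (see above);
  between traits never observed on the same record (heifer × cow) they are
  likewise prior-driven, so those phenotypic correlations are close to
  zero by construction — as they are in single-record field analyses.
* The AI-REML path requires complete records and modest sizes.
* Single-site location sampling keeps memory flat but mixes slowly for
  additive-vs-pe; budget longer chains when pe is fitted.
* No genetic groups for unknown parents, no genomic relationships, no
  multiple-chain convergence machinery (single chains by design).
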