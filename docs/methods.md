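# Methods

## Setting and model

`netmr` works in the two-sample summary-statistics setting: the SNP–exposure
and SNP–outcome associations come from non-overlapping studies, and only the
per-SNP marginal estimates (β̂, SE, p, EAF, N) are available.  Writing γ⟨j⟩
for SNP *j*'s effect on the exposure X and θ for the causal effect of X on
the outcome Y, a valid instrument satisfies β⟨Y,j⟩ = θ·γ⟨j⟩, so every SNP's
Wald ratio estimates the same θ.  The estimators, and the selection rule
that enforces that premise, are:

* **IVW** — weighted mean of ratios with weights w⟨j⟩ = β̂⟨X,j⟩²/σ⟨Y,j⟩²,
  SE = (Σw⟨j⟩)^(−1/2).  First-order delta method: exposure-side sampling
  noise is ignored in the weights (the NOME approximation).  Fixed-effect by
  default because selection enforces homogeneity; `random_effects=True`
  inflates the SE by √(Q/df) when Q/df > 1 for users who skip selection.
  Normal reference distribution.
* **Cochran's Q** — Σ w⟨j⟩(ratio⟨j⟩ − θ̂)², χ²⟨n−1⟩ under homogeneity.
  Evaluated at the IVW estimate of the set being tested.
* **MR-Egger** — weighted regression of β̂⟨Y⟩ on β̂⟨X⟩ with free intercept,
  weights 1/σ⟨Y⟩², each SNP first oriented to β̂⟨X⟩ ≥ 0.  The intercept is
  the average direct (pleiotropic) effect; slope and intercept use a
  t(n − 2) reference.  The SEs are the ordinary WLS ones (residual variance
  estimated), which makes the intercept test exactly calibrated under the
  null in the weighted linear model; the common alternative of flooring the
  residual SD at 1 is deliberately not used because it makes the test
  conservative.  Validity rests on the InSIDE assumption, which the package
  does not attempt to verify.
* **Power** — normal-approximation non-centrality √(N·R²·K(1−K))·|ln OR|
  for a binary outcome of case fraction K (√(N·R²)·|β| for a standardized
  continuous outcome), two-sided α, z₀.₉₇₅ = 1.959964.  At OR = 1 the
  formula returns α/2: folding the effect into |ln OR| keeps one rejection
  tail.

## Instrument selection

1. **Association filter**: p ≤ threshold, inclusive (default 5×10⁻⁴; this
   pipeline is meant for sub-genome-wide instrument panels where the
   heterogeneity constraint, not the p-value, does the heavy pruning).
2. **LD clumping**: repeatedly take the smallest-p remaining SNP as index and
   drop same-chromosome SNPs within 500 kb with r² > 0.001 against it.  LD
   is explicit input (3-column table); with no LD table every pair has
   r² = 0 and clumping only orders the records.  Ties break on (p, snp_id)
   so output is deterministic.
3. **Greedy R²-maximizing selection**: seed with the largest per-SNP r²;
   each round add the largest-r² candidate whose augmented set still passes
   Q (p ≥ 0.05 by default); stop when none qualifies.  Per-SNP
   r² = t²/(t² + n − 2) needs no allele frequency and equals the squared
   sample correlation of a simple regression; cumulative R² is the sum
   (SNPs in linkage equilibrium after clumping).  A 1-SNP set has a 0-df Q
   and is treated as passing.  The greedy path is not guaranteed to be the
   global optimum over all subsets; the test suite compares it with
   exhaustive search on small fixtures and reports (rather than hides)
   constructed cases where greediness loses.

## Harmonization

Outcome records are aligned to the exposure's effect allele: swapped alleles
flip the outcome beta's sign and complement the EAF; alleles matching only
as reverse complements are treated as a strand flip (no sign change).
Palindromic SNPs (A/T, C/G) are strand-ambiguous: they are dropped when
either EAF is missing or within 0.08 of 0.5, and otherwise oriented by EAF
concordance.  The 0.08 window is a convention, configurable, and flagged in
the harmonization report; published pipelines differ and no data-driven
choice is attempted.  The merge is an intersection; SNPs absent from either
trait are counted in the report, never imputed.

## Network MR and the mediated proportion

Step I (total effect, exposure instruments selected against the outcome) and
step II (exposure → mediator, same instruments) share the exposure's
instrument set.  Step III re-selects instruments from the mediator's own
associations **excluding SNPs associated with the exposure at the instrument
threshold**: a SNP acting on the mediator through the exposure also reaches
the outcome through the direct exposure path, so it violates the exclusion
restriction for the mediator.  Without this exclusion the step-III estimate
is measurably biased toward the total/a-path ratio (the residual
contaminants are exactly the weak ones whose huge ratio SEs the Q gate
cannot reject).  The bidirectional analysis, by contrast, uses each trait's
own associations symmetrically, matching how reverse-causation checks are
usually run.

The mediated proportion is (β⟨a⟩·β⟨b⟩)/β⟨total⟩ on the log-effect scale.
With a binary outcome all three outcome-side quantities are log-ORs, so the
proportion is a ratio of log-odds effects; the OR−1 convention would give
slightly different numbers and is not used.  A mediator is *declared* only
when steps II and III are both significant at two-sided α = 0.05.  A failed
step II/III yields a partial result with an explicit status, never an
exception.

## Synthetic-data generator

`simulate_gwas` emulates three disjoint cohorts typed at one SNP panel:

* genotypes binomial(2, MAF) under Hardy–Weinberg, MAF ~ U(0.05, 0.5);
  optional adjacent-pair LD via a Gaussian-copula haplotype model (note the
  thresholding attenuates the latent correlation, so genotype r² is well
  below the square of the latent r);
* exposure = genetic score + Gaussian noise, its SNP effects scaled so the
  panel explains exactly `h2_exposure` (default 0.1);
* mediator = θ⟨XM⟩·X + its own genetic score + noise (or the reverse
  ordering when a mediator→exposure effect is requested; both directions at
  once are rejected as circular);
* binary outcome from a logistic model, intercept solved by root-finding so
  the realized prevalence matches the target; directional pleiotropy as
  direct SNP→outcome effects on a configurable fraction of exposure SNPs;
* per-SNP marginals: closed-form OLS for continuous traits, Newton–Raphson
  logistic fits for the outcome.

`mode="summary"` skips individuals and draws the marginal betas from their
asymptotic normal laws on the standardized scale (outcome SE
1/√(N·K(1−K))).  It represents the same two-sample design at consortium
scale and is what the replicate-heavy calibration and recovery tests use
(2,000/1,000/500 replicates complete in seconds); those tests run at
consortium-sized studies (exposure/mediator N = 300,000, outcome
N = 500,000, prevalence 0.11 — the scale of the real data the generator
stands in for).  What summary mode does **not**
emulate: logistic non-collapsibility (individual mode does — marginal
log-ORs attenuate as the linear predictor's residual variance grows, which
is why the worked example's mediated proportion lands below the planted
25%), winner's-curse selection at the p-filter (negligible at the simulated
instrument strengths), LD, and sample overlap.  Passing tests therefore
show the estimators do what they claim under clean two-sample asymptotics,
not that real consortium data are free of those complications.

Scenario fixtures (`make_fixture`): `null`, `mediation` (a·b/c = 0.25 by
construction), `pleiotropy`, `outlier_snp` (one SNP with a planted direct
effect ≥ 10 ratio-SEs off), `bidirectional` (one-way causation).  All are
deterministic from their registered seeds and ≤ 60 SNPs / ≤ 12,000 virtual
individuals per cohort, chosen so the individual-level suite stays fast
while marginal estimates remain well resolved.

## Numerical and design choices

* Heterogeneity gate 0.05 and declaration gate 0.05 — "no heterogeneity"
  and "significant" are never quantified in common prose descriptions of
  the procedure, so both are explicit, configurable parameters.
* Ratio SEs are first-order delta method; the second-order term is ignored
  (its relative size is 1/F per SNP).
* Leave-one-out influence rule: omission crosses α in either direction or
  flips the estimate's sign.  Re-estimation after exclusion is a separate,
  explicit step — flagged SNPs are never dropped automatically.
* p-values are floored at 1e-320 when marginal tests underflow.
* The F-statistic needs the exposure study's N; when absent the instrument
  set reports `f_stat = None` rather than guessing.
* Degenerate inputs: empty instrument sets, zero exposure betas, < 2 SNPs
  for Q/leave-one-out and < 3 for Egger raise informative errors.

## Known limitations

Exposure-side uncertainty is ignored by the IVW weights (NOME), so very
weak instruments bias estimates toward the null; no weighted-median/mode or
MR-PRESSO estimators; no multivariable MR, so the mediated proportion is a
product-of-paths decomposition, not a direct-effect adjustment; LD is taken
as given, never estimated from a panel; no correction for sample overlap
between studies.
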