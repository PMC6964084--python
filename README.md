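# netmr — network Mendelian randomization from GWAS summary statistics

`netmr` is a tested, reusable pipeline for two-sample and network (mediation)
Mendelian randomization driven entirely by GWAS summary statistics — the
setting in which, for example, the causal pathway from ischemic stroke to
atrial fibrillation via blood pressure has been studied using consortium
summary data.  It is aimed at genetic epidemiologists who have per-SNP
association tables (beta or log-OR, SE, p, allele frequencies, sample sizes)
for an exposure, one or more candidate mediators, and an outcome, and want
the full chain — harmonization, instrument selection, estimation, sensitivity
analysis, mediation decomposition and power — in one place.

## What it computes

For harmonized SNP *j* with exposure effect β̂⟨X,j⟩ (SE σ⟨X,j⟩) and outcome
effect β̂⟨Y,j⟩ (SE σ⟨Y,j⟩):

* **Wald ratio** β̂⟨Y,j⟩/β̂⟨X,j⟩ with delta-method SE σ⟨Y,j⟩/|β̂⟨X,j⟩|.
* **IVW estimate** — the weighted mean of the ratios with weights
  w⟨j⟩ = β̂⟨X,j⟩²/σ⟨Y,j⟩² (equivalently a zero-intercept weighted regression of
  β̂⟨Y⟩ on β̂⟨X⟩); fixed-effect by default, multiplicative random-effects
  behind a flag.
* **Cochran's Q** of the ratios around the IVW estimate — the homogeneity
  diagnostic whose violation is the summary-level footprint of pleiotropy.
* **Instrument selection**: inclusive p-value filter (default p ≤ 5×10⁻⁴),
  greedy LD clumping (r² > 0.001 within 500 kb removed against an explicit
  LD table), then a greedy selection that grows the instrument set in
  descending order of per-SNP r² = t²/(t² + n − 2) while Q of the set stays
  non-significant; instrument strength reported as cumulative R² and
  F = ((n − k − 1)/k) · R²/(1 − R²).
* **MR-Egger** weighted regression with a free intercept; the intercept
  (average direct effect) with its t-test is the directional-pleiotropy test.
* **Leave-one-out** IVW with a configurable influence rule (significance
  crossing or sign flip).
* **Network MR**: total effect (step I), exposure→mediator (step II, same
  instruments), mediator→outcome (step III, mediator-derived instruments
  excluding exposure-associated SNPs), with
  mediated proportion = (β⟨a⟩·β⟨b⟩)/β⟨total⟩, and bidirectional MR with
  direction-specific instruments.
* **Analytic power** for a binary outcome:
  Φ(√(N·R²·K(1−K))·|ln OR| − z₀.₉₇₅), and the continuous-trait analogue.

A synthetic-GWAS generator (`netmr.simulate`) produces the three-cohort
two-sample setting — Hardy–Weinberg genotypes, a continuous exposure, a
mediator downstream of it, a logistic binary outcome, optional directional
pleiotropy and LD blocks — either at the individual level or by asymptotic
sampling of the marginal betas, and is the test bed for the whole pipeline.

## Worked example

```python
from netmr import make_fixture, run_network

data = make_fixture("mediation")   # planted: a=0.5, b=0.5, direct=0.75
res = run_network(data.exposure, data.mediator, data.outcome, with_reverse=True)
print(res.report())
```

```
path                    n_IV       R2      beta      OR  CI_low  CI_high           p
exposure->outcome         19   0.0967    0.7663   2.152   1.862    2.486    2.57e-25
exposure->mediator        19   0.0967    0.4997   1.648   1.545    1.758    6.24e-52
mediator->outcome         13   0.0747    0.2845   1.329   1.149    1.537     0.00013
mediator->exposure        13   0.0747   -0.0167   0.983   0.928    1.042       0.573
mediated proportion: 18.6%
mediator declared: yes
```

Nineteen of the 30 exposure SNPs survive filtering, clumping and the
heterogeneity-constrained selection; the exposure→mediator path recovers the
planted 0.5 almost exactly, the reverse (mediator→exposure) run is null as
planted, and both mediation paths are significant so the mediator is
declared.  The mediated proportion (planted 25% of the total log-odds
effect) is estimated at 18.6% here because marginal log-ORs from a logistic
model are non-collapsible and attenuate the outcome-side paths — see
`docs/methods.md`.

The same steps are available from the shell (`netmr simulate | harmonize |
select | mr | loo | network | bidirectional | power | run`), e.g.

```sh
netmr power --n 29633 --k 0.3478 --r2 0.017 --effect 1.48
power=0.9872 rounded=0.99
```

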