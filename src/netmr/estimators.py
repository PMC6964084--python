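"""Two-sample Mendelian randomization estimators on harmonized summary data.

Implements the per-SNP Wald ratio, the fixed-effect inverse-variance-weighted
(IVW) combination, MR-Egger regression with its directional-pleiotropy
intercept test, and Cochran's Q heterogeneity statistic.

Notation: for SNP *j*, ``beta_exposure`` is the SNP–exposure effect
:math:`\\hat\\beta_{Xj}` with SE :math:`\\sigma_{Xj}`, and ``beta_outcome``
the SNP–outcome effect :math:`\\hat\\beta_{Yj}` with SE :math:`\\sigma_{Yj}`.
The IVW estimate is the weighted mean of the ratios
:math:`\\hat\\beta_{Yj}/\\hat\\beta_{Xj}` with weights
:math:`w_j = \\hat\\beta_{Xj}^2/\\sigma_{Yj}^2` (first-order delta method,
exposure-side noise ignored).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .sumstats import HarmonizedPair

__all__ = [
    "MRResult",
    "ratio_estimate",
    "ivw",
    "mr_egger",
    "cochran_q",
    "to_or",
]

Z975 = 1.959963984540054  # two-sided 5% normal quantile


@dataclass(frozen=True)
class MRResult:
    """A causal estimate on the log-effect scale with its diagnostics.

    ``or_scale`` is ``exp((beta, ci_low, ci_high))`` — the odds-ratio view
    for binary outcomes.  ``q_df`` is ``n_snps - 1`` for IVW and
    ``n_snps - 2`` for Egger (slope + intercept).  The Egger intercept
    fields are None for IVW results.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    @property
    def or_scale(self) -> tuple[float, float, float]:
        return tuple(math.exp(v) for v in (self.beta, self.ci_low, self.ci_high))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["or"], d["or_ci_low"], d["or_ci_high"] = self.or_scale
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.pval < alpha


def _kept(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.kept]


def _arrays(pairs: Sequence[HarmonizedPair]):
    bx = np.array([p.beta_exposure for p in pairs], dtype=float)
    by = np.array([p.beta_outcome for p in pairs], dtype=float)
    sy = np.array([p.se_outcome for p in pairs], dtype=float)
    return bx, by, sy


def ratio_estimate(pair: HarmonizedPair) -> tuple[float, float]:
    """Wald ratio for a single SNP: ``beta_outcome / beta_exposure`` with
    first-order delta-method SE ``se_outcome / |beta_exposure|``."""
    if pair.beta_exposure == 0:
        raise ValueError(f"{pair.snp_id}: zero exposure effect, ratio undefined")
    beta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return beta, se


def cochran_q(
    pairs: Sequence[HarmonizedPair], beta_ref: float
) -> tuple[float, int, float]:
    """Cochran's Q of the per-SNP ratios around ``beta_ref``.

    Q = sum_j w_j (ratio_j - beta_ref)^2 with w_j = beta_Xj^2 / se_Yj^2;
    chi-square with n-1 df under homogeneity.  Substantial heterogeneity is
    the summary-level signature of pleiotropy, which is why instrument
    selection constrains it.
    """
    pairs = _kept(pairs)
    if len(pairs) < 2:
        raise ValueError("Cochran's Q needs at least 2 SNPs")
    bx, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect in Q computation")
    w = bx**2 / sy**2
    q = float(np.sum(w * (by / bx - beta_ref) ** 2))
    df = len(pairs) - 1
    pval = float(stats.chi2.sf(q, df))
    return q, df, pval


def ivw(pairs: Sequence[HarmonizedPair], random_effects: bool = False) -> MRResult:
    """Fixed-effect inverse-variance-weighted causal estimate.

    Equivalent to a zero-intercept weighted regression of outcome betas on
    exposure betas with weights 1/se_outcome^2.  With ``random_effects`` the
    SE is inflated multiplicatively by sqrt(Q/df) when Q/df > 1, matching the
    common software default; the fixed-effect form is the package default
    because the selection step already enforces homogeneity.
    """
    pairs = _kept(pairs)
    if not pairs:
        raise ValueError("IVW needs at least 1 SNP")
    bx, by, sy = _arrays(pairs)
    if np.any(bx == 0):
        raise ValueError("zero exposure effect; drop the SNP before IVW")
    w = bx**2 / sy**2
    beta = float(np.sum(w * (by / bx)) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))

    q_stat = q_df = q_pval = None
    if len(pairs) >= 2:
        q_stat, q_df, q_pval = cochran_q(pairs, beta)
        if random_effects and q_stat / q_df > 1:
            se *= math.sqrt(q_stat / q_df)

    pval = float(2 * stats.norm.sf(abs(beta) / se))
    return MRResult(
        method="ivw",
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        pval=pval,
        n_snps=len(pairs),
        q_stat=q_stat,
        q_df=q_df,
        q_pval=q_pval,
    )


def mr_egger(pairs: Sequence[HarmonizedPair], _constrain_intercept: bool = False) -> MRResult:
    """MR-Egger: weighted regression of outcome on exposure betas with a free
    intercept.

    Each SNP is first oriented so its exposure effect is non-negative (both
    betas negated where needed) — the estimate must not depend on the
    arbitrary choice of effect allele.  The slope is the causal estimate; the
    intercept is the average direct (pleiotropic) effect, and its two-sided
    t-test is the directional-pleiotropy test.  Valid under the InSIDE
    assumption (instrument strength independent of direct effects).

    ``_constrain_intercept`` is an internal test mode that drops the
    intercept, which must reproduce IVW exactly.
    """
    import statsmodels.api as sm

    pairs = _kept(pairs)
    if len(pairs) < 3 and not _constrain_intercept:
        raise ValueError("MR-Egger needs at least 3 SNPs (slope, intercept, Q df)")
    bx, by, sy = _arrays(pairs)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2

    if _constrain_intercept:
        X = bx[:, None]
    else:
        X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()

    slope_ix = 0 if _constrain_intercept else 1
    beta = float(fit.params[slope_ix])
    # SE on the known-weights (fixed-effect) scale, t reference with n-2 df
    # for finite-sample honesty about the estimated intercept.
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    n, k = len(pairs), X.shape[1]
    df = n - k
    if _constrain_intercept:
        se = float(math.sqrt(cov[0, 0]))
        pval = float(2 * stats.norm.sf(abs(beta) / se))
        intercept = intercept_se = intercept_p = None
        q_stat = q_df = q_pval = None
        if n >= 2:
            q_stat, q_df, q_pval = cochran_q(pairs, beta)
    else:
        sigma2 = float(fit.mse_resid)  # overdispersion relative to se_outcome
        se_fit = float(fit.bse[1])
        se = se_fit
        pval = float(2 * stats.t.sf(abs(beta) / se, df))
        intercept = float(fit.params[0])
        intercept_se = float(fit.bse[0])
        intercept_p = float(2 * stats.t.sf(abs(intercept) / intercept_se, df))
        resid = by - X @ fit.params
        q_stat = float(np.sum(w * resid**2))  # Rucker's Q'
        q_df = df
        q_pval = float(stats.chi2.sf(q_stat, q_df)) if q_df > 0 else None

    return MRResult(
        method="egger" if not _constrain_intercept else "ivw",
        beta=beta,
        se=se,
        ci_low=beta - Z975 * se if _constrain_intercept else beta - float(stats.t.ppf(0.975, df)) * se,
        ci_high=beta + Z975 * se if _constrain_intercept else beta + float(stats.t.ppf(0.975, df)) * se,
        pval=pval,
        n_snps=n,
        q_stat=q_stat,
        q_df=q_df,
        q_pval=q_pval,
        egger_intercept=intercept,
        egger_intercept_se=intercept_se,
        egger_intercept_pval=intercept_p,
    )


def to_or(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-OR and its 95% Wald limits."""
    if not se > 0:
        raise ValueError("se must be positive")
    return (
        math.exp(beta),
        math.exp(beta - Z975 * se),
        math.exp(beta + Z975 * se),
    )


def results_to_tsv(results: Sequence[MRResult], path) -> None:
    """Flat one-row-per-method TSV for report assembly."""
    import pandas as pd

    pd.DataFrame([r.to_dict() for r in results]).to_csv(path, sep="\t", index=False)
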