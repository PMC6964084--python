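"""Synthetic two-sample GWAS generator for exposure, mediator and a binary
outcome.

Emulates the setting of a network MR study: three non-overlapping cohorts,
each genotyped at the same SNP panel under Hardy–Weinberg equilibrium, with

* a continuous exposure X built from a genetic score plus Gaussian noise,
  with a configurable fraction of variance explained by its SNPs;
* a mediator M causally downstream of X (``theta_xm``) with its own genetic
  component, or upstream of it in the reverse-causation mode;
* a binary outcome from a logistic model with linear predictor
  ``theta_xy_direct·X + theta_my·M + sum_j alpha_j G_j`` and intercept solved
  from the baseline prevalence — the ``alpha_j`` are direct (pleiotropic)
  SNP effects bypassing the exposure.

Each cohort yields per-SNP marginal regressions (OLS for continuous traits,
logistic for the outcome), exactly the summary statistics a consortium would
publish.  ``mode="summary"`` skips genotypes and samples the marginal betas
from their asymptotic normal laws on the standardized scale — statistically
the same two-sample problem at a fraction of the cost, used for
replicate-heavy calibration studies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .instruments import LDInfo
from .sumstats import SumStatRecord, write_sumstats

__all__ = ["SimConfig", "SimTruth", "SimData", "simulate_gwas", "make_fixture", "SCENARIOS"]

_ALLELES = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))  # non-palindromic


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for one synthetic dataset.

    Effects on the outcome (``theta_my``, ``theta_xy_direct``, pleiotropy)
    are on the log-odds scale; ``theta_xm`` and the reverse effect are in
    trait SD units.  ``h2_exposure`` / ``h2_mediator`` are the variance
    fractions explained by each trait's own SNPs.
    """

    n_snps: int = 30                       # exposure-associated SNPs
    n_snps_mediator: int = 0               # mediator-specific SNPs
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_exposure: float = 0.1
    h2_mediator: float = 0.1
    theta_xm: float = 0.0                  # exposure -> mediator
    theta_my: float = 0.0                  # mediator -> outcome (log-odds)
    theta_xy_direct: float = 0.0           # direct exposure -> outcome (log-odds)
    theta_mx_reverse: float = 0.0          # mediator -> exposure (reverse mode)
    pleiotropy_frac: float = 0.0           # fraction of exposure SNPs with alpha_j != 0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_alpha: float = 0.0             # direct outcome effect planted on SNP 0
    ld_block_r: float = 0.0                # haplotype correlation within adjacent SNP pairs
    n_exposure: int = 10_000
    n_mediator: int = 10_000
    n_outcome: int = 10_000
    prevalence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2_exposure < 1 or not 0 <= self.h2_mediator < 1:
            raise ValueError("variance explained must be in [0,1)")
        if self.h2_exposure + 0 > 1 or self.h2_mediator > 1:
            raise ValueError("infeasible variance budget")
        if not 0 <= self.pleiotropy_frac <= 1:
            raise ValueError("pleiotropy_frac must be in [0,1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0,1)")
        if self.theta_xm and self.theta_mx_reverse:
            raise ValueError("set only one of theta_xm / theta_mx_reverse")

    @property
    def j_total(self) -> int:
        return self.n_snps + self.n_snps_mediator


@dataclass
class SimTruth:
    """Ground truth behind one dataset, on the standardized-genotype scale."""

    gamma: list[float]          # exposure effects of exposure SNPs
    delta: list[float]          # mediator effects of mediator SNPs
    alpha: list[float]          # direct outcome effects (pleiotropy), exposure SNPs
    mafs: list[float]
    snp_ids: list[str]
    theta_xm: float
    theta_my: float
    theta_xy_direct: float
    theta_mx_reverse: float
    theta_xy_total: float       # theta_xy_direct + theta_xm * theta_my

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SimData:
    exposure: list[SumStatRecord]
    mediator: list[SumStatRecord]
    outcome: list[SumStatRecord]
    truth: SimTruth
    ld: LDInfo = field(default_factory=LDInfo)

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(self.exposure, outdir / "exposure.tsv")
        write_sumstats(self.mediator, outdir / "mediator.tsv")
        write_sumstats(self.outcome, outdir / "outcome.tsv")
        (outdir / "truth.json").write_text(self.truth.to_json())
        if len(self.ld):
            self.ld.to_file(outdir / "ld.tsv")


def _snp_meta(j: int) -> tuple[str, str, int, str, str]:
    """Deterministic id/chrom/pos/alleles; adjacent pair members sit 10 kb
    apart (inside any clumping window), distinct pairs > 1 Mb apart."""
    block = j // 2
    chrom = str(block % 22 + 1)
    pos = 2_000_000 * (block // 22 + 1) + (j % 2) * 10_000
    ea, oa = _ALLELES[j % len(_ALLELES)]
    return f"rs{j + 1:05d}", chrom, pos, ea, oa


def _scaled_effects(rng, j: int, mafs: np.ndarray, h2: float) -> np.ndarray:
    """Per-allele effects with total explained variance exactly h2."""
    if j == 0 or h2 == 0:
        return np.zeros(j)
    raw = rng.normal(size=j)
    var_raw = np.sum(2 * mafs * (1 - mafs) * raw**2)
    return raw * math.sqrt(h2 / var_raw)


def _ols_marginal(G: np.ndarray, y: np.ndarray):
    """Simple-regression beta/se/p for every genotype column at once."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(gc**2, axis=0)
    beta = gc.T @ yc / sxx
    rss = np.sum(yc**2) - beta**2 * sxx
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta / se
    pval = 2 * stats.t.sf(np.abs(t), n - 2)
    return beta, se, pval


def _logit_marginal(g: np.ndarray, y: np.ndarray, max_iter: int = 30):
    """Single-covariate logistic fit by Newton–Raphson (intercept + slope)."""
    X = np.column_stack([np.ones_like(g), g])
    b = np.zeros(2)
    H = np.eye(2)
    for _ in range(max_iter):
        p = special.expit(X @ b)
        w = p * (1 - p)
        grad = X.T @ (y - p)
        H = X.T @ (X * w[:, None])
        step = np.linalg.solve(H, grad)
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(H)
    beta, se = b[1], math.sqrt(cov[1, 1])
    z = beta / se
    return beta, se, 2 * stats.norm.sf(abs(z))


def _genotypes(rng, n: int, mafs: np.ndarray, ld_block_r: float) -> np.ndarray:
    """n x J genotype matrix under HWE; optional correlation within adjacent
    SNP pairs via a Gaussian-copula haplotype model."""
    j = len(mafs)
    if ld_block_r == 0:
        return rng.binomial(2, mafs, size=(n, j)).astype(float)
    thresh = stats.norm.ppf(mafs)
    G = np.zeros((n, j))
    for _hap in range(2):
        z = rng.normal(size=(n, j))
        for k in range(0, j - 1, 2):
            z[:, k + 1] = ld_block_r * z[:, k] + math.sqrt(1 - ld_block_r**2) * z[:, k + 1]
        G += (z < thresh).astype(float)
    return G


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    f = lambda b0: special.expit(b0 + eta).mean() - prevalence
    return optimize.brentq(f, -40, 40)


def _records(
    snp_meta, mafs, beta, se, pval, n, trait_id, trait_type,
    n_case=None, n_control=None,
) -> list[SumStatRecord]:
    recs = []
    for j, (snp_id, chrom, pos, ea, oa) in enumerate(snp_meta):
        recs.append(
            SumStatRecord(
                snp_id=snp_id,
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(mafs[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(max(pval[j], 1e-320)),
                n=int(n),
                n_case=n_case,
                n_control=n_control,
                trait_id=trait_id,
                trait_type=trait_type,
            )
        )
    return recs


def simulate_gwas(config: SimConfig, mode: str = "individual") -> SimData:
    """Generate three studies' summary statistics plus the ground truth.

    ``mode="individual"`` simulates genotypes and phenotypes per person and
    runs the per-SNP marginal regressions; ``mode="summary"`` draws the
    marginal betas directly from their asymptotic distributions (standardized
    scale, outcome SEs ``1/sqrt(N·K(1−K))``).  Both are reproducible from
    ``config.seed`` alone.
    """
    if mode not in ("individual", "summary"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(config.seed)
    J, Jx, Jm = config.j_total, config.n_snps, config.n_snps_mediator
    if Jx == 0:
        raise ValueError("need at least one exposure SNP")
    mafs = rng.uniform(*config.maf_range, size=J)
    snp_meta = [_snp_meta(j) for j in range(J)]
    snp_ids = [m[0] for m in snp_meta]

    gamma = np.zeros(J)
    gamma[:Jx] = _scaled_effects(rng, Jx, mafs[:Jx], config.h2_exposure)
    delta = np.zeros(J)
    if Jm:
        delta[Jx:] = _scaled_effects(rng, Jm, mafs[Jx:], config.h2_mediator)

    alpha = np.zeros(J)
    n_pleio = int(round(config.pleiotropy_frac * Jx))
    if n_pleio:
        which = rng.choice(Jx, size=n_pleio, replace=False)
        alpha[which] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, n_pleio)
    if config.outlier_alpha:
        alpha[0] += config.outlier_alpha

    theta_total = config.theta_xy_direct + config.theta_xm * config.theta_my
    truth = SimTruth(
        gamma=[float(v) for v in gamma[:Jx]],
        delta=[float(v) for v in delta[Jx:]],
        alpha=[float(v) for v in alpha[:Jx]],
        mafs=[float(v) for v in mafs],
        snp_ids=snp_ids,
        theta_xm=config.theta_xm,
        theta_my=config.theta_my,
        theta_xy_direct=config.theta_xy_direct,
        theta_mx_reverse=config.theta_mx_reverse,
        theta_xy_total=theta_total,
    )

    if mode == "summary":
        return _simulate_summary(config, rng, snp_meta, mafs, gamma, delta, alpha, truth)

    ld = LDInfo()

    def phenos(n: int):
        G = _genotypes(rng, n, mafs, config.ld_block_r)
        gx = G @ gamma
        gm = G @ delta
        ex = rng.normal(0, math.sqrt(max(1 - config.h2_exposure, 1e-12)), n)
        em = rng.normal(0, math.sqrt(max(1 - config.h2_mediator, 1e-12)), n)
        if config.theta_mx_reverse:
            M = gm + em
            X = gx + config.theta_mx_reverse * M + ex
        else:
            X = gx + ex
            M = config.theta_xm * X + gm + em
        return G, X, M

    # exposure cohort
    G, X, _ = phenos(config.n_exposure)
    bx, sx, px = _ols_marginal(G, X)
    exposure = _records(snp_meta, mafs, bx, sx, px, config.n_exposure, "exposure", "continuous")
    if config.ld_block_r:
        corr = np.corrcoef(G, rowvar=False)
        for a in range(J):
            for b in range(a + 1, J):
                if abs(corr[a, b]) > 0.01:
                    ld.set(snp_ids[a], snp_ids[b], min(float(corr[a, b] ** 2), 1.0))

    # mediator cohort
    G, _, M = phenos(config.n_mediator)
    bm, sm, pm = _ols_marginal(G, M)
    mediator = _records(snp_meta, mafs, bm, sm, pm, config.n_mediator, "mediator", "continuous")

    # outcome cohort
    G, X, M = phenos(config.n_outcome)
    eta = config.theta_xy_direct * X + config.theta_my * M + G @ alpha
    b0 = _solve_intercept(eta, config.prevalence)
    y = (rng.uniform(size=config.n_outcome) < special.expit(b0 + eta)).astype(float)
    by = np.empty(J)
    sy = np.empty(J)
    py = np.empty(J)
    for j in range(J):
        by[j], sy[j], py[j] = _logit_marginal(G[:, j], y)
    n_case = int(y.sum())
    outcome = _records(
        snp_meta, mafs, by, sy, py, config.n_outcome, "outcome", "binary",
        n_case=n_case, n_control=config.n_outcome - n_case,
    )
    return SimData(exposure, mediator, outcome, truth, ld)


def _simulate_summary(config, rng, snp_meta, mafs, gamma, delta, alpha, truth) -> SimData:
    """Asymptotic sampling of the marginal betas on the standardized scale."""
    scale = np.sqrt(2 * mafs * (1 - mafs))  # per-allele -> standardized
    gs, ds, als = gamma * scale, delta * scale, alpha * scale
    K = config.prevalence
    se_x = np.full_like(gs, 1 / math.sqrt(config.n_exposure))
    se_m = np.full_like(gs, 1 / math.sqrt(config.n_mediator))
    se_y = np.full_like(gs, 1 / math.sqrt(config.n_outcome * K * (1 - K)))

    mu_x = gs + config.theta_mx_reverse * ds
    mu_m = config.theta_xm * gs + ds
    mu_y = (
        truth.theta_xy_total * gs
        + (config.theta_my + config.theta_xy_direct * config.theta_mx_reverse) * ds
        + als
    )
    bx = rng.normal(mu_x, se_x)
    bm = rng.normal(mu_m, se_m)
    by = rng.normal(mu_y, se_y)
    pv = lambda b, s: 2 * stats.norm.sf(np.abs(b / s))

    n_case = int(round(K * config.n_outcome))
    exposure = _records(snp_meta, mafs, bx, se_x, pv(bx, se_x), config.n_exposure, "exposure", "continuous")
    mediator = _records(snp_meta, mafs, bm, se_m, pv(bm, se_m), config.n_mediator, "mediator", "continuous")
    outcome = _records(
        snp_meta, mafs, by, se_y, pv(by, se_y), config.n_outcome, "outcome", "binary",
        n_case=n_case, n_control=config.n_outcome - n_case,
    )
    return SimData(exposure, mediator, outcome, truth)


#: deterministic small scenarios used throughout the test suite
SCENARIOS: dict[str, SimConfig] = {
    "null": SimConfig(n_snps=30, n_exposure=8000, n_mediator=8000, n_outcome=8000, seed=101),
    "mediation": SimConfig(
        n_snps=30,
        n_snps_mediator=30,
        theta_xm=0.5,
        theta_my=0.5,
        theta_xy_direct=0.75,  # indirect/total = 0.25/1.0
        n_exposure=12_000,
        n_mediator=12_000,
        n_outcome=12_000,
        seed=102,
    ),
    "pleiotropy": SimConfig(
        n_snps=30,
        theta_xy_direct=0.2,
        pleiotropy_frac=0.5,
        pleiotropy_mean=0.15,
        pleiotropy_sd=0.05,
        n_exposure=8000,
        n_mediator=8000,
        n_outcome=8000,
        seed=103,
    ),
    "outlier_snp": SimConfig(
        n_snps=20,
        theta_xy_direct=0.1,
        outlier_alpha=0.8,
        n_exposure=10_000,
        n_mediator=10_000,
        n_outcome=10_000,
        seed=104,
    ),
    "bidirectional": SimConfig(
        n_snps=30,
        n_snps_mediator=30,
        theta_xm=0.4,  # one-way exposure -> mediator
        n_exposure=12_000,
        n_mediator=12_000,
        n_outcome=12_000,
        seed=105,
    ),
}


def make_fixture(name: str, mode: str = "individual") -> SimData:
    """Deterministic small dataset from the scenario registry
    (null, mediation, pleiotropy, outlier_snp, bidirectional)."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        )
    return simulate_gwas(SCENARIOS[name], mode=mode)
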