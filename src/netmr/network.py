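"""Network MR: a three-step mediation framework over summary statistics.

Step I estimates the total causal effect of the exposure on the outcome
using exposure-derived instruments; step II estimates the exposure → mediator
path with the same instruments; step III re-selects instruments from the
mediator's own associations and estimates the mediator → outcome path.  A
mediator is declared *potential* only when both path estimates are
significant.  The mediated proportion is the product-of-paths share of the
total effect on the log-effect scale:

    mediated_proportion = (beta_a * beta_b) / beta_total

Bidirectional MR repeats the analysis with the roles exchanged, each
direction using instruments selected for its own exposure, to probe reverse
causation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .estimators import MRResult, ivw, mr_egger
from .instruments import (
    InstrumentSet,
    LDInfo,
    greedy_select,
    ld_clump,
    pvalue_filter,
    snp_r2,
)
from .sumstats import HarmonizedPair, SumStatRecord, harmonize

__all__ = ["SelectionConfig", "NetworkResult", "select_and_harmonize", "run_network", "bidirectional"]


@dataclass(frozen=True)
class SelectionConfig:
    """Instrument-selection parameters for one MR run.

    Defaults follow conventional two-sample MR practice: association filter
    p <= 5e-4, clumping at r² = 0.001 within 500 kb, heterogeneity gate at
    p >= 0.05 during greedy selection, palindromic-SNP eaf window 0.08.
    """

    pval_threshold: float = 5e-4
    clump_r2: float = 0.001
    clump_window_bp: int = 500_000
    het_alpha: float = 0.05
    palindromic_eaf_window: float = 0.08
    alpha: float = 0.05  # significance gate for declaring paths/mediators


@dataclass
class PathStatus:
    """Outcome of one selection+estimation attempt."""

    ok: bool
    message: str = ""


@dataclass
class NetworkResult:
    """Results of the three MR tests plus the mediation summary.

    ``total`` is the exposure → outcome effect (step I), ``a_path`` the
    exposure → mediator effect (step II), ``b_path`` the mediator → outcome
    effect (step III, mediator-derived instruments).  ``reverse`` holds the
    optional mediator → exposure run.  ``mediated_proportion`` is
    (a·b)/total, None when the total effect is zero or a step failed.
    """

    total: MRResult | None
    a_path: MRResult | None
    b_path: MRResult | None
    mediated_proportion: float | None
    mediator_declared: bool
    instruments_exposure: InstrumentSet | None
    instruments_mediator: InstrumentSet | None
    reverse: MRResult | None = None
    status: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def mr(r):
            return None if r is None else r.to_dict()

        return {
            "total": mr(self.total),
            "a_path": mr(self.a_path),
            "b_path": mr(self.b_path),
            "mediated_proportion": self.mediated_proportion,
            "mediator_declared": self.mediator_declared,
            "reverse": mr(self.reverse),
            "n_instruments_exposure": None
            if self.instruments_exposure is None
            else len(self.instruments_exposure),
            "n_instruments_mediator": None
            if self.instruments_mediator is None
            else len(self.instruments_mediator),
            "status": self.status,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def report(self) -> str:
        """Human-readable table mirroring the usual exposure/outcome layout
        (n IVs, R², beta, OR, 95% CI, p)."""
        lines = [
            f"{'path':<22}{'n_IV':>6}{'R2':>9}{'beta':>10}{'OR':>8}"
            f"{'CI_low':>8}{'CI_high':>9}{'p':>12}"
        ]

        def row(label, res, iset):
            if res is None:
                lines.append(f"{label:<22}{'-':>6}  (not estimated)")
                return
            orv, lo, hi = res.or_scale
            r2 = f"{iset.r2_total:.4f}" if iset is not None else "-"
            lines.append(
                f"{label:<22}{res.n_snps:>6}{r2:>9}{res.beta:>10.4f}{orv:>8.3f}"
                f"{lo:>8.3f}{hi:>9.3f}{res.pval:>12.3g}"
            )

        row("exposure->outcome", self.total, self.instruments_exposure)
        row("exposure->mediator", self.a_path, self.instruments_exposure)
        row("mediator->outcome", self.b_path, self.instruments_mediator)
        if self.reverse is not None:
            row("mediator->exposure", self.reverse, self.instruments_mediator)
        mp = (
            "undefined"
            if self.mediated_proportion is None
            else f"{100 * self.mediated_proportion:.1f}%"
        )
        lines.append(f"mediated proportion: {mp}")
        lines.append(f"mediator declared: {'yes' if self.mediator_declared else 'no'}")
        return "\n".join(lines)


def select_and_harmonize(
    assoc: Sequence[SumStatRecord],
    outcome: Sequence[SumStatRecord],
    config: SelectionConfig,
    ld: LDInfo | None = None,
) -> tuple[InstrumentSet, list[HarmonizedPair]]:
    """Full instrument pipeline for one exposure/outcome pair.

    Filters the exposure associations at ``pval_threshold``, clumps, then
    harmonizes against the outcome and runs the greedy heterogeneity-
    constrained selection.  Returns the instrument set and the harmonized
    pairs restricted to the selected SNPs, in selection order.
    """
    filtered = pvalue_filter(assoc, config.pval_threshold)
    if not filtered:
        raise ValueError("no SNP passes the association p-value filter")
    clumped = ld_clump(filtered, ld, config.clump_r2, config.clump_window_bp)
    pairs = harmonize(clumped, outcome, config.palindromic_eaf_window)
    kept = [p for p in pairs if p.kept]
    if not kept:
        raise ValueError("no SNP survives harmonization")
    clumped_by_id = {r.snp_id: r for r in clumped}
    r2_map = {p.snp_id: snp_r2(clumped_by_id[p.snp_id]) for p in kept}
    n_exp = next((r.n for r in clumped if r.n is not None), None)
    iset = greedy_select(kept, r2_map, config.het_alpha, n_exposure=n_exp)
    by_id = {p.snp_id: p for p in kept}
    return iset, [by_id[s] for s in iset.snp_ids]


def _mr_on_selected(
    selected_ids: Sequence[str],
    assoc: Sequence[SumStatRecord],
    outcome: Sequence[SumStatRecord],
    config: SelectionConfig,
) -> MRResult:
    """IVW of a fixed instrument list against a (possibly different) outcome."""
    wanted = set(selected_ids)
    sub = [r for r in assoc if r.snp_id in wanted]
    pairs = harmonize(sub, outcome, config.palindromic_eaf_window)
    kept = [p for p in pairs if p.kept]
    if not kept:
        raise ValueError("no instrument SNP found in the second trait's statistics")
    return ivw(kept)


def run_network(
    exposure_stats: Sequence[SumStatRecord],
    mediator_stats: Sequence[SumStatRecord],
    outcome_stats: Sequence[SumStatRecord],
    config: SelectionConfig = SelectionConfig(),
    ld: LDInfo | None = None,
    with_reverse: bool = False,
) -> NetworkResult:
    """Execute the three-step network MR framework.

    Steps I and II share the exposure-derived instruments (selected against
    the outcome); step III re-selects instruments from the mediator's own
    associations, excluding SNPs associated with the exposure at the
    instrument threshold (an upstream SNP reaches the outcome through the
    direct exposure path, so it is not a valid mediator instrument).  A
    failed step II/III leaves a partial result with the failure recorded in
    ``status`` rather than raising.
    """
    status: dict[str, str] = {}

    iset_x, pairs_xy = select_and_harmonize(exposure_stats, outcome_stats, config, ld)
    total = ivw(pairs_xy)
    status["total"] = "ok"

    a_path = None
    try:
        a_path = _mr_on_selected(iset_x.snp_ids, exposure_stats, mediator_stats, config)
        status["a_path"] = "ok"
    except ValueError as exc:
        status["a_path"] = str(exc)

    # Step III instruments must satisfy the exclusion restriction *for the
    # mediator*: a SNP acting on the mediator through the exposure also hits
    # the outcome through the direct path, so exposure-associated SNPs are
    # barred from the mediator's instrument candidates.
    exposure_hits = {
        r.snp_id for r in pvalue_filter(exposure_stats, config.pval_threshold)
    }
    mediator_candidates = [r for r in mediator_stats if r.snp_id not in exposure_hits]

    b_path = None
    iset_m = None
    try:
        iset_m, pairs_my = select_and_harmonize(mediator_candidates, outcome_stats, config, ld)
        b_path = ivw(pairs_my)
        status["b_path"] = "ok"
    except ValueError as exc:
        status["b_path"] = str(exc)

    reverse = None
    if with_reverse and iset_m is not None:
        try:
            reverse = _mr_on_selected(iset_m.snp_ids, mediator_stats, exposure_stats, config)
            status["reverse"] = "ok"
        except ValueError as exc:
            status["reverse"] = str(exc)

    mediated = None
    declared = False
    if a_path is not None and b_path is not None and total.beta != 0:
        mediated = a_path.beta * b_path.beta / total.beta
        declared = a_path.significant(config.alpha) and b_path.significant(config.alpha)

    return NetworkResult(
        total=total,
        a_path=a_path,
        b_path=b_path,
        mediated_proportion=mediated,
        mediator_declared=declared,
        instruments_exposure=iset_x,
        instruments_mediator=iset_m,
        reverse=reverse,
        status=status,
    )


def bidirectional(
    trait1_stats: Sequence[SumStatRecord],
    trait2_stats: Sequence[SumStatRecord],
    config: SelectionConfig = SelectionConfig(),
    ld: LDInfo | None = None,
) -> tuple[MRResult, MRResult]:
    """Two independent MR runs with the roles exchanged.

    Forward: trait1 → trait2 with trait1-derived instruments; reverse:
    trait2 → trait1 with trait2-derived instruments.  Instrument SNPs of one
    direction overlapping the other trait's instruments are a sample-overlap
    caveat reported by the pipeline layer, not corrected here.
    """
    _, pairs_fwd = select_and_harmonize(trait1_stats, trait2_stats, config, ld)
    forward = ivw(pairs_fwd)
    _, pairs_rev = select_and_harmonize(trait2_stats, trait1_stats, config, ld)
    reverse = ivw(pairs_rev)
    return forward, reverse
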