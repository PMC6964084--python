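"""Instrument construction for two-sample MR.

Pipeline: association filter (``pval <= threshold``), greedy LD clumping
(smallest p-value first, removing neighbours within a window whose r²
exceeds a threshold), then a greedy selection that grows the instrument set
in descending order of per-SNP variance explained while Cochran's Q of the
set against the outcome stays non-significant — heterogeneity being the
summary-level footprint of pleiotropy, the selection trades variance
explained for homogeneity.  Instrument strength is summarized by the
cumulative R² and the F-statistic (F > 10 is the conventional
weak-instrument rule of thumb).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .estimators import cochran_q, ivw
from .sumstats import HarmonizedPair, SumStatRecord

__all__ = [
    "LDInfo",
    "InstrumentSet",
    "SelectionStep",
    "pvalue_filter",
    "ld_clump",
    "snp_r2",
    "greedy_select",
    "f_statistic",
]


class LDInfo:
    """Symmetric pairwise r² lookup; unrecorded pairs are treated as r² = 0.

    The clumping reference panel is external input here: load one from a
    3-column delimited file (snp_a, snp_b, r2) or build it in memory.  An
    empty LDInfo makes clumping a no-op apart from ordering.
    """

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, snp_a: str, snp_b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValueError(f"r2 must be in [0,1], got {r2}")
        if snp_a == snp_b and r2 != 1.0:
            raise ValueError("diagonal r2 must be 1")
        self._r2[frozenset((snp_a, snp_b))] = r2

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self._r2.get(frozenset((snp_a, snp_b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)

    @classmethod
    def from_file(cls, path, sep: str = "\t") -> "LDInfo":
        ld = cls()
        with open(path) as fh:
            first = fh.readline()
            parts = first.split(sep if sep != " " else None)
            # tolerate an optional header line
            try:
                float(parts[2])
                ld.set(parts[0].strip(), parts[1].strip(), float(parts[2]))
            except (ValueError, IndexError):
                pass
            for line in fh:
                a, b, r2 = line.split(sep)[:3]
                ld.set(a.strip(), b.strip(), float(r2))
        return ld

    def to_file(self, path, sep: str = "\t") -> None:
        with open(path, "w") as fh:
            fh.write(sep.join(("snp_a", "snp_b", "r2")) + "\n")
            for key, r2 in sorted(self._r2.items(), key=lambda kv: sorted(kv[0])):
                ab = sorted(key)
                a, b = (ab[0], ab[0]) if len(ab) == 1 else ab
                fh.write(sep.join((a, b, f"{r2:.6g}")) + "\n")


@dataclass(frozen=True)
class SelectionStep:
    snp_id: str
    r2_total: float
    q_pval: float | None  # None for the 1-SNP seed (Q has 0 df)


@dataclass
class InstrumentSet:
    """Selected instruments with strength and heterogeneity diagnostics."""

    snp_ids: list[str]
    r2_total: float
    f_stat: float | None
    q_stat: float | None
    q_pval: float | None
    selection_log: list[SelectionStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def to_json(self) -> str:
        return json.dumps(
            {
                "snp_ids": self.snp_ids,
                "r2_total": self.r2_total,
                "f_stat": self.f_stat,
                "q_stat": self.q_stat,
                "q_pval": self.q_pval,
                "selection_log": [
                    {"snp_id": s.snp_id, "r2_total": s.r2_total, "q_pval": s.q_pval}
                    for s in self.selection_log
                ],
            },
            indent=2,
        )


def pvalue_filter(
    records: Sequence[SumStatRecord], threshold: float
) -> list[SumStatRecord]:
    """Keep records with ``pval <= threshold`` (inclusive bound)."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    return [r for r in records if r.pval <= threshold]


def _clump_key(r: SumStatRecord):
    return (r.pval, r.snp_id)


def ld_clump(
    records: Sequence[SumStatRecord],
    ld: LDInfo | None = None,
    r2_threshold: float = 0.001,
    window_bp: int = 500_000,
) -> list[SumStatRecord]:
    """Greedy p-value-ordered clumping.

    Repeatedly takes the remaining record with the smallest p-value (ties
    broken by snp_id) as an index SNP and discards remaining records on the
    same chromosome within ``window_bp`` whose r² with it exceeds
    ``r2_threshold``.  Returns index SNPs in selection order.  With an empty
    ``ld`` every unrecorded pair has r² = 0, so nothing is removed unless
    ``r2_threshold`` is 0 would still require r² > 0.
    """
    if ld is None:
        ld = LDInfo()
    for r in records:
        if r.pos is None or r.chrom is None:
            raise ValueError(f"{r.snp_id}: chrom/pos required for clumping")
    remaining = sorted(records, key=_clump_key)
    kept: list[SumStatRecord] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        remaining = [
            r
            for r in remaining
            if not (
                r.chrom == index.chrom
                and abs(r.pos - index.pos) <= window_bp
                and ld.r2(index.snp_id, r.snp_id) > r2_threshold
            )
        ]
    return kept


def snp_r2(record: SumStatRecord) -> float:
    """Variance of the trait explained by one SNP, from summary statistics.

    Uses r² = t² / (t² + n − 2) with t = beta/se — the squared-correlation
    identity for a simple regression — which needs no allele frequency and
    agrees with 2f(1−f)β² for standardized traits.
    """
    if record.n is None:
        raise ValueError(f"{record.snp_id}: sample size required for r2")
    if record.n < 3:
        raise ValueError(f"{record.snp_id}: n must be >= 3")
    t2 = (record.beta / record.se) ** 2
    return t2 / (t2 + record.n - 2)


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F-statistic: ((n−k−1)/k) · r²/(1−r²)."""
    if not 0 <= r2_total < 1:
        raise ValueError(f"r2_total must be in [0,1), got {r2_total}")
    if k < 1 or n <= k + 1:
        raise ValueError(f"need n > k+1 >= 2, got n={n}, k={k}")
    return (n - k - 1) / k * r2_total / (1 - r2_total)


def greedy_select(
    pairs: Sequence[HarmonizedPair],
    per_snp_r2: Mapping[str, float],
    het_alpha: float = 0.05,
    n_exposure: int | None = None,
) -> InstrumentSet:
    """Grow the instrument set by variance explained under a no-heterogeneity
    constraint.

    Step 1 seeds with the SNP of largest per-SNP r².  Each iteration adds the
    remaining SNP with the largest r² whose augmented set still passes
    Cochran's Q against the outcome (p >= ``het_alpha``, Q evaluated at the
    augmented set's IVW estimate); SNPs in linkage equilibrium make the
    cumulative r² the plain sum.  Stops when no candidate qualifies.  A
    1-SNP set has a 0-df Q, treated as passing.

    Ties in r² break toward the smaller snp_id for deterministic output.
    ``n_exposure`` (when given) is used to attach the F-statistic.
    """
    kept = [p for p in pairs if p.kept]
    if not kept:
        raise ValueError("no harmonized pairs to select from")
    missing = [p.snp_id for p in kept if p.snp_id not in per_snp_r2]
    if missing:
        raise ValueError(f"per_snp_r2 missing entries for {missing[:5]}")

    by_id = {p.snp_id: p for p in kept}
    order = sorted(by_id, key=lambda s: (-per_snp_r2[s], s))

    selected = [order[0]]
    r2_total = per_snp_r2[order[0]]
    log = [SelectionStep(order[0], r2_total, None)]
    candidates = order[1:]

    q_stat = q_pval = None
    while True:
        accepted = None
        for snp in candidates:
            trial = [by_id[s] for s in selected] + [by_id[snp]]
            beta_hat = ivw(trial).beta
            q, _, p = cochran_q(trial, beta_hat)
            if p >= het_alpha:
                accepted = (snp, q, p)
                break  # candidates are in descending r2: first pass maximizes r2
        if accepted is None:
            break
        snp, q_stat, q_pval = accepted
        selected.append(snp)
        r2_total += per_snp_r2[snp]
        log.append(SelectionStep(snp, r2_total, q_pval))
        candidates = [s for s in candidates if s != snp]

    f_stat = None
    if n_exposure is not None and r2_total < 1 and n_exposure > len(selected) + 1:
        f_stat = f_statistic(r2_total, n_exposure, len(selected))
    return InstrumentSet(
        snp_ids=selected,
        r2_total=r2_total,
        f_stat=f_stat,
        q_stat=q_stat,
        q_pval=q_pval,
        selection_log=log,
    )
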