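"""Leave-one-out influence analysis for IVW instrument sets.

Removing each SNP in turn and re-estimating exposes instruments that
dominate the causal estimate — a single variant whose omission moves the
p-value across the significance level, or flips the sign of the estimate,
is doing more work than an exchangeable instrument should.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .estimators import ivw
from .sumstats import HarmonizedPair

__all__ = ["LooTable", "leave_one_out", "flag_influential"]


@dataclass
class LooTable:
    """One row per omitted SNP plus the full-set row (``omitted = None``)."""

    rows: pd.DataFrame  # columns: omitted_snp_id, beta, se, pval, n_snps

    @property
    def full(self) -> pd.Series:
        return self.rows[self.rows.omitted_snp_id.isna()].iloc[0]

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def leave_one_out(pairs: Sequence[HarmonizedPair]) -> LooTable:
    """IVW with each SNP omitted in turn, in input order; the full-set
    estimate is the last row."""
    kept = [p for p in pairs if p.kept]
    if len(kept) < 2:
        raise ValueError("leave-one-out needs at least 2 SNPs")
    rows = []
    for i, omitted in enumerate(kept):
        rest = kept[:i] + kept[i + 1 :]
        res = ivw(rest)
        rows.append(
            {
                "omitted_snp_id": omitted.snp_id,
                "beta": res.beta,
                "se": res.se,
                "pval": res.pval,
                "n_snps": res.n_snps,
            }
        )
    full = ivw(kept)
    rows.append(
        {
            "omitted_snp_id": None,
            "beta": full.beta,
            "se": full.se,
            "pval": full.pval,
            "n_snps": full.n_snps,
        }
    )
    return LooTable(pd.DataFrame(rows))


def flag_influential(table: LooTable, alpha: float = 0.05) -> list[str]:
    """SNPs whose omission crosses ``alpha`` (either direction) or flips the
    sign of the estimate relative to the full set.

    The rule is an explicit convention: influence has no unique definition at
    summary level, so the criterion is configurable and reported, never
    silent.
    """
    full = table.full
    flags = []
    for _, row in table.rows.iterrows():
        if pd.isna(row.omitted_snp_id):
            continue
        crosses = (row.pval < alpha) != (full.pval < alpha)
        sign_flip = row.beta * full.beta < 0
        if crosses or sign_flip:
            flags.append(row.omitted_snp_id)
    return sorted(flags)
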