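"""GWAS summary-statistics records, delimited-text IO and allele harmonization.

A :class:`SumStatRecord` holds one SNP's marginal association with one trait
(beta or log-OR, SE, p-value, effect-allele frequency, sample sizes).  Two
traits' records are merged into :class:`HarmonizedPair` objects whose exposure
and outcome effects refer to the same effect allele; strand flips, allele
swaps and strand-ambiguous (palindromic) SNPs are resolved or dropped
according to the rules documented in :func:`harmonize`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SumStatRecord",
    "HarmonizedPair",
    "SumStatError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "harmonization_report",
    "pairs_to_records",
    "DEFAULT_COLUMNS",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column names; ``column_map`` in :func:`read_sumstats` maps these
#: keys to whatever the file's header uses.
DEFAULT_COLUMNS = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
    "n_case": "n_case",
    "n_control": "n_control",
}

_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")


class SumStatError(ValueError):
    """Raised for malformed summary-statistics input."""


@dataclass(frozen=True)
class SumStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele slope for continuous traits and the
    per-allele log odds ratio for binary traits.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None
    n_case: int | None = None
    n_control: int | None = None
    trait_id: str = ""
    trait_type: str = "continuous"

    def __post_init__(self) -> None:
        if self.effect_allele not in _VALID_ALLELES:
            raise SumStatError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not in A/C/G/T"
            )
        if self.other_allele not in _VALID_ALLELES:
            raise SumStatError(
                f"{self.snp_id}: other allele {self.other_allele!r} not in A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise SumStatError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise SumStatError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise SumStatError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumStatError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        if self.trait_type not in ("continuous", "binary"):
            raise SumStatError(f"{self.snp_id}: unknown trait_type {self.trait_type!r}")
        if (
            self.trait_type == "binary"
            and self.n is not None
            and self.n_case is not None
            and self.n_control is not None
            and self.n_case + self.n_control != self.n
        ):
            raise SumStatError(
                f"{self.snp_id}: n_case + n_control != n "
                f"({self.n_case} + {self.n_control} != {self.n})"
            )

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T or C/G SNPs."""
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common effect allele.

    ``action_taken`` records how the outcome record was reconciled:
    ``none`` (already aligned), ``flipped`` (outcome beta negated, eaf
    complemented), ``dropped_palindromic`` or ``dropped_mismatch``.
    Dropped pairs carry the exposure effect but NaN outcome fields.
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float | None
    action_taken: str

    @property
    def kept(self) -> bool:
        return self.action_taken in ("none", "flipped")


def _coerce(value, kind, where):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return kind(value)
    except (TypeError, ValueError) as exc:
        raise SumStatError(f"{where}: cannot parse {value!r}") from exc


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_id: str = "",
    trait_type: str = "continuous",
    sep: str | None = None,
    strict: bool = False,
) -> list[SumStatRecord]:
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    column_map
        Maps canonical field names (keys of :data:`DEFAULT_COLUMNS`) to the
        file's column names.  Unmapped optional fields are taken from columns
        with the canonical name when present.
    trait_id, trait_type
        Trait metadata stamped on every record.
    sep
        Field separator; inferred (``\\t`` vs ``,``) when None.
    strict
        When True any invalid row aborts the read; otherwise invalid rows are
        skipped and reported on the returned list's ``skipped`` attribute
        (list of ``(line_number, message)``).

    Raises
    ------
    SumStatError
        If a mandatory column is missing, or on the first bad row when
        ``strict``.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [f for f in _MANDATORY if colmap[f] not in df.columns]
    if missing:
        raise SumStatError(
            f"{path}: missing mandatory column(s) "
            + ", ".join(colmap[f] for f in missing)
        )

    records: list[SumStatRecord] = []
    skipped: list[tuple[int, str]] = []
    for i, (_, row) in enumerate(df.iterrows(), start=2):  # header = line 1
        get = lambda f: row[colmap[f]] if colmap[f] in df.columns else None
        try:
            rec = SumStatRecord(
                snp_id=str(get("snp_id")),
                chrom=None if get("chrom") is None else str(get("chrom")),
                pos=_coerce(get("pos"), lambda v: int(float(v)), f"line {i} pos"),
                effect_allele=str(get("effect_allele")).upper(),
                other_allele=str(get("other_allele")).upper(),
                eaf=_coerce(get("eaf"), float, f"line {i} eaf"),
                beta=_coerce(get("beta"), float, f"line {i} beta"),
                se=_coerce(get("se"), float, f"line {i} se"),
                pval=_coerce(get("pval"), float, f"line {i} pval"),
                n=_coerce(get("n"), lambda v: int(float(v)), f"line {i} n"),
                n_case=_coerce(get("n_case"), lambda v: int(float(v)), f"line {i} n_case"),
                n_control=_coerce(get("n_control"), lambda v: int(float(v)), f"line {i} n_control"),
                trait_id=trait_id,
                trait_type=trait_type,
            )
        except (SumStatError, TypeError) as exc:
            if strict:
                raise SumStatError(f"{path} line {i}: {exc}") from exc
            skipped.append((i, str(exc)))
            continue
        if rec.beta is None or rec.se is None or rec.pval is None:
            msg = f"{rec.snp_id}: beta/se/pval missing"
            if strict:
                raise SumStatError(f"{path} line {i}: {msg}")
            skipped.append((i, msg))
            continue
        records.append(rec)

    out = _RecordList(records)
    out.skipped = skipped
    return out


class _RecordList(list):
    """List of records that also carries the per-line skip report."""

    skipped: list[tuple[int, str]] = []


def write_sumstats(records: Iterable[SumStatRecord], path, sep: str = "\t") -> None:
    """Write records in the canonical column layout (round-trips with
    :func:`read_sumstats`)."""
    rows = [
        {
            "snp_id": r.snp_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "effect_allele": r.effect_allele,
            "other_allele": r.other_allele,
            "eaf": r.eaf,
            "beta": r.beta,
            "se": r.se,
            "pval": r.pval,
            "n": r.n,
            "n_case": r.n_case,
            "n_control": r.n_control,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def _index_by_snp(records: Sequence[SumStatRecord], label: str) -> dict[str, SumStatRecord]:
    index: dict[str, SumStatRecord] = {}
    for r in records:
        if r.snp_id in index:
            raise SumStatError(f"duplicate snp_id {r.snp_id!r} in {label} records")
        index[r.snp_id] = r
    return index


def harmonize(
    exposure: Sequence[SumStatRecord],
    outcome: Sequence[SumStatRecord],
    palindromic_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Only SNPs present in both lists are processed (the merge is an
    intersection; dropped ids are counted in :func:`harmonization_report`).
    For each shared SNP:

    * alleles already matching → kept as-is (``none``);
    * effect/other swapped → outcome beta negated, eaf complemented
      (``flipped``);
    * matching only after complementing the outcome alleles → treated as a
      strand flip, then the two rules above apply;
    * palindromic SNPs (A/T or C/G) cannot be strand-checked from alleles
      alone: they are dropped when either eaf is missing or within
      ``palindromic_eaf_window`` of 0.5; with informative frequencies the
      outcome is additionally flipped when the two eafs sit on opposite
      sides of 0.5;
    * any other allele combination → ``dropped_mismatch``.
    """
    exp_ix = _index_by_snp(exposure, "exposure")
    out_ix = _index_by_snp(outcome, "outcome")

    pairs: list[HarmonizedPair] = []
    for snp_id, e in exp_ix.items():
        if snp_id not in out_ix:
            continue
        o = out_ix[snp_id]

        if e.is_palindromic:
            allele_sets_match = {o.effect_allele, o.other_allele} == {
                e.effect_allele,
                e.other_allele,
            }
            if not allele_sets_match:
                pairs.append(_dropped(e, "dropped_mismatch"))
                continue
            ambiguous = (
                e.eaf is None
                or o.eaf is None
                or abs(e.eaf - 0.5) < palindromic_eaf_window
                or abs(o.eaf - 0.5) < palindromic_eaf_window
            )
            if ambiguous:
                pairs.append(_dropped(e, "dropped_palindromic"))
                continue
            # frequencies are informative: use them to orient the outcome.
            o_eaf_for_exp_allele = o.eaf if o.effect_allele == e.effect_allele else 1 - o.eaf
            same_side = (e.eaf > 0.5) == (o_eaf_for_exp_allele > 0.5)
            if o.effect_allele == e.effect_allele:
                action = "none" if same_side else "flipped"
            else:
                action = "flipped" if same_side else "none"
            # a frequency-discordant direct match is really the complementary
            # strand's opposite allele, hence the cross-over above.
            pairs.append(_aligned(e, o, action))
            continue

        o_eff, o_oth = o.effect_allele, o.other_allele
        if {o_eff, o_oth} != {e.effect_allele, e.other_allele}:
            o_eff, o_oth = _COMPLEMENT[o_eff], _COMPLEMENT[o_oth]  # try other strand
        if (o_eff, o_oth) == (e.effect_allele, e.other_allele):
            pairs.append(_aligned(e, o, "none"))
        elif (o_eff, o_oth) == (e.other_allele, e.effect_allele):
            pairs.append(_aligned(e, o, "flipped"))
        else:
            pairs.append(_dropped(e, "dropped_mismatch"))
    return pairs


def _aligned(e: SumStatRecord, o: SumStatRecord, action: str) -> HarmonizedPair:
    if action == "flipped":
        beta_out = -o.beta
        eaf = None if e.eaf is None else e.eaf
    else:
        beta_out = o.beta
        eaf = e.eaf
    return HarmonizedPair(
        snp_id=e.snp_id,
        beta_exposure=e.beta,
        se_exposure=e.se,
        beta_outcome=beta_out,
        se_outcome=o.se,
        eaf=eaf,
        action_taken=action,
    )


def _dropped(e: SumStatRecord, action: str) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=e.snp_id,
        beta_exposure=e.beta,
        se_exposure=e.se,
        beta_outcome=float("nan"),
        se_outcome=float("nan"),
        eaf=e.eaf,
        action_taken=action,
    )


def harmonization_report(
    exposure: Sequence[SumStatRecord],
    outcome: Sequence[SumStatRecord],
    pairs: Sequence[HarmonizedPair],
) -> dict:
    """JSON-serializable summary of a harmonization run (counts per action,
    intersection sizes, and the palindromic-handling caveat)."""
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.action_taken] = counts.get(p.action_taken, 0) + 1
    exp_ids = {r.snp_id for r in exposure}
    out_ids = {r.snp_id for r in outcome}
    return {
        "n_exposure": len(exp_ids),
        "n_outcome": len(out_ids),
        "n_shared": len(exp_ids & out_ids),
        "n_exposure_only": len(exp_ids - out_ids),
        "n_outcome_only": len(out_ids - exp_ids),
        "actions": counts,
        "note": (
            "palindromic SNPs dropped when eaf is missing or near 0.5; "
            "the window is a configurable convention, not inferred from data"
        ),
    }


def pairs_to_records(
    pairs: Sequence[HarmonizedPair],
    effect_allele: str = "A",
    other_allele: str = "G",
) -> tuple[list[SumStatRecord], list[SumStatRecord]]:
    """Rebuild (exposure, outcome) record lists from kept harmonized pairs.

    Used to express round-trip properties (re-harmonizing the output must be
    a no-op); alleles are synthesized since pairs no longer carry them.
    """
    exp, out = [], []
    for p in pairs:
        if not p.kept:
            continue
        common = dict(
            snp_id=p.snp_id,
            effect_allele=effect_allele,
            other_allele=other_allele,
            eaf=p.eaf,
        )
        exp.append(SumStatRecord(beta=p.beta_exposure, se=p.se_exposure, pval=1.0, **common))
        out.append(SumStatRecord(beta=p.beta_outcome, se=p.se_outcome, pval=1.0, **common))
    return exp, out


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
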