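import numpy as np
import pytest

from netmr import HarmonizedPair, SumStatRecord, make_fixture


def make_pair(snp_id="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02, eaf=0.3, action="none"):
    return HarmonizedPair(
        snp_id=snp_id,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        eaf=eaf,
        action_taken=action,
    )


def random_pairs(rng, n, theta=0.4, sy=0.05, het_sd=0.0):
    """Harmonized pairs around a common causal ratio ``theta`` with optional
    per-SNP heterogeneity of SD ``het_sd`` on the ratio scale."""
    pairs = []
    for j in range(n):
        bx = rng.uniform(0.05, 0.3) * rng.choice([-1, 1])
        ratio = theta + (rng.normal(0, het_sd) if het_sd else 0.0)
        by = ratio * bx + rng.normal(0, sy)
        pairs.append(make_pair(f"rs{j+1:04d}", bx=bx, by=by, sy=sy))
    return pairs


def make_record(snp_id="rs1", **kw):
    defaults = dict(
        chrom="1",
        pos=1_000_000,
        effect_allele="A",
        other_allele="G",
        eaf=0.3,
        beta=0.1,
        se=0.02,
        pval=1e-5,
        n=10_000,
    )
    defaults.update(kw)
    return SumStatRecord(snp_id=snp_id, **defaults)


@pytest.fixture(scope="session")
def mediation_data():
    return make_fixture("mediation")


@pytest.fixture(scope="session")
def outlier_data():
    return make_fixture("outlier_snp")


@pytest.fixture(scope="session")
def null_data():
    return make_fixture("null")
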