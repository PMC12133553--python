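import numpy as np
import pytest

from mrmediate.instruments import HarmonizedPair
from mrmediate.summary_io import AssociationRecord


def make_pair(
    snp_id="rs1",
    beta_exp=0.1,
    se_exp=0.02,
    beta_out=0.05,
    se_out=0.01,
    **kw,
) -> HarmonizedPair:
    defaults = dict(
        effect_allele="A",
        other_allele="G",
        pval_exp=1e-10,
        pval_out=0.5,
        eaf_exp=0.3,
        eaf_out=0.3,
        chrom="1",
        pos=1000,
        n_exp=100_000.0,
        n_out=500_000.0,
    )
    defaults.update(kw)
    return HarmonizedPair(
        snp_id=snp_id, beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out, **defaults,
    )


def pairs_from_ratios(ratios, ratio_ses=None, beta_exp=1.0, se_exp=1e-6):
    """Pairs whose Wald ratios and first-order ratio SEs are exactly as given.

    With beta_exp = 1 and negligible se_exp, ratio = beta_out and
    ratio SE = se_out, so toy configurations map directly onto pairs.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratio_ses is None:
        ratio_ses = np.full(ratios.shape, 0.1)
    return [
        make_pair(
            snp_id=f"rs{i + 1}", beta_exp=beta_exp, se_exp=se_exp,
            beta_out=float(r), se_out=float(s),
        )
        for i, (r, s) in enumerate(zip(ratios, ratio_ses))
    ]


def make_record(
    snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", eaf=0.3,
    beta=0.1, se=0.02, pval=None, n=100_000.0, trait_id="trait",
) -> AssociationRecord:
    if pval is None:
        from scipy import stats

        pval = float(2 * stats.norm.sf(abs(beta / se)))
    return AssociationRecord(
        snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n, trait_id=trait_id,
    )


@pytest.fixture
def small_study():
    """A small clean simulated study shared across tests."""
    from mrmediate.synthetic_data import SimulationConfig, simulate_mediation_gwas

    return simulate_mediation_gwas(SimulationConfig(m_snps=60, seed=42))
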