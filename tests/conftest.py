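import numpy as np
import pytest

from nexuslipid.mr import HarmonizedPair


def make_pairs(betas_exp, betas_out, ses_out, ses_exp=None, eafs=None):
    """Convenience constructor for HarmonizedPair fixtures."""
    n = len(betas_exp)
    ses_exp = ses_exp if ses_exp is not None else [0.01] * n
    eafs = eafs if eafs is not None else [0.3] * n
    return [
        HarmonizedPair(snp_id=f"s{i}", beta_exp=float(be), se_exp=float(se_e),
                       beta_out=float(bo), se_out=float(so),
                       eaf_exp=float(f), eaf_out=float(f))
        for i, (be, bo, so, se_e, f)
        in enumerate(zip(betas_exp, betas_out, ses_out, ses_exp, eafs))
    ]


@pytest.fixture
def ratio_fixture():
    """Wald ratios (0.5, 0.3) with ratio SEs (0.1, 0.2): beta_exp = 1 so the
    ratio SE equals se_out and weights are (100, 25)."""
    return make_pairs([1.0, 1.0], [0.5, 0.3], [0.1, 0.2])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
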