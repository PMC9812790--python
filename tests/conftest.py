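import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from mrkit.instruments import HarmonizedDataset, HarmonizedRow, harmonize
from mrkit.simulate import SyntheticConfig, simulate_two_sample
from mrkit.summary_io import SummaryAssociation


def make_assoc(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-10,
               eaf=0.3, chrom="1", pos=1000, n=20000, trait=""):
    return SummaryAssociation(
        snp_id=snp, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, eaf=eaf, chrom=chrom, pos=pos, n=n, trait=trait,
    )


def make_harmonized(bx, by, sy, sx=None, ids=None):
    """HarmonizedDataset straight from effect arrays (all rows retained)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    ids = ids or [f"rs{i+1}" for i in range(bx.size)]
    rows = [
        HarmonizedRow(snp_id=ids[i], beta_x=bx[i], se_x=sx[i], beta_y=by[i],
                      se_y=sy[i], eaf_x=0.3, eaf_y=0.3, action="unchanged")
        for i in range(bx.size)
    ]
    return HarmonizedDataset(rows)


def harmonized_from_sim(dataset):
    """Harmonize a simulated dataset's exposure/outcome tables."""
    return harmonize(dataset.exposure, dataset.outcome)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def strong_sim():
    """A clean strong-instrument dataset with a known causal effect of 0.2."""
    return simulate_two_sample(
        SyntheticConfig(j=50, theta_true=0.2, pleiotropy="none", seed=7)
    )
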