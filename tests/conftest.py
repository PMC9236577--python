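import numpy as np
import pytest

from svphylo.model import build_panel
from svphylo.simulate import SimConfig, simulate_cohort


@pytest.fixture
def tiny_panel():
    """1 SV (2 breakpoints), 1 SNV, 2 segments."""
    return build_panel(
        [
            dict(id="b1", chrom="chr1", pos=100, direction="right", mate_id="b2"),
            dict(id="b2", chrom="chr1", pos=500, direction="left", mate_id="b1"),
        ],
        [dict(id="s1", chrom="chr1", pos=800)],
        [dict(chrom="chr1", start=1, end=600), dict(chrom="chr1", start=601, end=1000)],
    )


@pytest.fixture
def make_cohort():
    """Factory for desk-scale simulated cohorts."""

    def _make(seed=0, n_leaves=2, m_samples=3, lambda_total=3.0, snv_rate=4.0,
              c_max=6, **kw):
        cfg = SimConfig.toy(
            n_leaves=n_leaves, m_samples=m_samples, lambda_total=lambda_total,
            snv_rate=snv_rate, c_max=c_max, seed=seed, **kw,
        )
        return simulate_cohort(cfg)

    return _make


def truth_columns_after_filter(gt):
    """Slice the true C to the variant-bearing segments the solver sees."""
    keep = np.asarray(gt.panel.Q.sum(axis=0) > 0)
    cols = np.concatenate([np.ones(gt.panel.n_variants, bool), keep, keep])
    return gt.profiles.C[:, cols]
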