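import numpy as np
import pandas as pd
import pytest

from mrtri.datatypes import HarmonizedSet, LDMatrix, SummaryStats


def make_summary(ids, betas, ses, pvals, eas=None, oas=None, eafs=None, trait="trait", regions=None):
    n = len(ids)
    return SummaryStats(
        trait,
        pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": "1",
                "pos": np.arange(1, n + 1),
                "effect_allele": eas or ["A"] * n,
                "other_allele": oas or ["G"] * n,
                "eaf": eafs if eafs is not None else [0.3] * n,
                "beta": betas,
                "se": ses,
                "pvalue": pvals,
                "region": regions or [""] * n,
            }
        ),
    )


def random_harmonized(rng, n=None) -> HarmonizedSet:
    n = n if n is not None else int(rng.integers(3, 101))
    return HarmonizedSet.from_arrays(
        beta_exp=rng.normal(0.3, 0.1, n) * rng.choice([-1, 1], n),
        se_exp=rng.uniform(0.01, 0.05, n),
        beta_out=rng.normal(0.0, 0.1, n),
        se_out=rng.uniform(0.01, 0.1, n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def worked_ivw_set():
    """Instruments whose Wald ratios/SEs are (0.2, 0.3, 0.4) / (0.1, 0.1, 0.2)."""
    return HarmonizedSet.from_arrays(
        beta_exp=[1.0, 1.0, 1.0],
        se_exp=[0.01, 0.01, 0.01],
        beta_out=[0.2, 0.3, 0.4],
        se_out=[0.1, 0.1, 0.2],
    )


@pytest.fixture
def identity_ld():
    def _make(ids):
        return LDMatrix(list(ids), np.eye(len(ids)))

    return _make
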