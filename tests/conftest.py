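import numpy as np
import pandas as pd
import pytest

from mrmediate import COLUMNS, HarmonizedPair, SummaryStatSet


def make_sumstats(trait_id="TRAIT", trait_type="continuous", **overrides):
    """Small well-formed summary-statistic set (3 variants by default)."""
    base = {
        "variant_id": ["rs1", "rs2", "rs3"],
        "chrom": ["1", "1", "1"],
        "pos": [1_000_000, 1_050_000, 1_100_000],
        "effect_allele": ["A", "C", "T"],
        "other_allele": ["G", "T", "G"],
        "beta": [0.12, -0.08, 0.30],
        "se": [0.01, 0.02, 0.03],
        "eaf": [0.25, 0.40, 0.10],
        "pval": [1e-10, 1e-5, 1e-12],
        "n": [30000, 30000, 30000],
    }
    base.update(overrides)
    return SummaryStatSet(trait_id, trait_type, pd.DataFrame(base)[COLUMNS])


def make_pair(beta_exp, se_exp, beta_out, se_out, exposure_id="EXP",
              outcome_id="OUT"):
    """HarmonizedPair straight from effect arrays (all rows kept)."""
    beta_exp = np.asarray(beta_exp, float)
    k = beta_exp.size
    rows = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(k)],
        "beta_exp": beta_exp, "se_exp": np.asarray(se_exp, float),
        "eaf_exp": np.full(k, 0.3), "pval_exp": np.full(k, 1e-10),
        "n_exp": np.full(k, 30000),
        "beta_out": np.asarray(beta_out, float),
        "se_out": np.asarray(se_out, float),
        "eaf_out": np.full(k, 0.3), "n_out": np.full(k, 100000),
        "action": "kept",
    })
    return HarmonizedPair(exposure_id, outcome_id, rows)


def random_pair(rng, k=None):
    """Random well-conditioned instrument set for oracle comparisons."""
    if k is None:
        k = int(rng.integers(3, 11))
    be = rng.uniform(0.05, 0.4, k) * rng.choice([-1, 1], k)
    se_e = rng.uniform(0.005, 0.02, k)
    bo = 0.2 * be + rng.normal(0, 0.02, k)
    se_o = rng.uniform(0.01, 0.08, k)
    return make_pair(be, se_e, bo, se_o)


@pytest.fixture
def toy_sumstats():
    return make_sumstats()
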