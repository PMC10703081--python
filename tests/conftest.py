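import numpy as np
import pandas as pd
import pytest

from mrkit.sumstats import SUMSTATS_COLUMNS, HarmonizedInstrumentSet, SummaryStats


def make_sumstats(
    trait_name,
    variant_ids,
    betas,
    ses,
    eafs=None,
    trait_type="continuous",
    effect_alleles=None,
    other_alleles=None,
    positions=None,
    chromosomes=None,
    n=10_000.0,
    p_values=None,
):
    m = len(variant_ids)
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    if p_values is None:
        from scipy import stats
        p_values = np.clip(2 * stats.norm.sf(np.abs(betas / ses)), 1e-300, 1.0)
    table = pd.DataFrame({
        "variant_id": variant_ids,
        "chromosome": chromosomes if chromosomes is not None else "1",
        "position": positions if positions is not None else 1 + 1000 * np.arange(m),
        "effect_allele": effect_alleles if effect_alleles is not None else "A",
        "other_allele": other_alleles if other_alleles is not None else "G",
        "eaf": eafs if eafs is not None else 0.3,
        "beta": betas,
        "se": ses,
        "p_value": p_values,
        "n": float(n),
        "n_case": np.nan,
        "n_control": np.nan,
    }, columns=SUMSTATS_COLUMNS)
    scale = "log_odds" if trait_type == "binary" else "sd_units"
    return SummaryStats(trait_name, trait_type, scale, table)


def make_hset(bx, sx, by, sy, mafs=None, ids=None, exposure="exposure", outcome="outcome"):
    m = len(bx)
    ids = ids if ids is not None else [f"snp{i:03d}" for i in range(m)]
    table = pd.DataFrame({
        "variant_id": ids,
        "chromosome": "1",
        "position": 1 + 1000 * np.arange(m),
        f"beta_exp__{exposure}": np.asarray(bx, float),
        f"se_exp__{exposure}": np.asarray(sx, float),
        f"eaf_exp__{exposure}": 0.3,
        "beta_outcome": np.asarray(by, float),
        "se_outcome": np.asarray(sy, float),
        "eaf_outcome": 0.3,
        "maf": mafs if mafs is not None else 0.3,
        "effect_allele": "A",
        "other_allele": "G",
        "action": "kept",
    })
    return HarmonizedInstrumentSet([exposure], outcome, table)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_hset():
    return make_hset(
        bx=[0.1, 0.2, 0.3, 0.15, 0.25],
        sx=[0.01] * 5,
        by=[0.02, 0.041, 0.06, 0.029, 0.052],
        sy=[0.01] * 5,
    )
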