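import numpy as np
import pandas as pd
import pytest

from mrchain import SimConfig, harmonize, simulate_chain_gwas


@pytest.fixture(scope="session")
def chain():
    """One simulated clean chain with a known truth, reused across tests."""
    cfg = SimConfig(n_snps=40, seed=11, palindrome_frac=0.0)
    gx, gy, gz, truth = simulate_chain_gwas(cfg)
    return cfg, gx, gy, gz, truth


def x_instruments(gx, truth):
    """Restrict an exposure table to its own dedicated instrument block."""
    return gx[gx["variant_id"].isin(truth.x_instrument_ids)].reset_index(drop=True)


@pytest.fixture(scope="session")
def harmonized_xy(chain):
    _, gx, gy, _, truth = chain
    return harmonize(x_instruments(gx, truth), gy)


@pytest.fixture(scope="session")
def harmonized_xz(chain):
    _, gx, _, gz, truth = chain
    return harmonize(x_instruments(gx, truth), gz)


def make_gwas(
    variant_id,
    beta,
    se,
    eaf=None,
    effect_allele=None,
    other_allele=None,
    chrom=None,
    pos=None,
    pvalue=None,
    n=10000,
):
    """Hand-build a small GWAS table with consistent defaults."""
    from scipy import stats

    j = len(variant_id)
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if pvalue is None:
        pvalue = 2 * stats.norm.sf(np.abs(beta) / se)
    return pd.DataFrame(
        {
            "variant_id": variant_id,
            "chrom": chrom if chrom is not None else ["1"] * j,
            "pos": pos if pos is not None else (1 + 1000 * np.arange(j)),
            "effect_allele": effect_allele if effect_allele is not None else ["A"] * j,
            "other_allele": other_allele if other_allele is not None else ["G"] * j,
            "eaf": eaf if eaf is not None else [0.3] * j,
            "beta": beta,
            "se": se,
            "pvalue": pvalue,
            "n": float(n),
        }
    )


def make_harmonized(beta_exp, se_exp, beta_out, se_out, eaf=None, n_exp=10000.0, n_out=10000.0):
    """Hand-build a harmonized table directly from aligned effect arrays."""
    from scipy import stats

    j = len(beta_exp)
    beta_exp = np.asarray(beta_exp, dtype=float)
    se_exp = np.asarray(se_exp, dtype=float)
    beta_out = np.asarray(beta_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    eaf = np.asarray(eaf if eaf is not None else [0.3] * j, dtype=float)
    from mrchain import HarmonizedTable

    table = pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(j)],
            "chrom": ["1"] * j,
            "pos": 1 + 1000 * np.arange(j),
            "effect_allele": ["A"] * j,
            "other_allele": ["G"] * j,
            "eaf_exp": eaf,
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "p_exp": 2 * stats.norm.sf(np.abs(beta_exp) / se_exp),
            "n_exp": n_exp,
            "eaf_out": eaf,
            "beta_out": beta_out,
            "se_out": se_out,
            "p_out": 2 * stats.norm.sf(np.abs(beta_out) / se_out),
            "n_out": n_out,
        }
    )
    return HarmonizedTable(table=table)
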