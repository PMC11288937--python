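import numpy as np
import pandas as pd
import pytest

import mrmediate as mm


@pytest.fixture
def selection_config():
    return mm.SelectionConfig()


@pytest.fixture(scope="session")
def chain():
    """One simulated three-sample dataset under the default scenario."""
    return mm.simulate_chain(mm.reference_scenario(seed=42))


def make_sumstats_frame(**overrides) -> pd.DataFrame:
    """Three well-formed rows in the default file dialect."""
    base = {
        "SNP": ["rs1", "rs2", "rs3"],
        "chr": ["1", "1", "2"],
        "pos": [1000, 500000, 2000],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "eaf": [0.25, 0.4, 0.1],
        "beta": [0.1, -0.05, 0.2],
        "se": [0.02, 0.01, 0.05],
        "pval": [5.7e-7, 5.7e-7, 6.3e-5],
        "samplesize": [10000, 10000, 10000],
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def sumstats_file(tmp_path):
    def _write(df: pd.DataFrame, name="sumstats.tsv", sep="\t"):
        path = tmp_path / name
        df.to_csv(path, sep=sep, index=False)
        return path
    return _write


def make_panel(snp_ids, pvals, chroms=None, positions=None, betas=None, ses=None,
               eafs=None, trait_id="t", trait_type="exposure",
               effect_alleles=None, other_alleles=None, n=10000):
    """Hand-built trait panel for targeted unit tests."""
    k = len(snp_ids)
    return mm.panel_from_arrays(
        trait_id, trait_type,
        snp_id=snp_ids,
        chrom=chroms if chroms is not None else ["1"] * k,
        pos=positions if positions is not None else [1000 * (i + 1) for i in range(k)],
        effect_allele=effect_alleles if effect_alleles is not None else ["A"] * k,
        other_allele=other_alleles if other_alleles is not None else ["G"] * k,
        eaf=eafs if eafs is not None else [0.3] * k,
        beta=betas if betas is not None else [0.1] * k,
        se=ses if ses is not None else [0.02] * k,
        pval=np.asarray(pvals, dtype=float),
        n=[n] * k,
    )
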