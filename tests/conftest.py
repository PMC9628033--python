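import numpy as np
import pandas as pd
import pytest

from methpair.config import SimulationConfig
from methpair.containers import BetaMatrix, ProbeAnnotation
from methpair.simulate import generate_genotypes, generate_paired_dataset, generate_probe_annotation


def make_annotation(positions, chrom="chr1", regions=None, flags=None):
    """Small hand-built annotation; positions are 1-based."""
    n = len(positions)
    tab = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else chrom,
            "pos": positions,
            "region": regions if regions is not None else ["Body"] * n,
            "flag_xy": [False] * n,
            "flag_snp": [False] * n,
            "flag_multimap": [False] * n,
        },
        index=pd.Index([f"cg{i:05d}" for i in range(n)], name="cpg_id"),
    )
    if flags:
        for col, idxs in flags.items():
            tab.loc[tab.index[idxs], col] = True
    return ProbeAnnotation(tab)


def combined_tissue_matrices(ds):
    """Concatenate the two batches per tissue, preserving pairing metadata."""
    out = {}
    for tissue in ("brain", "buccal"):
        vals = pd.concat(
            [ds.betas[(tissue, "batch1")].values, ds.betas[(tissue, "batch2")].values],
            axis=1,
        )
        out[tissue] = BetaMatrix(
            vals, annotation=ds.annotation, sheet=ds.sheet.loc[vals.columns]
        )
    return out


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_pairs=60, n_cpgs=800, n_snps=200, seed=42, batch_sizes=(24, 36),
        frac_correlated=0.1,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_paired_dataset(small_config)


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return generate_probe_annotation(small_config)


@pytest.fixture(scope="session")
def small_genotypes(small_config):
    return generate_genotypes(small_config)
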