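import numpy as np
import pandas as pd
import pytest

import methatlas as ma


def make_sites(rows, called=None):
    """Build a site table from (chrom, pos, strand, trinuc, mc, total) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "trinucleotide", "mc_reads",
                       "total_reads"]
    )
    df["context"] = ma.io.trinucleotide_context(df["trinucleotide"].to_numpy())
    if called is not None:
        df["called"] = called
    return df


@pytest.fixture(scope="session")
def sim_result():
    """A small compartmentalised methylome with genes and planted islands."""
    cfg = ma.SimConfig(seed=11, chrom_length=400_000, n_genes=30,
                       island_fraction=0.4)
    return ma.simulate_methylome(cfg)


@pytest.fixture(scope="session")
def called_sites(sim_result):
    est = ma.estimate_nonconversion(sim_result.sites, ["lambda"])
    return ma.call_sites(sim_result.sites, est)


@pytest.fixture(scope="session")
def nuclear_called(called_sites):
    return called_sites[called_sites["chrom"] != "lambda"]
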