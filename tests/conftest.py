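import logging

import numpy as np
import pytest

import dhsexmap as d

logging.getLogger("dhsexmap").setLevel(logging.ERROR)


def small_config(seed: int = 1, **kwargs) -> d.PanelConfig:
    """A compact panel (3 chromosomes, 12 contigs each) for fast tests."""
    defaults = dict(n_chromosomes=3, contigs_per_chrom=12, snps_per_contig=12, seed=seed)
    defaults.update(kwargs)
    return d.PanelConfig(**defaults)


@pytest.fixture(scope="session")
def small_panel():
    """One compact simulated panel shared by read-only tests."""
    cfg = small_config(seed=42)
    truth, records, profile = d.simulate_panel(cfg)
    return cfg, truth, records, profile


@pytest.fixture(scope="session")
def default_panel():
    """The full-size default panel (74 DH, 10 chromosomes)."""
    cfg = d.PanelConfig(seed=7)
    truth, records, profile = d.simulate_panel(cfg)
    return cfg, truth, records, profile


def make_record(genotypes, depths, qual=1500.0, n_alleles=2, is_indel=False,
                contig="ctg", pos=100):
    return d.SnpRecord(contig=contig, pos=pos, ref="A", alt="C",
                       n_alleles=n_alleles,
                       genotypes=np.asarray(genotypes, dtype=np.int8),
                       depths=np.asarray(depths, dtype=np.int32),
                       qual=qual, is_indel=is_indel)
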