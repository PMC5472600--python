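import numpy as np
import pytest

from mullersig import SimulationConfig, generate_dataset
from mullersig.models import GeneModel, TagLibrary


def small_config(seed=11, **overrides) -> SimulationConfig:
    """A scaled-down simulation for fast per-module tests."""
    kwargs = dict(seed=seed, n_genes=40, n_chroms=2, chrom_length=400_000,
                  frac_small_rna=0.1, frac_unscored=0.05, n_muller=8, n_rod=8,
                  n_tf_k27=4, library_size=20_000)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size dataset shared across tests that need realistic scale."""
    return generate_dataset(SimulationConfig(seed=20170615))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, n_genes=20, n_tags=500, chrom_length=60_000,
                    n_pairs=2):
    """A tiny random (genes, chip pairs, chrom_lengths) instance."""
    chrom_lengths = {"chr1": chrom_length, "chr2": chrom_length}
    genes = []
    for i in range(n_genes):
        chrom = "chr1" if i % 2 == 0 else "chr2"
        tss = int(rng.integers(0, chrom_length))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            start, end = tss, min(tss + 2000, chrom_length)
        else:
            start, end = max(tss - 2000, 0), tss + 1
        genes.append(GeneModel(f"g{i:03d}", chrom, strand, start, end))
    pairs = []
    for j in range(n_pairs):
        def lib(name):
            return TagLibrary(name, {
                c: rng.integers(0, L, size=rng.integers(1, n_tags + 1))
                for c, L in chrom_lengths.items()})
        pairs.append((lib(f"test{j}"), lib(f"input{j}")))
    return genes, pairs, chrom_lengths
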