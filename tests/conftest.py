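import numpy as np
import pytest

from corvmhc import simulate
from corvmhc.selection import CodonAlignment


@pytest.fixture(scope="session")
def tsp_pool():
    cfg = simulate.AlleleSimConfig(scenario="tsp", seed=11, alleles_per_class=2)
    pool, truth = simulate.simulate_allele_pools(cfg)
    return pool, truth


@pytest.fixture(scope="session")
def small_alignment():
    """Deterministic 6-sequence codon alignment with two species labels."""
    rng = np.random.default_rng(42)
    cfg = simulate.AlleleSimConfig(
        scenario="null", seed=42, n_species=2, n_classes=2, alleles_per_class=3,
        n_codons=20, selected_codons=(3, 7, 11),
    )
    pool, _ = simulate.simulate_allele_pools(cfg)
    return pool.to_alignment()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_alignment(seqs, species=None, ids=None):
    n = len(seqs)
    return CodonAlignment(
        ids or [f"s{i}" for i in range(n)],
        species or ["sp"] * n,
        list(seqs),
    )


@pytest.fixture(scope="session")
def neutral_alignment():
    """Sequences diverged by substitutions with no selective structure."""
    rng = np.random.default_rng(7)
    from corvmhc.simulate import _mutate_neutral, _random_sense_codon
    root = "".join(_random_sense_codon(rng) for _ in range(82))
    all_nt = np.arange(82 * 3)
    seqs = [_mutate_neutral(root, rng.poisson(12), all_nt, rng) for _ in range(12)]
    return make_alignment(seqs)
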