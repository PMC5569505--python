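"""Shared fixtures: the default synthetic community and its binning are
expensive enough to build once per session."""

from __future__ import annotations

import numpy as np
import pytest

from magsom import binning, synthetic


@pytest.fixture(scope="session")
def community():
    """Default five-genome community, seed 1, with reads."""
    return synthetic.simulate_community(seed=1)


@pytest.fixture(scope="session")
def binned(community):
    """Compositional binning of the default community."""
    return binning.bin_scaffolds(community.scaffolds, seed=7)


@pytest.fixture(scope="session")
def two_genome_scaffolds():
    """Two compositionally distinct genomes cut into 100 scaffolds each;
    small enough for permutation/purity tests."""
    rng = np.random.default_rng(123)
    scaffolds = {}
    truth = {}
    for gid, gc in (("a", 0.35), ("b", 0.62)):
        spec = synthetic.GenomeSpec(gid, 100 * 6000, gc, seed=int(rng.integers(2**31)))
        genome = synthetic.generate_genome(spec)
        for sc in synthetic.fragment_genome(genome, genome_id=gid, lengths=[6000] * 100):
            scaffolds[sc.scaffold_id] = sc.sequence
            truth[sc.scaffold_id] = gid
    return scaffolds, truth
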