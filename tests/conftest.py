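import numpy as np
import pytest

from phylofoot.genome import Genome, Site
from phylofoot.motifs import BackgroundModel, Motif
from phylofoot.simulate import FixtureConfig, generate_group


@pytest.fixture
def bg():
    return BackgroundModel.uniform()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_motif(rng, mid="m", n_sites=5, width=16, bg=None, genome_id="g"):
    bg = bg or BackgroundModel.uniform()
    sites = [
        Site(genome_id=genome_id, start=j * (width + 40), end=j * (width + 40) + width,
             strand="+", seq="".join("ACGT"[b] for b in rng.integers(0, 4, width)))
        for j in range(n_sites)
    ]
    return Motif(id=mid, sites=sites, background=bg)


def consensus_motif(seq, mid="m", n_sites=5, genome_id="g"):
    """Motif whose sites are n copies of one sequence."""
    w = len(seq)
    sites = [Site(genome_id=genome_id, start=j * (w + 40), end=j * (w + 40) + w,
                  strand="+", seq=seq) for j in range(n_sites)]
    return Motif(id=mid, sites=sites, background=BackgroundModel.uniform())


@pytest.fixture(scope="session")
def small_bundle():
    """A small genome group: 3 genomes, 20 operons, 2 planted motifs."""
    return generate_group(FixtureConfig(
        n_genomes=3, n_operons=20, n_planted_motifs=2, coor_fraction=0.3, seed=11,
    ))


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(5)
    seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 6000))
    return Genome(id="gt", sequence=seq)
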