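import numpy as np
import pytest
from hypothesis import settings

from mtfrag.genomes import build_contig_index, default_genome_pair
from mtfrag.simulate import demo_config, demo_models, emit_alignments, simulate_fragments

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome_pair():
    return default_genome_pair()


@pytest.fixture(scope="session")
def contig_index(genome_pair):
    graft, host = genome_pair
    return build_contig_index(graft, host)


@pytest.fixture(scope="session")
def models():
    return demo_models()


@pytest.fixture(scope="session")
def small_sample(contig_index):
    """A modest simulated sample shared by I/O-level tests."""
    cfg = demo_config(seed=11, n_nuclear=20_000, n_mito_graft=2_000, n_mito_host=1_000)
    frags, truth = simulate_fragments(cfg, contig_index)
    return cfg, frags, truth


@pytest.fixture(scope="session")
def small_sam(small_sample, contig_index, tmp_path_factory):
    _, frags, _ = small_sample
    path = tmp_path_factory.mktemp("sam") / "sample.sam"
    emit_alignments(frags, contig_index, path)
    return path


def rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
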