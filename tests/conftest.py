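import numpy as np
import pytest

from promarch import (
    MutationModel,
    SequenceSet,
    disjoint_motif_spec,
    encode,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def tiny_seqset():
    return SequenceSet(ids=["s1", "s2", "s3"], seqs=["ACGT", "TTTT", "ACGG"])


@pytest.fixture(scope="session")
def disjoint_data():
    """Noise-free planted data: four disjoint-support architectures."""
    spec = disjoint_motif_spec(n_per_cluster=60, L=60)
    seqs, truth = generate_dataset(spec, MutationModel(rate=0.0), seed=17)
    return seqs, truth


@pytest.fixture(scope="session")
def disjoint_encoded(disjoint_data):
    seqs, truth = disjoint_data
    return encode(seqs, order="di"), truth


def write_fasta_text(path, records):
    path.write_text("".join(f">{i}\n{s}\n" for i, s in records))
    return path
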