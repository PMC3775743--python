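import numpy as np
import pytest

from mitorepeats import GenomeFeature, MitoGenome

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def rotate(seq: str, k: int) -> str:
    k %= len(seq)
    return seq[k:] + seq[:k]


@pytest.fixture
def toy_genome() -> MitoGenome:
    """A 120 bp annotated genome: gene, tRNA-Phe and D-loop features."""
    return MitoGenome(
        sequence=random_sequence(120, seed=42),
        accession="TOY1",
        organism="Synthetica exemplaris",
        features=[
            GenomeFeature(kind="gene", start=1, end=70, strand="+", name="ND1"),
            GenomeFeature(kind="tRNA", start=71, end=100, strand="+", name="tRNA-Phe"),
            GenomeFeature(kind="D-loop", start=101, end=120, strand="+", name="D-loop"),
        ],
    )


def make_genome(length: int, seed: int, accession: str = "RND") -> MitoGenome:
    return MitoGenome(sequence=random_sequence(length, seed), accession=accession)
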