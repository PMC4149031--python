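from __future__ import annotations

import numpy as np
import pytest

from agioskit.seqio import Gene, GeneSet, SequenceRecord
from agioskit.simulate import _random_gene, _to_gene, _BASES  # noqa: F401


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def nt_scheme():
    from agioskit.pairwise import ScoringScheme

    return ScoringScheme.nucleotide()


@pytest.fixture
def prot_scheme():
    from agioskit.pairwise import ScoringScheme

    return ScoringScheme.protein()


def random_geneset(rng: np.random.Generator, genome_id: str, n_genes: int,
                   n_codons: int = 100) -> GeneSet:
    """Independent random coding genes (mutually non-homologous)."""
    genes = []
    for i in range(n_genes):
        arr = _random_gene(rng, n_codons * 3)
        genes.append(_to_gene(f"{genome_id}_g{i + 1:04d}", arr))
    return GeneSet(genome_id=genome_id, genes=genes)


@pytest.fixture
def tiny_geneset(rng):
    return random_geneset(rng, "tiny", 3, n_codons=60)


def make_record(seq: str, alphabet: str = "nucleotide",
                rid: str = "s1") -> SequenceRecord:
    return SequenceRecord(id=rid, residues=seq, alphabet=alphabet)
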