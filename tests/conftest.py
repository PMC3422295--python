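import numpy as np
import pytest

from codonbias.genetics import standard_code
from codonbias.seqio import CodingSequence, GeneSet
from codonbias.usage import CodonCounts


@pytest.fixture(scope="session")
def code():
    return standard_code()


def make_gene(gene_id: str, codons) -> CodingSequence:
    return CodingSequence(gene_id=gene_id, codons=tuple(codons))


def make_geneset(bodies, species_id="test", stop="TAA"):
    """Build a GeneSet from lists of body codons; ATG/stop added."""
    genes = [
        make_gene(f"g{i}", ("ATG", *body, stop)) for i, body in enumerate(bodies)
    ]
    return GeneSet(species_id=species_id, genes=genes)


def random_counts(rng: np.random.Generator, code, max_count=50) -> CodonCounts:
    """A random sense-codon count vector (some codons zero)."""
    x = {
        c: int(rng.integers(0, max_count))
        for c in code.sense_codons
        if rng.random() > 0.2
    }
    return CodonCounts(x=x, code=code)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
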