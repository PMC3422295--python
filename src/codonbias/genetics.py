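"""Standard genetic code with synonymous-family (degeneracy) metadata.

Everything downstream — RSCU expectations, Wright's ENC class averages,
SCUO maximal entropies, RSCPU denominators — keys off the family structure
held here: for each amino acid *i*, the set of synonymous codons and its
size ``n_i``.  The table is the standard nuclear code (transl_table 1);
Ser, Leu and Arg are treated as single six-fold families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

BASES = "ACGT"

#: Degeneracy classes used by Wright's ENC estimator: class -> number of
#: amino-acid families of that degeneracy in the standard code.
ENC_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}


@dataclass(frozen=True)
class GeneticCode:
    """The codon -> amino-acid mapping plus family-structure lookups.

    Attributes
    ----------
    table:
        Mapping of the 61 sense codons (DNA alphabet) to one-letter
        amino-acid symbols.
    stop_codons:
        The three termination triplets.
    """

    table: dict[str, str]
    stop_codons: frozenset[str]
    families: dict[str, tuple[str, ...]] = field(init=False)
    degeneracy: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon in sorted(self.table):
            fams.setdefault(self.table[codon], []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(cs) for aa, cs in fams.items()}
        )
        object.__setattr__(
            self, "degeneracy", {aa: len(cs) for aa, cs in fams.items()}
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.table))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.families))

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate_codon(self, codon: str) -> str:
        return "*" if codon in self.stop_codons else self.table[codon]


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard nuclear genetic code (NCBI transl_table 1)."""
    bio = CodonTable.unambiguous_dna_by_id[1]
    code = GeneticCode(
        table=dict(bio.forward_table),
        stop_codons=frozenset(bio.stop_codons),
    )
    assert len(code.table) == 61
    assert sum(code.degeneracy.values()) == 61
    return code


def dna_to_rna(codon: str) -> str:
    """ATG -> AUG; report tables print the RNA alphabet."""
    return codon.replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")
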