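"""Reading, validating and codonizing CDS FASTA inputs; tabular output.

A record is accepted only if it is a plausible complete coding sequence:
length a multiple of three and at least two codons, an exact ATG start, a
standard stop at the end, no internal stop, and (by default) no IUPAC
ambiguity codes.  Every input record ends up either as a validated
:class:`CodingSequence` or in the ``excluded`` list with a single reason,
so validation is total.  U is normalized to T on input and matching is
case-insensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import GeneticCode, dna_to_rna, standard_code

#: Exclusion reasons, in the order they are checked.
REASONS = (
    "length_not_multiple_of_3",
    "too_short",
    "ambiguous_base",
    "no_start",
    "no_stop",
    "internal_stop",
)


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame gene, stored as an ordered tuple of DNA codons."""

    gene_id: str
    codons: tuple[str, ...]

    @property
    def length_nt(self) -> int:
        return 3 * len(self.codons)

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass
class GeneSet:
    """A species' validated genes plus the records that failed validation."""

    species_id: str
    genes: list[CodingSequence] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def validate_record(
    gene_id: str,
    sequence: str,
    code: GeneticCode | None = None,
    policy: str = "reject",
) -> CodingSequence | tuple[str, str]:
    """Validate one nucleotide record into a CodingSequence or a reason.

    ``policy="keep"`` tolerates IUPAC ambiguity codes (the whole gene is
    kept and ambiguous codons simply never match any sense codon
    downstream); the default rejects the gene, because one ambiguous
    codon corrupts family counts.
    """
    code = code or standard_code()
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        return (gene_id, "length_not_multiple_of_3")
    if len(seq) < 6:
        return (gene_id, "too_short")
    if policy == "reject" and any(b not in "ACGT" for b in seq):
        return (gene_id, "ambiguous_base")
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    if codons[0] != "ATG":
        return (gene_id, "no_start")
    if codons[-1] not in code.stop_codons:
        return (gene_id, "no_stop")
    if any(c in code.stop_codons for c in codons[:-1]):
        return (gene_id, "internal_stop")
    return CodingSequence(gene_id=gene_id, codons=codons)


def read_cds_fasta(
    path: str | Path,
    policy: str = "reject",
    species_id: str | None = None,
    code: GeneticCode | None = None,
) -> GeneSet:
    """Read a multi-FASTA of CDS records into a validated :class:`GeneSet`."""
    path = Path(path)
    gs = GeneSet(species_id=species_id or path.stem)
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        out = validate_record(rec.id, str(rec.seq), code=code, policy=policy)
        if isinstance(out, CodingSequence):
            gs.genes.append(out)
        else:
            gs.excluded.append(out)
    if n == 0:
        warnings.warn(f"{path}: no FASTA records found", stacklevel=2)
    return gs


def write_cds_fasta(genes: GeneSet | Iterable[CodingSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


def translate(seq: CodingSequence, code: GeneticCode | None = None) -> str:
    """Translate a validated gene; the terminal stop is rendered as '*'."""
    code = code or standard_code()
    return "".join(code.translate_codon(c) for c in seq.codons)


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    alphabet: str = "dna",
    codon_columns: Iterable[str] = (),
) -> None:
    """Write a TSV with a schema header comment.

    ``alphabet="rna"`` prints codons with U (the convention of published
    codon-usage tables); the machine-readable default keeps DNA.  Codon
    content is looked for in the index (if named 'codon') and in the
    columns named by ``codon_columns``.
    """
    frame = frame.copy()
    if alphabet == "rna":
        for col in codon_columns:
            if col in frame.columns:
                frame[col] = frame[col].map(
                    lambda c: dna_to_rna(c) if isinstance(c, str) else c
                )
        if frame.index.name == "codon":
            frame.index = frame.index.map(dna_to_rna)
    path = Path(path)
    with open(path, "w") as fh:
        keep_index = frame.index.name is not None
        cols = ([frame.index.name] if keep_index else []) + list(frame.columns)
        fh.write("# columns: " + "\t".join(map(str, cols)) + "\n")
        frame.to_csv(fh, sep="\t", index=keep_index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
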