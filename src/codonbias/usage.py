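"""Single-codon usage statistics: counts, RSCU, ENC, CAI, composition.

The statistics live at two scopes: per gene (ENC, CAI, SCUO feed gene-level
distributions) and pooled over a genome (RSCU tables, amino-acid
frequencies, cross-species tests).  All of them are driven by the 61-cell
sense-codon count vector x_ij, where i indexes the amino acid and j its
synonymous codons.

RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij)            (n_i = family degeneracy)

Wright's effective number of codons uses per-family homozygosities
F̂ = (n Σ p̂² − 1)/(n − 1) averaged within degeneracy classes:

ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,   20 ≤ ENC ≤ 61.

CAI follows Sharp & Li: relative adaptiveness w_ij is the reference RSCU
scaled to the family maximum, and CAI is the geometric mean of w over a
gene's codons (ATG, TGG and stops excluded from the mean).
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genetics import GeneticCode, standard_code
from .seqio import CodingSequence, GeneSet

#: Conventional floor for the adaptiveness of reference codons never seen
#: in the reference set; avoids ln 0 without discarding the codon.
W_FLOOR = 0.01


@dataclass
class CodonCounts:
    """Sense-codon counts for a gene or a pooled genome.

    Stop codons are tallied separately in ``stops`` and never enter
    ``total_sense``.
    """

    x: dict[str, int]
    stops: dict[str, int] = field(default_factory=dict)
    scope: str = "gene"
    code: GeneticCode = field(default_factory=standard_code)

    @property
    def total_sense(self) -> int:
        return sum(self.x.values())

    def family_count(self, aa: str) -> int:
        return sum(self.x.get(c, 0) for c in self.code.families[aa])

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        x = Counter(self.x)
        x.update(other.x)
        st = Counter(self.stops)
        st.update(other.stops)
        return CodonCounts(x=dict(x), stops=dict(st), scope="pooled", code=self.code)


@dataclass
class RscuTable:
    rscu: dict[str, float]
    flags: dict[str, str]  # frequent / rare / neutral / undefined


@dataclass
class EncValue:
    enc: float  # NaN when undefined
    f_hat_by_class: dict[int, float]
    reason: str | None = None


@dataclass
class CaiValue:
    cai: float  # NaN when no informative codons remain
    w: dict[str, float]


@dataclass
class CompositionProfile:
    gc: float
    gc3s: float
    a3s: float
    t3s: float
    c3s: float
    g3s: float
    #: plain third-position fractions (Met/Trp included), same base order
    third_position: dict[str, float] = field(default_factory=dict)


def count_codons(
    genes: GeneSet | CodingSequence,
    pool: bool = True,
    include_start: bool = True,
    code: GeneticCode | None = None,
) -> CodonCounts | dict[str, CodonCounts]:
    """Tally codons for a gene, or per-gene / pooled over a GeneSet.

    The terminal stop goes to the stop side-table; ``include_start=False``
    drops the initiator ATG from the sense counts.
    """
    code = code or standard_code()
    if isinstance(genes, CodingSequence):
        return _count_one(genes, include_start, code)
    if len(genes) == 0:
        warnings.warn("empty GeneSet: counts are empty", stacklevel=2)
        return (
            CodonCounts(x={}, scope="pooled", code=code)
            if pool
            else {}
        )
    per_gene = {g.gene_id: _count_one(g, include_start, code) for g in genes}
    if not pool:
        return per_gene
    total = CodonCounts(x={}, scope="pooled", code=code)
    for c in per_gene.values():
        total = total + c
    return total


def _count_one(gene: CodingSequence, include_start: bool, code: GeneticCode) -> CodonCounts:
    body = gene.codons if include_start else gene.codons[1:]
    x: Counter[str] = Counter()
    stops: Counter[str] = Counter()
    for c in body:
        if c in code.stop_codons:
            stops[c] += 1
        elif c in code.table:
            x[c] += 1
    return CodonCounts(x=dict(x), stops=dict(stops), scope="gene", code=code)


def rscu(counts: CodonCounts) -> RscuTable:
    """Relative synonymous codon usage for every sense codon.

    Families with zero count get flag ``undefined`` (they carry no
    frequent/rare vote downstream); Met and Trp, as single-codon
    families, are always exactly 1 when present.
    """
    code = counts.code
    values: dict[str, float] = {}
    flags: dict[str, str] = {}
    for aa, fam in code.families.items():
        total = sum(counts.x.get(c, 0) for c in fam)
        if total == 0:
            for c in fam:
                values[c] = math.nan
                flags[c] = "undefined"
            continue
        expected = total / len(fam)
        for c in fam:
            r = counts.x.get(c, 0) / expected
            values[c] = r
            flags[c] = "frequent" if r > 1 else ("rare" if r < 1 else "neutral")
    return RscuTable(rscu=values, flags=flags)


def family_homozygosity(counts: CodonCounts, aa: str) -> float:
    """Wright's F̂ = (n Σ p̂² − 1)/(n − 1) for one family; NaN if n < 2."""
    fam = counts.code.families[aa]
    xs = np.array([counts.x.get(c, 0) for c in fam], dtype=float)
    n = xs.sum()
    if n < 2:
        return math.nan
    p = xs / n
    return (n * float(p @ p) - 1.0) / (n - 1.0)


def enc_from_homozygosity(f_bar: dict[int, float]) -> float:
    """ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61.

    Accepts class-average homozygosities directly, which also gives the
    two analytic limits: all F̄ = 1 → 20, F̄_k = 1/k → 61.
    """
    enc = (
        2.0
        + 9.0 / f_bar[2]
        + 1.0 / f_bar[3]
        + 5.0 / f_bar[4]
        + 3.0 / f_bar[6]
    )
    return min(enc, 61.0)


def enc(counts: CodonCounts) -> EncValue:
    """Wright's effective number of codons for one count vector.

    Families with fewer than 2 counted codons are skipped.  If the
    three-fold class (Ile) is unobserved, 1/F̄₃ is estimated from the
    mean of F̄₂ and F̄₄ (the usual CodonW convention); any other missing
    or non-positive class average makes the ENC undefined.
    """
    code = counts.code
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, n_i in code.degeneracy.items():
        if n_i == 1:
            continue
        f = family_homozygosity(counts, aa)
        if not math.isnan(f):
            by_class[n_i].append(f)
    f_bar = {k: (float(np.mean(v)) if v else math.nan) for k, v in by_class.items()}
    if math.isnan(f_bar[3]) and not (math.isnan(f_bar[2]) or math.isnan(f_bar[4])):
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
    bad = [k for k, v in f_bar.items() if math.isnan(v) or v <= 0]
    if bad:
        return EncValue(
            enc=math.nan,
            f_hat_by_class=f_bar,
            reason=f"class average undefined or non-positive: {bad}",
        )
    return EncValue(enc=enc_from_homozygosity(f_bar), f_hat_by_class=f_bar)


def relative_adaptiveness(reference: CodonCounts) -> dict[str, float]:
    """Sharp & Li w_ij from a reference gene set's RSCU table.

    Codons absent from the reference (within an observed family) get the
    conventional floor w = 0.01; families entirely absent are left out.
    """
    ref = rscu(reference)
    w: dict[str, float] = {}
    for aa, fam in reference.code.families.items():
        vals = [ref.rscu[c] for c in fam]
        if any(math.isnan(v) for v in vals):
            continue
        top = max(vals)
        for c, v in zip(fam, vals):
            w[c] = max(v / top, W_FLOOR)
    return w


def cai(counts: CodonCounts, reference: CodonCounts) -> CaiValue:
    """Codon adaptation index of a gene against a reference set.

    ATG, TGG (single-codon families, always w = 1) and any codon whose
    family is absent from the reference are excluded from the geometric
    mean.
    """
    if reference.total_sense == 0:
        raise ValueError("reference counts are empty")
    w = relative_adaptiveness(reference)
    code = counts.code
    single = {c for aa, fam in code.families.items() if len(fam) == 1 for c in fam}
    log_sum = 0.0
    length = 0
    for codon, n in counts.x.items():
        if codon in single or codon not in w:
            continue
        log_sum += n * math.log(w[codon])
        length += n
    if length == 0:
        return CaiValue(cai=math.nan, w=w)
    return CaiValue(cai=math.exp(log_sum / length), w=w)


def composition(
    genes: GeneSet | CodingSequence, code: GeneticCode | None = None
) -> CompositionProfile:
    """GC content and third-position base fractions over sense codons.

    The "s" fractions (a3s/t3s/c3s/g3s, gc3s) are taken over synonymous
    third positions only — codons of Met and Trp are excluded — while
    ``third_position`` keeps the plain fractions over all sense codons.
    Stops are outside every denominator; the initiator ATG is counted
    like any other codon.
    """
    code = code or standard_code()
    gene_list = [genes] if isinstance(genes, CodingSequence) else list(genes)
    nt = Counter()
    third = Counter()
    third_syn = Counter()
    for g in gene_list:
        for c in g.codons:
            if c not in code.table:
                continue
            nt.update(c)
            third[c[2]] += 1
            if code.degeneracy[code.table[c]] > 1:
                third_syn[c[2]] += 1
    total = sum(nt.values())
    n3 = sum(third.values())
    n3s = sum(third_syn.values())
    if total == 0:
        nan = math.nan
        return CompositionProfile(nan, nan, nan, nan, nan, nan, {})
    frac = {b: third_syn[b] / n3s for b in "ACGT"} if n3s else {}
    return CompositionProfile(
        gc=(nt["G"] + nt["C"]) / total,
        gc3s=frac.get("G", math.nan) + frac.get("C", math.nan)
        if frac
        else math.nan,
        a3s=frac.get("A", math.nan),
        t3s=frac.get("T", math.nan),
        c3s=frac.get("C", math.nan),
        g3s=frac.get("G", math.nan),
        third_position={b: third[b] / n3 for b in "ACGT"} if n3 else {},
    )


def aa_frequencies(
    genes: GeneSet, code: GeneticCode | None = None
) -> dict[str, float]:
    """Residue fractions over the 20 amino acids; stops excluded."""
    code = code or standard_code()
    counts = count_codons(genes, pool=True, code=code)
    by_aa = Counter()
    for codon, n in counts.x.items():
        by_aa[code.table[codon]] += n
    total = sum(by_aa.values())
    return {aa: by_aa.get(aa, 0) / total for aa in code.amino_acids}
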