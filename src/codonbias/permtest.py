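"""Codon-position permutation test of the association between codon
usage bias and amino-acid composition bias.

The "position" randomization keeps, for every gene, the multiset of
bases observed at each codon position: bases in the first-position
column are permuted among the gene's internal codons, and likewise —
independently — for the second and third positions.  Start and stop
codons are exempt, so the permutation cannot destroy them; randomized
genes are deliberately NOT re-validated (a permutation may create
internal stop triplets, which are simply counted as written).

Per codon, the observed total and the count expected under equal
synonymous usage (amino-acid total / degeneracy) are compared with the
same two quantities from the randomized data in a 2×2 Pearson
chi-square test; a small p flags a codon whose usage bias is tied to
the residue composition rather than to synonymous choice alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .genetics import GeneticCode, standard_code
from .seqio import CodingSequence, GeneSet
from .usage import count_codons


@dataclass(frozen=True)
class PermutationScheme:
    model: str = "position"
    replicates: int = 100
    seed: int = 0
    #: permute columns across genes instead of within each gene
    cross_gene: bool = False

    def __post_init__(self) -> None:
        if self.model != "position":
            raise ValueError(f"unknown permutation model: {self.model}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _permute_gene(gene: CodingSequence, rng: np.random.Generator) -> CodingSequence:
    body = gene.codons[1:-1]
    if len(body) <= 1:
        return gene
    arr = np.array([list(c) for c in body])  # (L-2, 3) base matrix
    for pos in range(3):
        arr[:, pos] = arr[rng.permutation(len(body)), pos]
    codons = (gene.codons[0],) + tuple("".join(row) for row in arr) + (gene.codons[-1],)
    return CodingSequence(gene_id=gene.gene_id, codons=codons)


def permute_positions(
    genes: GeneSet,
    scheme: PermutationScheme | None = None,
    rng: np.random.Generator | None = None,
) -> GeneSet:
    """One position-model randomization of every gene in the set."""
    scheme = scheme or PermutationScheme()
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    if not scheme.cross_gene:
        new = [_permute_gene(g, rng) for g in genes]
    else:
        new = _permute_cross_gene(list(genes), rng)
    return GeneSet(
        species_id=f"{genes.species_id}:randomized",
        genes=new,
        excluded=list(genes.excluded),
    )


def _permute_cross_gene(
    genes: list[CodingSequence], rng: np.random.Generator
) -> list[CodingSequence]:
    bodies = [g.codons[1:-1] for g in genes]
    pool = np.array([list(c) for body in bodies for c in body])
    for pos in range(3):
        pool[:, pos] = pool[rng.permutation(len(pool)), pos]
    out, at = [], 0
    for g, body in zip(genes, bodies):
        chunk = pool[at : at + len(body)]
        at += len(body)
        codons = (g.codons[0],) + tuple("".join(r) for r in chunk) + (g.codons[-1],)
        out.append(CodingSequence(gene_id=g.gene_id, codons=codons))
    return out


def _usage_summary(
    genes: GeneSet, code: GeneticCode
) -> tuple[dict[str, int], dict[str, float]]:
    """(codon totals, per-codon expected totals = aa total / degeneracy)."""
    counts = count_codons(genes, pool=True, code=code)
    observed = {c: counts.x.get(c, 0) for c in code.sense_codons}
    expected = {}
    for aa, fam in code.families.items():
        fam_total = sum(observed[c] for c in fam)
        for c in fam:
            expected[c] = fam_total / len(fam)
    return observed, expected


def _chi2_2x2(a: float, b: float, c: float, d: float) -> float:
    """Pearson chi-square p (1 df, no continuity correction)."""
    n = a + b + c + d
    e = np.outer([a + b, c + d], [a + c, b + d]) / n
    if (e == 0).any():
        return math.nan
    obs = np.array([[a, b], [c, d]], dtype=float)
    stat = float(((obs - e) ** 2 / e).sum())
    return float(chi2.sf(stat, df=1))


def codon_aa_association(
    observed: GeneSet,
    scheme: PermutationScheme | None = None,
    alpha: float = 0.05,
    code: GeneticCode | None = None,
    randomized: GeneSet | None = None,
) -> pd.DataFrame:
    """Per-codon chi-square comparison of observed vs randomized usage.

    Randomized codon totals and expectations are averaged over
    ``scheme.replicates`` independent position permutations (pass
    ``randomized`` to compare against a fixed gene set instead).
    Returns a frame indexed by codon with columns obs_total,
    obs_expected, rand_total, rand_expected, chi2_p, significant; codons
    of amino acids absent from the observed data are skipped.
    """
    scheme = scheme or PermutationScheme()
    code = code or standard_code()
    obs_tot, obs_exp = _usage_summary(observed, code)
    if randomized is not None:
        rand_tot = [_usage_summary(randomized, code)]
    else:
        rng = np.random.default_rng(scheme.seed)
        rand_tot = [
            _usage_summary(permute_positions(observed, scheme, rng), code)
            for _ in range(scheme.replicates)
        ]
    rows = []
    for codon in code.sense_codons:
        if obs_exp[codon] == 0:
            continue
        r_tot = float(np.mean([t[codon] for t, _ in rand_tot]))
        r_exp = float(np.mean([e[codon] for _, e in rand_tot]))
        p = _chi2_2x2(obs_tot[codon], obs_exp[codon], r_tot, r_exp)
        rows.append(
            {
                "codon": codon,
                "obs_total": obs_tot[codon],
                "obs_expected": obs_exp[codon],
                "rand_total": r_tot,
                "rand_expected": r_exp,
                "chi2_p": p,
                "significant": bool(not math.isnan(p) and p < alpha),
            }
        )
    return pd.DataFrame(rows).set_index("codon")
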