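"""Ordered codon-pair ("codon context") statistics.

A codon context is an adjacent in-frame pair of codons — the triplets
sitting in the ribosomal P and A sites.  This module counts contexts
within genes (never across gene boundaries), standardizes the pair table
with Haberman adjusted residuals, normalizes it per amino-acid pair as
RSCPU, tabulates the boundary contexts flanking the start and stop
codons, and clusters species by the correlation of their residual
matrices.

By default the two boundary pairs of each gene — (ATG, c₂) and
(c_{L−1}, stop) — are routed to the boundary tables rather than the
sense-pair table, so internal-context statistics are not contaminated by
the start/stop signals; ``inclusive=True`` restores whole-gene counting
over the sense × (sense ∪ stop) universe, the mode in which the rarest
genome-wide contexts are typically NNN-stop pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import average_linkage, correlation_distance, linkage_to_newick
from .genetics import GeneticCode, standard_code
from .seqio import GeneSet


@dataclass
class CodonPairTable:
    """Counts over ordered codon pairs (5′ codon in rows)."""

    counts: np.ndarray
    codons5: tuple[str, ...]
    codons3: tuple[str, ...]
    inclusive: bool
    code: GeneticCode = field(default_factory=standard_code)

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def get(self, c5: str, c3: str) -> int:
        return int(
            self.counts[self.codons5.index(c5), self.codons3.index(c3)]
        )

    def sense_only(self) -> "CodonPairTable":
        """Restrict the column universe to the 61 sense codons."""
        keep = [j for j, c in enumerate(self.codons3) if c in self.code.table]
        return CodonPairTable(
            counts=self.counts[:, keep],
            codons5=self.codons5,
            codons3=tuple(self.codons3[j] for j in keep),
            inclusive=False,
            code=self.code,
        )


@dataclass
class ResidualMatrix:
    residual: np.ndarray  # NaN where the expectation is zero
    codons5: tuple[str, ...]
    codons3: tuple[str, ...]

    def get(self, c5: str, c3: str) -> float:
        return float(
            self.residual[self.codons5.index(c5), self.codons3.index(c3)]
        )


@dataclass
class RscpuTable:
    rscpu: np.ndarray  # NaN where the amino-acid pair is absent
    codons5: tuple[str, ...]
    codons3: tuple[str, ...]

    def get(self, c5: str, c3: str) -> float:
        return float(
            self.rscpu[self.codons5.index(c5), self.codons3.index(c3)]
        )


@dataclass
class BoundaryContextTable:
    """5′-of-stop and 3′-of-start codon tallies."""

    stop5: dict[str, dict[str, int]]  # stop codon -> {sense codon: count}
    start3: dict[str, int]  # sense codon -> count

    def most_frequent(self, table: str, stop: str | None = None):
        return _extreme(self._select(table, stop), largest=True)

    def least_frequent(self, table: str, stop: str | None = None):
        return _extreme(self._select(table, stop), largest=False)

    def _select(self, table: str, stop: str | None) -> dict[str, int]:
        if table == "start3":
            return self.start3
        if table == "stop5":
            if stop is None:
                raise ValueError("stop5 query needs a stop codon")
            return self.stop5[stop]
        raise ValueError(f"unknown boundary table: {table}")


def _extreme(counts: dict[str, int], largest: bool) -> tuple[str, int, list[str]]:
    """(winner, count, all tied codons); lexicographic winner on ties."""
    if not counts:
        raise ValueError("empty boundary table")
    target = max(counts.values()) if largest else min(counts.values())
    tied = sorted(c for c, n in counts.items() if n == target)
    return tied[0], target, tied


def count_codon_pairs(
    genes: GeneSet, inclusive: bool = False, code: GeneticCode | None = None
) -> CodonPairTable:
    """Accumulate ordered adjacent codon pairs over all genes.

    Exclusive mode (default): pairs (c_k, c_{k+1}) for k = 2..L−2 of each
    gene (1-based), i.e. without the pair following the start codon and
    the pair ending in the stop.  Inclusive mode adds both and widens the
    3′ universe to include the stop codons.  Codons outside the universe
    (ambiguous triplets kept under a lenient input policy) are skipped.
    """
    code = code or standard_code()
    sense = tuple(sorted(code.table))
    cols = sense + tuple(sorted(code.stop_codons)) if inclusive else sense
    i5 = {c: i for i, c in enumerate(sense)}
    i3 = {c: i for i, c in enumerate(cols)}
    counts = np.zeros((len(sense), len(cols)), dtype=np.int64)
    for gene in genes:
        cs = gene.codons
        lo, hi = (0, len(cs) - 1) if inclusive else (1, len(cs) - 2)
        if hi <= lo:
            continue
        a = np.fromiter((i5.get(c, -1) for c in cs[lo:hi]), dtype=np.int64)
        b = np.fromiter((i3.get(c, -1) for c in cs[lo + 1 : hi + 1]), dtype=np.int64)
        ok = (a >= 0) & (b >= 0)
        np.add.at(counts, (a[ok], b[ok]), 1)
    return CodonPairTable(
        counts=counts, codons5=sense, codons3=cols, inclusive=inclusive, code=code
    )


def adjusted_residuals(table: CodonPairTable) -> ResidualMatrix:
    """Haberman adjusted residuals of the pair table against independence.

    d_rc = (x_rc − e_rc) / √(e_rc (1 − row_r/N)(1 − col_c/N)) with
    e_rc = row_r col_c / N; approximately standard normal when the two
    codon positions are independent.  Cells with e_rc = 0 are NaN.
    """
    N = table.N
    if N == 0:
        raise ValueError("empty pair table")
    row = table.row_marginals.astype(float)
    col = table.col_marginals.astype(float)
    e = np.outer(row, col) / N
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(e * np.outer(1.0 - row / N, 1.0 - col / N))
        resid = np.where(denom > 0, (table.counts - e) / denom, np.nan)
    return ResidualMatrix(
        residual=resid, codons5=table.codons5, codons3=table.codons3
    )


def pair_chi_square(table: CodonPairTable) -> float:
    """Pearson χ² of the pair table (Σ (obs − exp)²/exp over e > 0 cells)."""
    N = table.N
    e = np.outer(table.row_marginals, table.col_marginals).astype(float) / N
    mask = e > 0
    return float((((table.counts - e) ** 2)[mask] / e[mask]).sum())


def rscpu(table: CodonPairTable, code: GeneticCode | None = None) -> RscpuTable:
    """Relative synonymous codon pair usage.

    For a codon pair p encoding the amino-acid pair (a, b), the expected
    count is total(a, b) / (n_a n_b) — all synonymous pairs equally
    likely — and RSCPU(p) = count(p) / expected(p).  Pairs of an absent
    amino-acid pair are NaN.  Within each observed amino-acid pair the
    values sum to n_a × n_b.
    """
    code = code or standard_code()
    t = table.sense_only() if table.inclusive else table
    aa_of = np.array([code.table[c] for c in t.codons5])
    aas = sorted(set(aa_of))
    a_idx = {aa: np.flatnonzero(aa_of == aa) for aa in aas}
    out = np.full_like(t.counts, np.nan, dtype=float)
    for a in aas:
        rows = a_idx[a]
        for b in aas:
            cols = a_idx[b]
            block = t.counts[np.ix_(rows, cols)]
            total = block.sum()
            if total == 0:
                continue
            expected = total / block.size
            out[np.ix_(rows, cols)] = block / expected
    return RscpuTable(rscpu=out, codons5=t.codons5, codons3=t.codons3)


def boundary_contexts(
    genes: GeneSet, code: GeneticCode | None = None
) -> BoundaryContextTable:
    """Count the codon 5′ of each stop and the codon 3′ of the start."""
    code = code or standard_code()
    stop5 = {s: {} for s in sorted(code.stop_codons)}
    start3: dict[str, int] = {}
    for gene in genes:
        cs = gene.codons
        if len(cs) >= 3 and cs[1] in code.table:
            start3[cs[1]] = start3.get(cs[1], 0) + 1
        before_stop = cs[-2]
        if cs[-1] in stop5 and before_stop in code.table:
            d = stop5[cs[-1]]
            d[before_stop] = d.get(before_stop, 0) + 1
    return BoundaryContextTable(stop5=stop5, start3=start3)


def aa_pair_frequencies(
    genes: GeneSet, code: GeneticCode | None = None
) -> dict[tuple[str, str], float]:
    """Ordered amino-acid-pair fractions over the internal adjacencies.

    Uses exactly the adjacencies of :func:`count_codon_pairs` (exclusive
    mode), so the table equals the codon-pair table aggregated through
    the genetic code.
    """
    code = code or standard_code()
    table = count_codon_pairs(genes, inclusive=False, code=code)
    aa_of = [code.table[c] for c in table.codons5]
    freq: dict[tuple[str, str], float] = {}
    N = table.N
    if N == 0:
        return freq
    for i, a in enumerate(aa_of):
        for j, b in enumerate(aa_of):
            n = table.counts[i, j]
            if n:
                freq[(a, b)] = freq.get((a, b), 0.0) + n / N
    return freq


def context_cluster_tree(
    residuals_by_species: dict[str, ResidualMatrix],
    method: str = "pearson",
    min_defined: float = 0.5,
) -> tuple[str, np.ndarray, list[str]]:
    """Cluster species by similarity of their context residual matrices.

    Distance is 1 − correlation (Pearson by default, Spearman optional)
    between flattened residual matrices over cells defined in every
    retained species.  Species with fewer than ``min_defined`` defined
    cells are dropped with a warning.  Returns (newick, linkage, labels).
    """
    kept: dict[str, np.ndarray] = {}
    for sp, rm in residuals_by_species.items():
        flat = rm.residual.ravel()
        if np.mean(~np.isnan(flat)) < min_defined:
            warnings.warn(
                f"species {sp}: fewer than {min_defined:.0%} defined residual "
                "cells, excluded from clustering",
                stacklevel=2,
            )
            continue
        kept[sp] = flat
    if len(kept) < 3:
        raise ValueError("need at least 3 species with usable residuals")
    labels = sorted(kept)
    stack = np.vstack([kept[sp] for sp in labels])
    defined = ~np.isnan(stack).any(axis=0)
    dist = correlation_distance(stack[:, defined], method=method)
    linkage = average_linkage(dist)
    return linkage_to_newick(linkage, labels), linkage, labels
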