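"""Synonymous codon usage order (SCUO): per-gene entropy bias, binning,
and all-pairs DTK comparison of binned values.

SCUO measures, per amino-acid family, how far the within-family codon
distribution is from uniform, on the normalized Shannon scale:

    H_i = −Σ_j p_ij log₂ p_ij,   O_i = (log₂ n_i − H_i)/log₂ n_i,

and aggregates with composition weights F_i = c_i / Σ c_i over the
families with n_i ≥ 2 actually present in the gene:

    SCUO = Σ_i F_i O_i  ∈ [0, 1],

0 for exactly uniform family usage, 1 when every family is concentrated
on a single codon.  Genes are then binned into ten 0.1-wide SCUO
intervals and bins are compared pairwise with Dunnett's modification of
the Tukey–Kramer procedure (unequal n, unequal variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import studentized_range

from .usage import CodonCounts

BIN_EDGES = np.linspace(0.0, 1.0, 11)


@dataclass
class ScuoValue:
    scuo: float  # NaN when no multi-codon family is present
    per_aa: dict[str, tuple[float, float, float, float]]  # aa -> (H, Hmax, O, F)


@dataclass
class ScuoBins:
    edges: np.ndarray
    membership: dict[str, int]  # gene_id -> 1-based bin index
    values: dict[str, float]

    def bin_members(self, b: int) -> np.ndarray:
        return np.array(
            [v for g, v in self.values.items() if self.membership[g] == b]
        )

    def summary(self) -> list[tuple[int, int, float, float]]:
        """(bin, n, mean, variance) rows; variance is the ddof=1 sample
        variance, NaN below two members."""
        rows = []
        for b in range(1, 11):
            vals = self.bin_members(b)
            n = len(vals)
            mean = float(vals.mean()) if n else math.nan
            var = float(vals.var(ddof=1)) if n >= 2 else math.nan
            rows.append((b, n, mean, var))
        return rows


@dataclass
class DtkResult:
    pairs: list[tuple[int, int, float, float, float, bool]]
    skipped: list[tuple[int, int, str]] = field(default_factory=list)


def scuo_gene(counts: CodonCounts) -> ScuoValue:
    """Composition-weighted normalized entropy gap for one gene."""
    code = counts.code
    per_aa: dict[str, tuple[float, float, float, float]] = {}
    c_tot = 0
    for aa, fam in code.families.items():
        if len(fam) < 2:
            continue
        c_i = sum(counts.x.get(c, 0) for c in fam)
        if c_i == 0:
            continue
        c_tot += c_i
        hmax = math.log2(len(fam))
        h = 0.0
        for c in fam:
            x = counts.x.get(c, 0)
            if x:
                p = x / c_i
                h -= p * math.log2(p)
        per_aa[aa] = (h, hmax, (hmax - h) / hmax, c_i)
    if c_tot == 0:
        return ScuoValue(scuo=math.nan, per_aa={})
    per_aa = {
        aa: (h, hmax, o, c / c_tot) for aa, (h, hmax, o, c) in per_aa.items()
    }
    scuo = sum(f * o for (_, _, o, f) in per_aa.values())
    return ScuoValue(scuo=scuo, per_aa=per_aa)


def assign_bin(scuo: float) -> int:
    """1-based bin under [lo, hi) intervals, last bin closed at 1.0."""
    if not 0.0 <= scuo <= 1.0:
        raise ValueError(f"SCUO out of range: {scuo}")
    return min(int(scuo * 10) + 1, 10)


def bin_scuo(values: dict[str, float]) -> ScuoBins:
    """Partition gene-level SCUO values into the ten 0.1 intervals."""
    defined = {g: v for g, v in values.items() if not math.isnan(v)}
    if not defined:
        raise ValueError("no defined SCUO values to bin")
    membership = {g: assign_bin(v) for g, v in defined.items()}
    return ScuoBins(edges=BIN_EDGES, membership=membership, values=defined)


def dtk_pairwise(bins: ScuoBins, alpha: float = 0.05) -> DtkResult:
    """All-pairs mean comparison of per-bin SCUO values (Dunnett/T-K).

    Per pair (a, b): Welch-type standard error √(s²_a/n_a + s²_b/n_b),
    Welch–Satterthwaite degrees of freedom, and a simultaneous interval
    diff ± q(1−α; k, df)/√2 · SE from the studentized-range quantile,
    where k is the number of usable bins.  A pair is significant when
    its interval excludes zero.
    """
    groups = {
        b: bins.bin_members(b) for b in range(1, 11) if len(bins.bin_members(b)) >= 2
    }
    k = len(groups)
    result = DtkResult(pairs=[])
    ids = sorted(groups)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            xa, xb = groups[a], groups[b]
            na, nb = len(xa), len(xb)
            va, vb = xa.var(ddof=1), xb.var(ddof=1)
            diff = float(xa.mean() - xb.mean())
            se2 = va / na + vb / nb
            if se2 == 0.0:
                result.pairs.append((a, b, diff, diff, diff, diff != 0.0))
                continue
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
            q = studentized_range.ppf(1 - alpha, k, df)
            half = q / math.sqrt(2.0) * math.sqrt(se2)
            lo, hi = diff - half, diff + half
            result.pairs.append((a, b, diff, lo, hi, not (lo <= 0.0 <= hi)))
    skipped = [
        (a, b, "bin with n < 2")
        for a in range(1, 11)
        for b in range(a + 1, 11)
        if a not in groups or b not in groups
    ]
    result.skipped = skipped
    return result
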