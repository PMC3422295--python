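"""Independent brute-force oracles used to cross-check the library.

Everything here is written as plain loops over the code table and exact
rational arithmetic where possible, deliberately sharing no code with
the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction


def naive_rscu(x: dict[str, int], families: dict[str, tuple[str, ...]]) -> dict[str, float]:
    out = {}
    for aa, fam in families.items():
        total = 0
        for c in fam:
            total += x.get(c, 0)
        if total == 0:
            for c in fam:
                out[c] = math.nan
            continue
        for c in fam:
            out[c] = x.get(c, 0) * len(fam) / total
    return out


def naive_enc(x: dict[str, int], families: dict[str, tuple[str, ...]]) -> float:
    """Wright's estimator via explicit per-family loops; NaN if undefined."""
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in families.items():
        if len(fam) == 1:
            continue
        n = sum(x.get(c, 0) for c in fam)
        if n < 2:
            continue
        s = sum((x.get(c, 0) / n) ** 2 for c in fam)
        class_f[len(fam)].append((n * s - 1) / (n - 1))
    f_bar = {}
    for k, vals in class_f.items():
        f_bar[k] = sum(vals) / len(vals) if vals else math.nan
    if math.isnan(f_bar[3]) and not math.isnan(f_bar[2]) and not math.isnan(f_bar[4]):
        f_bar[3] = (f_bar[2] + f_bar[4]) / 2
    if any(math.isnan(v) or v <= 0 for v in f_bar.values()):
        return math.nan
    return min(2 + 9 / f_bar[2] + 1 / f_bar[3] + 5 / f_bar[4] + 3 / f_bar[6], 61.0)


def naive_scuo(x: dict[str, int], families: dict[str, tuple[str, ...]]) -> float:
    num = 0.0
    c_tot = 0
    for aa, fam in families.items():
        if len(fam) < 2:
            continue
        c_i = sum(x.get(c, 0) for c in fam)
        if c_i == 0:
            continue
        h = 0.0
        for c in fam:
            if x.get(c, 0):
                p = x[c] / c_i
                h -= p * math.log2(p)
        hmax = math.log2(len(fam))
        num += c_i * (hmax - h) / hmax
        c_tot += c_i
    return num / c_tot if c_tot else math.nan


def fisher_enumerate(k1: int, m1: int, k2: int, m2: int) -> float:
    """Two-sided Fisher exact p by exhaustive rational enumeration.

    Enumerates every 2×2 table with the observed margins, computes each
    hypergeometric probability as an exact Fraction, and sums those not
    exceeding the observed table's probability.
    """
    n1, n2 = k1 + m1, k2 + m2
    K = k1 + k2
    n = n1 + n2
    denom = math.comb(n, K)

    def prob(a: int) -> Fraction:
        b = K - a
        if b < 0 or b > n2 or a > n1:
            return Fraction(0)
        return Fraction(math.comb(n1, a) * math.comb(n2, b), denom)

    p_obs = prob(k1)
    total = Fraction(0)
    for a in range(0, min(K, n1) + 1):
        p = prob(a)
        if p <= p_obs:
            total += p
    return float(total)


def naive_pair_chi2(counts) -> float:
    """Pearson chi-square of a 2-D count table by explicit cell loops."""
    rows = len(counts)
    cols = len(counts[0])
    row_m = [sum(counts[r][c] for c in range(cols)) for r in range(rows)]
    col_m = [sum(counts[r][c] for r in range(rows)) for c in range(cols)]
    n = sum(row_m)
    stat = 0.0
    for r in range(rows):
        for c in range(cols):
            e = row_m[r] * col_m[c] / n
            if e > 0:
                stat += (counts[r][c] - e) ** 2 / e
    return stat
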