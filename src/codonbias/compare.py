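"""Cross-species and cross-group comparisons.

Covers the between-order statistics of the analysis: per-codon
frequent/rare tallies compared between two species groups with a
two-sided Fisher exact test, the ENC ~ third-position-composition GLM,
the CAI–ENC inverse-trend summary, rank-correlation clustering of RSCU
profiles, and the ortholog-vs-genome SCUO rank correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import hypergeom, rankdata
from scipy.stats import t as t_dist

from .cluster import (
    average_linkage,
    correlation_distance,
    leaf_order,
    linkage_to_newick,
)
from .genetics import GeneticCode, standard_code
from .usage import RscuTable


@dataclass
class CodonGroupTest:
    codon: str
    k1: int  # group-1 species with RSCU > 1
    m1: int  # group-1 species with RSCU < 1
    k2: int
    m2: int
    p: float  # NaN when a group has no voting species
    significant: bool


@dataclass
class GroupComparison:
    tests: dict[str, CodonGroupTest]
    alpha: float

    def significant_codons(self) -> list[str]:
        return sorted(c for c, t in self.tests.items() if t.significant)


@dataclass
class RegressionFit:
    coefficients: dict[str, float]
    p_values: dict[str, float]
    model: str
    condition_number: float
    scale: float


@dataclass
class TrendResult:
    pearson_r: float
    inverse_fraction: float
    n: int


def fisher_exact_two_sided(k1: int, m1: int, k2: int, m2: int) -> float:
    """Two-sided Fisher exact p for the 2×2 table [[k1, m1], [k2, m2]].

    Conditions on all margins and sums the hypergeometric probabilities
    of every table no more probable than the observed one (the standard
    two-sided summation rule).  A small tolerance absorbs floating-point
    ties between equally probable tables.
    """
    if min(k1, m1, k2, m2) < 0:
        raise ValueError("negative cell count")
    n1 = k1 + m1
    n = n1 + k2 + m2
    K = k1 + k2  # first-column margin
    if n == 0:
        return math.nan
    rv = hypergeom(n, K, n1)
    support = np.arange(max(0, K - (n - n1)), min(K, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(k1)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def cross_group_exact_test(
    rscu_by_species: dict[str, RscuTable],
    groups: dict[str, int],
    alpha: float = 0.05,
    code: GeneticCode | None = None,
) -> GroupComparison:
    """Per-codon frequent/rare 2×2 exact tests between two species groups.

    For each sense codon, k_g counts the group-g species where the codon
    is frequent (RSCU > 1) and m_g those where it is rare (RSCU < 1);
    neutral (RSCU exactly 1, e.g. single-codon families) and undefined
    species carry no vote.  p is the two-sided Fisher exact probability
    of [[k1, m1], [k2, m2]].
    """
    code = code or standard_code()
    ids_1 = [s for s, g in groups.items() if g == 1]
    ids_2 = [s for s, g in groups.items() if g == 2]
    if len(ids_1) < 2 or len(ids_2) < 2:
        raise ValueError("need at least 2 species per group")
    tests: dict[str, CodonGroupTest] = {}
    for codon in code.sense_codons:
        tallies = []
        for ids in (ids_1, ids_2):
            flags = [rscu_by_species[s].flags.get(codon, "undefined") for s in ids]
            tallies.append(
                (flags.count("frequent"), flags.count("rare"))
            )
        (k1, m1), (k2, m2) = tallies
        if k1 + m1 == 0 or k2 + m2 == 0:
            p = math.nan
        else:
            p = fisher_exact_two_sided(k1, m1, k2, m2)
        tests[codon] = CodonGroupTest(
            codon, k1, m1, k2, m2, p, bool(not math.isnan(p) and p < alpha)
        )
    return GroupComparison(tests=tests, alpha=alpha)


def enc_regression(
    gene_table: pd.DataFrame,
    drop: tuple[str, ...] = (),
    min_genes: int = 50,
) -> RegressionFit:
    """Quasi-Poisson GLM of per-gene ENC on third-position composition.

    ``gene_table`` needs columns enc, a3s, t3s, c3s, g3s.  The model is
    log E[ENC] = β₀ + β·(a3s, g3s, c3s, t3s): a log-link GLM with the
    Poisson variance function fit by IRLS, with the dispersion estimated
    from the Pearson χ² (the response is continuous, so the Poisson
    likelihood serves as a quasi-likelihood).  The four fractions sum to
    one, so the full design with intercept is singular; the default fit
    reports the minimum-norm IRLS solution together with the design
    condition number, while ``drop=("t3s",)`` gives the identifiable
    parameterization.
    """
    tab = gene_table.dropna(subset=["enc", "a3s", "t3s", "c3s", "g3s"])
    if len(tab) < min_genes:
        raise ValueError(f"need at least {min_genes} genes with defined ENC")
    predictors = [p for p in ("a3s", "g3s", "c3s", "t3s") if p not in drop]
    X = sm.add_constant(tab[predictors].to_numpy())
    y = tab["enc"].to_numpy()
    cond = float(np.linalg.cond(X))
    model = sm.GLM(y, X, family=sm.families.Poisson())
    fit = model.fit(scale=1.0)
    # quasi-likelihood dispersion from the Pearson chi-square; a perfect
    # fit (scale 0) keeps the unit scale so the coefficients stay defined
    disp = float(fit.pearson_chi2 / fit.df_resid) if fit.df_resid > 0 else 1.0
    if disp > 0:
        fit = model.fit(scale=disp)
    names = ["intercept"] + predictors
    return RegressionFit(
        coefficients=dict(zip(names, map(float, fit.params))),
        p_values=dict(zip(names, map(float, fit.pvalues))),
        model="quasi-poisson log link",
        condition_number=cond,
        scale=float(fit.scale),
    )


def cai_enc_trend(gene_table: pd.DataFrame, min_genes: int = 10) -> TrendResult:
    """Pearson r between CAI and ENC plus the inverse-trend fraction.

    A gene is counted as following the inverse trend when its CAI and
    ENC sit on opposite sides of the respective medians (above-median
    CAI with below-median ENC, or the reverse) — the quadrant
    operationalization of "CAI rises as ENC falls".
    """
    tab = gene_table.dropna(subset=["cai", "enc"])
    if len(tab) < min_genes:
        raise ValueError(f"need at least {min_genes} genes with CAI and ENC")
    cai = tab["cai"].to_numpy()
    enc = tab["enc"].to_numpy()
    if cai.std() == 0 or enc.std() == 0:
        return TrendResult(math.nan, math.nan, len(tab))
    r = float(np.corrcoef(cai, enc)[0, 1])
    d_cai = cai - np.median(cai)
    d_enc = enc - np.median(enc)
    frac = float(np.mean(d_cai * d_enc < 0))
    return TrendResult(pearson_r=r, inverse_fraction=frac, n=len(tab))


@dataclass
class RscuClustering:
    species_newick: str
    codon_newick: str
    matrix: pd.DataFrame  # rows/columns reordered to leaf order
    dropped_codons: list[str] = field(default_factory=list)


def cluster_rscu(
    rscu_by_species: dict[str, RscuTable],
    method: str = "spearman",
    code: GeneticCode | None = None,
) -> RscuClustering:
    """Average-linkage clustering of species and codons by RSCU profile.

    Distance is 1 − rank correlation (Spearman) between RSCU vectors;
    species are clustered over codons and codons over species.  Codons
    undefined in any species (absent families) are dropped and reported.
    """
    code = code or standard_code()
    if len(rscu_by_species) < 3:
        raise ValueError("need at least 3 species")
    species = sorted(rscu_by_species)
    mat = pd.DataFrame(
        {sp: rscu_by_species[sp].rscu for sp in species}
    ).T.reindex(columns=list(code.sense_codons))
    dropped = [c for c in mat.columns if mat[c].isna().any()]
    mat = mat.drop(columns=dropped)
    # constant columns (Met/Trp are exactly 1 everywhere) carry no rank
    # information and make correlations undefined for the codon tree
    constant = [c for c in mat.columns if mat[c].nunique() == 1]
    dropped += constant
    mat = mat.drop(columns=constant)
    sp_link = average_linkage(correlation_distance(mat.to_numpy(), method))
    cd_link = average_linkage(correlation_distance(mat.to_numpy().T, method))
    sp_order = leaf_order(sp_link, list(mat.index))
    cd_order = leaf_order(cd_link, list(mat.columns))
    return RscuClustering(
        species_newick=linkage_to_newick(sp_link, list(mat.index)),
        codon_newick=linkage_to_newick(cd_link, list(mat.columns)),
        matrix=mat.loc[sp_order, cd_order],
        dropped_codons=dropped,
    )


def spearman_correlation(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman rho with mid-rank ties and a two-sided p-value.

    p is an exact permutation probability (all n! rank permutations) for
    n ≤ ``exact_max_n`` and the usual t-approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y) or n < 3:
        raise ValueError("need two equal-length vectors, n >= 3")
    rx, ry = rankdata(x), rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return math.nan, math.nan
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = _pearson_rows(rx[np.newaxis, :], ry[perms])
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(2 * t_dist.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


def _pearson_rows(x: np.ndarray, ys: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    yc = ys - ys.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    return num / den


def ortho_scuo_correlation(table: pd.DataFrame) -> tuple[float, float]:
    """Rank correlation between ortholog-mean and genome-mean SCUO.

    ``table`` needs columns ortho_scuo and genome_scuo, one row per
    species (≥ 5 rows).
    """
    tab = table.dropna(subset=["ortho_scuo", "genome_scuo"])
    if len(tab) < 5:
        raise ValueError("need at least 5 species rows")
    return spearman_correlation(
        tab["ortho_scuo"].to_numpy(), tab["genome_scuo"].to_numpy()
    )
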