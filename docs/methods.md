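# Methods

This note documents the statistical definitions the package implements,
the conventions chosen where the literature is ambiguous, what the
synthetic generator does and does not emulate, and known limitations.

## Input validation

A record is accepted as a coding sequence only if its length is a
multiple of three and at least six nucleotides, it starts with an exact
ATG, ends with TAA/TAG/TGA, contains no internal stop, and (by default)
no IUPAC ambiguity code. Checks run in that order and the first failure
is the recorded exclusion reason, so validation is total: every input
record is either a validated gene or an excluded (id, reason) pair.
Rationale for the strict choices: a single ambiguous codon corrupts
family counts (so the gene, not the base, is rejected; `policy="keep"`
relaxes this), and non-ATG annotated starts are excluded because the
boundary-context statistics are defined relative to the initiator ATG.
U is normalized to T internally; report writers can print the RNA
alphabet (the convention of published codon tables) via
`alphabet="rna"`, while machine-readable TSVs stay DNA-keyed.

The genetic code is fixed to the standard nuclear code (transl_table 1);
Leu, Ser and Arg are treated as single six-fold families rather than
2+4 splits, because every family-expectation here divides by the full
number of synonymous codons of the amino acid.

## Single-codon statistics

**RSCU.** RSCU_ij = x_ij / ((1/n_i) Σ_j x_ij). Families with zero count
are *undefined*, not zero — an absent amino acid casts no frequent/rare
vote in cross-group tallies. Met and Trp are exactly 1 whenever present.

**ENC (Wright's estimator).** Per family with n ≥ 2 counted codons,
F̂ = (nΣp̂² − 1)/(n − 1); class averages F̄_k over the families of
degeneracy k ∈ {2, 3, 4, 6}; ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆,
capped at 61. Missing-class rules follow the common CodonW conventions:
families with n < 2 are skipped; if the three-fold class (Ile alone) is
unobserved, F̄₃ is estimated as (F̄₂ + F̄₄)/2; any other missing or
non-positive class average leaves the gene's ENC undefined with a
recorded reason. Note that F̂ can legitimately be ≤ 0 at very small n
(e.g. two counts on different codons of a ≥ 3-fold family), so short
genes often have undefined ENC — that is a property of the estimator,
not an error.

**CAI (Sharp & Li).** w_ij = RSCU_ij(ref)/max_j RSCU_ij(ref); reference
codons with zero count receive the conventional floor w = 0.01;
single-codon families (ATG, TGG) and stops are excluded from the
geometric mean. CAI is length-invariant at fixed codon proportions and
equals 1 iff the gene uses only family-maximal codons.

**Composition.** GC is taken over all positions of sense codons
(initiator ATG included, stops excluded). The synonymous third-position
fractions A3s/T3s/C3s/G3s exclude Met and Trp codons (their third
position is not synonymous); plain third-position fractions are also
reported. Whether CodonW's denominators included the initiator and
terminal stop is not documented anywhere authoritative; the convention
here (stops out, ATG in) is explicit and a flag on `count_codons`
removes the initiator.

## SCUO

Per amino acid with n_i ≥ 2 present in the gene: H_i = −Σ p_ij log₂
p_ij, O_i = (log₂ n_i − H_i)/log₂ n_i, composition weight
F_i = c_i/Σc_i, and SCUO = Σ F_i O_i ∈ [0, 1]. The phrase "one minus
the ratio of expected to observed entropy" sometimes used to gloss this
index is internally inconsistent (the ratio diverges at zero observed
entropy); the implemented definition is the original
normalized-entropy-difference form, which has the stated limits
(0 uniform, 1 one-codon-per-family). Entropies are reported in bits;
SCUO itself is base-invariant.

Genes are binned into ten 0.1-wide intervals, lower-inclusive with the
last bin closed ([0.9, 1.0]), so assignment is deterministic and total.
All-pairs bin comparison uses Dunnett's modification of the
Tukey–Kramer procedure for unequal group sizes and variances: per pair,
Welch SE √(s²_a/n_a + s²_b/n_b), Welch–Satterthwaite df, and the
simultaneous interval diff ± q(0.95; k, df)/√2 · SE from the
studentized-range quantile, k being the number of usable (n ≥ 2) bins.
The published variance plots are ambiguous about whether DTK ran on
per-bin SCUO values or on variance contributions; this implementation
compares per-bin SCUO values and reports per-bin variances alongside.

## Codon-pair contexts

Pairs are adjacent in-frame codons within single genes, never across
gene boundaries. By default the two boundary pairs of each gene —
(ATG, c₂) and (c_{L−1}, stop) — are excluded from the 61×61 sense-pair
table and routed to the boundary-context tables, keeping internal
context statistics free of the start/stop signals; `inclusive=True`
restores whole-gene counting over sense × (sense ∪ stop), the mode in
which a genome's rarest contexts are typically NNN-stop pairs.
Published RSCPU tables are sometimes described as 60×60 without naming
the excluded codon; there being no defensible single exclusion, the
full 61×61 sense universe is used here.

Adjusted residuals are Haberman's: (x − e)/√(e(1 − row/N)(1 − col/N)),
approximately standard normal under independence (verified
distributionally in tests). RSCPU for a pair coding amino-acid pair
(a, b) is count/expected with expected = total(a, b)/(n_a n_b); within
each observed amino-acid pair the values sum to n_a × n_b.

Most/least-frequent boundary queries break ties lexicographically and
report the full tie set. Species-level context clustering flattens the
residual matrices over cells defined in every retained species
(species under 50 % defined cells are dropped with a warning), uses
1 − Pearson correlation (Spearman available via a flag), average
linkage, and emits Newick with ultrametric branch lengths.

## Cross-group statistics

**Fisher exact tests.** For each codon, k_g/m_g count the group-g
species with RSCU > 1 / < 1 (neutral and undefined species drop out);
the two-sided p sums all hypergeometric probabilities not exceeding the
observed table's, with a 1e-7 relative tolerance absorbing
floating-point ties between equally probable tables. Although such
tables are often labelled "chi-square significance" in print, the
published values this package reproduces are exactly these two-sided
Fisher probabilities (e.g. [[15,0],[0,7]] → 1/C(22,7) = 5.86×10⁻⁶); a
chi-square alternative is deliberately not the default. The
implementation is validated against exhaustive rational enumeration for
every margin with N ≤ 30.

**ENC regression.** ENC ~ A3s + G3s + C3s + T3s as a log-link GLM with
Poisson variance function; since ENC is continuous this is a
quasi-likelihood fit, with dispersion estimated from the Pearson χ²
(unit scale is kept when the fit is perfect, where the dispersion is
zero). The four fractions sum to one, so the full design with intercept
is singular; the default fit reports the minimum-norm IRLS solution
plus the design condition number, and `drop=("t3s",)` gives the
identifiable parameterization used for coefficient-recovery tests.
Coefficient signs and significance, not magnitudes, are the comparable
surface across datasets.

**CAI–ENC trend.** Pearson r plus a quadrant rule: a gene follows the
inverse trend when its CAI and ENC lie on opposite sides of the
respective medians. This is an explicit operationalization of "CAI
rises as ENC falls"; the published description of the trend fraction is
not a defined statistic, so the median-quadrant rule is documented as
this package's convention.

**RSCU clustering.** Species over codon vectors and codons over species
vectors, distance 1 − Spearman, average linkage. Codons undefined in
any species are dropped and reported, as are constant codons (Met/Trp
are exactly 1 everywhere and carry no rank information).

**Ortholog SCUO correlation.** Spearman rho with mid-rank ties; exact
permutation p for n ≤ 10 (all n! permutations of one rank vector),
t-approximation above.

## Permutation test

The "position" model permutes, within each gene independently, the
bases of the first, second and third codon positions among the gene's
internal codons; start and stop codons are exempt. The randomization
exactly preserves per-gene, per-position base multisets (hence GC and
GC3), and randomized genes are deliberately not re-validated — internal
stop triplets created by the shuffle are counted as written. Per codon,
the 2×2 table [[obs_total, obs_expected], [rand_total, rand_expected]]
(expected = amino-acid total/degeneracy in the respective data) is
tested with Pearson's chi-square, no continuity correction (flag
available); randomized quantities average over the scheme's replicates
(default 100; a fixed seed is required). Cross-gene column pooling is
available behind a flag.

A caveat this package verifies empirically: the four cells of that
table are mutually dependent (the expected entries are deterministic
functions of the same family totals), so under a position-independent
null the test is strongly conservative — the fraction of codons flagged
at α = 0.05 is near zero rather than 5 %. It controls false positives,
but its p-values are not uniform; treat them as a screening statistic.
Power for real coupling remains high: concentrating the six-fold
families (Leu/Arg/Ser), where first/second-position changes are
synonymous, flags essentially all of their codons.

## Synthetic generator

The generator emulates: species-specific synonymous preference (one
probability vector per family), a GC3 tilt axis (`gc3_bias`: each
G/C-ending codon weighted ∝ b, A/T-ending ∝ 1 − b within its family,
reversed for the AT-tilted preset), a fixed residue composition
(default: Leu 9 %, Trp 1 %, remainder even — the qualitative shape of
insect proteomes), negative-binomial gene lengths (default mean 400
codons, dispersion 5, floor 10), optional boundary-context preferences,
and an injectable codon-pair bias. Pair bias uses a pair-field model —
the body distribution is ∝ Π w(c_i) Π boost(c_i, c_{i+1}), sampled
exactly by a backward message pass and forward conditional draw — so an
isolated boosted pair (x, y) has within-block probability
b·w_x·w_y/(1 + (b−1)w_x w_y); e.g. boost 3 on GAA-GAA with uniform Glu
usage gives an expected RSCPU of exactly 2.0. One global seed drives a
counter-based substream per gene, so gene g's sequence is independent
of how many genes are drawn.

Not emulated: expression levels and translational selection, isochore
or positional GC structure, introns/splicing, phylogenetic covariance
between species, indels or misannotation noise. Passing recovery tests
therefore demonstrates that the estimators measure what they claim on
data satisfying their assumptions — not that real genomes satisfy those
assumptions.

## Problem sizes and numerical choices

Tests and the analysis scripts run at deliberately modest scales chosen
so each statistic's sampling error is far below its tested tolerance:
recovery experiments use 10²–10³ genes of 100–250 codons (10⁴–5×10⁵
codons), the RSCU-recovery check uses ~5×10⁵ codons so the ±0.05 band
is a 4σ bound for four-fold families, the regression recovery uses
5 000 genes, and the permutation null uses 200 genomes of 30×100
codons. IRLS and clustering are deterministic; correlation distances
are clipped into [0, 2] and symmetrized before linkage; all randomness
flows from explicit seeds.

## Known limitations

- ENC is undefined for short genes (small-sample F̂ ≤ 0); downstream
  tables carry NaN rather than imputations.
- The permutation-association chi-square is conservative (above).
- The DTK intervals use the studentized-range quantile at per-pair
  Welch df; for very small bins the simultaneous coverage is
  approximate.
- Exact Spearman permutation p at n = 10 materializes all 10!
  permutations (~0.3 GB transient); above n = 10 the t-approximation
  is used.
- The pipeline treats each species independently; no phylogenetic
  correction is applied to cross-species correlations.
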