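"""Cross-group exact tests, composition regression, CAI-ENC trend,
RSCU clustering, and ortholog SCUO correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from codonbias.compare import (
    cai_enc_trend,
    cluster_rscu,
    cross_group_exact_test,
    enc_regression,
    fisher_exact_two_sided,
    ortho_scuo_correlation,
    spearman_correlation,
)
from codonbias.usage import CodonCounts, rscu

from .oracles import fisher_enumerate


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((15, 0, 0, 7), 5.86e-06),
            ((15, 0, 1, 6), 9.38e-05),
            ((14, 1, 1, 6), 0.000622),
            ((15, 0, 4, 3), 0.022727),
            ((13, 2, 2, 5), 0.013551),
        ],
    )
    def test_two_group_tally_p_values(self, table, expected):
        """Frequent/rare species tallies between a 15- and a 7-species
        group give the published two-sided exact probabilities."""
        p = fisher_exact_two_sided(*table)
        assert p == pytest.approx(expected, rel=5e-3)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(8, 7, 4, 3) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        for k1, m1, k2, m2 in [
            (3, 2, 1, 4),
            (5, 5, 5, 5),
            (9, 0, 2, 4),
            (0, 6, 6, 0),
            (1, 1, 1, 1),
            (12, 3, 2, 8),
        ]:
            assert fisher_exact_two_sided(k1, m1, k2, m2) == pytest.approx(
                fisher_enumerate(k1, m1, k2, m2), rel=1e-9
            )

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k1, m1, k2, m2 = rng.integers(0, 12, size=4)
            if k1 + m1 == 0 or k2 + m2 == 0:
                continue
            ref = scipy.stats.fisher_exact([[k1, m1], [k2, m2]])[1]
            assert fisher_exact_two_sided(k1, m1, k2, m2) == pytest.approx(ref, rel=1e-9)

    def test_symmetries(self):
        p = fisher_exact_two_sided(11, 2, 3, 9)
        assert fisher_exact_two_sided(3, 9, 11, 2) == pytest.approx(p)  # group swap
        assert fisher_exact_two_sided(2, 11, 9, 3) == pytest.approx(p)  # column swap


class TestCrossGroup:
    def _rscu_tables(self, spec):
        """spec: species -> RSCU value for GAA (GAG gets the complement)."""
        out = {}
        for sp, gaa in spec.items():
            counts = CodonCounts(x={"GAA": int(100 * gaa), "GAG": int(100 * (2 - gaa))})
            out[sp] = rscu(counts)
        return out

    def test_divergent_groups_significant(self):
        spec = {f"d{i}": 1.5 for i in range(6)} | {f"h{i}": 0.5 for i in range(4)}
        groups = {s: 1 if s.startswith("d") else 2 for s in spec}
        comp = cross_group_exact_test(self._rscu_tables(spec), groups)
        t = comp.tests["GAA"]
        assert (t.k1, t.m1, t.k2, t.m2) == (6, 0, 0, 4)
        assert t.significant
        assert t.p == pytest.approx(fisher_enumerate(6, 0, 0, 4))

    def test_neutral_species_carry_no_vote(self):
        spec = {"a": 1.0, "b": 1.5, "c": 0.5, "d": 1.5, "e": 0.5}
        groups = {"a": 1, "b": 1, "c": 1, "d": 2, "e": 2}
        comp = cross_group_exact_test(self._rscu_tables(spec), groups)
        t = comp.tests["GAA"]
        assert t.k1 + t.m1 == 2  # species "a" (RSCU exactly 1) dropped

    def test_undefined_in_whole_group_gives_nan(self):
        spec = {"a": 1.5, "b": 0.5, "c": 1.5, "d": 0.5}
        tables = self._rscu_tables(spec)
        groups = {s: 1 if s in "ab" else 2 for s in spec}
        comp = cross_group_exact_test(tables, groups)
        # CTG never counted in any species: no votes anywhere
        assert math.isnan(comp.tests["CTG"].p)


class TestRegression:
    @staticmethod
    def _planted_table(n, beta_a3s, seed, noise=0.03):
        rng = np.random.default_rng(seed)
        comp = rng.dirichlet([8.0, 8.0, 8.0, 8.0], size=n)
        a3s, t3s, c3s, g3s = comp.T
        enc = np.exp(np.log(48.0) + beta_a3s * a3s + rng.normal(0, noise, n))
        return pd.DataFrame(
            {"enc": enc, "a3s": a3s, "t3s": t3s, "c3s": c3s, "g3s": g3s}
        )

    def test_constant_response_zero_slopes(self):
        tab = self._planted_table(200, 0.0, seed=1, noise=0.0)
        fit = enc_regression(tab, drop=("t3s",))
        for name in ("a3s", "g3s", "c3s"):
            assert fit.coefficients[name] == pytest.approx(0.0, abs=1e-6)

    def test_recovers_planted_coefficient(self):
        tab = self._planted_table(2000, -0.4, seed=2)
        fit = enc_regression(tab, drop=("t3s",))
        assert fit.coefficients["a3s"] == pytest.approx(-0.4, abs=0.05)
        assert fit.p_values["a3s"] < 1e-6

    def test_sign_convention_negative_for_concentrating_a3(self):
        tab = self._planted_table(1500, -0.3, seed=3)
        fit = enc_regression(tab, drop=("t3s",))
        assert fit.coefficients["a3s"] < 0

    def test_full_design_reports_condition_number(self):
        tab = self._planted_table(300, -0.2, seed=4)
        fit = enc_regression(tab)
        assert fit.condition_number > 1e6  # fractions sum to 1: singular design
        assert set(fit.coefficients) == {"intercept", "a3s", "g3s", "c3s", "t3s"}

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            enc_regression(self._planted_table(10, 0.0, seed=5))


class TestTrend:
    def test_perfect_inverse_trend(self):
        enc = np.linspace(30, 60, 50)
        tab = pd.DataFrame({"cai": 1.2 - enc / 60.0, "enc": enc})
        tr = cai_enc_trend(tab)
        assert tr.pearson_r == pytest.approx(-1.0)
        assert tr.inverse_fraction == pytest.approx(1.0)

    def test_independent_inputs_near_zero(self):
        rng = np.random.default_rng(11)
        tab = pd.DataFrame(
            {"cai": rng.random(2000), "enc": rng.uniform(20, 61, 2000)}
        )
        tr = cai_enc_trend(tab)
        assert abs(tr.pearson_r) < 0.1

    def test_zero_variance_undefined(self):
        tab = pd.DataFrame({"cai": [0.5] * 20, "enc": np.linspace(30, 50, 20)})
        assert math.isnan(cai_enc_trend(tab).pearson_r)

    def test_stronger_bias_more_negative(self):
        """Generated genomes: heavier codon bias gives a more negative
        CAI-ENC correlation than near-uniform usage."""
        from codonbias.synth import generate_genes, make_profile
        from codonbias.usage import cai, count_codons, enc

        rows = {}
        for label, gc3 in (("strong", 0.92), ("weak", 0.6)):
            profile = make_profile("diptera_like", gc3_bias=gc3, length_mean=150)
            genes, _ = generate_genes(profile, 250, seed=17)
            ref_profile = make_profile("diptera_like", gc3_bias=0.95, length_mean=150)
            ref_genes, _ = generate_genes(ref_profile, 40, seed=18)
            reference = count_codons(ref_genes, pool=True)
            per_gene = count_codons(genes, pool=False)
            tab = pd.DataFrame(
                {
                    "cai": [cai(c, reference).cai for c in per_gene.values()],
                    "enc": [enc(c).enc for c in per_gene.values()],
                }
            )
            rows[label] = cai_enc_trend(tab).pearson_r
        assert rows["strong"] < rows["weak"]


class TestClusterRscu:
    def _tables(self, gc3_by_species):
        from codonbias.synth import generate_genes, make_profile
        from codonbias.usage import count_codons

        out = {}
        for sp, (preset, gc3, seed) in gc3_by_species.items():
            profile = make_profile(preset, gc3_bias=gc3, length_mean=120, species_id=sp)
            genes, _ = generate_genes(profile, 40, seed=seed)
            out[sp] = rscu(count_codons(genes, pool=True))
        return out

    def test_identical_species_join_first_at_zero(self):
        from codonbias.cluster import average_linkage, correlation_distance

        tables = self._tables({"a": ("uniform", 0.5, 1), "c": ("diptera_like", 0.9, 2)})
        tables["b"] = tables["a"]
        clustering = cluster_rscu(tables)
        mat = clustering.matrix.sort_index()
        link = average_linkage(
            correlation_distance(mat.to_numpy(), "spearman")
        )
        first = {int(link[0, 0]), int(link[0, 1])}
        assert first == {0, 1}  # rows a and b
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_two_block_recovery(self):
        spec = {
            f"d{i}": ("diptera_like", 0.85, i) for i in range(4)
        } | {f"h{i}": ("hymenoptera_like", 0.85, 10 + i) for i in range(3)}
        clustering = cluster_rscu(self._tables(spec))
        order = list(clustering.matrix.index)
        d_pos = [order.index(s) for s in spec if s.startswith("d")]
        h_pos = [order.index(s) for s in spec if s.startswith("h")]
        assert max(d_pos) < min(h_pos) or max(h_pos) < min(d_pos)
        # C/G-ending codons co-cluster in the codon ordering
        cod_order = list(clustering.matrix.columns)
        gc_pos = [i for i, c in enumerate(cod_order) if c[2] in "GC"]
        at_pos = [i for i, c in enumerate(cod_order) if c[2] in "AT"]
        gc_mean = np.mean(gc_pos)
        at_mean = np.mean(at_pos)
        assert abs(gc_mean - at_mean) > len(cod_order) / 4

    def test_spearman_invariant_to_monotone_rescale(self):
        tables = self._tables(
            {"a": ("diptera_like", 0.8, 1), "b": ("uniform", 0.5, 2), "c": ("hymenoptera_like", 0.8, 3)}
        )
        base = cluster_rscu(tables)
        import copy

        warped = copy.deepcopy(tables)
        warped["a"].rscu.update(
            {c: v**2 for c, v in warped["a"].rscu.items()}
        )  # monotone transform of one species
        again = cluster_rscu(warped)
        assert base.species_newick == again.species_newick


class TestSpearman:
    def test_identical_columns(self):
        x = np.arange(8.0)
        rho, p = spearman_correlation(x, x * 3 + 1)
        assert rho == pytest.approx(1.0)
        # only the identity and the full reversal reach |rho| = 1
        assert p == pytest.approx(2 / math.factorial(8))

    def test_reversed_ranks(self):
        x = np.arange(8.0)
        rho, _ = spearman_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_exact_permutation_matches_enumeration(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = spearman_correlation(x, y)
        # independent enumeration over all 720 permutations
        robs = scipy.stats.spearmanr(x, y).statistic
        hits = 0
        for perm in itertools.permutations(y):
            if abs(scipy.stats.spearmanr(x, perm).statistic) >= abs(robs) - 1e-12:
                hits += 1
        assert rho == pytest.approx(robs)
        assert p == pytest.approx(hits / 720)

    def test_t_approximation_against_scipy(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(40), rng.random(40)
        rho, p = spearman_correlation(x, y)
        ref = scipy.stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ortho_table(self):
        tab = pd.DataFrame(
            {
                "ortho_scuo": [0.115, 0.3, 0.411, 0.263, 0.176, 0.208],
                "genome_scuo": [0.148, 0.218, 0.272, 0.221, 0.178, 0.201],
            }
        )
        rho, p = ortho_scuo_correlation(tab)
        assert rho == pytest.approx(scipy.stats.spearmanr(
            tab["ortho_scuo"], tab["genome_scuo"]).statistic)
        assert 0 < p <= 1
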