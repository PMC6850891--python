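import math

import numpy as np
import pytest

from refstab.genorm import (GenormError, gene_pair_variation, genorm, m_values,
                            pairwise_variation_nf, relative_quantities,
                            stepwise_ranking)
from refstab.simulate import SimConfig, default_gene_specs, simulate_ct

from .conftest import make_matrix
from .oracles import (brute_m, brute_pair_v, brute_q, brute_stepwise,
                      brute_v_series)


def _q_rows(q):
    return {g: list(q.q[i]) for i, g in enumerate(q.genes)}


class TestRelativeQuantities:
    def test_one_cycle_halving(self):
        m = make_matrix(["g"], ["a", "b", "c"], [[20.0, 21.0, 22.0]])
        q = relative_quantities(m)
        np.testing.assert_allclose(q.q[0], [1.0, 0.5, 0.25])

    def test_constant_row(self):
        m = make_matrix(["g"], ["a", "b"], [[25.0, 25.0]])
        np.testing.assert_allclose(relative_quantities(m).q[0], [1.0, 1.0])

    def test_custom_base_formula(self):
        row = [21.3, 20.0, 23.7]
        m = make_matrix(["g"], ["a", "b", "c"], [row])
        q = relative_quantities(m, base=1.95)
        expect = [1.95 ** (min(row) - c) for c in row]
        np.testing.assert_allclose(q.q[0], expect)

    def test_row_max_is_one(self):
        rng = np.random.default_rng(0)
        m = make_matrix([f"g{i}" for i in range(5)],
                        [f"s{j}" for j in range(7)],
                        20 + 8 * rng.random((5, 7)))
        q = relative_quantities(m)
        np.testing.assert_allclose(q.q.max(axis=1), 1.0)
        assert (q.q > 0).all()

    def test_bad_base(self):
        m = make_matrix(["g"], ["a", "b"], [[20.0, 21.0]])
        with pytest.raises(GenormError, match="base"):
            relative_quantities(m, base=1.0)


class TestPairVariation:
    def test_scalar_multiple_is_zero(self):
        q = np.array([1.0, 0.5, 0.25, 0.125])
        assert gene_pair_variation(q, 3.0 * q) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        # log2 ratios (0, 1) -> sample SD = 1/sqrt(2)
        assert gene_pair_variation(np.array([1.0, 1.0]),
                                   np.array([1.0, 0.5])) == pytest.approx(
            1 / math.sqrt(2), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(6) + 0.1, rng.random(6) + 0.1
        assert gene_pair_variation(a, b) == pytest.approx(
            gene_pair_variation(b, a))

    def test_single_sample_errors(self):
        with pytest.raises(GenormError):
            gene_pair_variation(np.array([1.0]), np.array([1.0]))

    def test_t1_full_pairwise_oracle(self, t1_matrix):
        q = relative_quantities(t1_matrix)
        rows = _q_rows(q)
        for gj in q.genes:
            for gk in q.genes:
                if gj == gk:
                    continue
                got = gene_pair_variation(q.row(gj), q.row(gk))
                assert got == pytest.approx(brute_pair_v(rows[gj], rows[gk]))


class TestMValues:
    def test_two_genes_share_m(self, t1_matrix):
        q = relative_quantities(t1_matrix)
        ms = m_values(q, ["gA", "gB"])
        v = gene_pair_variation(q.row("gA"), q.row("gB"))
        assert ms["gA"] == pytest.approx(v)
        assert ms["gB"] == pytest.approx(v)

    def test_coregulated_panel_all_zero(self):
        base = np.array([20.0, 21.0, 19.0, 22.0])
        m = make_matrix(["a", "b", "c"], ["s1", "s2", "s3", "s4"],
                        [base, base + 2.0, base + 5.0])
        ms = m_values(relative_quantities(m))
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in ms.values())

    def test_t1_oracle(self, t1_matrix):
        q = relative_quantities(t1_matrix)
        got = m_values(q)
        expect = brute_m(_q_rows(q))
        for g in q.genes:
            assert got[g] == pytest.approx(expect[g])

    def test_singleton_errors(self, t1_matrix):
        with pytest.raises(GenormError):
            m_values(relative_quantities(t1_matrix), ["gA"])


class TestStepwiseRanking:
    def test_constructed_separation(self):
        rng = np.random.default_rng(0)
        base = np.array([20.0, 21.0, 19.0, 22.0, 20.5])
        noise = 20 + 6 * rng.random(5)
        m = make_matrix(["a", "b", "noise", "c"],
                        [f"s{j}" for j in range(5)],
                        [base, base + 1.0, noise, base + 3.0])
        res = stepwise_ranking(relative_quantities(m))
        assert res.exclusion_order[0] == "noise"
        assert res.best_pair_m == pytest.approx(0.0, abs=1e-12)

    def test_t1_oracle(self, t1_matrix):
        q = relative_quantities(t1_matrix)
        res = stepwise_ranking(q)
        order, m_at = brute_stepwise(_q_rows(q), list(q.genes))
        assert res.exclusion_order == order
        for g, v in m_at.items():
            assert res.m_at_removal[g] == pytest.approx(v)

    def test_high_variance_gene_ranked_last(self):
        hits = 0
        for seed in range(100):
            specs = default_gene_specs(sigmas=[0.2] * 9 + [0.6])
            cfg = SimConfig(genes=specs, groups={"A": 8}, seed=seed)
            mat, _ = simulate_ct(cfg)
            res = stepwise_ranking(relative_quantities(mat))
            if res.exclusion_order[0] == "G10":
                hits += 1
        assert hits >= 95

    def test_needs_three_genes(self, t1_matrix):
        q = relative_quantities(t1_matrix.subset_genes(["gA", "gB"]))
        with pytest.raises(GenormError):
            stepwise_ranking(q)

    def test_rankings(self, t1_matrix):
        res = stepwise_ranking(relative_quantities(t1_matrix))
        sp = res.ranking("single_pass")
        assert sorted(sp.values()) == [1, 2, 3]
        st = res.ranking("stepwise")
        assert sorted(st.values()) == [1, 1, 3]


class TestPairwiseVariationNF:
    def test_coregulated_all_zero(self):
        base = np.array([20.0, 21.0, 19.0, 22.0])
        m = make_matrix(["a", "b", "c", "d"], [f"s{j}" for j in range(4)],
                        [base, base + 1, base + 2, base + 3])
        res = genorm(m)
        assert all(v == pytest.approx(0.0, abs=1e-12)
                   for v in res.v_series.values())
        assert res.recommended_n == 2

    def test_t1_v23_oracle(self, t1_matrix):
        q = relative_quantities(t1_matrix)
        res = pairwise_variation_nf(q, stepwise_ranking(q))
        order = list(reversed(res.exclusion_order))
        expect = brute_v_series(_q_rows(q), order)
        assert set(res.v_series) == set(expect)
        for n in expect:
            assert res.v_series[n] == pytest.approx(expect[n])

    def test_paper_scale_v23_below_threshold(self):
        specs = default_gene_specs(sigmas=[0.2] * 10)
        cfg = SimConfig(genes=specs, groups={f"g{i}": 2 for i in range(6)},
                        replicates=1, loading_sd=0.5, seed=4)
        mat, _ = simulate_ct(cfg)
        res = genorm(mat)
        assert res.v_series[2] < 0.15
        assert res.recommended_n == 2


class TestInvariances:
    def test_m_shift_invariance(self, t1_matrix):
        q1 = relative_quantities(t1_matrix)
        shifted = t1_matrix.copy()
        shifted.ct[1] += 3.7  # constant Ct shift of one gene
        q2 = relative_quantities(shifted)
        m1, m2 = m_values(q1), m_values(q2)
        for g in q1.genes:
            assert m1[g] == pytest.approx(m2[g], abs=1e-10)

    def test_duplicate_gene_does_not_raise_m(self, t1_matrix):
        q = relative_quantities(t1_matrix)
        m_before = m_values(q)["gA"]
        dup = make_matrix(["gA", "gB", "gC", "gA2"],
                          t1_matrix.samples,
                          np.vstack([t1_matrix.ct, t1_matrix.ct[0]]))
        m_after = m_values(relative_quantities(dup))["gA"]
        assert m_after <= m_before + 1e-12

    def test_brute_force_equivalence_100_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            ct = 18 + 10 * rng.random((5, 8))
            mat = make_matrix([f"g{i}" for i in range(5)],
                              [f"s{j}" for j in range(8)], ct)
            q = relative_quantities(mat)
            res = pairwise_variation_nf(q, stepwise_ranking(q))
            rows = _q_rows(q)
            order, m_at = brute_stepwise(rows, list(q.genes))
            assert res.exclusion_order == order
            expect_v = brute_v_series(rows, list(reversed(order)))
            for n in expect_v:
                assert res.v_series[n] == pytest.approx(expect_v[n])
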