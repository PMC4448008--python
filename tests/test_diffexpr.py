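"""Fisher exact, chi-squared, BH adjustment, and the DE calling procedure."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency, fisher_exact as scipy_fisher, hypergeom

from mirpipe.diffexpr import bh_adjust, call_de, chi2_2x2, fisher_exact_2x2, fisher_grid


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert fisher_exact_2x2(7, 7, 120, 120) == 1.0

    def test_degenerate_all_zero(self):
        assert fisher_exact_2x2(0, 0, 50, 60) == 1.0

    def test_five_vs_zero_equals_direct_enumeration(self):
        # two-sided p for [[5,95],[0,100]] by explicit hypergeometric enumeration
        rv = hypergeom(200, 5, 100)
        pmf = rv.pmf(np.arange(6))
        expected = pmf[pmf <= pmf[5] * (1 + 1e-9)].sum()
        assert fisher_exact_2x2(5, 0, 100, 100) == pytest.approx(expected, rel=1e-10)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            Na, Nb = int(rng.integers(1, 500)), int(rng.integers(1, 500))
            a, b = int(rng.integers(0, Na + 1)), int(rng.integers(0, Nb + 1))
            p_scipy = scipy_fisher([[a, Na - a], [b, Nb - b]]).pvalue
            assert fisher_exact_2x2(a, b, Na, Nb) == pytest.approx(p_scipy, rel=1e-6, abs=1e-12)

    def test_grid_matches_scalar(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            Na, Nb = int(rng.integers(1, 80)), int(rng.integers(1, 80))
            grid = fisher_grid(Na, Nb)
            for _ in range(10):
                a, b = int(rng.integers(0, Na + 1)), int(rng.integers(0, Nb + 1))
                assert grid[a, b] == pytest.approx(fisher_exact_2x2(a, b, Na, Nb), rel=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            fisher_exact_2x2(1.5, 0, 10, 10)  # type: ignore[arg-type]
        with pytest.raises(ValueError):
            fisher_exact_2x2(11, 0, 10, 10)


class TestChi2:
    def test_symmetric_table_statistic_zero(self):
        p, unreliable = chi2_2x2(30, 30, 1000, 1000)
        assert p == pytest.approx(1.0) and not unreliable

    def test_hand_computed_statistic(self):
        # [[10,990],[40,960]]: E = [[25,975],[25,975]]
        stat = 2 * (15**2 / 25) + 2 * (15**2 / 975)
        from scipy.stats import chi2 as chi2_dist

        p, unreliable = chi2_2x2(10, 40, 1000, 1000)
        assert not unreliable
        assert p == pytest.approx(float(chi2_dist.sf(stat, 1)), rel=1e-12)

    def test_agrees_with_scipy_no_correction(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            Na, Nb = int(rng.integers(50, 400)), int(rng.integers(50, 400))
            a, b = int(rng.integers(5, 40)), int(rng.integers(5, 40))
            p, unreliable = chi2_2x2(a, b, Na, Nb)
            if not unreliable:
                ref = chi2_contingency([[a, Na - a], [b, Nb - b]], correction=False)
                assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_low_expected_cells_flagged(self):
        p, unreliable = chi2_2x2(0, 0, 10, 10)
        assert p == 1.0 and unreliable
        p, unreliable = chi2_2x2(1, 0, 1000, 1000)  # expected 0.5 per library
        assert p == 1.0 and unreliable


class TestBH:
    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_adjust([0.001, 0.02, 0.9]) == pytest.approx([0.003, 0.03, 0.9])

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDE:
    def test_low_abundance_excluded_before_testing(self):
        res = call_de(["x"], [9], [9], 100000, 100000)
        assert res[0].call == "excluded-low-abundance" and res[0].q is None

    def test_fold_change_gate(self):
        # strong p-value but fold < 2 must stay not-DE
        res = call_de(["x"], [10000, ], [18000], 1_000_000, 1_000_000)
        assert res[0].fold_change < 2 and res[0].call == "not-DE"

    def test_direction_and_q_gate(self):
        res = call_de(["x"], [50], [200], 1_000_000, 1_000_000)
        assert res[0].call == "up-in-B" and res[0].q <= 0.01 and res[0].fold_change >= 2

    def test_swap_flips_direction_keeps_pvalue(self):
        r1 = call_de(["x"], [50], [200], 1_000_000, 1_000_000)[0]
        r2 = call_de(["x"], [200], [50], 1_000_000, 1_000_000)[0]
        assert r1.p_fisher == pytest.approx(r2.p_fisher, rel=1e-12)
        assert (r1.call, r2.call) == ("up-in-B", "down-in-B")

    def test_zero_count_pseudocount_keeps_fold_finite(self):
        r = call_de(["x"], [40], [0], 1_000_000, 1_000_000)[0]
        assert np.isfinite(r.fold_change) and r.call == "down-in-B"

    def test_bh_over_retained_set_only(self):
        names = ["a", "b", "c"]
        res = call_de(names, [5, 50, 60], [5, 52, 240], 1_000_000, 1_000_000)
        qs = [r.q for r in res if r.q is not None]
        assert res[0].q is None and len(qs) == 2
        # m=2 in the BH denominator, not 3
        ps = sorted(r.p_fisher for r in res if r.p_fisher is not None)
        assert min(qs) == pytest.approx(min(ps) * 2 / 1, abs=1e-9) or min(qs) >= min(ps)
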