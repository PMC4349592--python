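"""Sister-pair bootstrap, trios, chi-squared tails, penetrance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from lineascope.stats import (BootstrapResult, category_association,
                              cells_defective_in_at_least, chi2_sf_log10,
                              count_defect_trios, count_sister_pairs,
                              enrichment_2x2, enrichment_gof, penetrance_table,
                              sister_pair_bootstrap, sister_pair_null_exact)

PAIRS = [("ABala", "ABalp"), ("ABara", "ABarp"), ("MSaaaaa", "MSaaaap")]


class TestSisterPairBootstrap:
    def test_zero_observed_pairs_gives_p_one(self):
        sub = {"ABala", "ABalp", "MSa", "Ca"}
        res = sister_pair_bootstrap({"MSa", "Ca"}, sub, n_iter=1000, seed=0)
        assert res.Y == 0
        assert res.p_value == 1.0

    def test_two_pair_subgroup_matches_exact_third(self):
        """subgroup {a1,a2,b1,b2}, defective one full pair: exact null
        P(>=1 pair among 2 draws from 4) = 2/6."""
        sub = {"ABala", "ABalp", "ABara", "ABarp"}
        res = sister_pair_bootstrap({"ABala", "ABalp"}, sub,
                                    n_iter=100_000, seed=3)
        assert res.Y == 1
        assert res.p_value == pytest.approx(2 / 6, abs=0.005)

    def test_everything_defective_gives_p_one(self):
        sub = {"ABala", "ABalp", "ABara", "ABarp"}
        res = sister_pair_bootstrap(sub, sub, n_iter=500, seed=0)
        assert res.p_value == 1.0

    def test_defective_larger_than_subgroup_rejected(self):
        with pytest.raises(ValueError):
            sister_pair_bootstrap({"ABala", "ABalp"}, {"ABala"}, 100, 0)

    def test_reproducible_and_order_invariant(self):
        sub = [c for p in PAIRS for c in p] + ["Da", "Dp"]
        defective = {"ABala", "ABalp", "Da"}
        a = sister_pair_bootstrap(defective, set(sub), n_iter=20_000, seed=9)
        b = sister_pair_bootstrap(defective, set(reversed(sub)), n_iter=20_000,
                                  seed=9)
        assert a.p_value == b.p_value
        assert a.exceedances == b.exceedances

    @pytest.mark.parametrize("x,y_pairs", [(2, 1), (3, 1), (4, 2), (5, 2)])
    def test_agrees_with_enumeration_on_small_subgroups(self, x, y_pairs):
        """Bootstrap within 3*sqrt(p(1-p)/n) of the exact full enumeration."""
        sub = [c for p in PAIRS for c in p] + ["Da", "Dp"]  # 8 cells, 3 pairs
        defective = set(sub[:x])
        res = sister_pair_bootstrap(defective, set(sub), n_iter=100_000, seed=17)
        exact = sister_pair_null_exact(x, sub, res.Y)
        tol = 3 * np.sqrt(exact * (1 - exact) / 100_000) + 1e-5
        assert abs(res.p_value - exact) <= tol

    def test_minimum_reportable_p_is_one_over_n(self):
        # draw 2 of many singletons plus one pair; observing the pair itself
        sub = {"ABala", "ABalp"} | {f"MSaaaa{c}" for c in "ap"} \
            | {"Ca", "Cp", "Da", "Dp", "Ea", "Ep"}
        res = sister_pair_bootstrap({"ABala", "ABalp"}, sub, n_iter=200, seed=2)
        assert res.p_value >= 1 / 200


class TestDefectTrios:
    def test_counts(self, template):
        tree = template.tree
        assert count_defect_trios(set(), tree) == 0
        trio = {"ABal", "ABala", "ABalp"}
        assert count_defect_trios(trio, tree) == 1
        assert count_defect_trios({"ABal", "ABala"}, tree) == 0
        # nested trios count per mother
        nested = {"ABa", "ABal", "ABar", "ABala", "ABalp"}
        assert count_defect_trios(nested, tree) == 2


class TestEnrichment:
    def test_gof_null_is_zero(self):
        chi2, p, _ = enrichment_gof(30, 100, 0.30)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_gof_scaling_property(self):
        c1, _, _ = enrichment_gof(33, 49, 0.30)
        c10, _, _ = enrichment_gof(330, 490, 0.30)
        assert c10 == pytest.approx(10 * c1)

    def test_gof_matches_scipy_chisquare(self):
        chi2, p, _ = enrichment_gof(33, 49, 0.30)
        ref = sps.chisquare([33, 16], [49 * 0.3, 49 * 0.7])
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_2x2_independence_gives_zero(self):
        chi2, p, _ = enrichment_2x2(10, 20, 30, 60)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_2x2_row_swap_symmetry(self):
        a = enrichment_2x2(495, 9141, 85, 26086)
        b = enrichment_2x2(85, 26086, 495, 9141)
        assert a[0] == pytest.approx(b[0])

    def test_2x2_matches_scipy_at_moderate_size(self):
        chi2, p, _ = enrichment_2x2(20, 80, 40, 60)
        ref = sps.chi2_contingency([[20, 80], [40, 60]], correction=False)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_2x2_approaches_gof_for_huge_reference_row(self):
        """With one row ~infinite the 2x2 test reduces to goodness-of-fit."""
        f = 0.30
        n_big = int(49 * 1e6)
        chi2_2x2, _, _ = enrichment_2x2(33, 16, int(n_big * f),
                                        int(n_big * (1 - f)))
        chi2_gof, _, _ = enrichment_gof(33, 49, f)
        assert chi2_2x2 == pytest.approx(chi2_gof, rel=1e-3)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            enrichment_2x2(0, 0, 5, 5)

    @given(st.floats(min_value=1.0, max_value=2000.0))
    @settings(max_examples=200, deadline=None)
    def test_log_tail_matches_high_precision_oracle(self, chi2):
        """log10 p agrees with an arbitrary-precision erfc oracle to 1%:
        the exact 1-df tail is erfc(sqrt(x/2))."""
        import mpmath
        oracle = float(mpmath.log(mpmath.erfc(mpmath.sqrt(chi2 / 2)), 10))
        ours = chi2_sf_log10(chi2)
        assert ours == pytest.approx(oracle, rel=0.01)

    def test_finite_far_below_underflow(self):
        lg = chi2_sf_log10(1500.0)
        assert np.isfinite(lg) and lg < -300


def _table(eid, cells_cats):
    return pd.DataFrame(
        [(eid, c, cat) for c, cat in cells_cats],
        columns=["embryo_id", "cell", "category"])


class TestPenetrance:
    def test_single_defect_single_embryo(self):
        s = penetrance_table([_table("e1", [("ABala", "position")])])
        row = s.per_cell.set_index("cell").loc["ABala"]
        assert row["penetrance"] == 1.0
        assert row["n_embryos_assayed"] == 1

    def test_at_least_k_monotone(self):
        tables = [_table(f"e{i}", [("ABala", "position")]) for i in range(4)]
        tables[0] = _table("e0", [("ABala", "position"), ("MSa", "cycle_late")])
        s = penetrance_table(tables)
        counts = [cells_defective_in_at_least(s, k) for k in range(1, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_group_membership_by_pattern(self):
        s = penetrance_table(
            [_table("e1", [("ABplpappa", "position"), ("MSpaapp", "position")])],
            groups={"ABpxp": "ABpxp"})
        per = s.per_cell.set_index("cell")
        assert bool(per.loc["ABplpappa", "in_ABpxp"]) is True
        assert bool(per.loc["MSpaapp", "in_ABpxp"]) is False
        emb = s.per_embryo.iloc[0]
        assert emb["defective_cells_in_ABpxp"] == 1

    def test_category_association_ratio(self):
        tables = [_table("e1", [("ABala", "position"), ("ABala", "cycle_late"),
                                ("ABalp", "cycle_late"), ("ABara", "position")])]
        out = category_association(tables, universe=["ABala", "ABalp", "ABara",
                                                     "ABarp", "MSa"])
        # P(pos | cycle) = 1/2, P(pos | no cycle) = 1/3
        assert out["risk_ratio"] == pytest.approx((1 / 2) / (1 / 3))
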