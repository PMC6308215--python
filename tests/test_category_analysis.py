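import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppbqsar.category_analysis import (
    CategoryStats,
    assign_categories,
    benjamini_hochberg,
    category_report,
    fisher_exact,
    flag_outliers,
    likelihood_ratio,
)
from ppbqsar.synthetic import SyntheticConfig, generate_dataset, simulate_predictions


def fisher_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration for the 2x2 table [[a,b],[c,d]]."""
    r1, r2 = a + b, c + d
    n = r1 + r2
    k = a + c  # first-column margin
    if n == 0 or r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    denom = math.comb(n, k)
    p_obs = math.comb(r1, a) * math.comb(r2, c) / denom
    total = 0.0
    for x in range(max(0, k - r2), min(r1, k) + 1):
        p = math.comb(r1, x) * math.comb(r2, k - x) / denom
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFlagOutliers:
    def test_all_equal_none_flagged(self):
        assert flag_outliers([1, 1, 1, 1]) == [False] * 4

    def test_single_spike(self):
        assert flag_outliers([0, 0, 0, 4]) == [False, False, False, True]

    def test_singleton(self):
        assert flag_outliers([2.0]) == [False]

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            flag_outliers([0.1, -0.2])


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact(1, 1, 2, 2) == pytest.approx(1.0)

    def test_hand_enumeration(self):
        # margins (4,4,4,4): p = 0.485714...
        assert fisher_exact(3, 1, 4, 4) == pytest.approx(0.4857142857142857, abs=1e-10)
        assert fisher_oracle(3, 1, 1, 3) == pytest.approx(0.4857142857142857, abs=1e-10)

    def test_empty_margin(self):
        assert fisher_exact(0, 0, 5, 5) == pytest.approx(1.0)

    def test_inconsistent_counts(self):
        with pytest.raises(ValueError):
            fisher_exact(3, 1, 2, 5)
        with pytest.raises(ValueError):
            fisher_exact(-1, 1, 2, 5)

    def test_oracle_spot_grid(self):
        for a, b, c, d in product(range(0, 7, 2), repeat=4):
            assert fisher_exact(a, c, a + b, c + d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9
            )


class TestLikelihoodRatio:
    def test_no_enrichment(self):
        assert likelihood_ratio(3, 3, 10, 10) == 1.0

    def test_hand_value(self):
        assert likelihood_ratio(6, 2, 10, 90) == pytest.approx(27.0)

    def test_zero_tp(self):
        assert likelihood_ratio(0, 5, 10, 90) == 0.0

    def test_undefined_signalled(self):
        assert likelihood_ratio(3, 0, 10, 90) == math.inf
        assert math.isnan(likelihood_ratio(0, 0, 0, 90))

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 6))
    @settings(derandomize=True, max_examples=60)
    def test_lr_is_one_when_rates_match(self, tp, fp, k):
        # category outlier rate equals the global rate (positives/negatives
        # scaled versions of tp/fp) -> LR = 1
        assert likelihood_ratio(tp, fp, tp * k, fp * k) == pytest.approx(1.0)


class TestAssignCategories:
    @pytest.mark.parametrize(
        "smiles,expected_in",
        [
            ("CCOC(C)=O", "aliphatic_ester"),
            ("Oc1ccccc1", "aromatic_hydroxyl"),
            ("CSC", "sulfide"),
            ("CCO", "primary_alcohol"),
            ("NC(=O)N", "urea_derivative"),
            ("O=C1CCN1", "beta_lactam"),
            ("C[N+](C)(C)C", "quaternary_N"),
        ],
    )
    def test_patterns(self, smiles, expected_in):
        assert expected_in in assign_categories(smiles)

    def test_plain_alkane_clean(self):
        assert assign_categories("CCCC") == set()


class TestCategoryReport:
    def test_planted_category_flagged(self):
        recs = generate_dataset(SyntheticConfig(n_compounds=500, seed=1))
        y = np.array([np.sqrt(r.fu) for r in recs])
        pred = simulate_predictions(
            recs, y, noise_sd=0.1, category_effects={"aliphatic_ester": 3.0}, seed=1
        )
        flags = flag_outliers(np.abs(y - pred))
        rep = category_report(recs, flags)
        row = next(
            s
            for s in rep
            if s.category == "aliphatic_ester" and s.direction == "badly_predicted"
        )
        assert row.p_value < 0.05 and row.lr > 1 and row.significant

    def test_universal_category_no_contrast(self):
        records = [{"x"} for _ in range(10)]
        flags = [True] * 3 + [False] * 7
        rep = category_report(records, flags)
        row = next(s for s in rep if s.direction == "badly_predicted")
        assert row.p_value == pytest.approx(1.0)

    def test_empty(self):
        assert category_report([], []) == []
        assert category_report([set(), set()], [True, False]) == []

    def test_order_invariant(self):
        records = [{"a"}, {"b"}, {"a", "b"}, set(), {"a"}]
        flags = [True, False, True, False, False]
        fwd = category_report(records, flags)
        rev = category_report(records[::-1], flags[::-1])
        assert [(s.category, s.direction, s.tp, s.p_value) for s in fwd] == [
            (s.category, s.direction, s.tp, s.p_value) for s in rev
        ]

    def test_both_directions_reported(self):
        records = [{"a"}, {"a"}, set(), set()]
        rep = category_report(records, [True, False, True, False])
        dirs = {s.direction for s in rep}
        assert dirs == {"badly_predicted", "well_predicted"}


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert all(a >= b for a, b in zip(adj, p))
    assert adj == sorted(adj)
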