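"""Threshold engine: the weight equation, alpha-budget conservation,
the NA fallback for non-enriched categories, and flat-vs-weighted counting."""

import numpy as np
import pandas as pd
import pytest

from annotawas.thresholds import (
    apply_thresholds,
    category_thresholds,
    category_weights,
    flat_bonferroni,
)
from tests.conftest import make_census


class TestFlatBonferroni:
    def test_genome_wide_threshold_rounds_to_8_5(self):
        _, neglog10 = flat_bonferroni(0.05, 16_503_508)
        assert neglog10 == pytest.approx(8.52, abs=0.005)
        assert round(neglog10, 1) == 8.5

    def test_single_test(self):
        p_bc, _ = flat_bonferroni(0.05, 1)
        assert p_bc == 0.05

    def test_doubling_T_adds_log10_2(self):
        _, a = flat_bonferroni(0.05, 1000)
        _, b = flat_bonferroni(0.05, 2000)
        assert b - a == pytest.approx(np.log10(2))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            flat_bonferroni(0.05, 0)
        with pytest.raises(ValueError):
            flat_bonferroni(1.5, 100)


class TestCategoryWeights:
    def test_identity_when_all_enrichments_one(self):
        census = make_census({"A": 30, "B": 70})
        w = category_weights(pd.Series({"A": 1.0, "B": 1.0}), census)
        assert w.tolist() == [1.0, 1.0]

    def test_hand_evaluated_example(self):
        # T=100, (T_A, e_A)=(10, 5), (T_B, e_B)=(90, 0.5): normalizer 0.95
        census = make_census({"A": 10, "B": 90})
        w = category_weights(pd.Series({"A": 5.0, "B": 0.5}), census)
        assert w["A"] == pytest.approx(5.0 / 0.95)
        assert w["B"] == pytest.approx(0.5 / 0.95)
        assert (census.counts * w).sum() == pytest.approx(100.0)

    def test_weight_sum_identity_on_random_cases(self, rng):
        for _ in range(1000):
            k = rng.integers(2, 9)
            counts = rng.integers(1, 10_000, size=k)
            e = rng.uniform(0, 50, size=k)
            if e.sum() == 0:
                continue
            census = make_census({f"c{i}": int(c) for i, c in enumerate(counts)})
            w = category_weights(pd.Series(e, index=census.counts.index), census)
            total = float((census.counts * w).sum())
            assert total == pytest.approx(census.T, rel=1e-9)

    def test_all_zero_enrichment_rejected(self):
        census = make_census({"A": 10, "B": 90})
        with pytest.raises(ValueError, match="zero"):
            category_weights(pd.Series({"A": 0.0, "B": 0.0}), census)

    def test_enriched_only_normalizer(self):
        census = make_census({"A": 10, "B": 90})
        w = category_weights(
            pd.Series({"A": 5.0, "B": 0.5}), census, normalizer="enriched-only"
        )
        # non-enriched B contributes unit mass: normalizer = (10·5 + 90·1)/100
        assert w["A"] == pytest.approx(5.0 / 1.4)


class TestCategoryThresholds:
    def test_proportionality_between_categories(self):
        census = make_census({"A": 100, "B": 400, "C": 9500})
        e = pd.Series({"A": 12.0, "B": 3.0, "C": 0.7})
        tt = category_thresholds(e, census, alpha=0.05)
        t = tt.table
        assert t.loc["A", "p_wt"] / t.loc["B", "p_wt"] == pytest.approx(4.0, rel=1e-12)

    def test_na_rule_keeps_flat_threshold(self):
        census = make_census({"A": 100, "B": 900})
        tt = category_thresholds(pd.Series({"A": 3.0, "B": 0.89}), census)
        assert bool(tt.table.loc["B", "na_flag"])
        assert tt.table.loc["B", "applied_threshold"] == tt.p_bc
        assert not bool(tt.table.loc["A", "na_flag"])

    def test_alpha_budget_identity_and_na_inflation(self):
        census = make_census({"A": 100, "B": 400, "C": 9500})
        e = pd.Series({"A": 12.0, "B": 3.0, "C": 0.7})
        tt = category_thresholds(e, census, alpha=0.05)
        budget = tt.budget()
        assert budget["weighted"] == pytest.approx(0.05, rel=1e-9)
        assert budget["applied"] >= 0.05

    def test_reduces_to_flat_when_unenriched(self):
        census = make_census({"A": 100, "B": 900})
        tt = category_thresholds(pd.Series({"A": 1.0, "B": 1.0}), census)
        # e == 1 is "no enrichment": every category keeps the flat threshold
        assert (tt.table["applied_threshold"] == tt.p_bc).all()

    def test_increasing_enrichment_never_lowers_weighted_count(self, rng):
        census = make_census({"A": 50, "B": 950})
        p = rng.uniform(1e-9, 1e-3, size=200)
        ids = [f"v{i}" for i in range(200)]
        results = pd.DataFrame(dict(id=ids, p=p))
        cats = pd.Series(["A"] * 100 + ["B"] * 100, index=ids)
        prev = -1
        for e_a in (1.5, 3.0, 6.0, 12.0):
            tt = category_thresholds(pd.Series({"A": e_a, "B": 1.0}), census)
            report, _ = apply_thresholds(results, cats, tt)
            count = int(report.set_index("category").loc["A", "n_sig_weighted"])
            assert count >= prev
            prev = count


class TestApplyThresholds:
    def test_all_weights_one_equal_counts(self, rng):
        census = make_census({"A": 100, "B": 900})
        tt = category_thresholds(pd.Series({"A": 1.0, "B": 1.0}), census)
        ids = [f"v{i}" for i in range(50)]
        results = pd.DataFrame(dict(id=ids, p=rng.uniform(size=50)))
        cats = pd.Series(["A", "B"] * 25, index=ids)
        report, newly = apply_thresholds(results, cats, tt)
        assert (report["n_sig_flat"] == report["n_sig_weighted"]).all()
        assert newly == []

    def test_enumerated_toy_counts(self):
        # 5 category-A variants at p = 1e-10; flat threshold 3e-11; w_A ≈ 10
        census = make_census({"A": 3, "B": 1_666_666_664})
        e = pd.Series({"A": 1e10 / 3.0, "B": 0.5})
        tt = category_thresholds(e, census, alpha=0.05)
        assert tt.p_bc == pytest.approx(3e-11, rel=1e-6)
        assert tt.table.loc["A", "applied_threshold"] > 1e-10
        ids = [f"a{i}" for i in range(5)]
        results = pd.DataFrame(dict(id=ids, p=[1e-10] * 5))
        cats = pd.Series(["A"] * 5, index=ids)
        report, newly = apply_thresholds(results, cats, tt)
        row = report.set_index("category").loc["A"]
        assert row["n_sig_flat"] == 0
        assert row["n_sig_weighted"] == 5
        assert len(newly) == 5

    def test_na_category_counts_equal_by_construction(self, rng):
        census = make_census({"A": 100, "B": 900})
        tt = category_thresholds(pd.Series({"A": 5.0, "B": 0.8}), census)
        ids = [f"v{i}" for i in range(100)]
        results = pd.DataFrame(dict(id=ids, p=rng.uniform(1e-8, 1e-2, size=100)))
        cats = pd.Series(["B"] * 100, index=ids)
        report, _ = apply_thresholds(results, cats, tt)
        row = report.set_index("category").loc["B"]
        assert row["n_sig_flat"] == row["n_sig_weighted"]

    def test_missing_assignment_rejected(self):
        census = make_census({"A": 10, "B": 90})
        tt = category_thresholds(pd.Series({"A": 2.0, "B": 0.9}), census)
        results = pd.DataFrame(dict(id=["v1", "v2"], p=[0.1, 0.2]))
        cats = pd.Series({"v1": "A"})
        with pytest.raises(ValueError, match="v2"):
            apply_thresholds(results, cats, tt)


class TestPrintedTableReproduction:
    """Recompute published per-category thresholds from published enrichments
    via the proportionality P_wt,A / P_wt,B = e_A / e_B, anchored on one
    printed threshold per table; agreement at printed 3-figure precision."""

    # (anchor enrichment, anchor threshold, target enrichment, printed target)
    CASES = [
        # four-category scheme
        (245.45, 3.84e-7, 4.40, 6.88e-9),
        # five-category scheme, anchored on the low-impact row
        (405.08, 4.82e-7, 4.92, 5.87e-9),
        (405.08, 4.82e-7, 5.04, 6.00e-9),
        (405.08, 4.82e-7, 2.49, 2.96e-9),
        # eight-category scheme, anchored on the high-impact row
        (33.69, 1.02e-7, 17.16, 5.20e-8),
        (33.69, 1.02e-7, 7.30, 2.21e-8),
        (33.69, 1.02e-7, 16.64, 5.04e-8),
        (33.69, 1.02e-7, 3.59, 1.09e-8),
        (33.69, 1.02e-7, 2.53, 7.65e-9),
        (33.69, 1.02e-7, 22.70, 6.88e-8),
    ]

    @pytest.mark.parametrize("e_anchor, p_anchor, e_target, p_expected", CASES)
    def test_threshold_cells(self, e_anchor, p_anchor, e_target, p_expected):
        census = make_census({"anchor": 500, "target": 500})
        tt = category_thresholds(
            pd.Series({"anchor": e_anchor, "target": e_target}), census
        )
        ratio = tt.table.loc["target", "p_wt"] / tt.table.loc["anchor", "p_wt"]
        recomputed = p_anchor * ratio
        assert recomputed == pytest.approx(p_expected, rel=5e-3)
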