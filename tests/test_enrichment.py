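"""Enrichment estimator: EM fixed points, likelihood monotonicity,
grid-search oracle equivalence, bootstrap CIs, and parameter recovery on
synthetic QTL."""

import numpy as np
import pandas as pd
import pytest

from annotawas.annotation import CategoryCensus, CategoryScheme
from annotawas.enrichment import (
    bootstrap_enrichment,
    em_enrichment,
    estimate_enrichment,
    qtl_category_counts,
)
from tests.conftest import make_census


def grid_search_2cat(counts, f, n_points=2001, n_zoom=4):
    """Independent oracle: maximize Σ_q log(n_qA·λ_A + n_qB·λ_B) over the
    1-D constrained family λ_B = (1 − λ_A f_A)/f_B by iteratively zoomed
    grid search (final resolution < 1e-6)."""
    counts = np.asarray(counts, dtype=float)
    lo, hi = 0.0, 1.0 / f[0]
    for _ in range(n_zoom):
        lam_a = np.linspace(lo, hi, n_points)
        lam_b = (1.0 - lam_a * f[0]) / f[1]
        vals = counts[:, 0][:, None] * lam_a[None, :] + counts[:, 1][:, None] * lam_b[None, :]
        with np.errstate(divide="ignore"):
            ll = np.where(vals > 0, np.log(vals), -np.inf).sum(axis=0)
        best = int(np.argmax(ll))
        step = (hi - lo) / (n_points - 1)
        lo, hi = max(0.0, lam_a[best] - step), min(1.0 / f[0], lam_a[best] + step)
    return 0.5 * (lo + hi)


def random_problem(rng):
    f_a = rng.uniform(0.05, 0.5)
    f = np.array([f_a, 1 - f_a])
    Q = rng.integers(5, 50)
    true_lam_a = rng.uniform(0.0, 0.8) / f_a
    pi_a = true_lam_a * f_a
    rows = []
    for _ in range(Q):
        s = rng.integers(1, 15)
        causal = rng.random() < pi_a
        n = np.zeros(2, dtype=int)
        n[0 if causal else 1] += 1
        bg = rng.random(s - 1) < f_a
        n[0] += bg.sum()
        n[1] += (s - 1) - bg.sum()
        rows.append(n)
    return np.array(rows), f


class TestEmFixedPoints:
    def test_forced_responsibilities(self):
        # QTL1 all A (3), QTL2 all B (5); f_A = 0.1 → π = (½, ½), e = π/f
        _, lam = em_enrichment(np.array([[3, 0], [0, 5]]), np.array([0.1, 0.9]))
        assert lam[0] == pytest.approx(0.5 / 0.1)
        assert lam[1] == pytest.approx(0.5 / 0.9)

    def test_analytic_two_qtl_fixed_point(self):
        # QTL1 = {1 A, 1 B}, QTL2 = {1 B}; f = (0.1, 0.9).
        # Fixed point: r satisfies 8r = 7 → π_A = 7/16, e_A = 4.375
        _, lam = em_enrichment(np.array([[1, 1], [0, 1]]), np.array([0.1, 0.9]))
        assert lam[0] == pytest.approx(4.375, abs=1e-6)
        assert lam[1] == pytest.approx(0.625, abs=1e-6)

    def test_null_self_consistency(self):
        # candidate composition equal to genomic frequencies → λ = 1
        counts = np.array([[1, 9], [2, 18], [3, 27]])
        _, lam = em_enrichment(counts, np.array([0.1, 0.9]))
        np.testing.assert_allclose(lam, 1.0, atol=1e-8)

    def test_absent_category_gets_zero(self):
        _, lam = em_enrichment(np.array([[0, 4], [0, 2]]), np.array([0.2, 0.8]))
        assert lam[0] == pytest.approx(0.0, abs=1e-7)

    def test_loglik_monotone_every_iteration(self, rng):
        for _ in range(20):
            counts, f = random_problem(rng)
            _, _, trace = em_enrichment(counts, f, return_trace=True)
            assert np.all(np.diff(trace) >= -1e-10)

    def test_constraint_holds_at_convergence(self, rng):
        for _ in range(20):
            counts, f = random_problem(rng)
            pi, lam = em_enrichment(counts, f)
            assert (lam * f).sum() == pytest.approx(1.0, abs=1e-9)
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_qtl_list_rejected(self):
        with pytest.raises(ValueError):
            em_enrichment(np.empty((0, 2)), np.array([0.5, 0.5]))

    def test_candidates_in_zero_frequency_category_rejected(self):
        with pytest.raises(ValueError, match="zero genomic frequency"):
            em_enrichment(np.array([[1, 1]]), np.array([0.0, 1.0]))


class TestGridOracle:
    def test_em_matches_grid_search(self, rng):
        for _ in range(30):
            counts, f = random_problem(rng)
            _, lam = em_enrichment(counts, f)
            oracle = grid_search_2cat(counts, f)
            assert lam[0] == pytest.approx(oracle, abs=1e-4)


class TestEstimateEnrichment:
    def test_dataframe_interface(self):
        census = make_census({"A": 100, "B": 900})
        counts = pd.DataFrame({"A": [3, 0], "B": [0, 5]}, index=["q1", "q2"])
        est = estimate_enrichment(counts, census)
        assert est.loc["A", "enrichment"] == pytest.approx(5.0)
        assert est.loc["A", "n_candidates"] == 3
        assert est["pi"].sum() == pytest.approx(1.0)

    def test_counts_builder_from_signals(self):
        from annotawas.qtl import QTLSignal

        sig = QTLSignal(lead_id="L", chrom="1", pos=1, round=1, lead_neglog10p=10.0,
                        candidates=["L", "x", "y"])
        cats = {"L": "A", "x": "A", "y": "B"}
        counts = qtl_category_counts([sig], cats, CategoryScheme("AB", ("A", "B")))
        assert counts.iloc[0].tolist() == [2, 1]


class TestBootstrap:
    def test_single_qtl_degenerate(self):
        census = make_census({"A": 10, "B": 90})
        counts = pd.DataFrame({"A": [2], "B": [3]})
        table, reps = bootstrap_enrichment(counts, census, n_boot=10, seed=1)
        assert table["boot_se"].max() == pytest.approx(0.0, abs=1e-12)
        assert (table["ci_high"] - table["ci_low"]).max() == pytest.approx(0.0, abs=1e-10)

    def test_seed_determinism(self):
        census = make_census({"A": 10, "B": 90})
        counts = pd.DataFrame({"A": [2, 0, 1], "B": [3, 4, 0]})
        t1, r1 = bootstrap_enrichment(counts, census, n_boot=25, seed=7)
        t2, r2 = bootstrap_enrichment(counts, census, n_boot=25, seed=7)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(r1, r2)

    def test_normal_ci_can_go_negative(self):
        # symmetric normal-approximation interval around a near-zero estimate
        census = make_census({"A": 10, "B": 90})
        counts = pd.DataFrame({"A": [1, 0, 0, 0], "B": [4, 5, 3, 6]})
        table, _ = bootstrap_enrichment(counts, census, n_boot=50, seed=3)
        assert table.loc["A", "ci_low"] < table.loc["A", "enrichment"]

    def test_percentile_option(self):
        census = make_census({"A": 10, "B": 90})
        counts = pd.DataFrame({"A": [2, 0, 1], "B": [3, 4, 1]})
        table, reps = bootstrap_enrichment(counts, census, n_boot=40, seed=9, ci="percentile")
        assert (table["ci_low"] >= 0).all()

    def test_too_few_resamples_rejected(self):
        census = make_census({"A": 10, "B": 90})
        with pytest.raises(ValueError):
            bootstrap_enrichment(pd.DataFrame({"A": [1], "B": [1]}), census, n_boot=1)

    def test_ci_covers_true_enrichment(self):
        # 100 QTL with true 10× per-variant rate for a 1%-frequency category.
        # (With far fewer QTL the estimate can collapse to the zero boundary,
        # where the symmetric normal-approximation interval under-covers.)
        f = np.array([0.01, 0.99])
        true_lam = np.array([10.0, 0.9 / 0.99])
        pi_true = true_lam * f
        census = make_census({"A": 100, "B": 9900})
        covered = 0
        n_meta = 40
        for seed in range(n_meta):
            rng = np.random.default_rng(seed)
            rows = []
            for _ in range(100):
                s = rng.integers(1, 21)
                causal = rng.choice(2, p=pi_true)
                n = np.zeros(2, dtype=int)
                n[causal] += 1
                bg = rng.random(s - 1) < f[0]
                n[0] += bg.sum()
                n[1] += (s - 1) - bg.sum()
                rows.append(n)
            counts = pd.DataFrame(np.array(rows), columns=["A", "B"])
            table, _ = bootstrap_enrichment(counts, census, n_boot=60, seed=seed)
            if table.loc["A", "ci_low"] <= 10.0 <= table.loc["A", "ci_high"]:
                covered += 1
        assert covered >= 0.9 * n_meta


class TestParameterRecovery:
    def test_median_recovery_of_tenfold_enrichment(self):
        f = np.array([0.01, 0.99])
        pi_true = np.array([0.1, 0.9])  # λ = (10, 10/11·...)
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rows = []
            for _ in range(200):
                s = rng.integers(1, 21)
                causal = rng.choice(2, p=pi_true)
                n = np.zeros(2, dtype=int)
                n[causal] += 1
                bg = rng.random(s - 1) < f[0]
                n[0] += bg.sum()
                n[1] += (s - 1) - bg.sum()
                rows.append(n)
            _, lam = em_enrichment(np.array(rows), f)
            estimates.append(lam[0])
        assert abs(np.median(estimates) - 10.0) <= 3.0

    def test_null_calibration(self):
        # causal categories drawn at genomic frequencies → e ≈ 1
        f = np.array([0.3, 0.7])
        meds = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            rows = []
            for _ in range(200):
                s = rng.integers(1, 21)
                n = np.bincount((rng.random(s) < f[0]).astype(int), minlength=2)[::-1]
                if n.sum() == 0:
                    n[1] = 1
                rows.append(n)
            _, lam = em_enrichment(np.array(rows), f)
            meds.append(lam)
        med = np.median(np.array(meds), axis=0)
        assert np.all(med >= 0.8) and np.all(med <= 1.25)
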