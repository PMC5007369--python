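"""Spot statistics, Welch test, BH correction, selection and Venn classes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from snoquant.diffstats import (
    DifferentialModel,
    bh_adjust,
    select_spots,
    spot_stats,
    venn_classify,
    welch_t,
)
from snoquant.errors import ValidationError
from snoquant.normalize import normalize_gelset
from snoquant.simulate import SyntheticConfig, simulate_gelset


class TestSpotStats:
    def test_constant_input(self):
        assert spot_stats([3, 3, 3]) == pytest.approx((3.0, 0.0, 0.0))

    def test_hand_computation(self):
        assert spot_stats([1, 2, 3]) == pytest.approx((2.0, 1.0, 0.5))

    def test_requires_two_values(self):
        with pytest.raises(ValidationError):
            spot_stats([1.0])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert t == 0.0 and p == 1.0

    def test_against_direct_formula(self):
        a = np.array([10.0, 11.0, 12.0])
        b = np.array([20.0, 22.0, 24.0])
        t, df, p = welch_t(a, b)
        # independent textbook evaluation
        se2 = a.var(ddof=1) / 3 + b.var(ddof=1) / 3
        t_ref = (a.mean() - b.mean()) / np.sqrt(se2)
        df_ref = se2**2 / (
            (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2
        )
        p_ref = 2 * sps.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert df == pytest.approx(df_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_against_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 12))
            b = rng.normal(0.5, 2, rng.integers(3, 12))
            t, df, p = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert df == pytest.approx(ref.df, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_equal_variances_match_student(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 1, 8)
        b = a + 2.0  # identical sample variance, shifted mean
        _, df, p = welch_t(a, b)
        student = sps.ttest_ind(a, b, equal_var=True)
        assert df == pytest.approx(14.0)
        assert p == pytest.approx(student.pvalue, abs=1e-10)

    def test_zero_variance_conventions(self):
        t, _, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        with pytest.warns(UserWarning):
            _, _, p = welch_t([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0

    def test_requires_two_per_group(self):
        with pytest.raises(ValidationError):
            welch_t([1.0], [1.0, 2.0])


def bh_oracle(p):
    """Brute-force step-up: q_(i) = min over j >= i of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_order_equivariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.001, 1, 25)
        q = bh_adjust(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p[perm]), q[perm])

    def test_matches_brute_force_oracle_on_grid_vectors(self):
        rng = np.random.default_rng(8)
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
        for _ in range(300):
            n = rng.integers(1, 7)
            p = rng.choice(grid, size=n)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.0, 0.5])


class TestSelection:
    def frame(self):
        rng = np.random.default_rng(9)
        return pd.DataFrame(
            {
                "fold": np.r_[rng.uniform(-4, 4, 50), 1.49, -1.88],
                "p": np.r_[rng.uniform(0.0001, 1, 50), 0.001, 0.01],
                "q": np.r_[rng.uniform(0.0001, 1, 50), 0.001, 0.01],
            },
            index=[f"s{i}" for i in range(52)],
        )

    def test_threshold_boundary(self):
        stats = pd.DataFrame({"fold": [1.49, 1.5], "p": [0.001, 0.001], "q": [0.001, 0.001]})
        mask = select_spots(stats, 1.5, 0.05, use_adjusted=False)
        assert list(mask) == [False, True]

    def test_fold_down_included_with_direction(self):
        stats = pd.DataFrame({"fold": [-1.88], "p": [0.01], "q": [0.02]})
        assert select_spots(stats, 1.5, 0.05, use_adjusted=False).all()

    def test_monotone_in_alpha_and_threshold(self):
        stats = self.frame()
        base = select_spots(stats, 1.5, 0.05)
        stricter_alpha = select_spots(stats, 1.5, 0.01)
        stricter_fold = select_spots(stats, 2.0, 0.05)
        assert not (stricter_alpha & ~base).any()
        assert not (stricter_fold & ~base).any()


class TestVenn:
    def test_basic_partition(self):
        assert venn_classify({1, 2}, {2, 3}) == {
            "both": 1, "abundance_only": 1, "sno_only": 1,
        }

    def test_identical_sets(self):
        assert venn_classify({1, 2, 3}, {1, 2, 3}) == {
            "both": 3, "abundance_only": 0, "sno_only": 0,
        }

    def test_planted_categories_recovered(self):
        # plant 10 abundance-only, 5 both, 7 S-NO-only at large effects
        ab = tuple(range(15))          # 0-9 abundance only, 10-14 both
        sno = tuple(range(10, 22))     # 10-14 both, 15-21 S-NO only
        cfg = SyntheticConfig(
            n_subjects_per_group=30, n_spots=120,
            abundance_effect_fold=3.0, sno_quench_effect=0.4,
            abundance_spots=ab, sno_spots=sno, seed=17,
        )
        gs, truth = simulate_gelset(cfg)
        res = DifferentialModel(gs, preset="discovery").fit()
        table = res.table.set_index("spot_id")
        expected = {}
        for i in range(22):
            sid = f"s{i + 1:04d}"
            if i < 10:
                expected[sid] = "abundance_only"
            elif i < 15:
                expected[sid] = "both"
            else:
                expected[sid] = "sno_only"
        hits = sum(
            table.loc[sid, "venn_category"] == cat for sid, cat in expected.items()
        )
        assert hits / len(expected) >= 0.9
        # unaffected spots stay out of the selection almost entirely
        unaffected = table.drop(index=list(expected))
        assert (unaffected["venn_category"] == "neither").mean() >= 0.95


class TestNullBehaviour:
    def test_null_pvalues_uniform(self):
        cfg = SyntheticConfig(
            n_subjects_per_group=30, n_spots=500,
            frac_abundance_diff=0.0, frac_sno_diff=0.0, seed=23,
        )
        gs, _ = simulate_gelset(cfg)
        res = DifferentialModel(gs).fit()
        p = res.table["p_abundance"].dropna()
        assert sps.kstest(p, "uniform").pvalue > 0.01
        assert res.table["significant_abundance"].sum() == 0


class TestModelSurface:
    def test_summary_mentions_counts(self):
        gs, _ = simulate_gelset(SyntheticConfig(n_subjects_per_group=5, n_spots=40, seed=2))
        res = DifferentialModel(gs).fit()
        text = res.summary()
        assert "differentially abundant" in text and "venn" in text

    def test_unknown_preset_rejected(self):
        gs, _ = simulate_gelset(SyntheticConfig(n_subjects_per_group=2, n_spots=10, seed=2))
        with pytest.raises(ValidationError):
            DifferentialModel(gs, preset="nope")

    def test_normalizes_lazily(self):
        gs, _ = simulate_gelset(SyntheticConfig(n_subjects_per_group=4, n_spots=30, seed=3))
        res_raw = DifferentialModel(gs).fit()
        res_pre = DifferentialModel(normalize_gelset(gs)).fit()
        pd.testing.assert_frame_equal(res_raw.table, res_pre.table)
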