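import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tastekit import stats as st
from tastekit import synthetic as syn


# ---------------------------------------------------------------------------
# Independent brute-force oracle: sums of squares via least-squares fits of
# nested dummy-coded linear models (balanced designs, so the decomposition
# is unambiguous).
# ---------------------------------------------------------------------------


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(labels):
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    return np.column_stack([(labels == l).astype(float) for l in levels])


def oracle_oneway_rm(y):
    n, a = y.shape
    subj = np.repeat(np.arange(n), a)
    lvl = np.tile(np.arange(a), n)
    yy = y.ravel()
    one = np.ones((n * a, 1))
    X_s = np.column_stack([one, _dummies(subj)])
    X_l = np.column_stack([one, _dummies(lvl)])
    X_full = np.column_stack([one, _dummies(subj), _dummies(lvl)])
    return {
        "within": _rss(X_s, yy) - _rss(X_full, yy),
        "subject": _rss(X_l, yy) - _rss(X_full, yy),
        "error": _rss(X_full, yy),
    }


def oracle_mixed_rm(data):
    groups = list(data)
    g = len(groups)
    n, a = data[groups[0]].shape
    rows_y, rows_grp, rows_subj, rows_lvl = [], [], [], []
    for gi, key in enumerate(groups):
        for si in range(n):
            for li in range(a):
                rows_y.append(data[key][si, li])
                rows_grp.append(gi)
                rows_subj.append(gi * n + si)
                rows_lvl.append(li)
    y = np.asarray(rows_y, float)
    one = np.ones((len(y), 1))
    G, S, L = _dummies(rows_grp), _dummies(rows_subj), _dummies(rows_lvl)
    GL = np.column_stack(
        [G[:, i] * L[:, j] for i in range(G.shape[1]) for j in range(L.shape[1])]
    )
    X0 = one
    X_g = np.column_stack([one, G])
    X_s = np.column_stack([one, S])
    X_sl = np.column_stack([one, S, L])
    X_full = np.column_stack([one, S, L, GL])
    return {
        "between": _rss(X0, y) - _rss(X_g, y),
        "subject(between)": _rss(X_g, y) - _rss(X_s, y),
        "within": _rss(X_s, y) - _rss(X_sl, y),
        "interaction": _rss(X_sl, y) - _rss(X_full, y),
        "error": _rss(X_full, y),
    }


class TestOnewayRmAnova:
    def test_all_identical_guarded(self):
        table = st.oneway_rm_anova(np.full((4, 3), 2.0))
        assert table.F("within") == 0.0
        assert table.p("within") == 1.0

    def test_two_levels_equals_paired_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(8, 2))
        table = st.oneway_rm_anova(y)
        t, p = sps.ttest_rel(y[:, 0], y[:, 1])
        assert table.F("within") == pytest.approx(t**2, rel=1e-10)
        assert table.p("within") == pytest.approx(p, rel=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, a = rng.integers(3, 8), rng.integers(2, 6)
        y = rng.normal(size=(n, a)) + rng.normal(size=(n, 1)) + rng.normal(size=(1, a))
        table = st.oneway_rm_anova(y)
        expected = oracle_oneway_rm(y)
        for effect, ss in expected.items():
            assert table.effect(effect)["ss"] == pytest.approx(ss, rel=1e-9)

    def test_ss_conservation_and_df_bookkeeping(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(6, 4))
        table = st.oneway_rm_anova(y)
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert table.table["ss"].sum() == pytest.approx(ss_total, rel=1e-9)
        assert table.table["df"].sum() == y.size - 1

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(5, 4))
        perm = rng.permutation(4)
        a = st.oneway_rm_anova(y)
        b = st.oneway_rm_anova(y[:, perm])
        assert a.F("within") == pytest.approx(b.F("within"), rel=1e-12)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            st.oneway_rm_anova(np.ones((1, 3)))

    def test_nan_rejected(self):
        y = np.ones((4, 3))
        y[0, 0] = np.nan
        with pytest.raises(ValueError, match="incomplete"):
            st.oneway_rm_anova(y)


class TestMixedRmAnova:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g, n, a = 2 + seed % 2, rng.integers(3, 7), rng.integers(2, 5)
        data = {f"grp{j}": rng.normal(size=(n, a)) + j * rng.normal() for j in range(g)}
        table = st.mixed_rm_anova(data)
        expected = oracle_mixed_rm(data)
        for effect, ss in expected.items():
            assert table.effect(effect)["ss"] == pytest.approx(ss, rel=1e-9, abs=1e-12)

    def test_ss_conservation(self):
        rng = np.random.default_rng(5)
        data = {"a": rng.normal(size=(6, 3)), "b": rng.normal(size=(6, 3))}
        table = st.mixed_rm_anova(data)
        y = np.concatenate([data["a"].ravel(), data["b"].ravel()])
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert table.table["ss"].sum() == pytest.approx(ss_total, rel=1e-9)
        assert table.table["df"].sum() == y.size - 1

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError, match="nbalanced"):
            st.mixed_rm_anova({"a": np.ones((4, 3)), "b": np.ones((5, 3))})

    def test_long_format_front_end(self):
        rng = np.random.default_rng(6)
        rows = []
        for state in ("fed", "starved"):
            for g in range(4):
                for dose in (0.0, 1.0, 5.0):
                    rows.append({
                        "group_id": f"{state}{g}", "state": state, "dose": dose,
                        "percent_per": rng.uniform(0, 100),
                    })
        df = pd.DataFrame(rows)
        table = st.rm_anova(df, dv="percent_per", within="dose",
                            subject="group_id", between="state")
        wide = df.pivot_table(index="group_id", columns="dose", values="percent_per")
        grp = df.groupby("group_id")["state"].first()
        data = {s: wide.loc[grp[grp == s].index].to_numpy() for s in ("fed", "starved")}
        direct = st.mixed_rm_anova(data)
        for effect in ("between", "within", "interaction"):
            assert table.F(effect) == pytest.approx(direct.F(effect), rel=1e-12)

    def test_incomplete_long_format_rejected(self):
        df = pd.DataFrame({
            "group_id": ["g0", "g0", "g1"], "state": ["a", "a", "b"],
            "dose": [0.0, 1.0, 0.0], "percent_per": [1.0, 2.0, 3.0],
        })
        with pytest.raises(ValueError, match="incomplete"):
            st.rm_anova(df, dv="percent_per", within="dose",
                        subject="group_id", between="state")

    def test_arcsine_transform_option(self):
        rng = np.random.default_rng(7)
        data = {"a": rng.uniform(0, 100, (5, 3)), "b": rng.uniform(0, 100, (5, 3))}
        plain = st.mixed_rm_anova(data)
        trans = st.mixed_rm_anova(data, transform="arcsine")
        assert plain.F("within") != pytest.approx(trans.F("within"))


class TestBonferroni:
    def test_scaling(self):
        assert st.bonferroni([0.01], m=5) == [0.05]

    def test_capping(self):
        assert st.bonferroni([0.5], m=5) == [1.0]

    def test_identity_at_m1(self):
        assert st.bonferroni([0.3]) == [0.3]

    def test_m_smaller_than_family_rejected(self):
        with pytest.raises(ValueError):
            st.bonferroni([0.1, 0.2], m=1)

    def test_posttests_adjusted_geq_raw(self):
        rng = np.random.default_rng(8)
        data = {"a": rng.normal(size=(5, 3)), "b": rng.normal(size=(5, 3))}
        for r in st.bonferroni_posttests(data):
            assert r.adjusted_p >= r.raw_p
            assert r.adjusted_p <= 1.0


class TestDunnett:
    def test_single_comparison_reduces_to_paired_t(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(10, 2))
        res = st.dunnett(y, control=0, n_mc=100_000, seed=0)
        assert len(res) == 1
        # with a=2 the RM error MS equals the paired-difference variance / 2,
        # so the comparison t is the paired t and adjusted p ~ its p
        t, p = sps.ttest_rel(y[:, 1], y[:, 0])
        assert res[0].statistic == pytest.approx(t, rel=1e-9)
        assert res[0].adjusted_p == pytest.approx(p, abs=0.005)

    def test_adjusted_p_monotone_in_k(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(8, 2))
        ps = []
        for extra in range(3):
            y = np.column_stack([base] + [base[:, [1]] + rng.normal(0, 1, (8, 1))
                                          for _ in range(extra)])
            res = st.dunnett(y, control=0, n_mc=50_000, seed=1)
            ps.append(res[0].adjusted_p)
        # same first comparison, larger family -> adjusted p non-decreasing
        # (up to Monte-Carlo jitter on the same seed)
        assert ps[0] <= ps[1] + 0.01 <= ps[2] + 0.02

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(6, 4))
        for r in st.dunnett(y, seed=2):
            assert r.adjusted_p >= r.raw_p

    def test_labels(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(5, 3))
        res = st.dunnett(y, control=0, labels=["0%", "1%", "5%"], n_mc=1000, seed=0)
        assert [r.comparison for r in res] == ["1% vs 0%", "5% vs 0%"]


class TestPowerAudit:
    def test_zero_effect_rate_near_alpha(self):
        params = syn.null_behavior_params(n_groups=4)
        rate = st.power_audit(params, effect="interaction", n_sims=200, seed=3)
        sd = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) <= 3 * sd + 0.01

    def test_crossover_effect_detected(self):
        params = syn.default_behavior_params(n_groups=4)
        rate = st.power_audit(params, effect="interaction", n_sims=100, seed=4)
        assert rate > 0.8

    def test_min_sims_enforced(self):
        with pytest.raises(ValueError):
            st.power_audit(syn.null_behavior_params(), n_sims=10)
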