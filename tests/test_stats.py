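"""RM ANOVA, post hocs and d-prime, against brute-force and library oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from hemiretina.stats import (
    RATE_CEIL,
    RATE_FLOOR,
    behavioural_analysis,
    bonferroni_posthoc,
    d_prime,
    rm_anova,
)


def oracle_rm_anova_ss(Y):
    """Independent sums-of-squares oracle for (n_subjects, l1, l2) tables.

    Explicit mean-decomposition loops: effect estimates by subtraction of
    marginal means, SS by direct summation.
    """
    n, l1, l2 = Y.shape
    grand = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)
    out = {}
    ss_a = ss_b = ss_ab = ss_as = ss_bs = ss_abs = 0.0
    for s in range(n):
        for i in range(l1):
            for j in range(l2):
                ss_a += (m_a[i] - grand) ** 2
                ss_b += (m_b[j] - grand) ** 2
                ss_ab += (m_ab[i, j] - m_a[i] - m_b[j] + grand) ** 2
                ss_as += (m_sa[s, i] - m_s[s] - m_a[i] + grand) ** 2
                ss_bs += (m_sb[s, j] - m_s[s] - m_b[j] + grand) ** 2
                ss_abs += (
                    Y[s, i, j] - m_sa[s, i] - m_sb[s, j] - m_ab[i, j]
                    + m_s[s] + m_a[i] + m_b[j] - grand
                ) ** 2
    out["A"] = (ss_a, ss_as, l1 - 1, (l1 - 1) * (n - 1))
    out["B"] = (ss_b, ss_bs, l2 - 1, (l2 - 1) * (n - 1))
    out["A * B"] = (ss_ab, ss_abs, (l1 - 1) * (l2 - 1), (l1 - 1) * (l2 - 1) * (n - 1))
    return out


def long_frame(Y, f1="A", f2="B"):
    n, l1, l2 = Y.shape
    rows = []
    for s, i, j in itertools.product(range(n), range(l1), range(l2)):
        rows.append({"subject": s, f1: f"a{i}", f2: f"b{j}", "y": Y[s, i, j]})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_df_for_36_subjects_3_levels(self, rng):
        rows = [
            {"subject": s, "sf": sf, "y": rng.normal()}
            for s in range(36)
            for sf in ("BSF", "LSF", "HSF")
        ]
        res = rm_anova(pd.DataFrame(rows), "y", "subject", ["sf"])
        assert (int(res.df1.iloc[0]), int(res.df2.iloc[0])) == (2, 70)

    def test_identical_levels_give_zero_f(self, rng):
        base = rng.normal(size=10)
        rows = [{"subject": s, "c": lvl, "y": base[s]} for s in range(10) for lvl in "xyz"]
        res = rm_anova(pd.DataFrame(rows), "y", "subject", ["c"])
        assert res.F.iloc[0] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            Y = rng.normal(size=(8, 2, 3))
            res = rm_anova(long_frame(Y), "y", "subject", ["A", "B"]).set_index("effect")
            for eff, (ss_e, ss_r, df1, df2) in oracle_rm_anova_ss(Y).items():
                row = res.loc[eff]
                F = (ss_e / df1) / (ss_r / df2)
                assert abs(row.F - F) < 1e-10
                assert (row.df1, row.df2) == (df1, df2)
                assert abs(row.eta_p2 - ss_e / (ss_e + ss_r)) < 1e-10
                assert abs(row.p - sstats.f.sf(F, df1, df2)) < 1e-10

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(12, 2, 3))
        df = long_frame(Y, "emotion", "sf")
        mine = rm_anova(df, "y", "subject", ["emotion", "sf"], correction=True).set_index("effect")
        ref = pg.rm_anova(data=df, dv="y", within=["emotion", "sf"], subject="subject").set_index("Source")
        for eff, src in (("emotion", "emotion"), ("sf", "sf"), ("emotion * sf", "emotion * sf")):
            assert mine.loc[eff, "F"] == pytest.approx(float(ref.loc[src, "F"]), abs=1e-8)
            assert mine.loc[eff, "p"] == pytest.approx(float(ref.loc[src, "p_unc"]), abs=1e-8)
            assert mine.loc[eff, "eps_gg"] == pytest.approx(float(ref.loc[src, "eps"]), abs=1e-6)

    def test_invariant_to_global_and_subject_constants(self, rng):
        Y = rng.normal(size=(9, 2, 3))
        shifted = Y + 3.7 + rng.normal(size=(9, 1, 1))
        a = rm_anova(long_frame(Y), "y", "subject", ["A", "B"])
        b = rm_anova(long_frame(shifted), "y", "subject", ["A", "B"])
        np.testing.assert_allclose(a.F.to_numpy(), b.F.to_numpy(), atol=1e-8)

    def test_eta_identity(self, rng):
        Y = rng.normal(size=(7, 2, 3))
        res = rm_anova(long_frame(Y), "y", "subject", ["A", "B"])
        for _, r in res.iterrows():
            assert r.eta_p2 == pytest.approx(r.F * r.df1 / (r.F * r.df1 + r.df2), abs=1e-12)
            assert 0.0 <= r.eta_p2 <= 1.0

    def test_unbalanced_rejected(self, rng):
        df = long_frame(rng.normal(size=(4, 2, 3))).iloc[:-1]
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(df, "y", "subject", ["A", "B"])


class TestPosthoc:
    def test_identical_vectors_flagged(self):
        x = np.arange(10.0)
        (res,) = bonferroni_posthoc({"same": (x, x.copy())})
        assert res.t == 0.0 and res.p_bonf == 1.0 and res.flag is not None

    def test_single_comparison_uncorrected(self, rng):
        x, y = rng.normal(size=(2, 15))
        (res,) = bonferroni_posthoc({"only": (x, y)})
        assert res.p_bonf == pytest.approx(res.p_raw)

    def test_constructed_t_value(self, rng):
        # diffs with mean 1, sd 1, n 16 -> t = mean / (sd/sqrt(n)) = 4
        d = rng.normal(size=16)
        d = (d - d.mean()) / d.std(ddof=1) + 1.0
        y = rng.normal(size=16)
        (res,) = bonferroni_posthoc({"c": (y + d, y)})
        assert res.t == pytest.approx(4.0, abs=1e-10)
        assert res.cohen_d == pytest.approx(1.0, abs=1e-10)

    def test_bonferroni_multiplies_and_caps(self, rng):
        pairs = {f"p{i}": (rng.normal(size=12), rng.normal(size=12)) for i in range(3)}
        for res in bonferroni_posthoc(pairs):
            assert res.p_bonf == pytest.approx(min(1.0, 3 * res.p_raw))
            assert res.p_bonf >= res.p_raw

    def test_dav_convention(self, rng):
        x, y = rng.normal(size=(2, 20))
        (dz,) = bonferroni_posthoc({"a": (x, y)}, d_convention="dz")
        (dav,) = bonferroni_posthoc({"a": (x, y)}, d_convention="dav")
        assert dav.cohen_d == pytest.approx(
            (x - y).mean() / ((x.std(ddof=1) + y.std(ddof=1)) / 2), abs=1e-12
        )
        assert dz.t == dav.t


class TestDPrime:
    def test_equal_rates_give_zero(self):
        assert d_prime(5, 10, 50, 100).d_prime == pytest.approx(0.0)

    def test_extreme_rates_substituted_and_finite(self):
        res = d_prime(10, 10, 0, 10)
        assert res.hit_rate == RATE_CEIL and res.fa_rate == RATE_FLOOR
        expected = sstats.norm.ppf(RATE_CEIL) - sstats.norm.ppf(RATE_FLOOR)
        assert np.isfinite(res.d_prime)
        assert res.d_prime == pytest.approx(expected, abs=1e-10)

    def test_antisymmetry(self):
        a = d_prime(8, 10, 2, 10).d_prime
        b = d_prime(2, 10, 8, 10).d_prime
        assert a == pytest.approx(-b, abs=1e-12)

    def test_monotonicity_over_rate_grid(self):
        grid = range(0, 21)
        for fa in (0, 5, 10):
            vals = [d_prime(h, 20, fa, 20).d_prime for h in grid]
            assert all(x < y for x, y in zip(vals, vals[1:]))
        for h in (5, 10, 15):
            vals = [d_prime(h, 20, fa, 20).d_prime for fa in grid]
            assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_zero_trials_rejected(self):
        with pytest.raises(ValueError):
            d_prime(0, 0, 0, 10)


class TestBehaviouralAnalysis:
    @staticmethod
    def _frame(rt_fn, hits_fn, rng):
        rows = []
        for s in range(12):
            for emo in ("neutral", "fear"):
                for sf in ("BSF", "LSF", "HSF"):
                    rows.append({
                        "subject": s, "emotion": emo, "sf": sf,
                        "n_signal": 20, "n_noise": 200,
                        "hits": hits_fn(s, emo, sf, rng),
                        "false_alarms": 1,
                        "mean_rt_s": rt_fn(s, emo, sf, rng),
                    })
        return pd.DataFrame(rows)

    def test_constant_rts_give_zero_f(self, rng):
        df = self._frame(lambda *a: 1.5, lambda s, e, sf, r: 18, rng)
        out = behavioural_analysis(df)
        assert (out["rt_anova"].F == 0.0).all()

    def test_additive_emotion_shift_kills_interaction(self, rng):
        # hits: subject base + emotion shift (same across SF) -> interaction F = 0
        base = {s: int(rng.integers(8, 13)) for s in range(12)}
        jitter = {(s, e): int(rng.integers(0, 3)) for s in range(12) for e in ("neutral", "fear")}
        hits = lambda s, e, sf, r: base[s] + (4 if e == "neutral" else 0) + jitter[(s, e)]
        df = self._frame(lambda *a: 1.5, hits, rng)
        out = behavioural_analysis(df)
        dp = out["dprime_anova"].set_index("effect")
        assert dp.loc["emotion * sf", "F"] == pytest.approx(0.0, abs=1e-18)
        assert (int(dp.loc["emotion", "df1"]), int(dp.loc["emotion", "df2"])) == (1, 11)

    def test_rt_emotion_effect_power(self, rng):
        """10 ms fear slowdown, 5 ms between-subject sd, n=36: detected in >=80% of reps."""
        detections = 0
        n_reps = 100
        for _ in range(n_reps):
            rows = []
            for s in range(36):
                base = rng.normal(1.46, 0.05)
                slow = rng.normal(0.010, 0.005)
                for emo in ("neutral", "fear"):
                    for sf in ("BSF", "LSF", "HSF"):
                        rows.append({
                            "subject": s, "emotion": emo, "sf": sf,
                            "n_signal": 20, "n_noise": 200, "hits": 18, "false_alarms": 1,
                            "mean_rt_s": base + (slow if emo == "fear" else 0) + rng.normal(0, 0.005),
                        })
            res = behavioural_analysis(pd.DataFrame(rows))["rt_anova"].set_index("effect")
            if res.loc["emotion", "p"] < 0.05:
                detections += 1
        assert detections / n_reps >= 0.8
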