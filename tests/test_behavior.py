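"""Split-plot ANOVA against independent oracles, Shaffer adjustment,
paired change summaries."""

import numpy as np
import pandas as pd
import pytest

from posturestats import (
    MixedAnova,
    gen_cop_session,
    ips_records,
    paired_change_summary,
    shaffer_adjust,
    simple_effects,
    split_plot_anova,
)
from posturestats.behavior import MissingDataError
from posturestats import SimConfig


def long_table(y_by_group):
    """Build a long table from {group: (n_subj x n_time) array}."""
    rows = []
    times = None
    for g, y in y_by_group.items():
        y = np.asarray(y, float)
        times = [f"T{t}" for t in range(y.shape[1])]
        for i, vals in enumerate(y):
            for t, v in zip(times, vals):
                rows.append((f"{g}{i}", g, t, v))
    return pd.DataFrame(rows, columns=["participant", "group", "time", "ips"])


def projection_oracle(data, dv="ips"):
    """Sequential (Type I) SS via explicit design-matrix projections:
    group | subject(group) | time | group:time | residual."""
    d = data.sort_values(["participant", "time"]).reset_index(drop=True)
    subs = pd.Categorical(d["participant"])
    grps = pd.Categorical(d["group"])
    tims = pd.Categorical(d["time"])
    y = d[dv].to_numpy(float)
    n = len(y)

    def dummies(cat):
        return pd.get_dummies(cat).to_numpy(float)

    blocks = {
        "intercept": np.ones((n, 1)),
        "group": dummies(grps),
        "subject": dummies(subs),
        "time": dummies(tims),
        "interaction": dummies(
            pd.Categorical(d["group"].astype(str) + ":" + d["time"].astype(str))
        ),
    }

    def rss(cols):
        X = np.hstack(cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    seq = ["intercept", "group", "subject", "time", "interaction"]
    rss_prev = rss([blocks["intercept"]])
    ss = {}
    cols = [blocks["intercept"]]
    for name in seq[1:]:
        cols.append(blocks[name])
        rss_cur = rss(cols)
        ss[name] = rss_prev - rss_cur
        rss_prev = rss_cur
    ss["residual"] = rss_prev

    g = len(grps.categories)
    k = len(tims.categories)
    n_sub = len(subs.categories)
    df = {
        "group": g - 1,
        "subject": n_sub - g,
        "time": k - 1,
        "interaction": (g - 1) * (k - 1),
        "residual": (n_sub - g) * (k - 1),
    }
    out = {}
    for eff, err in (("group", "subject"), ("time", "residual"), ("interaction", "residual")):
        F = (ss[eff] / df[eff]) / (ss[err] / df[err])
        ges = ss[eff] / (ss[eff] + ss["subject"] + ss["residual"])
        out[eff] = {"SS": ss[eff], "df1": df[eff], "df2": df[err], "F": F, "ges": ges}
    out["ss_total"] = sum(ss.values())
    return out


class TestSplitPlotAnova:
    def test_matches_projection_oracle_on_integer_fixture(self):
        y = {
            "A": [[3, 5, 4], [1, 2, 2], [4, 6, 7], [2, 3, 3]],
            "B": [[5, 4, 3], [6, 6, 5], [4, 3, 4], [7, 5, 6]],
        }
        data = long_table(y)
        mine = split_plot_anova(data).set_index("effect")
        oracle = projection_oracle(data)
        for eff, key in (("group", "group"), ("time", "time"), ("group:time", "interaction")):
            assert mine.loc[eff, "SS"] == pytest.approx(oracle[key]["SS"], abs=1e-10)
            assert mine.loc[eff, "F"] == pytest.approx(oracle[key]["F"], abs=1e-10)
            assert mine.loc[eff, "df1"] == oracle[key]["df1"]
            assert mine.loc[eff, "df2"] == oracle[key]["df2"]
            assert mine.loc[eff, "gen_eta_sq"] == pytest.approx(
                oracle[key]["ges"], abs=1e-10
            )

    def test_matches_oracle_on_random_unbalanced_fixtures(self, rng):
        for _ in range(10):
            y = {
                "A": rng.integers(0, 20, size=(5, 3)),
                "B": rng.integers(0, 20, size=(7, 3)),
            }
            data = long_table(y)
            mine = split_plot_anova(data).set_index("effect")
            oracle = projection_oracle(data)
            for eff, key in (
                ("group", "group"),
                ("time", "time"),
                ("group:time", "interaction"),
            ):
                assert mine.loc[eff, "F"] == pytest.approx(oracle[key]["F"], abs=1e-10)
                assert mine.loc[eff, "gen_eta_sq"] == pytest.approx(
                    oracle[key]["ges"], abs=1e-10
                )

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = {"A": rng.normal(size=(8, 3)), "B": rng.normal(size=(6, 3))}
        data = long_table(y)
        mine = split_plot_anova(data).set_index("effect")
        ref = pg.mixed_anova(
            data, dv="ips", within="time", subject="participant", between="group",
            effsize="ng2",
        ).set_index("Source")
        for eff, src in (("group", "group"), ("time", "time"), ("group:time", "Interaction")):
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"], rel=1e-9)
            assert mine.loc[eff, "p"] == pytest.approx(ref.loc[src, "p_unc"], rel=1e-9)
            assert mine.loc[eff, "gen_eta_sq"] == pytest.approx(
                ref.loc[src, "ng2"], rel=1e-9
            )

    def test_sum_of_squares_conservation(self, rng):
        y = {"A": rng.normal(size=(6, 3)), "B": rng.normal(size=(9, 3))}
        data = long_table(y)
        res = split_plot_anova(data)
        total = ((data["ips"] - data["ips"].mean()) ** 2).sum()
        parts = (
            res["SS"].sum()
            + res.attrs["ss_subjects_within"]
            + res.attrs["ss_within_residual"]
        )
        assert parts == pytest.approx(total, abs=1e-9)

    def test_constant_data_degenerate(self):
        data = long_table({"A": np.ones((3, 3)), "B": np.ones((3, 3))})
        res = split_plot_anova(data).set_index("effect")
        assert np.isnan(res.loc["group:time", "F"]) or res.loc["group:time", "F"] == 0

    def test_epsilon_near_one_under_compound_symmetry(self, rng):
        eps = []
        for _ in range(50):
            subj = rng.normal(0, 1.0, size=(48, 1))
            y = subj + rng.normal(0, 1.0, size=(48, 3))
            data = long_table({"A": y[:24], "B": y[24:]})
            res = split_plot_anova(data)
            eps.append(res.set_index("effect").loc["time", "epsilon_gg"])
        assert np.mean(eps) == pytest.approx(1.0, abs=0.05)

    def test_interaction_invariant_to_constant_shift(self, rng):
        y = {"A": rng.normal(size=(5, 3)), "B": rng.normal(size=(5, 3))}
        a = split_plot_anova(long_table(y)).set_index("effect")
        y2 = {g: np.asarray(v) + 7.3 for g, v in y.items()}
        b = split_plot_anova(long_table(y2)).set_index("effect")
        assert a.loc["group:time", "F"] == pytest.approx(
            b.loc["group:time", "F"], rel=1e-9
        )

    def test_missing_cell_rejected(self):
        data = long_table({"A": np.ones((3, 3)), "B": np.ones((3, 3))})
        with pytest.raises(MissingDataError):
            split_plot_anova(data.drop(index=0))

    def test_type_one_error_near_nominal_under_null(self):
        # Null synthetic studies: the interaction should reject at ~alpha.
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            subj = rng.normal(0, 0.18, size=(48, 1))
            y = 1.7 + subj + rng.normal(0, 0.08, size=(48, 3))
            data = long_table({"A": y[:24], "B": y[24:]})
            res = split_plot_anova(data).set_index("effect")
            rejections += res.loc["group:time", "p"] < 0.05
        # 95% binomial interval around 0.05 with 200 replicates
        lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_rep), 0.05 + 1.96 * np.sqrt(
            0.05 * 0.95 / n_rep
        )
        assert lo <= rejections / n_rep <= hi


class TestShaffer:
    def test_hand_applied_multipliers(self):
        adj = shaffer_adjust([0.001, 0.01, 0.40])
        assert adj == pytest.approx([0.003, 0.01, 0.40])

    def test_running_max_enforcement(self):
        # ties: multipliers {3,1,1} give {1.0 (capped), 0.5, 0.5}; the
        # running max then lifts all to 1.0
        adj = shaffer_adjust([0.5, 0.5, 0.5])
        assert adj == pytest.approx([1.0, 1.0, 1.0])

    def test_zero_fixed_point(self):
        adj = shaffer_adjust([0.0, 0.2, 0.7])
        assert adj[0] == 0.0

    def test_adjusted_at_least_raw_and_order_preserved(self, rng):
        for _ in range(20):
            raw = rng.uniform(size=3)
            adj = shaffer_adjust(raw)
            assert (adj >= raw - 1e-15).all()
            order = np.argsort(raw)
            assert (np.diff(adj[order]) >= -1e-15).all()

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            shaffer_adjust([0.1, 0.2])
        with pytest.raises(ValueError):
            shaffer_adjust([0.1, 0.2, 1.7])


class TestPairedChange:
    def test_constant_difference_degenerate(self):
        res = paired_change_summary([1.0, 2.0, 3.0], [1.1, 2.1, 3.1])
        assert res.degenerate
        assert res.mean_change == pytest.approx(0.1)

    def test_symmetric_differences(self):
        res = paired_change_summary([0, 0, 0, 0], [1, -1, 1, -1])
        assert res.mean_change == 0.0
        assert res.dz == 0.0

    def test_arithmetic_oracle(self, rng):
        # n = 25 pairs with known change moments: dz must equal
        # mean(diff) / sd(diff) computed independently.
        a = rng.normal(1.7, 0.2, size=25)
        d = rng.normal(0.09, 0.214, size=25)
        res = paired_change_summary(a, a + d)
        assert res.dz == pytest.approx(d.mean() / d.std(ddof=1), abs=1e-12)
        assert res.mean_change == pytest.approx(d.mean(), abs=1e-12)
        # magnitude sanity: these moments put dz in the small-to-medium range
        assert 0.1 < abs(res.dz) < 1.0

    def test_d_av_uses_mean_of_raw_sds(self, rng):
        a = rng.normal(size=30)
        b = a + rng.normal(0.5, 0.3, size=30)
        res = paired_change_summary(a, b)
        expect = (b - a).mean() / ((a.std(ddof=1) + b.std(ddof=1)) / 2)
        assert res.d_av == pytest.approx(expect, abs=1e-12)

    def test_ci_against_scipy(self, rng):
        from scipy import stats

        a = rng.normal(size=12)
        b = a + rng.normal(0.2, 0.5, size=12)
        res = paired_change_summary(a, b)
        t, p = stats.ttest_rel(b, a)
        assert res.t == pytest.approx(t, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)
        lo, hi = stats.t.interval(
            0.95, 11, loc=(b - a).mean(), scale=stats.sem(b - a)
        )
        assert res.ci_low == pytest.approx(lo, abs=1e-9)
        assert res.ci_high == pytest.approx(hi, abs=1e-9)


class TestSimpleEffectsAndEstimator:
    def test_effect_recovery_on_synthetic_study(self):
        # Planted treated-arm improvement is recovered by the T1-T0
        # simple effect and the interaction is significant.
        cfg = SimConfig(seed=21)
        recs = ips_records(gen_cop_session(cfg))
        model = MixedAnova().fit(recs)
        assert model.interaction_significant_
        se = model.simple_effects_
        row = se[(se.group == "SDE") & (se.contrast == "T1-T0")].iloc[0]
        assert row["mean_change"] == pytest.approx(0.09, abs=0.05)
        assert row["adjusted_p"] < 0.05

    def test_gate_suppresses_simple_effects_under_null(self, rng):
        y = {"A": rng.normal(size=(10, 3)), "B": rng.normal(size=(10, 3))}
        data = long_table(y)
        model = MixedAnova().fit(data)
        if not model.interaction_significant_:
            assert model.simple_effects_ is None
        model2 = MixedAnova(simple_effects_gate=False).fit(data)
        assert model2.simple_effects_ is not None
        assert len(model2.simple_effects_) == 6  # 2 groups x 3 contrasts

    def test_get_set_params_roundtrip(self):
        m = MixedAnova()
        p = m.get_params()
        assert p["dv"] == "ips"
        m.set_params(alpha=0.01)
        assert m.alpha == 0.01
        with pytest.raises(ValueError):
            m.set_params(nope=1)
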