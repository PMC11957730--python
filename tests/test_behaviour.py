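import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpmvpa.behaviour import (
    UndefinedRateError,
    dprime,
    group_sdt,
    likert_summary,
    rates,
    rt_summary,
    sdt_summary,
)
from erpmvpa.io import RatingTable, TrialTable
from erpmvpa.simulate import GeneratorConfig, simulate_behaviour

LABELS = dict(
    condition_labels=("human", "android", "robot"),
    response_labels=("human", "nonhuman"),
)


def _table(rows):
    df = pd.DataFrame(rows, columns=["participant", "condition", "response", "rt"])
    return TrialTable(df, **LABELS)


def _mixed_table():
    rows = []
    # 10 human trials, 9 judged human
    for i in range(10):
        rows.append(["P01", "human", "human" if i < 9 else "nonhuman", 700])
    # 10 android + 10 robot trials, 2 judged human (one each)
    for cond in ("android", "robot"):
        for i in range(10):
            rows.append(["P01", cond, "human" if i < 1 else "nonhuman", 700])
    return _table(rows)


class TestRates:
    def test_human_condition_definitions(self):
        tt = _mixed_table()
        hit, fa = rates(tt, "human", "human")
        assert hit == pytest.approx(0.9)
        assert fa == pytest.approx(2 / 20)

    def test_nonhuman_condition_definitions(self):
        tt = _mixed_table()
        hit, fa = rates(tt, "robot", "human")
        assert hit == pytest.approx(0.9)  # robots judged non-human
        assert fa == pytest.approx(1 / 10)  # humans judged non-human

    def test_fa_rate_shared_across_nonhuman_conditions(self, tiny_cfg):
        tt = simulate_behaviour(tiny_cfg)
        _, fa_android = rates(tt, "android", "human")
        _, fa_robot = rates(tt, "robot", "human")
        assert fa_android == fa_robot

    def test_missing_cell_raises(self):
        tt = _table([["P01", "human", "human", 700]])
        with pytest.raises(UndefinedRateError):
            rates(tt, "human", "human")


class TestDprime:
    def test_perfect_performance_capped_at_5(self):
        assert dprime(1.0, 0.0) == 5.0

    def test_equal_rates_give_zero(self):
        assert dprime(0.3, 0.3) == 0.0
        assert dprime(1.0, 1.0) == 0.0

    def test_standard_normal_quantile_oracle(self):
        # probit(0.84134) ~ +1, probit(0.15866) ~ -1
        assert dprime(0.84134, 0.15866) == pytest.approx(2.0, abs=1e-3)

    def test_single_infinite_rate_capped(self):
        assert dprime(1.0, 0.3) == 5.0
        assert dprime(0.0, 0.3) == -5.0

    @given(
        h=st.floats(0.05, 0.95), f=st.floats(0.05, 0.95),
        delta=st.floats(0.001, 0.04),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_rates(self, h, f, delta):
        base = dprime(h, f)
        assert dprime(min(h + delta, 1.0), f) >= base
        assert dprime(h, min(f + delta, 1.0)) <= base

    @given(h=st.floats(0.0, 1.0), f=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_and_capped(self, h, f):
        d = dprime(h, f)
        assert abs(d) <= 5.0
        assert dprime(f, h) == pytest.approx(-d, abs=1e-12)


class TestRT:
    def test_geometric_mean_of_two_points(self):
        tt = _table([["P01", "human", "human", 100], ["P01", "human", "human", 10000]])
        out = rt_summary(tt)
        assert out.set_index("condition").loc["human", "rt_geomean"] == pytest.approx(1000.0)

    def test_constant_rts_identity(self):
        tt = _table([["P01", "human", "human", 700]] * 4)
        out = rt_summary(tt)
        assert out["rt_geomean"].iloc[0] == pytest.approx(700.0)

    def test_lognormal_recovery(self):
        cfg = GeneratorConfig(
            n_participants=1, n_trials_per_condition=10000,
            behav_dprime={"android": 1.0},
            rt_log_mean={"human": np.log(800.0), "android": np.log(800.0)},
            rt_log_sd=0.3, effects={}, seed=9,
        )
        tt = simulate_behaviour(cfg)
        out = rt_summary(tt).set_index("condition")
        assert out.loc["human", "rt_geomean"] == pytest.approx(800.0, rel=0.02)


class TestSDTSummaryPipeline:
    def test_group_dprime_recovers_generator_truth(self):
        cfg = GeneratorConfig(
            n_participants=20, n_trials_per_condition=60,
            behav_dprime={"android": 2.3},
            rt_log_mean={"human": np.log(800.0), "android": np.log(800.0)},
            effects={}, seed=21,
        )
        tt = simulate_behaviour(cfg)
        summ = sdt_summary(tt, human_label="human")
        grp = summ[summ.condition == "android"]["dprime"].mean()
        assert grp == pytest.approx(2.3, abs=0.2)

    def test_group_table_columns(self, tiny_cfg, rng):
        tt = simulate_behaviour(tiny_cfg)
        grp = group_sdt(sdt_summary(tt, "human"), n_boot=200, rng=rng)
        assert {"condition", "dprime", "dprime_ci_low", "dprime_ci_high",
                "rt_geomean"} <= set(grp.columns)
        assert (grp["dprime_ci_low"] <= grp["dprime"]).all()
        assert (grp["dprime"] <= grp["dprime_ci_high"]).all()


class TestLikert:
    def _ratings(self, scores_by_participant):
        rows = []
        for pid, scores in scores_by_participant.items():
            for i, s in enumerate(scores):
                rows.append([pid, "uncanny", f"s{i}", "mask", s])
        df = pd.DataFrame(
            rows, columns=["participant", "item", "stimulus", "condition", "score"]
        )
        return RatingTable(df, scale=(1, 5))

    def test_constant_scores_zero_width(self, rng):
        rt = self._ratings({"P01": [3, 3], "P02": [3, 3]})
        out = likert_summary(rt, n_boot=200, rng=rng)
        assert out["mean"].iloc[0] == 3.0
        assert out["ci_low"].iloc[0] == out["ci_high"].iloc[0] == 3.0

    def test_two_participant_grand_mean(self, rng):
        rt = self._ratings({"P01": [2, 2], "P02": [4, 4]})
        out = likert_summary(rt, n_boot=200, rng=rng)
        assert out["mean"].iloc[0] == pytest.approx(3.0)
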