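"""Signal-detection and reaction-time analysis of human/non-human judgements.

Hit and false-alarm rates follow asymmetric, condition-specific definitions:
for the human condition, a hit is a human image judged human and a false
alarm is any non-human image judged human (pooled over non-human
conditions); for each non-human condition, a hit is one of its images judged
non-human and a false alarm is a human image judged non-human.  A direct
consequence is that all non-human conditions in a table share the same
false-alarm rate.

Sensitivity is d' = probit(hit) - probit(fa), capped at +/-5 so that
degenerate rates (e.g. a hit rate of exactly 1) yield a finite value rather
than an infinite outlier.  Reaction times are analysed on the log scale and
reported back-transformed (geometric means).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import ParameterError, RatingTable, TrialTable
from .preprocess import bootstrap_mean_ci

__all__ = [
    "UndefinedRateError",
    "rates",
    "dprime",
    "sdt_summary",
    "group_sdt",
    "rt_summary",
    "likert_summary",
    "DPRIME_CAP",
]

DPRIME_CAP = 5.0


class UndefinedRateError(ValueError):
    """A hit or false-alarm rate has no trials to be computed from."""


def _judged_human(df: pd.DataFrame, human_response: str) -> pd.Series:
    return df["response"].astype(str) == human_response


def rates(
    tt: TrialTable,
    target_condition: str,
    human_label: str,
    human_response: str | None = None,
) -> tuple[float, float]:
    """Hit and false-alarm rate for one condition, pooled over the table.

    ``human_response`` is the response value meaning "judged human"; it
    defaults to ``human_label``.
    """
    if target_condition not in tt.condition_labels:
        raise ParameterError(f"unknown condition {target_condition!r}")
    if human_label not in tt.condition_labels:
        raise ParameterError(f"unknown human condition {human_label!r}")
    if human_response is None:
        human_response = human_label
    df = tt.data
    judged_human = _judged_human(df, human_response)
    cond = df["condition"].astype(str)
    if target_condition == human_label:
        sig = cond == human_label
        noise = cond != human_label
        if not sig.any() or not noise.any():
            raise UndefinedRateError(
                f"no trials to compute rates for {target_condition!r}"
            )
        hit = float(judged_human[sig].mean())
        fa = float(judged_human[noise].mean())
    else:
        sig = cond == target_condition
        noise = cond == human_label
        if not sig.any() or not noise.any():
            raise UndefinedRateError(
                f"no trials to compute rates for {target_condition!r}"
            )
        hit = float((~judged_human[sig]).mean())
        fa = float((~judged_human[noise]).mean())
    return hit, fa


def dprime(hit_rate: float, fa_rate: float, cap: float = DPRIME_CAP) -> float:
    """Sensitivity index probit(hit) - probit(fa), clipped to +/-cap.

    ``hit_rate == fa_rate`` (including the doubly degenerate 0/0 and 1/1
    cases) gives exactly 0, preserving antisymmetry under capping.
    """
    if not (0.0 <= hit_rate <= 1.0 and 0.0 <= fa_rate <= 1.0):
        raise ParameterError("rates must lie in [0, 1]")
    if hit_rate == fa_rate:
        return 0.0
    d = norm.ppf(hit_rate) - norm.ppf(fa_rate)
    if not np.isfinite(d):
        return cap if (hit_rate > fa_rate) else -cap
    return float(np.clip(d, -cap, cap))


def sdt_summary(
    tt: TrialTable,
    human_label: str,
    cap: float = DPRIME_CAP,
    human_response: str | None = None,
    correct_rts_only: bool = False,
) -> pd.DataFrame:
    """Per participant x condition: hit rate, FA rate, capped d', geometric-mean RT.

    d' is computed within each participant first (group averages are taken
    downstream), matching per-participant analysis of the judgement task.
    With ``correct_rts_only`` the RT geometric mean is restricted to trials
    answered correctly; by default all trials contribute.
    """
    if human_response is None:
        human_response = human_label
    rows = []
    for pid, pdf in tt.data.groupby("participant", sort=True):
        sub = TrialTable(
            pdf.reset_index(drop=True), tt.condition_labels, tt.response_labels
        )
        for cond in tt.condition_labels:
            hit, fa = rates(sub, cond, human_label, human_response)
            rt_df = pdf[pdf["condition"].astype(str) == cond]
            if correct_rts_only:
                judged_human = rt_df["response"].astype(str) == human_response
                correct = judged_human if cond == human_label else ~judged_human
                rt_df = rt_df[correct]
            rt = pd.to_numeric(rt_df["rt"])
            if (rt <= 0).any():
                raise ParameterError("reaction times must be positive")
            geo = float(np.exp(np.log(rt).mean())) if len(rt) else np.nan
            rows.append(
                {
                    "participant": str(pid),
                    "condition": cond,
                    "hit_rate": hit,
                    "fa_rate": fa,
                    "dprime": dprime(hit, fa, cap),
                    "rt_geomean": geo,
                }
            )
    return pd.DataFrame(rows)


def group_sdt(
    summary: pd.DataFrame,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Group means of per-participant d' and geometric-mean RT, with bootstrap CIs.

    RTs are averaged on the log scale and back-transformed to milliseconds.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for cond, cdf in summary.groupby("condition", sort=True):
        d = cdf["dprime"].to_numpy(dtype=float)
        log_rt = np.log(cdf["rt_geomean"].to_numpy(dtype=float))
        d_mean, d_lo, d_hi = bootstrap_mean_ci(d[:, None], n_boot, level, rng)
        r_mean, r_lo, r_hi = bootstrap_mean_ci(log_rt[:, None], n_boot, level, rng)
        rows.append(
            {
                "condition": cond,
                "dprime": float(d_mean[0]),
                "dprime_ci_low": float(d_lo[0]),
                "dprime_ci_high": float(d_hi[0]),
                "rt_geomean": float(np.exp(r_mean[0])),
                "rt_ci_low": float(np.exp(r_lo[0])),
                "rt_ci_high": float(np.exp(r_hi[0])),
                "n_participants": len(cdf),
            }
        )
    return pd.DataFrame(rows)


def rt_summary(tt: TrialTable) -> pd.DataFrame:
    """Per-condition geometric-mean RT (ms): participant log-means, group-averaged."""
    rt = pd.to_numeric(tt.data["rt"])
    if (rt <= 0).any():
        raise ParameterError("reaction times must be positive")
    df = tt.data.assign(log_rt=np.log(rt))
    per_part = (
        df.groupby(["condition", "participant"], sort=True)["log_rt"].mean().reset_index()
    )
    group = per_part.groupby("condition", sort=True)["log_rt"].mean()
    return pd.DataFrame(
        {"condition": group.index, "rt_geomean": np.exp(group.to_numpy())}
    ).reset_index(drop=True)


def likert_summary(
    ratings: RatingTable,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean Likert score per item x condition with a participant-level bootstrap CI."""
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for (item, cond), idf in ratings.data.groupby(["item", "condition"], sort=True):
        per_part = idf.groupby("participant", sort=True)["score"].mean().to_numpy(float)
        if len(per_part) < 2:
            raise ParameterError("need >= 2 participants per item x condition")
        mean, lo, hi = bootstrap_mean_ci(per_part[:, None], n_boot, level, rng)
        rows.append(
            {
                "item": item,
                "condition": cond,
                "mean": float(mean[0]),
                "ci_low": float(lo[0]),
                "ci_high": float(hi[0]),
                "n_participants": len(per_part),
            }
        )
    return pd.DataFrame(rows)
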