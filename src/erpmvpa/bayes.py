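"""Default Bayesian t-tests with the Jeffreys-Zellner-Siow (JZS) prior.

The alternative places a Cauchy prior with scale ``r`` on the standardised
effect size (equivalently, delta | g ~ N(0, g) with g ~ InverseGamma(1/2,
r^2/2)) and a Jeffreys prior on the variance.  The Bayes factor BF10 then
reduces to a one-dimensional integral over g of the t likelihood ratio,
which is evaluated here by adaptive quadrature after the substitution
g = u/(1-u), carried out in log space so that very large t statistics do
not overflow.

Evidence categories follow the conventional thresholds: BF10 > 3 is some
evidence for the alternative, > 10 strong, > 30 very strong; BF10 < 1 leans
toward the null and 1 <= BF10 <= 3 is anecdotal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .io import ParameterError

__all__ = [
    "BFResult",
    "BFTimecourse",
    "DegenerateDataError",
    "DEFAULT_R_SCALE",
    "jzs_bf_from_t",
    "jzs_bf_one_sample",
    "jzs_bf_paired",
    "bf_timecourse",
    "classify_evidence",
]

DEFAULT_R_SCALE = math.sqrt(2.0) / 2.0  # ~0.707, the common software default


class DegenerateDataError(ValueError):
    """The sample has zero variance, so the t statistic is undefined."""


@dataclass
class BFResult:
    """A single JZS Bayes factor with its ingredients."""

    bf10: float
    log10bf10: float
    t: float
    n: int
    df: int
    r_scale: float

    @property
    def category(self) -> str:
        return classify_evidence(self.bf10)


@dataclass
class BFTimecourse:
    """Per-timepoint log10 BF10 for one comparison; degenerate points flagged."""

    times: np.ndarray
    log10bf10: np.ndarray
    bf10: np.ndarray
    comparison: str
    flags: np.ndarray  # True where the input was degenerate (BF undefined)

    def __len__(self) -> int:
        return len(self.times)

    def categories(self) -> list[str]:
        return [
            "degenerate" if f else classify_evidence(b)
            for f, b in zip(self.flags, self.bf10)
        ]


def _log_integrand(u: np.ndarray, t: float, n: int, r: float) -> np.ndarray:
    """Log of the JZS numerator integrand after g = u/(1-u)."""
    nu = n - 1
    g = u / (1.0 - u)
    log_prior = (
        0.5 * math.log(r * r / 2.0)
        - math.lgamma(0.5)
        - 1.5 * np.log(g)
        - r * r / (2.0 * g)
    )
    one_ng = 1.0 + n * g
    log_lik = -0.5 * np.log(one_ng) - (nu + 1) / 2.0 * np.log1p(
        t * t / (one_ng * nu)
    )
    log_jac = -2.0 * np.log1p(-u)
    return log_lik + log_prior + log_jac


def jzs_bf_from_t(t: float, n: int, r_scale: float = DEFAULT_R_SCALE) -> BFResult:
    """JZS Bayes factor for a one-sample/paired t statistic with n observations.

    The g integral is evaluated by adaptive quadrature with a log-space
    shift located on a dense grid, giving relative error well below 1e-6.
    """
    if n < 2:
        raise ParameterError("need n >= 2")
    if r_scale <= 0:
        raise ParameterError("r_scale must be positive")
    nu = n - 1
    u_grid = np.linspace(1e-9, 1.0 - 1e-9, 2001)
    log_f = _log_integrand(u_grid, t, n, r_scale)
    shift = float(np.max(log_f))
    peak = float(u_grid[int(np.argmax(log_f))])

    def f(u: float) -> float:
        return math.exp(float(_log_integrand(np.asarray([u]), t, n, r_scale)[0]) - shift)

    integral, _ = quad(f, 0.0, 1.0, points=[peak], epsabs=1e-14, epsrel=1e-10, limit=300)
    log_num = shift + math.log(integral)
    log_denom = -(nu + 1) / 2.0 * math.log1p(t * t / nu)
    log_bf = log_num - log_denom
    with np.errstate(over="ignore"):
        bf10 = float(np.exp(log_bf))
    return BFResult(
        bf10=bf10,
        log10bf10=log_bf / math.log(10.0),
        t=float(t),
        n=int(n),
        df=nu,
        r_scale=float(r_scale),
    )


def jzs_bf_one_sample(
    x: np.ndarray, r_scale: float = DEFAULT_R_SCALE, popmean: float = 0.0
) -> BFResult:
    """JZS Bayes factor that the mean of ``x`` differs from ``popmean``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ParameterError("x must be a 1-D sample with n >= 2")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise DegenerateDataError("sample has zero variance")
    t = (float(np.mean(x)) - popmean) / (sd / math.sqrt(len(x)))
    return jzs_bf_from_t(t, len(x), r_scale)


def jzs_bf_paired(
    x: np.ndarray, y: np.ndarray, r_scale: float = DEFAULT_R_SCALE
) -> BFResult:
    """Paired JZS Bayes factor; identical to the one-sample test on x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError(f"length mismatch: {x.shape} vs {y.shape}")
    return jzs_bf_one_sample(x - y, r_scale)


def bf_timecourse(
    data: np.ndarray,
    times: np.ndarray,
    mode: str = "paired",
    data2: np.ndarray | None = None,
    constant: float = 0.0,
    r_scale: float = DEFAULT_R_SCALE,
    comparison: str = "",
) -> BFTimecourse:
    """Timepoint-wise JZS Bayes factors over participants.

    ``data`` is (n_participants, n_timepoints).  In ``paired`` mode,
    ``data2`` holds the second condition and each timepoint tests the paired
    difference; in ``one_sample`` mode each timepoint tests ``data`` against
    ``constant`` (e.g. decoding accuracy against chance 0.5).  Timepoints
    with zero-variance input are flagged rather than fatal.
    """
    data = np.asarray(data, dtype=float)
    times = np.asarray(times, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ParameterError("data must be (n_participants >= 2, n_timepoints)")
    if data.shape[1] != len(times):
        raise ParameterError("data and times length mismatch")
    if mode == "paired":
        if data2 is None:
            raise ParameterError("paired mode needs data2")
        data2 = np.asarray(data2, dtype=float)
        if data2.shape != data.shape:
            raise ParameterError("data and data2 shape mismatch")
        diffs = data - data2
    elif mode == "one_sample":
        diffs = data - constant
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    n_t = diffs.shape[1]
    log10bf = np.full(n_t, np.nan)
    bf = np.full(n_t, np.nan)
    flags = np.zeros(n_t, dtype=bool)
    for j in range(n_t):
        try:
            res = jzs_bf_one_sample(diffs[:, j], r_scale)
        except DegenerateDataError:
            flags[j] = True
            continue
        log10bf[j] = res.log10bf10
        bf[j] = res.bf10
    return BFTimecourse(
        times=times, log10bf10=log10bf, bf10=bf, comparison=comparison, flags=flags
    )


def classify_evidence(bf10: float) -> str:
    """Jeffreys-style evidence category for a Bayes factor."""
    if not bf10 > 0:
        raise ParameterError("bf10 must be positive")
    if bf10 < 1.0:
        return "null-leaning"
    if bf10 <= 3.0:
        return "anecdotal"
    if bf10 <= 10.0:
        return "some"
    if bf10 <= 30.0:
        return "strong"
    return "very strong"
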