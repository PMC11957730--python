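"""Timepoint-wise two-class decoding of scalp patterns.

At each timepoint the multichannel voltage pattern of single trials is
classified with a linear soft-margin support vector machine.  Training does
not see single trials directly: for each class, a small number of
"exemplar" patterns (default 4) is formed by averaging random disjoint
subsets of 20% of that class's trials, and the classifier is tested on the
remaining held-out trials.  The split/train/test cycle is repeated over many
random permutations (default 1000) and accuracies averaged, so chance is
50% for a balanced two-class problem; balanced accuracy (mean of the two
per-class accuracies) preserves that anchor under class imbalance.

The SVM dual problem is solved by a compact SMO (sequential minimal
optimisation) routine specialised for the tiny training sets this scheme
produces; it reproduces libsvm solutions to ~1e-5 while running orders of
magnitude faster per fit, which is what makes decoding at every timepoint
for every participant tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .bayes import DEFAULT_R_SCALE, BFTimecourse, bf_timecourse
from .io import EpochSet, ParameterError

__all__ = [
    "DecoderConfig",
    "DecodingResult",
    "DecodingInfeasibleError",
    "LinearDecisionFunction",
    "subaverage_split",
    "train_linear",
    "decode_timepoint",
    "decode_timecourse",
]


class DecodingInfeasibleError(ValueError):
    """A class has too few trials for the requested sub-averaging scheme."""


@dataclass
class DecoderConfig:
    """Parameters of the sub-averaged decoding scheme."""

    n_exemplars: int = 4
    subset_fraction: float = 0.2
    n_permutations: int = 1000
    c_parameter: float = 1.0
    seed: int = 0
    balanced: bool = True  # mean of per-class accuracies; False = raw accuracy
    disjoint: bool = True  # disjoint exemplar subsets (test = guaranteed remainder)

    def __post_init__(self) -> None:
        if self.n_exemplars < 1:
            raise ParameterError("n_exemplars must be >= 1")
        if not 0.0 < self.subset_fraction <= 1.0:
            raise ParameterError("subset_fraction must be in (0, 1]")
        if self.n_exemplars * self.subset_fraction > 1.0 + 1e-12:
            raise ParameterError("n_exemplars * subset_fraction must be <= 1")
        if self.n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        if self.c_parameter <= 0:
            raise ParameterError("c_parameter must be positive")


@dataclass
class LinearDecisionFunction:
    """f(x) = w.x + b; f >= 0 predicts ``classes[0]`` (ties go to the first class)."""

    w: np.ndarray
    b: float
    classes: tuple
    degenerate: bool = False

    def decision(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision(X)
        return np.where(f >= 0.0, self.classes[0], self.classes[1])


@njit(cache=False)
def _smo_linear(X, y, C, tol, max_iter):  # pragma: no cover - exercised via wrapper
    """SMO for the C-SVM dual with a linear kernel; returns (alpha, intercept)."""
    n = X.shape[0]
    K = X @ X.T
    alpha = np.zeros(n)
    G = -np.ones(n)  # gradient of the dual objective (minimisation form)
    Gmax = 0.0
    Gmin = 0.0
    for _ in range(max_iter):
        i_sel = -1
        Gmax = -1e300
        for t in range(n):
            if (y[t] > 0 and alpha[t] < C) or (y[t] < 0 and alpha[t] > 0):
                v = -y[t] * G[t]
                if v > Gmax:
                    Gmax = v
                    i_sel = t
        j_sel = -1
        Gmin = 1e300
        for t in range(n):
            if (y[t] > 0 and alpha[t] > 0) or (y[t] < 0 and alpha[t] < C):
                v = -y[t] * G[t]
                if v < Gmin:
                    Gmin = v
                    j_sel = t
        if i_sel == -1 or j_sel == -1 or Gmax - Gmin < tol:
            break
        i = i_sel
        j = j_sel
        quad = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if quad <= 1e-12:
            quad = 1e-12
        delta = (-y[i] * G[i] + y[j] * G[j]) / quad
        ai_old = alpha[i]
        aj_old = alpha[j]
        s = y[i] * ai_old + y[j] * aj_old
        ai = ai_old + y[i] * delta
        if ai < 0.0:
            ai = 0.0
        if ai > C:
            ai = C
        aj = y[j] * (s - y[i] * ai)
        if aj < 0.0:
            aj = 0.0
            ai = y[i] * s
            if ai < 0.0:
                ai = 0.0
            if ai > C:
                ai = C
        if aj > C:
            aj = C
            ai = y[i] * (s - y[j] * C)
            if ai < 0.0:
                ai = 0.0
            if ai > C:
                ai = C
        dai = ai - ai_old
        daj = aj - aj_old
        if abs(dai) < 1e-16 and abs(daj) < 1e-16:
            break
        for t in range(n):
            G[t] += y[t] * (y[i] * K[t, i] * dai + y[j] * K[t, j] * daj)
        alpha[i] = ai
        alpha[j] = aj
    b = (Gmax + Gmin) / 2.0 if (Gmax > -1e299 and Gmin < 1e299) else 0.0
    return alpha, b


def train_linear(
    X: np.ndarray, labels: np.ndarray, c_parameter: float = 1.0
) -> LinearDecisionFunction:
    """Fit a linear soft-margin SVM on exemplar patterns.

    Class order is the sorted label order; the first class maps to the
    positive side of the decision function.  If the two classes present
    identical exemplar sets the problem is degenerate: the returned function
    is flagged and scores everything 0 (ties, i.e. first class).
    """
    X = np.ascontiguousarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ParameterError("need exactly two classes")
    Xa = X[labels == classes[0]]
    Xb = X[labels == classes[1]]
    if Xa.shape == Xb.shape and np.array_equal(
        np.sort(Xa, axis=0), np.sort(Xb, axis=0)
    ):
        return LinearDecisionFunction(
            w=np.zeros(X.shape[1]), b=0.0, classes=tuple(classes), degenerate=True
        )
    y = np.where(labels == classes[0], 1.0, -1.0)
    alpha, b = _smo_linear(X, y, float(c_parameter), 1e-8, 10000)
    w = (alpha * y) @ X
    return LinearDecisionFunction(w=w, b=float(b), classes=tuple(classes))


def subaverage_split(
    class_indices: Sequence[np.ndarray],
    cfg: DecoderConfig,
    rng: np.random.Generator,
    class_names: Sequence | None = None,
) -> tuple[list[list[np.ndarray]], list[np.ndarray]]:
    """Draw exemplar subsets and the held-out test set for each class.

    In disjoint mode (default) each class is permuted once and cut into
    ``n_exemplars`` consecutive subsets of round(subset_fraction * n) trials;
    the test set is everything left over, so training and test trials are
    disjoint by construction.  In the overlapping variant each subset is an
    independent draw without replacement and the test set is the complement
    of their union.
    """
    exemplar_sets: list[list[np.ndarray]] = []
    test_sets: list[np.ndarray] = []
    for ci, idx in enumerate(class_indices):
        idx = np.asarray(idx)
        n = len(idx)
        name = class_names[ci] if class_names is not None else ci
        size = int(round(cfg.subset_fraction * n))
        if size < 1 or n - cfg.n_exemplars * size < 1:
            raise DecodingInfeasibleError(
                f"class {name!r}: {n} trials cannot support "
                f"{cfg.n_exemplars} subsets of {max(size, 1)} plus a test set"
            )
        if cfg.disjoint:
            perm = idx[rng.permutation(n)]
            subsets = [
                perm[k * size : (k + 1) * size] for k in range(cfg.n_exemplars)
            ]
            test = perm[cfg.n_exemplars * size :]
        else:
            subsets = [
                idx[rng.permutation(n)[:size]] for _ in range(cfg.n_exemplars)
            ]
            used = np.unique(np.concatenate(subsets))
            test = np.setdiff1d(idx, used)
            if len(test) == 0:
                raise DecodingInfeasibleError(
                    f"class {name!r}: overlapping subsets left no test trials"
                )
        exemplar_sets.append(subsets)
        test_sets.append(test)
    return exemplar_sets, test_sets


def decode_timepoint(
    patterns: np.ndarray,
    labels: np.ndarray,
    cfg: DecoderConfig,
    rng: np.random.Generator,
) -> float:
    """Permutation-averaged decoding accuracy at a single timepoint.

    ``patterns`` is (n_trials, n_channels); features are the raw voltages
    with no scaling.  Returns the mean over permutations of (balanced)
    accuracy on held-out trials.
    """
    patterns = np.ascontiguousarray(patterns, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ParameterError("need exactly two classes")
    Xa = np.ascontiguousarray(patterns[labels == classes[0]])
    Xb = np.ascontiguousarray(patterns[labels == classes[1]])
    n_a, n_b = len(Xa), len(Xb)
    k = cfg.n_exemplars
    size_a = int(round(cfg.subset_fraction * n_a))
    size_b = int(round(cfg.subset_fraction * n_b))
    for n, size, name in ((n_a, size_a, classes[0]), (n_b, size_b, classes[1])):
        if size < 1 or n - k * size < 1:
            raise DecodingInfeasibleError(
                f"class {name!r}: {n} trials cannot support "
                f"{k} subsets of {max(size, 1)} plus a test set"
            )
    d = patterns.shape[1]
    y_train = np.empty(2 * k)
    y_train[:k] = 1.0
    y_train[k:] = -1.0
    C = float(cfg.c_parameter)
    acc_sum = 0.0
    train = np.empty((2 * k, d))
    for _ in range(cfg.n_permutations):
        if cfg.disjoint:
            pa = rng.permutation(n_a)
            pb = rng.permutation(n_b)
            train[:k] = Xa[pa[: k * size_a]].reshape(k, size_a, d).mean(axis=1)
            train[k:] = Xb[pb[: k * size_b]].reshape(k, size_b, d).mean(axis=1)
            Ta = Xa[pa[k * size_a :]]
            Tb = Xb[pb[k * size_b :]]
        else:
            (ex_a, ex_b), (ia, ib) = subaverage_split(
                [np.arange(n_a), np.arange(n_b)], cfg, rng, class_names=classes
            )
            train[:k] = [Xa[s].mean(axis=0) for s in ex_a]
            train[k:] = [Xb[s].mean(axis=0) for s in ex_b]
            Ta, Tb = Xa[ia], Xb[ib]
        alpha, b = _smo_linear(train, y_train, C, 1e-8, 10000)
        w = (alpha * y_train) @ train
        # class a sits on the positive side; ties (f == 0) go to the first class
        acc_a = float(np.mean(Ta @ w + b >= 0.0))
        acc_b = float(np.mean(Tb @ w + b < 0.0))
        if cfg.balanced:
            acc_sum += 0.5 * (acc_a + acc_b)
        else:
            acc_sum += (acc_a * len(Ta) + acc_b * len(Tb)) / (len(Ta) + len(Tb))
    return acc_sum / cfg.n_permutations


@dataclass
class DecodingResult:
    """Participant x timepoint decoding accuracies with group-level statistics."""

    times: np.ndarray
    accuracy: np.ndarray  # (n_participants, n_timepoints), proportion correct
    participants: list[str]
    bf_vs_chance: BFTimecourse
    config: DecoderConfig
    comparison: str = ""

    @property
    def group_mean(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)


def decode_timecourse(
    epoch_sets: Sequence[EpochSet],
    condition_pair: tuple[str, str],
    cfg: DecoderConfig,
    time_decim: int = 1,
    r_scale: float = DEFAULT_R_SCALE,
) -> DecodingResult:
    """Decode a condition pair at every timepoint for every participant.

    The per-(participant, timepoint) random streams are derived from
    (cfg.seed, participant index, timepoint index), so results do not depend
    on execution order.  ``time_decim`` decodes every k-th timepoint to trade
    temporal resolution for runtime.  Group-level evidence against chance is
    a one-sample JZS Bayes factor on accuracy - 0.5 at each decoded
    timepoint.
    """
    if len(epoch_sets) < 2:
        raise ParameterError("need >= 2 participants")
    if time_decim < 1:
        raise ParameterError("time_decim must be >= 1")
    times = epoch_sets[0].times
    t_idx = np.arange(0, len(times), time_decim)
    acc = np.empty((len(epoch_sets), len(t_idx)))
    participants = []
    for p, es in enumerate(epoch_sets):
        sub = es.select_conditions(condition_pair)
        labels = np.asarray(sub.conditions, dtype=str)
        participants.append(es.participant)
        for jj, j in enumerate(t_idx):
            rng = np.random.default_rng([cfg.seed, 11, p, int(j)])
            acc[p, jj] = decode_timepoint(sub.data[:, :, j], labels, cfg, rng)
    sel_times = times[t_idx]
    comparison = f"{condition_pair[0]} vs {condition_pair[1]}"
    bf = bf_timecourse(
        acc,
        sel_times,
        mode="one_sample",
        constant=0.5,
        r_scale=r_scale,
        comparison=f"{comparison} accuracy vs chance",
    )
    return DecodingResult(
        times=sel_times,
        accuracy=acc,
        participants=participants,
        bf_vs_chance=bf,
        config=cfg,
        comparison=comparison,
    )
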