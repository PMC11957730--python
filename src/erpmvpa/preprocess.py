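"""Filtering, epoching, baseline subtraction, exclusion, pooling and grand means.

The band-pass filter is a zero-phase FIR built from Hamming-window designs
(transition width 0.5 Hz at the low edge, 7.5 Hz at the high edge) and
applied in the frequency domain with zero padding, i.e. the effective
magnitude response is |H(f)|^2 with no phase distortion.  On signals long
enough to contain the kernel this meets a +/-1 dB passband (1-25 Hz) and
>= 30 dB stopband (0.05 Hz, 50 Hz) contract; epochs shorter than the kernel
are filtered with the same response but carry edge transients, as any
offline filter does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.fft
import scipy.signal

from .io import EpochSet, ParameterError

__all__ = [
    "PooledTimecourse",
    "design_bandpass",
    "bandpass",
    "bandpass_array",
    "epoch",
    "baseline_correct",
    "exclude_participants",
    "pool_electrodes",
    "grand_mean_ci",
    "bootstrap_mean_ci",
]

POOL_DEFAULT = ("P6", "P8", "PO6", "PO8")


@dataclass
class PooledTimecourse:
    """Per-trial mean voltage over a named electrode set (trials x timepoints)."""

    data: np.ndarray
    electrode_set: tuple[str, ...]
    srate: float
    times: np.ndarray
    conditions: np.ndarray
    participant: str

    def __post_init__(self) -> None:
        if len(self.electrode_set) == 0:
            raise ParameterError("electrode_set must be non-empty")


def _hamming_numtaps(transition_hz: float, srate: float) -> int:
    # Hamming window design rule: transition width ~ 3.3 / N (normalised).
    n = int(np.ceil(3.3 * srate / transition_hz))
    return n + 1 if n % 2 == 0 else n


def design_bandpass(
    low: float = 0.5,
    high: float = 30.0,
    srate: float = 250.0,
    low_trans: float = 0.5,
    high_trans: float = 7.5,
) -> np.ndarray:
    """FIR band-pass kernel: high-pass at ``low`` convolved with low-pass at ``high``.

    Cutoffs are placed half a transition width outside the passband edges so
    the -6 dB points sit mid-transition (passband edge gain ~ 1).
    """
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    if high >= srate / 2:
        raise ParameterError(f"high ({high} Hz) must be below Nyquist ({srate / 2} Hz)")
    hp = scipy.signal.firwin(
        _hamming_numtaps(low_trans, srate),
        low - low_trans / 2.0,
        pass_zero=False,
        window="hamming",
        fs=srate,
    )
    lp = scipy.signal.firwin(
        _hamming_numtaps(high_trans, srate),
        high + high_trans / 2.0,
        pass_zero=True,
        window="hamming",
        fs=srate,
    )
    return np.convolve(hp, lp)


def _zero_phase_apply(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Apply ``h`` forward and backward (|H|^2 response) along the last axis."""
    n = x.shape[-1]
    nfft = scipy.fft.next_fast_len(n + 2 * (len(h) - 1))
    gain2 = np.abs(np.fft.rfft(h, nfft)) ** 2
    y = np.fft.irfft(np.fft.rfft(x, nfft, axis=-1) * gain2, n=nfft, axis=-1)
    return y[..., :n]


def bandpass(es: EpochSet, low: float = 0.5, high: float = 30.0) -> EpochSet:
    """Zero-phase FIR band-pass of every trial and channel."""
    h = design_bandpass(low, high, es.srate)
    out = es.copy()
    out.data = _zero_phase_apply(es.data, h)
    return out


def bandpass_array(
    data: np.ndarray, srate: float, low: float = 0.5, high: float = 30.0
) -> np.ndarray:
    """Band-pass a continuous (channels x samples) record; filter-then-epoch order."""
    h = design_bandpass(low, high, srate)
    return _zero_phase_apply(np.asarray(data, dtype=float), h)


def epoch(
    continuous: np.ndarray,
    events: Sequence[tuple[int, str]],
    window: tuple[float, float],
    srate: float,
    channels: Sequence[str],
    participant: str = "",
) -> tuple[EpochSet, list[tuple[int, str]]]:
    """Cut trials around event onsets from a continuous (channels x samples) record.

    Returns the epoched set and a list of skipped events (those whose window
    falls outside the recording), so no trial is dropped silently.
    """
    continuous = np.asarray(continuous, dtype=float)
    n_samples = continuous.shape[1]
    w0, w1 = window
    step = 1000.0 / srate
    i0 = int(round(w0 / step))
    i1 = int(round(w1 / step))
    times = np.arange(i0, i1 + 1) * step
    trials, labels, skipped = [], [], []
    for onset, label in events:
        lo, hi = onset + i0, onset + i1
        if lo < 0 or hi >= n_samples:
            skipped.append((onset, label))
            continue
        trials.append(continuous[:, lo : hi + 1])
        labels.append(label)
    if not trials:
        data = np.empty((0, continuous.shape[0], len(times)))
    else:
        data = np.stack(trials)
    es = EpochSet(
        data=data,
        srate=srate,
        times=times,
        channels=list(channels),
        conditions=np.asarray(labels, dtype=object),
        participant=participant,
    )
    return es, skipped


def baseline_correct(es: EpochSet, window: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the pre-stimulus window.

    The window is half-open, [start, end): with the default, the mean covers
    the 200 ms before stimulus onset and excludes the onset sample itself.
    """
    w0, w1 = window
    mask = (es.times >= w0) & (es.times < w1)
    if not mask.any():
        raise ParameterError(f"baseline window {window} contains no samples")
    out = es.copy()
    out.data = es.data - es.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def exclude_participants(
    sets: Sequence[EpochSet],
    threshold: float = 100.0,
    max_bad_fraction: float = 0.2,
) -> tuple[list[EpochSet], list[tuple[str, str]]]:
    """Drop participants with too many high-amplitude trials.

    A trial is bad when any sample exceeds ``threshold`` microvolts in
    magnitude; a participant is excluded when the fraction of bad trials
    exceeds ``max_bad_fraction``.  Returns (kept, [(participant, reason)]).
    """
    kept: list[EpochSet] = []
    excluded: list[tuple[str, str]] = []
    for es in sets:
        bad = np.abs(es.data).max(axis=(1, 2)) > threshold
        frac = float(bad.mean()) if es.n_trials else 0.0
        if frac > max_bad_fraction:
            excluded.append(
                (
                    es.participant,
                    f"{frac:.1%} of trials exceed +/-{threshold:g} uV "
                    f"(limit {max_bad_fraction:.0%})",
                )
            )
        else:
            kept.append(es)
    return kept, excluded


def pool_electrodes(
    es: EpochSet, electrodes: Sequence[str] = POOL_DEFAULT
) -> PooledTimecourse:
    """Unweighted per-trial mean over a named electrode set."""
    electrodes = tuple(electrodes)
    missing = [e for e in electrodes if e not in es.channels]
    if missing:
        raise ParameterError(f"electrode(s) not in montage: {', '.join(missing)}")
    idx = [es.channels.index(e) for e in electrodes]
    return PooledTimecourse(
        data=es.data[:, idx, :].mean(axis=1),
        electrode_set=electrodes,
        srate=es.srate,
        times=es.times.copy(),
        conditions=es.conditions.copy(),
        participant=es.participant,
    )


def bootstrap_mean_ci(
    values: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap of the mean over axis 0 of ``values``.

    ``values`` is (n_units, ...); units (participants) are resampled with
    replacement.  Returns (mean, ci_low, ci_high) with the trailing shape.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    if n < 2:
        raise ParameterError("need >= 2 units to bootstrap")
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = values[idx].mean(axis=1)  # (n_boot, ...)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    return values.mean(axis=0), lo, hi


def grand_mean_ci(
    participant_means: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grand-mean timecourse with a percentile-bootstrap CI band.

    ``participant_means`` is (n_participants, n_timepoints).  The band is
    computed independently at each timepoint and always contains the mean.
    """
    return bootstrap_mean_ci(participant_means, n_boot=n_boot, level=level, rng=rng)
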