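"""Data containers and on-disk formats for epoched EEG and behavioural tables.

The native epoch container is deliberately simple: a flat binary float64
array (row-major, trials x channels x timepoints) next to a JSON sidecar
carrying the sampling rate, time axis, channel labels, per-trial condition
labels and participant identifier.  Behavioural trial tables and Likert
rating tables are UTF-8 delimited text (tab or comma) with a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EpochSet",
    "TrialTable",
    "RatingTable",
    "FormatError",
    "ValidationError",
    "ParameterError",
    "read_epochs",
    "write_epochs",
    "read_trial_table",
    "write_trial_table",
    "read_rating_table",
    "write_rating_table",
]


class FormatError(ValueError):
    """A container on disk does not match its declared structure."""


class ValidationError(ValueError):
    """Ingested rows or fields violate a declared invariant."""


class ParameterError(ValueError):
    """A caller-supplied parameter is outside its valid domain."""


@dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x timepoints, in microvolts.

    ``times`` is the per-timepoint latency in milliseconds relative to
    stimulus onset (onset = 0, baseline samples negative), uniformly spaced
    at 1000/srate ms.
    """

    data: np.ndarray
    srate: float
    times: np.ndarray
    channels: list[str]
    conditions: np.ndarray
    participant: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.channels = [str(c) for c in self.channels]
        if self.data.ndim != 3:
            raise ValidationError("data must be trials x channels x timepoints")
        n_trials, n_ch, n_t = self.data.shape
        if len(self.times) != n_t:
            raise ValidationError(
                f"times has {len(self.times)} entries for {n_t} timepoints"
            )
        if len(self.channels) != n_ch:
            raise ValidationError(
                f"{len(self.channels)} channel labels for {n_ch} channels"
            )
        if len(set(self.channels)) != n_ch:
            raise ValidationError("channel labels must be unique")
        if len(self.conditions) != n_trials:
            raise ValidationError(
                f"{len(self.conditions)} condition labels for {n_trials} trials"
            )
        if n_t > 1:
            dt = np.diff(self.times)
            step = 1000.0 / self.srate
            if not np.all(dt > 0):
                raise ValidationError("times must be strictly increasing")
            if not np.allclose(dt, step, rtol=0, atol=1e-6 * step):
                raise ValidationError(
                    f"times must be uniformly spaced at {step:g} ms"
                )
        if np.isnan(self.data).any():
            raise ValidationError("voltage data contain NaN values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            srate=self.srate,
            times=self.times.copy(),
            channels=list(self.channels),
            conditions=self.conditions.copy(),
            participant=self.participant,
        )

    def select_conditions(self, labels: Sequence[str]) -> "EpochSet":
        """Restrict to trials whose condition label is in ``labels``."""
        labels = list(labels)
        mask = np.isin(np.asarray(self.conditions, dtype=str), labels)
        return EpochSet(
            data=self.data[mask],
            srate=self.srate,
            times=self.times.copy(),
            channels=list(self.channels),
            conditions=self.conditions[mask],
            participant=self.participant,
        )


def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".bin", ".json"}:
        base = base.with_suffix("")
    return base.with_suffix(".bin"), base.with_suffix(".json")


def write_epochs(es: EpochSet, path: str | Path) -> Path:
    """Write an :class:`EpochSet` as ``<path>.bin`` + ``<path>.json``.

    Lossless for 64-bit float voltages; overwrites any existing container.
    Returns the ``.bin`` path.
    """
    bin_path, json_path = _paths(path)
    bin_path.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(es.data, dtype="<f8").tofile(bin_path)
    sidecar = {
        "shape": list(es.data.shape),
        "srate": float(es.srate),
        "times": [float(t) for t in es.times],
        "channels": list(es.channels),
        "conditions": [str(c) for c in es.conditions],
        "participant": str(es.participant),
    }
    json_path.write_text(json.dumps(sidecar), encoding="utf-8")
    return bin_path


def read_epochs(path: str | Path) -> EpochSet:
    """Read a container written by :func:`write_epochs`."""
    bin_path, json_path = _paths(path)
    if not json_path.exists():
        raise FormatError(f"missing sidecar {json_path}")
    if not bin_path.exists():
        raise FormatError(f"missing voltage array {bin_path}")
    sidecar = json.loads(json_path.read_text(encoding="utf-8"))
    for key in ("shape", "srate", "times", "channels", "conditions", "participant"):
        if key not in sidecar:
            raise FormatError(f"sidecar {json_path} missing field '{key}'")
    shape = tuple(int(s) for s in sidecar["shape"])
    raw = np.fromfile(bin_path, dtype="<f8")
    if raw.size != int(np.prod(shape)):
        raise FormatError(
            f"array {bin_path} has {raw.size} values, sidecar declares shape {shape}"
        )
    n_trials, n_ch, n_t = shape
    if len(sidecar["channels"]) != n_ch:
        raise FormatError(
            f"sidecar declares {len(sidecar['channels'])} channels "
            f"over a {n_ch}-channel array"
        )
    if len(sidecar["times"]) != n_t:
        raise FormatError("sidecar times length does not match array")
    if len(sidecar["conditions"]) != n_trials:
        raise FormatError("sidecar conditions length does not match array")
    try:
        return EpochSet(
            data=raw.reshape(shape),
            srate=float(sidecar["srate"]),
            times=np.asarray(sidecar["times"], dtype=float),
            channels=list(sidecar["channels"]),
            conditions=np.asarray(sidecar["conditions"], dtype=object),
            participant=str(sidecar["participant"]),
        )
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


@dataclass
class TrialTable:
    """Per-trial behavioural records: participant, condition, response, rt (ms)."""

    data: pd.DataFrame
    condition_labels: tuple[str, ...]
    response_labels: tuple[str, ...]

    REQUIRED = ("participant", "condition", "response", "rt")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"trial table missing columns {missing}")
        self.condition_labels = tuple(self.condition_labels)
        self.response_labels = tuple(self.response_labels)
        bad = self.validate(self.data)
        if len(bad):
            raise ValidationError(
                "invalid trial rows: "
                + "; ".join(f"row {i}: {r}" for i, r in bad[:10])
            )

    def validate(self, df: pd.DataFrame) -> list[tuple[int, str]]:
        """Return (row index, reason) for every row violating an invariant."""
        bad: list[tuple[int, str]] = []
        cond_ok = df["condition"].astype(str).isin(self.condition_labels)
        resp_ok = df["response"].astype(str).isin(self.response_labels)
        rt = pd.to_numeric(df["rt"], errors="coerce")
        for i in df.index[~cond_ok]:
            bad.append((int(i), f"unknown condition label {df.at[i, 'condition']!r}"))
        for i in df.index[~resp_ok]:
            bad.append((int(i), f"unknown response label {df.at[i, 'response']!r}"))
        for i in df.index[~(rt > 0)]:
            bad.append((int(i), f"non-positive rt {df.at[i, 'rt']!r}"))
        return sorted(set(bad))

    @property
    def participants(self) -> list[str]:
        return sorted(self.data["participant"].astype(str).unique())

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class RatingTable:
    """Likert ratings: participant, item, stimulus, condition, integer score."""

    data: pd.DataFrame
    scale: tuple[int, int]

    REQUIRED = ("participant", "item", "stimulus", "condition", "score")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"rating table missing columns {missing}")
        lo, hi = self.scale
        if not lo < hi:
            raise ParameterError("scale bounds must satisfy lo < hi")
        score = pd.to_numeric(self.data["score"], errors="coerce")
        if score.isna().any() or (score % 1 != 0).any():
            raise ValidationError("scores must be integers")
        if ((score < lo) | (score > hi)).any():
            raise ValidationError(f"scores outside scale bounds {self.scale}")

    def __len__(self) -> int:
        return len(self.data)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a delimited text table, auto-detecting tab vs comma."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(path, sep=sep)


def read_trial_table(
    path: str | Path,
    condition_labels: Sequence[str],
    response_labels: Sequence[str],
    errors: str = "raise",
) -> TrialTable | tuple[TrialTable, list[tuple[int, str]]]:
    """Read and validate a behavioural trial table.

    With ``errors="raise"`` any invalid row raises :class:`ValidationError`
    naming the row.  With ``errors="report"`` invalid rows are dropped and the
    return value is ``(table, rejects)`` where ``rejects`` lists
    (row index, reason) pairs, so rows in = rows accepted + rows reported.
    """
    df = _read_delimited(path)
    probe = TrialTable.__new__(TrialTable)
    probe.data = df
    probe.condition_labels = tuple(condition_labels)
    probe.response_labels = tuple(response_labels)
    bad = TrialTable.validate(probe, df)
    if errors == "raise":
        if bad:
            raise ValidationError(
                "invalid trial rows: "
                + "; ".join(f"row {i}: {r}" for i, r in bad[:10])
            )
        return TrialTable(df, tuple(condition_labels), tuple(response_labels))
    bad_idx = {i for i, _ in bad}
    kept = df.drop(index=list(bad_idx)).reset_index(drop=True)
    return TrialTable(kept, tuple(condition_labels), tuple(response_labels)), bad


def write_trial_table(tt: TrialTable, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tt.data.to_csv(path, sep=sep, index=False)
    return path


def read_rating_table(path: str | Path, scale: tuple[int, int]) -> RatingTable:
    return RatingTable(_read_delimited(path), tuple(scale))


def write_rating_table(rt: RatingTable, path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rt.data.to_csv(path, sep=sep, index=False)
    return path
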