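"""End-to-end orchestration: synthetic or supplied cohorts through the full chain.

A run produces a results directory holding TSV tables (behavioural
signal-detection summaries, univariate Bayes-factor timecourses, decoding
timecourses), figures, and a JSON run manifest that snapshots every
parameter (including seeds and the JZS prior scale) plus content hashes of
any input files, so any output can be traced and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bayes import DEFAULT_R_SCALE, BFTimecourse, bf_timecourse, classify_evidence
from .behaviour import group_sdt, sdt_summary
from .decoding import DecoderConfig, DecodingResult, decode_timecourse
from .io import (
    EpochSet,
    TrialTable,
    read_epochs,
    read_trial_table,
    write_epochs,
    write_trial_table,
)
from .preprocess import (
    POOL_DEFAULT,
    bandpass,
    baseline_correct,
    exclude_participants,
    grand_mean_ci,
    pool_electrodes,
)
from .simulate import EffectSpec, GeneratorConfig, simulate_behaviour, simulate_epochs

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_synthetic",
    "run_study",
    "load_config",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in ``stage``."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Analysis-side parameters of a run (the generator has its own config)."""

    condition_pair: tuple[str, str] = ("human", "android")
    filter_band: tuple[float, float] | None = (0.5, 30.0)
    baseline: tuple[float, float] = (-200.0, 0.0)
    exclude_threshold: float = 100.0
    exclude_max_bad_fraction: float = 0.2
    pool: tuple[str, ...] = POOL_DEFAULT
    r_scale: float = DEFAULT_R_SCALE
    n_boot: int = 2000
    time_decim: int = 1
    write_epochs: bool = False
    figures: bool = True


def _effects_to_json(effects: dict) -> dict:
    out = {}
    for pair, effs in effects.items():
        out["|".join(pair)] = [
            {"window": list(e.window), "amplitude": e.amplitude,
             "pattern": None if e.pattern is None else list(e.pattern)}
            for e in effs
        ]
    return out


def _effects_from_json(obj: dict) -> dict:
    out = {}
    for key, effs in obj.items():
        pair = tuple(key.split("|"))
        out[pair] = [
            EffectSpec(
                window=tuple(e["window"]),
                amplitude=float(e["amplitude"]),
                pattern=None if e.get("pattern") is None else np.asarray(e["pattern"]),
            )
            for e in effs
        ]
    return out


def load_config(path_or_dict: str | Path | dict) -> tuple[GeneratorConfig, DecoderConfig, PipelineConfig]:
    """Load a keyed JSON run configuration (generator / decoder / pipeline)."""
    if isinstance(path_or_dict, (str, Path)):
        obj = json.loads(Path(path_or_dict).read_text(encoding="utf-8"))
    else:
        obj = dict(path_or_dict)
    gen_kwargs = dict(obj.get("generator", {}))
    if "effects" in gen_kwargs:
        gen_kwargs["effects"] = _effects_from_json(gen_kwargs["effects"])
    for key in ("channels", "epoch_window"):
        if key in gen_kwargs:
            gen_kwargs[key] = tuple(gen_kwargs[key])
    gen = GeneratorConfig(**gen_kwargs)
    dec = DecoderConfig(**obj.get("decoder", {}))
    pipe_kwargs = dict(obj.get("pipeline", {}))
    for key in ("condition_pair", "filter_band", "baseline", "pool"):
        if key in pipe_kwargs and pipe_kwargs[key] is not None:
            pipe_kwargs[key] = tuple(pipe_kwargs[key])
    pipe = PipelineConfig(**pipe_kwargs)
    return gen, dec, pipe


def _config_snapshot(gen: GeneratorConfig | None, dec: DecoderConfig, pipe: PipelineConfig) -> dict:
    snap: dict[str, Any] = {"decoder": asdict(dec), "pipeline": asdict(pipe)}
    if gen is not None:
        g = asdict(gen)
        g["effects"] = _effects_to_json(gen.effects)
        g["components"] = [
            {"name": c.name, "latency": c.latency, "width": c.width,
             "amplitude": c.amplitude, "topography": list(c.topography)}
            for c in gen.components
        ]
        snap["generator"] = g
    return json.loads(json.dumps(snap, default=_jsonable))


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, out: Path, config: dict, seed: int | None):
        self.out = out
        self.doc: dict[str, Any] = {
            "software": {"name": "erpmvpa", "version": __version__},
            "seed": seed,
            "config": config,
            "inputs": {},
            "stages": [],
        }

    def add_input(self, path: Path) -> None:
        self.doc["inputs"][str(path)] = _sha256(path)

    def stage(self, name: str, **details) -> None:
        self.doc["stages"].append({"name": name, "status": "ok", **details})
        self.write()

    def fail(self, name: str, err: BaseException) -> None:
        self.doc["stages"].append({"name": name, "status": "error", "error": str(err)})
        self.write()

    def write(self) -> None:
        (self.out / "manifest.json").write_text(
            json.dumps(self.doc, indent=1), encoding="utf-8"
        )


def _write_bf_tsv(bf: BFTimecourse, path: Path) -> None:
    cats = bf.categories()
    pd.DataFrame(
        {"time_ms": bf.times, "log10bf10": bf.log10bf10, "category": cats}
    ).to_csv(path, sep="\t", index=False)


def _write_decoding_tsv(result: DecodingResult, out: Path) -> None:
    cats = result.bf_vs_chance.categories()
    pd.DataFrame(
        {
            "time_ms": result.times,
            "group_accuracy": result.group_mean,
            "log10bf10": result.bf_vs_chance.log10bf10,
            "category": cats,
        }
    ).to_csv(out / "decoding.tsv", sep="\t", index=False)
    mat = pd.DataFrame(
        result.accuracy.T,
        columns=result.participants,
    )
    mat.insert(0, "time_ms", result.times)
    mat.to_csv(out / "decoding_matrix.tsv", sep="\t", index=False)


def _figures(out: Path) -> list[str]:
    """Render figures from the TSV outputs present in ``out``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    made = []
    erp_path = out / "erp_grand_mean.tsv"
    if erp_path.exists():
        df = pd.read_csv(erp_path, sep="\t")
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.fill_between(df["time_ms"], df["ci_low"], df["ci_high"], alpha=0.3)
        ax.plot(df["time_ms"], df["mean_uv"], lw=1.5)
        ax.axvline(0, color="k", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("pooled voltage (uV)")
        ax.set_title("grand mean ERP (95% bootstrap CI)")
        fig.savefig(out / "erp_grand_mean.png", dpi=120)
        plt.close(fig)
        made.append("erp_grand_mean.png")
    uni_path = out / "univariate_bf.tsv"
    if uni_path.exists():
        df = pd.read_csv(uni_path, sep="\t")
        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax.plot(df["time_ms"], df["log10bf10"], lw=1.0)
        for thr, lab in ((0.5, "BF=3"), (1.0, "BF=10"), (1.5, "BF=30")):
            ax.axhline(thr, color="grey", lw=0.5, ls="--")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("log10 BF10")
        ax.set_title("univariate ERP comparison")
        fig.savefig(out / "univariate_bf.png", dpi=120)
        plt.close(fig)
        made.append("univariate_bf.png")
    dec_path = out / "decoding.tsv"
    if dec_path.exists():
        df = pd.read_csv(dec_path, sep="\t")
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(df["time_ms"], 100 * df["group_accuracy"], lw=1.5)
        ax.axhline(50, color="k", lw=0.5, ls="--")
        strong = df["log10bf10"] > np.log10(30)
        ax.plot(
            df["time_ms"][strong],
            np.full(strong.sum(), 100 * df["group_accuracy"].max() + 2),
            ".", ms=3, color="firebrick", label="BF10 > 30",
        )
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("decoding accuracy (%)")
        ax.legend(loc="upper right", fontsize=8)
        ax.set_title("timepoint-wise decoding")
        fig.savefig(out / "decoding.png", dpi=120)
        plt.close(fig)
        made.append("decoding.png")
    return made


def _analyse(
    out: Path,
    manifest: _Manifest,
    epoch_sets: Sequence[EpochSet] | None,
    trials: TrialTable | None,
    human_label: str,
    dec: DecoderConfig,
    pipe: PipelineConfig,
) -> None:
    """Shared analysis chain for synthetic and supplied cohorts."""
    rng = np.random.default_rng([dec.seed, 21])

    if trials is not None:
        stage = "behaviour"
        try:
            write_trial_table(trials, out / "behaviour_trials.tsv")
            per_part = sdt_summary(trials, human_label=human_label)
            per_part.to_csv(out / "sdt_participant.tsv", sep="\t", index=False)
            grp = group_sdt(per_part, n_boot=pipe.n_boot, rng=rng)
            grp.to_csv(out / "sdt_group.tsv", sep="\t", index=False)
            manifest.stage(stage, n_trials=len(trials), n_participants=len(trials.participants))
        except Exception as err:
            manifest.fail(stage, err)
            raise PipelineStageError(stage, err) from err

    if epoch_sets is None:
        return

    stage = "preprocess"
    try:
        processed: list[EpochSet] = []
        for es in epoch_sets:
            if pipe.filter_band is not None:
                es = bandpass(es, *pipe.filter_band)
            es = baseline_correct(es, pipe.baseline)
            processed.append(es)
        kept, excluded = exclude_participants(
            processed, pipe.exclude_threshold, pipe.exclude_max_bad_fraction
        )
        if excluded:
            pd.DataFrame(excluded, columns=["participant", "reason"]).to_csv(
                out / "exclusions.tsv", sep="\t", index=False
            )
        manifest.stage(stage, n_kept=len(kept), n_excluded=len(excluded))
    except Exception as err:
        manifest.fail(stage, err)
        raise PipelineStageError(stage, err) from err

    stage = "univariate"
    try:
        pair = pipe.condition_pair
        pooled_by_cond = {c: [] for c in pair}
        pooled_all = []
        for es in kept:
            pt = pool_electrodes(es, pipe.pool)
            conds = np.asarray(pt.conditions, dtype=str)
            for c in pair:
                pooled_by_cond[c].append(pt.data[conds == c].mean(axis=0))
            pooled_all.append(pt.data.mean(axis=0))
        times = kept[0].times
        mean, lo, hi = grand_mean_ci(
            np.asarray(pooled_all), n_boot=pipe.n_boot, rng=rng
        )
        pd.DataFrame(
            {"time_ms": times, "mean_uv": mean, "ci_low": lo, "ci_high": hi}
        ).to_csv(out / "erp_grand_mean.tsv", sep="\t", index=False)
        bf = bf_timecourse(
            np.asarray(pooled_by_cond[pair[0]]),
            times,
            mode="paired",
            data2=np.asarray(pooled_by_cond[pair[1]]),
            r_scale=pipe.r_scale,
            comparison=f"{pair[0]} vs {pair[1]} pooled ERP",
        )
        _write_bf_tsv(bf, out / "univariate_bf.tsv")
        manifest.stage(stage, n_participants=len(kept), electrodes=list(pipe.pool))
    except Exception as err:
        manifest.fail(stage, err)
        raise PipelineStageError(stage, err) from err

    stage = "decode"
    try:
        result = decode_timecourse(
            kept, pipe.condition_pair, dec,
            time_decim=pipe.time_decim, r_scale=pipe.r_scale,
        )
        _write_decoding_tsv(result, out)
        n_strong = int(np.nansum(result.bf_vs_chance.bf10 > 30))
        manifest.stage(
            stage,
            n_participants=len(kept),
            n_timepoints=len(result.times),
            n_timepoints_bf_above_30=n_strong,
        )
    except Exception as err:
        manifest.fail(stage, err)
        raise PipelineStageError(stage, err) from err

    if pipe.figures:
        stage = "report"
        try:
            made = _figures(out)
            manifest.stage(stage, figures=made)
        except Exception as err:
            manifest.fail(stage, err)
            raise PipelineStageError(stage, err) from err


def run_synthetic(
    config: str | Path | dict | None,
    out_dir: str | Path,
    gen: GeneratorConfig | None = None,
    dec: DecoderConfig | None = None,
    pipe: PipelineConfig | None = None,
) -> Path:
    """Generate a synthetic cohort and run the full analysis chain on it.

    ``config`` may be a JSON file/dict with "generator", "decoder" and
    "pipeline" sections; alternatively pass the three config objects.
    Returns the results directory.
    """
    if config is not None:
        gen, dec, pipe = load_config(config)
    gen = gen or GeneratorConfig()
    dec = dec or DecoderConfig(seed=gen.seed)
    pipe = pipe or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, _config_snapshot(gen, dec, pipe), seed=gen.seed)

    stage = "generate"
    try:
        epoch_sets = simulate_epochs(gen, pipe.condition_pair)
        trials = simulate_behaviour(gen)
        if pipe.write_epochs:
            epo_dir = out / "epochs"
            for es in epoch_sets:
                write_epochs(es, epo_dir / es.participant)
        manifest.stage(
            stage,
            n_participants=len(epoch_sets),
            n_trials_per_participant=epoch_sets[0].n_trials,
        )
    except Exception as err:
        manifest.fail(stage, err)
        raise PipelineStageError(stage, err) from err

    _analyse(out, manifest, epoch_sets, trials, gen.human_label, dec, pipe)
    return out


def run_study(
    out_dir: str | Path,
    epochs_dir: str | Path | None = None,
    trial_table: str | Path | None = None,
    condition_labels: Sequence[str] = ("human", "android", "robot"),
    response_labels: Sequence[str] = ("human", "nonhuman"),
    human_label: str = "human",
    dec: DecoderConfig | None = None,
    pipe: PipelineConfig | None = None,
) -> Path:
    """Run the analysis chain on supplied (deposited or exported) data.

    ``epochs_dir`` holds one ``<participant>.bin``/``.json`` container per
    participant.  A behavioural-only run is possible by omitting the EEG.
    """
    if epochs_dir is None and trial_table is None:
        raise ValueError("need at least one of epochs_dir or trial_table")
    dec = dec or DecoderConfig()
    pipe = pipe or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, _config_snapshot(None, dec, pipe), seed=dec.seed)

    stage = "ingest"
    epoch_sets = None
    trials = None
    try:
        if epochs_dir is not None:
            sidecars = sorted(Path(epochs_dir).glob("*.json"))
            epoch_sets = [read_epochs(p) for p in sidecars]
            for p in sidecars:
                manifest.add_input(p)
                manifest.add_input(p.with_suffix(".bin"))
            if not epoch_sets:
                raise FileNotFoundError(f"no epoch containers in {epochs_dir}")
        if trial_table is not None:
            trials = read_trial_table(trial_table, condition_labels, response_labels)
            manifest.add_input(Path(trial_table))
        manifest.stage(
            stage,
            n_participants_eeg=0 if epoch_sets is None else len(epoch_sets),
            n_trials_behaviour=0 if trials is None else len(trials),
        )
    except Exception as err:
        manifest.fail(stage, err)
        raise PipelineStageError(stage, err) from err

    _analyse(out, manifest, epoch_sets, trials, human_label, dec, pipe)
    return out
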