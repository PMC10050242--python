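"""End-to-end orchestration: simulate -> preprocess -> features -> study.

Each stage reads and writes plain files under an output directory so it
can be re-run and inspected independently; :func:`run_all` chains them
and writes a manifest with configuration, seeds, per-file hashes and
timings. :func:`run_default_study` is the in-memory path used by the
acceptance script and the heavier tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, preprocess, synthetic, windowing
from .classifiers import ClassifierSpec, train_lstm
from .core_io import (
    STANDARD_REQUIRED_CHANNELS,
    EEGRecording,
    RunConfig,
    load_config,
    read_recording,
    write_recording,
)

__all__ = [
    "STAGES",
    "RunManifest",
    "run_all",
    "run_stage",
    "subject_power_series",
    "run_default_study",
]

log = logging.getLogger("winbci")

#: Pipeline stages in execution order (mirrors the processing flowchart:
#: acquisition, denoising/filter/threshold, power, datasets+classification).
STAGES = ("simulate", "preprocess", "features", "study", "stream")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)   # stage -> {files, seconds}

    def add_stage(self, name: str, out_files: list[Path], seconds: float) -> None:
        self.stages[name] = {
            "seconds": round(seconds, 3),
            "files": {str(p): _sha256(p) for p in out_files},
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages},
            indent=1,
        ))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def subject_power_series(
    rec: EEGRecording, cfg: RunConfig
) -> features.PowerSeries:
    """Preprocess one recording and extract its alpha power series."""
    clean, mask, _ = preprocess.preprocess_recording(rec, cfg)
    return features.alpha_power_series(clean, mask, cfg)


# ---------------------------------------------------------------------------
# file-based stages


def _stage_simulate(cfg: RunConfig, synth_cfg: synthetic.SynthConfig,
                    out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i in range(synth_cfg.n_subjects):
        rec, gt = synthetic.generate_subject(synth_cfg, i)
        path = out_dir / f"subject_{i:02d}.csv"
        write_recording(rec, path)
        truth = {
            "blink_intervals": gt.blink_intervals,
            "artifact_intervals": gt.artifact_intervals,
            "blink_weights": gt.blink_weights,
        }
        truth_path = out_dir / f"subject_{i:02d}.truth.json"
        truth_path.write_text(json.dumps(truth, indent=1))
        written += [path, path.with_suffix(".json"), truth_path]
        log.info("simulate: subject %d, %d samples, %d blinks, %d bursts",
                 i, rec.n_samples, len(gt.blink_intervals),
                 len(gt.artifact_intervals))
    return written


def _stage_preprocess(cfg: RunConfig, in_dir: Path, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in sorted(in_dir.glob("subject_*.csv")):
        rec = read_recording(path, required_channels=STANDARD_REQUIRED_CHANNELS)
        clean, mask, corr = preprocess.preprocess_recording(rec, cfg)
        out_csv = out_dir / path.name
        write_recording(clean, out_csv)
        kept = mask.kept
        # rejected runs as [start_s, end_s] intervals
        edges = np.flatnonzero(np.diff(np.concatenate(([True], kept, [True]))))
        rejected = [[float(a / rec.fs), float(b / rec.fs)]
                    for a, b in zip(edges[::2], edges[1::2])]
        report = {
            "blink_intervals": corr.blink_intervals,
            "weights": corr.weights,
            "th_rej": mask.th_rej,
            "kept_fraction": mask.kept_fraction,
            "rejected_intervals": rejected,
        }
        rpt = out_dir / (path.stem + ".report.json")
        rpt.write_text(json.dumps(report, indent=1))
        written += [out_csv, out_csv.with_suffix(".json"), rpt]
        log.info("preprocess: %s kept %.1f%%, %d blink intervals", path.stem,
                 100 * mask.kept_fraction, len(corr.blink_intervals))
    return written


def _stage_features(cfg: RunConfig, in_dir: Path, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path in sorted(in_dir.glob("subject_*.csv")):
        rec = read_recording(path)
        report = json.loads((in_dir / (path.stem + ".report.json")).read_text())
        kept = np.ones(rec.n_samples, dtype=bool)
        for a, b in report["rejected_intervals"]:
            kept[int(round(a * rec.fs)):int(round(b * rec.fs))] = False
        ps = features.alpha_power_series(rec, kept, cfg)
        df = pd.DataFrame({"time": ps.times, "p_o1": ps.p_o1,
                           "p_o2": ps.p_o2, "label": ps.labels})
        out_csv = out_dir / (path.stem + ".power.csv")
        df.to_csv(out_csv, index=False, float_format="%.17g")
        written.append(out_csv)
        log.info("features: %s -> %d power samples (%.5g Hz)",
                 path.stem, len(df), ps.fs_power)
    return written


def _load_power(path: Path) -> features.PowerSeries:
    df = pd.read_csv(path)
    fs_power = 1.0 / float(np.median(np.diff(df["time"].to_numpy())))
    return features.PowerSeries(
        times=df["time"].to_numpy(), p_o1=df["p_o1"].to_numpy(),
        p_o2=df["p_o2"].to_numpy(), labels=df["label"].to_numpy(dtype="<U6"),
        fs_power=fs_power,
    )


def _stage_study(cfg: RunConfig, in_dir: Path, out_dir: Path,
                 seed: int) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = [_load_power(p) for p in sorted(in_dir.glob("*.power.csv"))]
    result = evaluation.window_study(
        cohort, cfg.windows_s, ClassifierSpec("LSTM", "default"), cfg=cfg,
        J=cfg.repetitions, seed=seed,
    )
    roster_df, _ = evaluation.classifier_roster_study(
        cohort, cfg.classifiers, cfg=cfg, J=cfg.repetitions, seed=seed)
    t3 = out_dir / "table3.csv"
    result.table.to_csv(t3)
    t2 = out_dir / "table2.csv"
    roster_df.to_csv(t2)
    written = [t3, t2]
    wf = result.wilcoxon_frame()
    if wf is not None:
        t4 = out_dir / "table4.csv"
        wf.to_csv(t4)
        written.append(t4)
    summary = {
        "friedman_stat": result.friedman_stat,
        "friedman_p": result.friedman_p,
        "windows_s": list(result.windows_s),
        "lstm_accuracy_mean": result.table["accuracy_mean"].tolist(),
        "best_pointwise": roster_df["accuracy_mean"].idxmax(),
        "best_pointwise_accuracy": float(roster_df["accuracy_mean"].max()),
    }
    sj = out_dir / "summary.json"
    sj.write_text(json.dumps(summary, indent=1))
    written.append(sj)
    log.info("study: Friedman chi2=%.3f p=%.3g; LSTM acc %s",
             result.friedman_stat, result.friedman_p,
             np.round(result.table["accuracy_mean"].to_numpy(), 3))
    return written


def _stage_stream(cfg: RunConfig, synth_cfg: synthetic.SynthConfig,
                  power_dir: Path, out_dir: Path, seed: int) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    first = sorted(power_dir.glob("*.power.csv"))[0]
    ps = _load_power(first)
    window_s = max(w for w in cfg.windows_s if w <= 7.0) if cfg.windows_s else 7.0
    ds = windowing.make_sequences(ps, window_s, cfg.hop)
    model = train_lstm(ds, n_layers=cfg.lstm_layers, n_cells=cfg.lstm_cells,
                       epochs=cfg.lstm_epochs, lr=cfg.lstm_lr,
                       batch_size=cfg.lstm_batch, seed=seed)
    stream_rec, _ = synthetic.generate_stream(synth_cfg, 0)
    stream_ps = subject_power_series(stream_rec, cfg)
    res = evaluation.stream_classify(stream_ps, model, window_s)
    df = pd.DataFrame({"time": res.times, "predicted": res.predicted,
                       "true": res.true_states})
    out_csv = out_dir / "stream.csv"
    df.to_csv(out_csv, index=False)
    out_json = out_dir / "stream.json"
    out_json.write_text(json.dumps(
        {"window_s": window_s, "accuracy": res.accuracy,
         "transitions": res.transitions}, indent=1))
    log.info("stream: window %.1fs timeline accuracy %.3f", window_s,
             res.accuracy)
    return [out_csv, out_json]


def run_stage(
    stage: str,
    cfg: RunConfig,
    out_dir: str | Path,
    synth_cfg: synthetic.SynthConfig | None = None,
    seed: int = 0,
) -> list[Path]:
    """Execute one named stage against ``out_dir``'s layout; inputs must
    already exist for downstream stages."""
    out_dir = Path(out_dir)
    synth_cfg = synth_cfg or synthetic.SynthConfig(seed=seed)
    if stage == "simulate":
        return _stage_simulate(cfg, synth_cfg, out_dir / "sim")
    if stage == "preprocess":
        _require(out_dir / "sim", "simulate")
        return _stage_preprocess(cfg, out_dir / "sim", out_dir / "clean")
    if stage == "features":
        _require(out_dir / "clean", "preprocess")
        return _stage_features(cfg, out_dir / "clean", out_dir / "power")
    if stage == "study":
        _require(out_dir / "power", "features")
        return _stage_study(cfg, out_dir / "power", out_dir / "study", seed)
    if stage == "stream":
        _require(out_dir / "power", "features")
        return _stage_stream(cfg, synth_cfg, out_dir / "power",
                             out_dir / "stream", seed)
    raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")


def _require(path: Path, upstream: str) -> None:
    if not path.exists():
        raise FileNotFoundError(
            f"{path} missing: run the {upstream!r} stage first")


def run_all(
    config_path: str | Path | None,
    out_dir: str | Path,
    seed: int = 0,
    synth_cfg: synthetic.SynthConfig | None = None,
) -> RunManifest:
    """Run every stage in order and write ``manifest.json``."""
    cfg = load_config(config_path) if config_path else RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    synth_cfg = synth_cfg or synthetic.SynthConfig(seed=seed)
    manifest = RunManifest(config=cfg.to_dict(), seed=seed)
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            files = run_stage(stage, cfg, out_dir, synth_cfg, seed)
        except Exception:
            manifest.save(out_dir / "manifest.json")
            log.error("pipeline aborted in stage %r", stage)
            raise
        manifest.add_stage(stage, files, time.perf_counter() - t0)
    manifest.save(out_dir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# in-memory study (acceptance path)


def run_default_study(
    seed: int = 0,
    n_subjects: int = 13,
    windows_s: tuple[float, ...] = (1.0, 2.0, 4.0, 7.0, 10.0),
    J: int = 5,
    cfg: RunConfig | None = None,
    synth_cfg: synthetic.SynthConfig | None = None,
    include_roster: bool = True,
):
    """Generate the default cohort, run the LSTM window study and (optionally)
    the classical roster; returns a dict of results.

    Problem sizes (13 subjects, 5 windows, J=5 splits, class-capped
    training sets) keep the full study in the minutes range on one CPU.
    """
    cfg = cfg or RunConfig(windows_s=windows_s, repetitions=J, seed=seed)
    synth_cfg = synth_cfg or synthetic.SynthConfig(seed=seed)
    if synth_cfg.n_subjects != n_subjects:
        synth_cfg = replace(synth_cfg, n_subjects=n_subjects)
    cohort = []
    for i in range(n_subjects):
        rec, _ = synthetic.generate_subject(synth_cfg, i)
        cohort.append(subject_power_series(rec, cfg))
        log.info("cohort: subject %d power series ready", i)
    result = evaluation.window_study(
        cohort, windows_s, ClassifierSpec("LSTM", "default"), cfg=cfg, J=J,
        seed=seed)
    out = {"window_study": result, "cohort": cohort, "cfg": cfg,
           "synth_cfg": synth_cfg}
    if include_roster:
        roster_df, roster_acc = evaluation.classifier_roster_study(
            cohort, cfg.classifiers, cfg=cfg, J=J, seed=seed)
        out["roster"] = roster_df
        out["roster_accuracy"] = roster_acc
    return out
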