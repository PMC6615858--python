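"""Configuration, container I/O and orchestration of full analysis runs.

A run is driven by a YAML configuration (validated against a pydantic
schema) and proceeds through the stages

    simulate -> preprocess -> decode -> stats -> rsa -> tuning -> controls
    -> report

each of which reads the previous stage's files and writes its own, together
with a manifest recording parameters, seeds, wall-clock times and SHA-256
digests of every output, so identical configurations reproduce identical
derived files.

Epoched data live in an HDF5 container::

    /data                      epochs x channels x time
    /time                      ms relative to onset
    /labels/color              class angle per epoch
    /labels/motion             class angle per epoch
    /labels/sequence_position
    /labels/luminance
    /channels/name, /channels/area, /channels/signal_class

Confusion tensors are stored as ``/confusion`` (T x K x K), ``/time`` and
``/class_angles`` plus metadata attributes.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import controls as ctl
from . import decode as dec
from . import rsa as rsa_mod
from . import stats as st
from . import synthdata as sd
from . import tuning as tun
from .containers import ConfusionTensor, EpochedData, make_channel_table
from .preprocess import analysis_bandpass

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "load_config",
    "write_epochs",
    "read_epochs",
    "write_confusion",
    "read_confusion",
    "run_stage",
    "run_all",
    "STAGES",
]


class SchemaError(ValueError):
    """Raised when a container file violates the expected layout."""


# --------------------------------------------------------------------------
# configuration schema


class PopulationSpec(BaseModel):
    area: str = "V1like"
    n_units: int = Field(12, ge=1)
    signal_class: str = "MUA"
    tuned_feature: Literal["color", "motion"] = "color"
    tuning_shape: Literal["unimodal", "bimodal", "untuned"] = "unimodal"
    amplitude: float = Field(1.0, ge=0)
    kappa: float = Field(2.0, gt=0)
    onset_latency: float = Field(80.0, ge=0)
    kernel_width: float = Field(40.0, gt=0)
    noise_sd: float = Field(0.35, ge=0)
    baseline: float = 0.0
    luminance_gain: float = 0.0

    def to_config(self) -> sd.PopulationConfig:
        return sd.PopulationConfig(**self.model_dump())


class DecodeSpec(BaseModel):
    feature: Literal["color", "motion"] = "color"
    n_folds: int = Field(10, ge=2)
    shrinkage: float = Field(0.1, ge=0, le=1)
    oversample: bool = False
    stratify_by_sequence_position: bool = False


class WindowsSpec(BaseModel):
    epoch: tuple[float, float] = (-250.0, 500.0)
    step: float = Field(10.0, gt=0)
    rsa: tuple[float, float] = (50.0, 250.0)


class PermutationSpec(BaseModel):
    cluster: int = Field(10000, ge=1)
    rsa: int = Field(10000, ge=1)
    latency: int = Field(10000, ge=1)
    luminance_shuffle: int = Field(100, ge=0)


class PreprocessSpec(BaseModel):
    analysis_bandpass: bool = False
    average_reference: bool = False


class PipelineConfig(BaseModel):
    seed: int = 0
    n_sessions: int = Field(8, ge=1)
    n_events_per_session: int = Field(2000, ge=1)
    stimulus: Literal["A", "B"] = "B"
    populations: list[PopulationSpec] = Field(default_factory=lambda: [PopulationSpec()])
    decode: DecodeSpec = DecodeSpec()
    preprocess: PreprocessSpec = PreprocessSpec()
    windows: WindowsSpec = WindowsSpec()
    permutations: PermutationSpec = PermutationSpec()
    fast_factor: int = Field(1, ge=1)
    outdir: str = "runs/default"

    def perm_count(self, name: str) -> int:
        """Permutation count reduced by the fast factor (definitions unchanged)."""
        return max(1, getattr(self.permutations, name) // self.fast_factor)

    @property
    def stimulus_config(self) -> sd.StimulusConfig:
        return sd.CONFIG_A if self.stimulus == "A" else sd.CONFIG_B

    def time_axis(self) -> np.ndarray:
        lo, hi = self.windows.epoch
        n = int(round((hi - lo) / self.windows.step)) + 1
        return lo + self.windows.step * np.arange(n)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update(overrides)
    return PipelineConfig.model_validate(raw)


def apply_overrides(cfg: PipelineConfig, pairs: Sequence[str]) -> PipelineConfig:
    """Apply ``key=value`` overrides with dotted keys (e.g. decode.n_folds=2)."""
    data = cfg.model_dump()
    for pair in pairs:
        key, _, val = pair.partition("=")
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node[part]
        node[parts[-1]] = yaml.safe_load(val)
    return PipelineConfig.model_validate(data)


# --------------------------------------------------------------------------
# HDF5 containers

_LABEL_COLUMNS = {
    "color": "color_angle",
    "motion": "motion_angle",
    "sequence_position": "sequence_position",
    "luminance": "luminance_level",
}


def write_epochs(path: str | Path, epoched: EpochedData) -> None:
    """Write epoched data in the canonical HDF5 layout (lossless)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epoched.data)
        f.create_dataset("time", data=epoched.time)
        lab = f.create_group("labels")
        for name, col in _LABEL_COLUMNS.items():
            if col in epoched.trials.columns:
                lab.create_dataset(name, data=epoched.trials[col].to_numpy(float))
        ch = f.create_group("channels")
        str_dt = h5py.string_dtype()
        for col in ("name", "area", "signal_class"):
            ch.create_dataset(
                col, data=epoched.channels[col].astype(str).to_numpy(), dtype=str_dt
            )
        if "position" in epoched.channels.columns:
            ch.create_dataset(
                "position", data=epoched.channels["position"].to_numpy(float)
            )
        if "session_id" in epoched.trials.columns:
            f.attrs["session_id"] = str(epoched.trials["session_id"].iloc[0])


def read_epochs(path: str | Path) -> EpochedData:
    """Read the canonical epoch container; raises SchemaError on violations."""
    with h5py.File(path, "r") as f:
        missing = [k for k in ("data", "time", "labels", "channels") if k not in f]
        if missing:
            raise SchemaError(f"{path}: missing required entries {missing}")
        data = f["data"][()]
        time = f["time"][()]
        if data.ndim != 3 or data.shape[2] != time.size:
            raise SchemaError(f"{path}: /data shape does not match /time")
        trials = {}
        for name, col in _LABEL_COLUMNS.items():
            if name in f["labels"]:
                trials[col] = f["labels"][name][()]
        trials = pd.DataFrame(trials)
        if "session_id" in f.attrs:
            trials["session_id"] = f.attrs["session_id"]
        ch = f["channels"]
        for col in ("name", "area", "signal_class"):
            if col not in ch:
                raise SchemaError(f"{path}: missing /channels/{col}")
        channels = pd.DataFrame(
            {
                col: [x.decode() if isinstance(x, bytes) else str(x) for x in ch[col][()]]
                for col in ("name", "area", "signal_class")
            }
        )
        if "position" in ch:
            channels["position"] = ch["position"][()]
    return EpochedData(data, time, trials, channels)


def write_confusion(path: str | Path, conf: ConfusionTensor) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("confusion", data=conf.probs)
        f.create_dataset("time", data=conf.time)
        f.create_dataset("class_angles", data=conf.class_angles)
        for key, val in conf.meta.items():
            f.attrs[key] = val


def read_confusion(path: str | Path) -> ConfusionTensor:
    with h5py.File(path, "r") as f:
        for key in ("confusion", "time", "class_angles"):
            if key not in f:
                raise SchemaError(f"{path}: missing /{key}")
        return ConfusionTensor(
            f["confusion"][()],
            f["time"][()],
            f["class_angles"][()],
            meta=dict(f.attrs),
        )


# --------------------------------------------------------------------------
# manifest helpers


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _update_manifest(outdir: Path, stage: str, cfg: PipelineConfig, outputs, dt):
    mpath = outdir / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {
        "config_hash": hashlib.sha256(
            json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": cfg.seed,
        "stages": {},
    }
    manifest["stages"][stage] = {
        "wall_clock_s": round(dt, 3),
        "outputs": {str(p.relative_to(outdir)): _digest(p) for p in outputs},
    }
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _require(path: Path, needed_by: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' needs {path.name}; run stage '{produced_by}' first"
        )
    return path


# --------------------------------------------------------------------------
# stages


def _session_paths(outdir: Path, cfg: PipelineConfig, suffix: str):
    return [outdir / f"session{s:02d}{suffix}" for s in range(cfg.n_sessions)]


def _stage_simulate(cfg: PipelineConfig, outdir: Path):
    outputs = []
    pops = [p.to_config() for p in cfg.populations]
    for s in range(cfg.n_sessions):
        trials = sd.generate_stimulus_stream(
            cfg.stimulus_config,
            cfg.n_events_per_session,
            seed=cfg.seed + 1000 * s,
            session_id=s,
        )
        epochs = sd.simulate_tuned_responses(
            trials, pops, cfg.time_axis(), seed=cfg.seed + 1000 * s + 1
        )
        csv_path = outdir / f"session{s:02d}_trials.csv"
        trials.to_csv(csv_path, index=False)
        h5_path = outdir / f"session{s:02d}_epochs.h5"
        write_epochs(h5_path, epochs)
        outputs += [csv_path, h5_path]
    return outputs


def _stage_preprocess(cfg: PipelineConfig, outdir: Path):
    outputs = []
    for s in range(cfg.n_sessions):
        src = _require(
            outdir / f"session{s:02d}_epochs.h5", "preprocess", "simulate"
        )
        epochs = read_epochs(src)
        if cfg.preprocess.analysis_bandpass:
            epochs = analysis_bandpass(epochs)
        if cfg.preprocess.average_reference:
            epochs = EpochedData(
                epochs.data - epochs.data.mean(axis=1, keepdims=True),
                epochs.time,
                epochs.trials,
                epochs.channels,
            )
        dst = outdir / f"session{s:02d}_preproc.h5"
        write_epochs(dst, epochs)
        outputs.append(dst)
    return outputs


def _preproc_or_raw(outdir: Path, s: int, stage: str) -> Path:
    pre = outdir / f"session{s:02d}_preproc.h5"
    if pre.exists():
        return pre
    return _require(outdir / f"session{s:02d}_epochs.h5", stage, "simulate")


def _stage_decode(cfg: PipelineConfig, outdir: Path):
    outputs = []
    scheme = dec.CVScheme(
        n_folds=cfg.decode.n_folds,
        stratify_by_sequence_position=cfg.decode.stratify_by_sequence_position,
        oversample=cfg.decode.oversample,
        seed=cfg.seed,
    )
    for s in range(cfg.n_sessions):
        epochs = read_epochs(_preproc_or_raw(outdir, s, "decode"))
        for area in sorted(epochs.channels["area"].unique()):
            idx = np.flatnonzero(epochs.channels["area"] == area)
            conf = dec.crossvalidated_confusion(
                epochs.select_channels(idx),
                cfg.decode.feature,
                scheme,
                cfg.decode.shrinkage,
            )
            if conf.n_classes == 12:
                conf = dec.interpolate_confusion(conf)
            conf.meta.update(session=s, area=area)
            dst = outdir / f"session{s:02d}_{area}_confusion.h5"
            write_confusion(dst, conf)
            outputs.append(dst)
    return outputs


def _load_area_confusions(cfg, outdir, stage):
    by_area: dict[str, list[ConfusionTensor]] = {}
    for s in range(cfg.n_sessions):
        found = sorted(outdir.glob(f"session{s:02d}_*_confusion.h5"))
        if not found:
            raise FileNotFoundError(
                f"stage '{stage}' found no confusion tensors; run 'decode' first"
            )
        for path in found:
            conf = read_confusion(path)
            by_area.setdefault(str(conf.meta["area"]), []).append(conf)
    return by_area


def _stage_stats(cfg: PipelineConfig, outdir: Path):
    by_area = _load_area_confusions(cfg, outdir, "stats")
    results = {}
    cluster_raw = {}
    for area, confs in by_area.items():
        tcs = [
            dec.accuracy_timecourse(c, session_id=c.meta.get("session"))
            for c in confs
        ]
        entry = {}
        if len(tcs) >= 3:
            res = st.cluster_sign_permutation(
                tcs, n_perm=cfg.perm_count("cluster"), seed=cfg.seed
            )
            cluster_raw[area] = res
        normalized, included = st.normalize_and_select(tcs)
        kept = [tc for tc, ok in zip(normalized, included) if ok]
        if kept:
            group = st.group_latency(kept)
            if len(kept) >= 2 and group.defined:
                lo, hi = st.bootstrap_latency_ci(
                    kept, n_boot=cfg.perm_count("latency"), seed=cfg.seed
                )
                group.ci_low_ms, group.ci_high_ms = lo, hi
            entry["latency"] = {
                "latency_ms": group.latency_ms,
                "ci_low_ms": group.ci_low_ms,
                "ci_high_ms": group.ci_high_ms,
                "peak_time_ms": group.peak_time_ms,
                "n_included": int(sum(included)),
            }
        results[area] = entry
    for area, res in st.bonferroni_correct(cluster_raw).items():
        results[area]["clusters"] = [
            {
                "start_ms": c.start_ms,
                "end_ms": c.end_ms,
                "mass": c.mass,
                "p_value": c.p_value,
            }
            for c in res.clusters
        ]
    dst = outdir / "stats.json"
    dst.write_text(json.dumps({
        "seed": cfg.seed,
        "n_permutations": cfg.perm_count("cluster"),
        "cluster_alpha": 0.01,
        "areas": results,
    }, indent=2))
    return [dst]


def _stage_rsa(cfg: PipelineConfig, outdir: Path):
    by_area = _load_area_confusions(cfg, outdir, "rsa")
    reps = {
        area: rsa_mod.time_average_confusion(
            ConfusionTensor(
                np.mean([c.probs for c in confs], axis=0),
                confs[0].time,
                confs[0].class_angles,
            ),
            window=cfg.windows.rsa,
            descriptor=area,
        )
        for area, confs in by_area.items()
    }
    rows = []
    areas = sorted(reps)
    for i, a in enumerate(areas):
        for b in areas[i + 1 :]:
            res = rsa_mod.rsa_permutation_test(
                reps[a], reps[b], n_perm=cfg.perm_count("rsa"), seed=cfg.seed
            )
            rows.append({"entity_a": a, "entity_b": b, "r": res.r, "p": res.p})
    dst = outdir / "rsa_similarity.csv"
    pd.DataFrame(rows, columns=["entity_a", "entity_b", "r", "p"]).to_csv(
        dst, index=False
    )
    return [dst]


def _stage_tuning(cfg: PipelineConfig, outdir: Path):
    by_area = _load_area_confusions(cfg, outdir, "tuning")
    rows = []
    for area, confs in by_area.items():
        indices = []
        for c in confs:
            rep = rsa_mod.time_average_confusion(c, window=cfg.windows.rsa)
            bi = tun.bimodality_index(tun.collapse_to_tuning(rep))
            indices.append(bi.value)
        p = tun.bimodality_group_test(indices) if len(indices) >= 3 else np.nan
        rows.append(
            {
                "entity": area,
                "mean_bimodality": float(np.mean(indices)),
                "group_p": p,
                "n_sessions": len(indices),
            }
        )
    dst = outdir / "bimodality.csv"
    pd.DataFrame(rows).to_csv(dst, index=False)
    return [dst]


def _stage_controls(cfg: PipelineConfig, outdir: Path):
    # luminance control on a dedicated two-level simulated session
    pops = [p.to_config() for p in cfg.populations]
    trials = sd.generate_stimulus_stream(
        cfg.stimulus_config,
        cfg.n_events_per_session,
        seed=cfg.seed + 77,
        session_id="lum",
        luminance_levels=(1, 2),
    )
    epochs = sd.simulate_tuned_responses(
        trials, pops, cfg.time_axis(), seed=cfg.seed + 78
    )
    lum = ctl.luminance_crossclassification(
        epochs,
        n_shuffle=cfg.perm_count("luminance_shuffle"),
        seed=cfg.seed,
    )
    eye = sd.generate_eye_traces(seed=cfg.seed + 79)
    eq = ctl.equiluminance_from_eyetraces(eye)
    dst = outdir / "controls.json"
    dst.write_text(
        json.dumps(
            {
                "luminance": {
                    mode: {
                        "accuracy": r.accuracy,
                        "shuffle_p": None if np.isnan(r.shuffle_p) else r.shuffle_p,
                    }
                    for mode, r in lum.items()
                },
                "equiluminance": {
                    "L_estimate": eq.L_estimate,
                    "slope": eq.slope,
                    "r_squared": eq.r_squared,
                },
            },
            indent=2,
        )
    )
    return [dst]


def _stage_report(cfg: PipelineConfig, outdir: Path):
    report = {"config": cfg.model_dump(), "results": {}}
    for name, path in [
        ("stats", outdir / "stats.json"),
        ("controls", outdir / "controls.json"),
    ]:
        if path.exists():
            report["results"][name] = json.loads(path.read_text())
    for name, path in [
        ("rsa", outdir / "rsa_similarity.csv"),
        ("tuning", outdir / "bimodality.csv"),
    ]:
        if path.exists():
            report["results"][name] = pd.read_csv(path).to_dict(orient="records")
    dst = outdir / "report.json"
    dst.write_text(json.dumps(report, indent=2, default=str))
    return [dst]


STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "decode": _stage_decode,
    "stats": _stage_stats,
    "rsa": _stage_rsa,
    "tuning": _stage_tuning,
    "controls": _stage_controls,
    "report": _stage_report,
}


def run_stage(stage: str, cfg: PipelineConfig, outdir: str | Path | None = None):
    """Run one named stage, writing outputs and a manifest entry."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _time.perf_counter()
    outputs = STAGES[stage](cfg, outdir)
    _update_manifest(outdir, stage, cfg, outputs, _time.perf_counter() - t0)
    return outputs


def run_all(cfg: PipelineConfig, outdir: str | Path | None = None):
    """Run every stage in order."""
    outputs = []
    for stage in STAGES:
        outputs += run_stage(stage, cfg, outdir)
    return outputs
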