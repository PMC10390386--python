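"""End-to-end synthetic study orchestration.

Runs, from one config: cohort simulation -> model fitting -> uncertainty
filtering -> pupil synthesis -> preprocessing -> per-bin statistics, writing
plain-text artifacts and a provenance manifest.  Every stage draws from an
independent substream spawned from the master seed, so adding participants
or rerunning a stage never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fitting, preprocess, pupilgen, stats, task
from .agents import build_agent
from .hmm import ESTIMATE_COLUMNS, HMMParams, run_filter

__all__ = ["StudyConfig", "run_study", "load_config"]

_STAGES = ("simulate", "fit", "filter", "pupilgen", "preprocess", "stats")


@dataclass
class StudyConfig:
    condition: str = "exp2a"
    cohort_size: int = 8
    master_seed: int = 0
    agent_model: str = "hmm"
    agent_theta: list = field(default_factory=lambda: [1.0, 1.0, 1.0, 30.0, 10.0])
    fit_models: list = field(default_factory=lambda: ["hmm", "rescorla_wagner", "no_reversal"])
    fit_n_starts: int = 4
    fit_n_particles: int = 500
    filter_n_particles: int = 5000
    pupil: dict | None = field(default_factory=dict)  # PupilGenSpec overrides; None disables
    stats_predictors: list = field(default_factory=lambda: ["state_change_probability"])
    stats_n_perm: int = 100
    stats_alpha: float = 0.05


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return StudyConfig(**raw)


def _spawn_seed(master: int, *tags) -> int:
    h = hashlib.sha256(("|".join(map(str, (master,) + tags))).encode()).digest()
    return int.from_bytes(h[:4], "little")


def _stage_done(outdir: Path, stage: str) -> bool:
    return (outdir / f".{stage}.done").exists()


def _mark_done(outdir: Path, stage: str) -> None:
    (outdir / f".{stage}.done").write_text(time.strftime("%Y-%m-%dT%H:%M:%S"))


def run_study(config: StudyConfig, outdir, log=print) -> Path:
    """Run all stages into ``outdir``; completed stages are skipped on rerun."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = task.named_condition(config.condition)
    seed = config.master_seed
    participants = [f"p{i:02d}" for i in range(config.cohort_size)]

    def stage(name):
        def deco(fn):
            if _stage_done(outdir, name):
                log(f"[{name}] cached")
            else:
                t0 = time.time()
                fn()
                _mark_done(outdir, name)
                log(f"[{name}] done in {time.time() - t0:.1f}s")
        return deco

    @stage("simulate")
    def _simulate():
        for pid in participants:
            agent = build_agent(config.agent_model, config.agent_theta,
                                seed=_spawn_seed(seed, "agent", pid))
            s = task.generate_session(cfg, agent, _spawn_seed(seed, "session", pid))
            task.session_to_tsv(s, outdir / f"session_{pid}.tsv")

    @stage("fit")
    def _fit():
        rows = []
        for pid in participants:
            s = task.read_session_tsv(outdir / f"session_{pid}.tsv", cfg)
            for model in config.fit_models:
                spec = fitting.FitSpec(model, n_starts=config.fit_n_starts,
                                       seed=_spawn_seed(seed, "fit", pid, model),
                                       n_particles=config.fit_n_particles)
                fr = fitting.fit_mle(spec, s)
                d = fr.as_dict()
                d["participant"] = pid
                rows.append(d)
        pd.DataFrame(rows).to_csv(outdir / "fits.tsv", sep="\t", index=False)

    @stage("filter")
    def _filter():
        if config.agent_model == "hmm":
            params = HMMParams(*config.agent_theta[:4])
        else:  # fall back to a weakly informative observer
            params = HMMParams(1.0, 1.0, 1.0, 30.0)
        for pid in participants:
            s = task.read_session_tsv(outdir / f"session_{pid}.tsv", cfg)
            est = run_filter(params, s.x, s.y,
                             n_particles=config.filter_n_particles,
                             seed=_spawn_seed(seed, "filter", pid))
            est[ESTIMATE_COLUMNS].to_csv(outdir / f"estimates_{pid}.tsv",
                                         sep="\t", index=False)

    if config.pupil is None:
        _write_manifest(config, outdir, stages=("simulate", "fit", "filter"))
        return outdir

    @stage("pupilgen")
    def _pupilgen():
        spec = pupilgen.PupilGenSpec(**config.pupil)
        for pid in participants:
            s = task.read_session_tsv(outdir / f"session_{pid}.tsv", cfg)
            est = pd.read_csv(outdir / f"estimates_{pid}.tsv", sep="\t")
            rec = pupilgen.generate_recording(spec, s, est,
                                              seed=_spawn_seed(seed, "pupil", pid))
            pupilgen.recording_to_tsv(rec, outdir / f"samples_{pid}.tsv",
                                      outdir / f"events_{pid}.tsv")

    @stage("preprocess")
    def _preprocess():
        frames, reports = [], []
        for pid in participants:
            rec = pupilgen.read_recording_tsv(outdir / f"samples_{pid}.tsv",
                                              outdir / f"events_{pid}.tsv")
            cleaned = preprocess.clean_series(rec)
            epochs = preprocess.epoch_and_baseline(cleaned, rec.events)
            epochs.insert(0, "participant", pid)
            frames.append(epochs)
            reports.append({"participant": pid,
                            "percent_interpolated": cleaned.percent_interpolated})
        reports = pd.DataFrame(reports)
        excluded = preprocess.participant_exclusion(
            reports["percent_interpolated"].to_numpy())
        reports["excluded"] = excluded
        reports.to_csv(outdir / "preprocess_report.tsv", sep="\t", index=False)
        keep = set(reports.loc[~reports["excluded"], "participant"])
        epochs_all = pd.concat(frames, ignore_index=True)
        epochs_all = epochs_all[epochs_all["participant"].isin(keep)]
        epochs_all.to_csv(outdir / "epochs.csv", index=False)

    @stage("stats")
    def _stats():
        epochs = pd.read_csv(outdir / "epochs.csv")
        merged_frames = []
        for pid in epochs["participant"].unique():
            est = pd.read_csv(outdir / f"estimates_{pid}.tsv", sep="\t")
            events = pd.read_csv(outdir / f"events_{pid}.tsv", sep="\t")
            ev = events.merge(est, on="trial", suffixes=("", "_est"))
            sub = epochs[epochs["participant"] == pid].merge(
                ev[["trial", "feedback_sign", "state_change_probability",
                    "state_entropy"]], on="trial")
            merged_frames.append(sub)
        table = pd.concat(merged_frames, ignore_index=True)
        table = table.dropna(subset=config.stats_predictors)
        result = stats.cluster_permutation(
            table, config.stats_predictors,
            n_perm=config.stats_n_perm, alpha=config.stats_alpha,
            seed=_spawn_seed(seed, "stats"))
        result.bins.to_csv(outdir / "bin_stats.csv", index=False)
        with open(outdir / "clusters.json", "w") as fh:
            json.dump(result.to_json_dict(), fh, indent=2)

    _write_manifest(config, outdir, stages=_STAGES)
    return outdir


def _write_manifest(config: StudyConfig, outdir: Path, stages) -> None:
    import revlearn

    payload = asdict(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    manifest = {
        "config": payload,
        "config_sha256": digest,
        "stages": list(stages),
        "versions": {"revlearn": revlearn.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
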