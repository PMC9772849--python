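"""End-to-end orchestration: simulate -> extract -> bouts -> align -> windows.

A single :class:`RunConfig` (YAML/JSON round-trippable, unknown keys
rejected) drives all five stages into one run directory with a manifest
recording parameters and the SHA-256 of every output, so identical
config + seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import alignment, bouts, io as pio, pupil, synthetic
from .types import SessionData

log = logging.getLogger(__name__)

VERSION_TAG = "pavpupil-0.1.0"


class ExtractionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_confidence: float = 0.9
    max_gap_s: float = 0.5


class BoutSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: str = "mle"
    min_irts: int = 50
    min_licks_per_bout: int = 2


class AlignmentSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_width_s: float = 0.1
    window_s: Tuple[float, float] = (-3.0, 3.0)
    exclusion_s: float = 3.0


class RunConfig(BaseModel):
    """Full pipeline configuration; serializes losslessly to YAML/JSON."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "pavpupil_run"
    n_subjects_per_group: int = 2
    n_sessions: int = 1
    n_rewards: int = 20
    dose_blocks: Optional[List[str]] = None
    include_landmarks: bool = True
    version: str = VERSION_TAG
    generator: synthetic.GeneratorConfig = None  # type: ignore[assignment]
    extraction: ExtractionSettings = ExtractionSettings()
    bout: BoutSettings = BoutSettings()
    alignment: AlignmentSettings = AlignmentSettings()

    def model_post_init(self, __context) -> None:
        if self.generator is None:
            self.generator = synthetic.GeneratorConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)
        )


def demo_config(out_dir: Union[str, Path] = "pavpupil_demo", seed: int = 0) -> RunConfig:
    """Desk-scale demo: 2 subjects/group, 1 session, 20 rewards, 10 Hz video."""
    gen = synthetic.GeneratorConfig(seed=seed, frame_rate=10.0)
    return RunConfig(
        seed=seed, out_dir=str(out_dir), n_subjects_per_group=2,
        n_sessions=1, n_rewards=20, generator=gen,
    )


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Any stage failure raises with the stage name and the offending file
    in the message.
    """
    out = Path(config.out_dir)
    raw = out / "raw"
    derived = out / "derived"
    derived.mkdir(parents=True, exist_ok=True)
    stage_log: Dict[str, dict] = {}

    _stage("simulate")
    sim_manifest = synthetic.gen_experiment(
        config.n_subjects_per_group,
        config.n_sessions,
        config.dose_blocks,
        config.generator,
        raw,
        n_rewards=config.n_rewards,
        include_landmarks=config.include_landmarks,
    )
    stage_log["simulate"] = {"n_files": len(sim_manifest["files"])}

    sessions: List[SessionData] = []
    n_dropped_trials = 0
    n_excluded_onsets = 0
    bout_rows = []
    for sub in sim_manifest["subjects"]:
        subject = sub["subject"]
        for k, dose in enumerate(sub["doses"]):
            ses = f"ses{k + 1:02d}"
            sdir = raw / subject / ses
            ddir = derived / subject / ses
            ddir.mkdir(parents=True, exist_ok=True)
            try:
                schedule = pio.read_schedule(sdir / "schedule.json")
                licks = pio.read_licks(
                    sdir / "licks.csv", session_length=schedule.session_length
                )

                _stage(f"extract {subject}/{ses}")
                trace = None
                if config.include_landmarks:
                    lm = pio.read_landmarks(sdir / "landmarks.csv")
                    trace = pupil.extract_pupil_trace(
                        lm,
                        min_confidence=config.extraction.min_confidence,
                        max_gap_s=config.extraction.max_gap_s,
                    )
                    trace = pupil.zscore_session(trace)
                    pio.write_trace(trace, ddir / "trace.csv")

                _stage(f"bouts {subject}/{ses}")
                irts = bouts.compute_irts(licks)
                fit = bouts.fit_mixture(
                    irts,
                    method=config.bout.method,
                    min_irts=min(config.bout.min_irts, max(len(irts), 2)),
                    seed=config.seed,
                )
                labels = bouts.classify_licks(irts, fit)
                seg = bouts.segment_bouts(
                    licks, labels, min_licks_per_bout=config.bout.min_licks_per_bout
                )
                (ddir / "bout_params.json").write_text(
                    json.dumps(
                        {
                            "q": fit.q, "w": fit.w, "b": fit.b,
                            "loglik": fit.loglik, "method": fit.method,
                            "converged": bool(fit.converged), "n_irts": fit.n_irts,
                        },
                        indent=1,
                    )
                )
                pd.DataFrame(
                    {
                        "onset_s": np.round(seg.bout_onsets, 6),
                        "offset_s": np.round(seg.bout_offsets, 6),
                        "n_licks": seg.licks_per_bout,
                    }
                ).to_csv(ddir / "bouts.csv", index=False)

                _stage(f"align {subject}/{ses}")
                retained = alignment.filter_bout_onsets(
                    seg.bout_onsets, schedule, config.alignment.exclusion_s
                )
                n_excluded_onsets += len(seg.bout_onsets) - len(retained)
                for event_class, events in (
                    ("CS", schedule.cs_onsets),
                    ("US", schedule.us_times),
                    ("bout_onset", retained),
                ):
                    if len(events) == 0:
                        continue
                    mat = alignment.align_signal(
                        licks, events, config.alignment.window_s,
                        config.alignment.bin_width_s, event_class=event_class,
                    )
                    n_dropped_trials += mat.n_dropped
                    _write_aligned(mat, ddir / f"aligned_lick_{event_class}")
                    if trace is not None:
                        pmat = alignment.align_signal(
                            trace, events, config.alignment.window_s,
                            config.alignment.bin_width_s, event_class=event_class,
                        )
                        n_dropped_trials += pmat.n_dropped
                        _write_aligned(pmat, ddir / f"aligned_pupil_{event_class}")

                sessions.append(
                    SessionData(
                        subject=subject, session=k + 1, schedule=schedule,
                        licks=licks, pupil=trace,
                    )
                )
                bout_rows.append(
                    {
                        "subject": subject, "session": k + 1, "dose": dose,
                        "group": sub["group"], "q": fit.q, "w": fit.w, "b": fit.b,
                        "n_bouts": len(seg.bout_onsets),
                        "n_bouts_retained": len(retained),
                    }
                )
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed at session {subject}/{ses}: {exc}"
                ) from exc

    _stage("windows")
    table = alignment.build_window_table(sessions, config.alignment.bin_width_s)
    table.to_csv(derived / "windows.csv", index=False)
    pd.DataFrame(bout_rows).to_csv(derived / "bout_summary.csv", index=False)
    stage_log["align"] = {
        "dropped_trials": n_dropped_trials,
        "excluded_bout_onsets": n_excluded_onsets,
    }
    stage_log["windows"] = {"n_rows": len(table)}

    files = {
        str(p.relative_to(out)): _sha(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "run_manifest.json"
    }
    manifest = {
        "version": config.version,
        "config": json.loads(config.model_dump_json()),
        "stages": stage_log,
        "files": files,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_aligned(mat: alignment.AlignedMatrix, stem: Path) -> None:
    cols = {"event_time_s": np.round(mat.event_times, 6)}
    for j, c in enumerate(mat.bin_centers):
        cols[f"t{c:+.3f}"] = np.round(mat.values[:, j], 6)
    pd.DataFrame(cols).to_csv(stem.with_suffix(".csv"), index=False)
    meta = {
        "event_class": mat.event_class,
        "signal_kind": mat.signal_kind,
        "bin_edges_s": [round(float(e), 6) for e in mat.bin_edges],
        "n_trials": int(mat.n_trials),
        "n_dropped": int(mat.n_dropped),
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
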