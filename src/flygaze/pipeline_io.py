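"""Trial/transform file formats, run configuration, and the pipeline driver.

Trials are stored as CSV (columns ``time_s, stimulus_deg, body_deg,
head_deg``) with an optional JSON sidecar carrying the simulation config,
the perturbation spec, the ground-truth loop (synthetic trials), and the
injected-saccade log. Frequency responses and saccade tables are CSV. A run
writes a manifest with the configuration, every seed, and a SHA-256 hash of
each output file so reruns can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis, decompose, flysim, saccades, sysid
from .perturbations import SINGLE_SINE_FREQS, SINGLE_SINE_VNORM, PerturbationSpec
from .signals import TimeSeries

log = logging.getLogger("flygaze")

FLOAT_FMT = "%.12g"
MAX_NAN_GAP_S = 0.1
TIME_UNIFORMITY_TOL = 1e-6


# ---------------------------------------------------------------------------
# trial files
# ---------------------------------------------------------------------------

def write_trial(trial: flysim.Trial, path) -> None:
    """Write a trial as CSV plus a JSON sidecar (same stem, .json)."""
    path = Path(path)
    df = pd.DataFrame({
        "time_s": trial.R.time,
        "stimulus_deg": trial.R.values,
        "body_deg": trial.B.values,
        "head_deg": trial.H.values,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    sidecar = {}
    if trial.config is not None:
        sidecar["config"] = trial.config.to_dict()
    if trial.spec is not None:
        sidecar["spec"] = trial.spec.to_dict()
    if trial.truth is not None:
        sidecar["truth"] = trial.truth.to_dict()
    if trial.truth_events is not None:
        sidecar["truth_events"] = trial.truth_events
    if sidecar:
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True))


def read_trial(path) -> flysim.Trial:
    """Read a trial CSV (+ optional JSON sidecar) back into a Trial.

    The time column must be uniform to 1e-6 s. NaN gaps up to 0.1 s are
    linearly interpolated (with a logged count); longer runs are rejected.
    A missing body column is read as a body-fixed trial with B = 0.
    """
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: trial too short")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.ptp(dt) > TIME_UNIFORMITY_TOL:
        raise ValueError(f"{path}: non-uniform or non-monotone time column")
    fs = 1.0 / float(np.mean(dt))
    max_gap = int(np.ceil(MAX_NAN_GAP_S * fs))

    def column(name: str) -> np.ndarray:
        y = df[name].to_numpy(dtype=float)
        isnan = np.isnan(y)
        if isnan.any():
            runs = np.diff(np.flatnonzero(np.diff(
                np.concatenate([[0], isnan.view(np.int8), [0]]))).reshape(-1, 2),
                axis=1)
            if runs.size and runs.max() > max_gap:
                raise ValueError(
                    f"{path}: NaN run longer than {MAX_NAN_GAP_S} s in {name}")
            good = ~isnan
            if isnan[0] or isnan[-1]:
                raise ValueError(f"{path}: NaN at trial boundary in {name}")
            y = y.copy()
            y[isnan] = np.interp(t[isnan], t[good], y[good])
            log.info("interpolated %d NaN sample(s) in %s of %s",
                     int(isnan.sum()), name, path.name)
        return y

    r = column("stimulus_deg")
    h = column("head_deg")
    body_fixed = "body_deg" not in df.columns
    b = np.zeros_like(r) if body_fixed else column("body_deg")
    sidecar = path.with_suffix(".json")
    config = spec = truth = truth_events = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "config" in meta:
            config = flysim.SimulationConfig.from_dict(meta["config"])
        if "spec" in meta:
            spec = PerturbationSpec.from_dict(meta["spec"])
        if "truth" in meta:
            truth = flysim.LoopComponents.from_dict(meta["truth"])
        truth_events = meta.get("truth_events")
    if config is None and body_fixed:
        config = flysim.SimulationConfig(mode="body_fixed")
    mk = lambda v: TimeSeries(v, fs, t0=float(t[0]))
    return flysim.Trial(R=mk(r), H=mk(h), B=mk(b), E=mk(r - h - b),
                        spec=spec, config=config, truth=truth,
                        truth_events=truth_events)


def frequency_response_frame(fr: sysid.FrequencyResponse) -> pd.DataFrame:
    none_to_nan = lambda a: np.full(fr.freqs.size, np.nan) if a is None else a
    return pd.DataFrame({
        "freq_hz": fr.freqs,
        "gain": fr.gain,
        "gain_sd": none_to_nan(fr.gain_sd),
        "phase_deg": fr.phase,
        "phase_sd_deg": none_to_nan(fr.phase_sd_circ),
        "comp_err": np.abs(1 - fr.values),
        "comp_err_sd": none_to_nan(fr.comp_err_sd),
        "coherence": none_to_nan(fr.coherence),
        "n_flies": fr.n_flies,
        "valid": fr.valid.astype(int),
    })


def write_frequency_response(fr: sysid.FrequencyResponse, path) -> None:
    frequency_response_frame(fr).to_csv(path, index=False, float_format=FLOAT_FMT)


def events_frame(events: list, fly_id: str = "", trial_id: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "fly_id": fly_id, "trial_id": trial_id,
        "onset_s": e.onset, "offset_s": e.offset,
        "amplitude_deg": e.amplitude, "peak_velocity_dps": e.peak_velocity,
        "duration_s": e.duration,
        "tau_s": e.tau if e.tau is not None else np.nan,
        "r2": e.fit_quality if e.fit_quality is not None else np.nan,
        "direction": e.direction,
    } for e in events])


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    n_flies: int = 3
    stim_freqs: tuple = SINGLE_SINE_FREQS
    v_norm: float = SINGLE_SINE_VNORM
    trial_duration: float = analysis.DEFAULT_TRIAL_DURATION
    noise_std: float = 0.25
    head_limit: float = 15.0
    mech_gate_external: float = 0.1
    coherence_floor: float = 0.2
    saccade_vel_threshold: float = 100.0
    saccade_tau_free: float = 0.2
    saccade_tau_ratio: float = 8.0
    saccade_n_trials: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stim_freqs"] = list(self.stim_freqs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stim_freqs" in d:
            d["stim_freqs"] = tuple(d["stim_freqs"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Simulate -> identify -> decompose -> replay -> saccades, to files.

    Writes per-fly and averaged transform tables, the three-term
    decomposition table, the predictions, the Gm estimates and gating
    contrast, the saccade event/statistics tables, and a manifest with the
    config and a SHA-256 hash of every output. Rerunning with the same
    config reproduces every file bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_frame(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format=FLOAT_FMT)
        written.append(path)

    def save_fr(fr, name):
        path = out / name
        write_frequency_response(fr, path)
        written.append(path)

    components = flysim.default_fly()
    freqs = np.asarray(config.stim_freqs, dtype=float)

    log.info("stage=identify n_flies=%d freqs=%s", config.n_flies,
             list(config.stim_freqs))
    population = analysis.identify_population(
        components, config.n_flies, config.noise_std, config.seed,
        stim_freqs=config.stim_freqs, v_norm=config.v_norm,
        duration=config.trial_duration, head_limit=config.head_limit)
    for i, fly in enumerate(population["per_fly"]):
        for key, fr in fly.items():
            save_fr(fr, f"fly{i:02d}_{key}.csv")
    for key, fr in population["averaged"].items():
        save_fr(fr, f"avg_{key}.csv")

    log.info("stage=decompose")
    avg = population["averaged"]
    gm = decompose.estimate_Gm_self(avg["G_head_V"], avg["H_over_R_free"],
                                    avg["B_over_R"])
    full = decompose.closed_loop_head_free(avg["G_head_V"], gm.primary,
                                           avg["B_over_R"])
    terms = pd.DataFrame({
        "freq_hz": freqs,
        "head_visual_gain": full.head_visual.gain,
        "head_visual_phase_deg": full.head_visual.phase,
        "body_visual_gain": full.body_visual.gain,
        "body_visual_phase_deg": full.body_visual.phase,
        "body_mech_gain": full.body_mechanosensory.gain,
        "body_mech_phase_deg": full.body_mechanosensory.phase,
        "sum_gain": full.total.gain,
        "sum_phase_deg": full.total.phase,
        "measured_H_over_R_gain": avg["H_over_R_free"].gain,
        "measured_H_over_R_phase_deg": avg["H_over_R_free"].phase,
    })
    save_frame(terms, "decomposition_terms.csv")
    save_fr(decompose.closed_loop_head_fixed(avg["G_head_V"]),
            "pred_head_fixed.csv")
    save_fr(decompose.predict_visual_only(avg["G_head_V"], avg["B_over_R"]),
            "pred_visual_only.csv")
    save_fr(decompose.predict_mechano_only(avg["G_head_VM"]),
            "pred_mechano_only.csv")
    save_fr(gm.primary, "gm_self.csv")
    weighting = decompose.feedback_weighting(avg["G_head_VM"], avg["G_head_V"])
    save_fr(weighting, "feedback_weighting.csv")

    log.info("stage=replay mech_gate=%.3g", config.mech_gate_external)
    replay = analysis.replay_study(
        components, config.mech_gate_external, config.n_flies,
        config.noise_std, config.seed + 77, stim_freqs=config.stim_freqs,
        v_norm=config.v_norm, duration=config.trial_duration)
    save_fr(replay["H_over_B"], "replay_H_over_B.csv")
    save_fr(replay["gm_estimate"], "gm_external.csv")
    contrast = pd.DataFrame({
        "freq_hz": freqs,
        "gm_self_gain": gm.primary.gain,
        "gm_external_gain": replay["gm_estimate"].gain,
        "gain_ratio_self_over_external":
            gm.primary.gain / replay["gm_estimate"].gain,
    })
    save_frame(contrast, "gating_contrast.csv")

    log.info("stage=saccades n_trials=%d/condition", config.saccade_n_trials)
    study = analysis.saccade_damping_study(
        config.saccade_tau_free, config.saccade_tau_ratio,
        config.saccade_n_trials, config.seed + 99,
        config.saccade_vel_threshold)
    for label, evts in study["events"].items():
        save_frame(events_frame(evts, fly_id=label), f"saccades_{label}.csv")
        save_frame(saccades.saccade_population_stats(evts),
                   f"saccade_stats_{label}.csv")
    save_frame(pd.DataFrame([study["comparison"]]), "saccade_group_tests.csv")

    manifest = {
        "config": config.to_dict(),
        "thresholds": {
            "saccade_vel_threshold_dps": config.saccade_vel_threshold,
            "coherence_floor": config.coherence_floor,
            "singularity_floor": decompose.SINGULARITY_FLOOR,
        },
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    log.info("stage=done files=%d", len(written) + 1)
    return out
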