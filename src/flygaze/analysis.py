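"""High-level studies: simulate a battery, identify transforms, recover the
hidden mechanosensory pathway, contrast gating, and run the saccade study.

These routines chain the simulator, the non-parametric system identification,
and the decomposition algebra into the standard analyses; the file-based
pipeline and the command-line interface are thin layers over them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import decompose, flysim, saccades, sysid
from .perturbations import SINGLE_SINE_FREQS, SINGLE_SINE_VNORM, single_sine_spec
from .signals import TimeSeries

DEFAULT_TRIAL_DURATION = 12.0  # s: 2 s transient discard + 10 s analysis window


def battery_trials(components: flysim.LoopComponents,
                   config: flysim.SimulationConfig,
                   stim_freqs=SINGLE_SINE_FREQS,
                   v_norm: float = SINGLE_SINE_VNORM,
                   duration: float = DEFAULT_TRIAL_DURATION) -> dict:
    """Simulate the single-sine battery; one trial per stimulus frequency."""
    trials = {}
    for k, f in enumerate(stim_freqs):
        spec = single_sine_spec(f, v_norm, duration, config.sample_rate)
        cfg = replace(config, seed=config.seed + k)
        trials[f] = flysim.simulate_trial(components, spec, cfg)
    return trials


def _analysis_window(trial: flysim.Trial) -> dict:
    """Preprocessed stimulus/response signals after transient discard."""
    t0 = trial.config.transient_discard if trial.config else 0.0
    out = {}
    for name in ("R", "H", "B"):
        out[name] = sysid.preprocess(getattr(trial, name).crop(t0))
    # retinal slip recomputed from the measured signals
    out["E"] = out["R"].with_values(
        out["R"].values - out["H"].values - out["B"].values)
    return out


def identify_fly(trials_free: dict, trials_fixed: dict, stim_freqs=None) -> dict:
    """Per-fly closed-loop transforms on the stimulus-frequency grid.

    ``trials_free``/``trials_fixed`` map stimulus frequency -> Trial. Returns
    the transforms the decomposition needs: Gv (error to head, body-fixed),
    GvM (error to head, body-free), H/R in both conditions, and B/R.
    """
    if stim_freqs is None:
        stim_freqs = sorted(trials_free)
    stim_freqs = list(stim_freqs)

    def battery_frf(trials, in_name, out_name):
        values = []
        for f in stim_freqs:
            sigs = _analysis_window(trials[f])
            fr = sysid.frf(sigs[in_name], sigs[out_name], [f])
            values.append(fr.at([f]).values[0])
        return sysid.FrequencyResponse(
            freqs=np.asarray(stim_freqs, dtype=float),
            values=np.asarray(values, dtype=complex))

    return {
        "G_head_V": battery_frf(trials_fixed, "E", "H"),
        "G_head_VM": battery_frf(trials_free, "E", "H"),
        "H_over_R_free": battery_frf(trials_free, "R", "H"),
        "H_over_R_fixed": battery_frf(trials_fixed, "R", "H"),
        "B_over_R": battery_frf(trials_free, "R", "B"),
    }


def identify_population(components: flysim.LoopComponents, n_flies: int,
                        noise_std: float = 0.25, seed: int = 0,
                        stim_freqs=SINGLE_SINE_FREQS,
                        v_norm: float = SINGLE_SINE_VNORM,
                        duration: float = DEFAULT_TRIAL_DURATION,
                        head_limit: float = 15.0) -> dict:
    """Simulate and identify a population of synthetic animals.

    Each animal contributes one body-free and one body-fixed battery with
    independent tracking noise; transforms are averaged across animals with
    circular statistics on phase. Returns per-fly and averaged transforms
    plus the generating components.
    """
    per_fly = []
    for i in range(n_flies):
        base = dict(noise_std_head=noise_std, noise_std_body=noise_std,
                    head_limit=head_limit, transient_discard=2.0)
        cfg_free = flysim.SimulationConfig(mode="body_free",
                                           seed=seed + 1000 * i, **base)
        cfg_fixed = flysim.SimulationConfig(mode="body_fixed",
                                            seed=seed + 1000 * i + 500, **base)
        trials_free = battery_trials(components, cfg_free, stim_freqs, v_norm,
                                     duration)
        trials_fixed = battery_trials(components, cfg_fixed, stim_freqs, v_norm,
                                      duration)
        per_fly.append(identify_fly(trials_free, trials_fixed, stim_freqs))
    averaged = {
        key: sysid.average_across_flies([fly[key] for fly in per_fly])
        for key in per_fly[0]
    }
    return {"per_fly": per_fly, "averaged": averaged, "components": components,
            "stim_freqs": np.asarray(stim_freqs, dtype=float)}


def recover_gm(population: dict) -> dict:
    """Estimate the hidden mechanosensory transform from a population study."""
    avg = population["averaged"]
    est = decompose.estimate_Gm_self(avg["G_head_V"], avg["H_over_R_free"],
                                     avg["B_over_R"])
    truth = flysim.closed_loop_truth(population["components"],
                                     population["stim_freqs"])
    return {"estimate": est, "truth_gm": truth["G_head_M"], "truth": truth}


def replay_study(components: flysim.LoopComponents, mech_gate: float,
                 n_flies: int = 5, noise_std: float = 0.25, seed: int = 0,
                 stim_freqs=SINGLE_SINE_FREQS,
                 v_norm: float = SINGLE_SINE_VNORM,
                 duration: float = DEFAULT_TRIAL_DURATION) -> dict:
    """Motor-replay study: impose body motion, identify H/B, estimate Gm.

    The imposed body motion per frequency is the closed-loop body response
    of the default loop to the matching single sine (the 'replayed' trace).
    The Gm estimate uses the exact replay-loop inversion ((1+Gv)*H/B).
    """
    stim_freqs = list(stim_freqs)
    truth = flysim.closed_loop_truth(components, np.asarray(stim_freqs))
    per_fly = []
    for i in range(n_flies):
        values = []
        for k, f in enumerate(stim_freqs):
            spec = single_sine_spec(f, v_norm, duration, 100.0)
            amp = spec.amplitudes[0] * np.abs(truth["B_over_R"][k])
            phase = np.angle(truth["B_over_R"][k])
            n = int(duration * 100)
            t = np.arange(n) / 100.0
            body = TimeSeries(amp * np.sin(2 * np.pi * f * t + phase), 100.0)
            cfg = flysim.SimulationConfig(
                mode="motor_replay", mech_gate=mech_gate,
                noise_std_head=noise_std, transient_discard=2.0,
                seed=seed + 1000 * i + k)
            trial = flysim.simulate_motor_replay(components, body, cfg)
            b = sysid.preprocess(trial.B.crop(cfg.transient_discard))
            h = sysid.preprocess(trial.H.crop(cfg.transient_discard))
            values.append(sysid.frf(b, h, [f]).at([f]).values[0])
        per_fly.append(sysid.FrequencyResponse(
            freqs=np.asarray(stim_freqs, dtype=float),
            values=np.asarray(values, dtype=complex)))
    h_over_b = sysid.average_across_flies(per_fly)
    gv_truth = sysid.FrequencyResponse(freqs=np.asarray(stim_freqs, dtype=float),
                                       values=truth["G_head_V"])
    gm = decompose.estimate_Gm_external(gv_truth, h_over_b,
                                        sign_convention="rederived")
    return {"H_over_B": h_over_b, "gm_estimate": gm, "truth": truth}


def gating_contrast(components: flysim.LoopComponents | None = None,
                    gate_external: float = 0.1, n_flies: int = 3,
                    noise_std: float = 0.1, seed: int = 0,
                    stim_freqs=(2.1, 3.5, 5.3)) -> dict:
    """|Gm| during self-generated vs externally generated body motion.

    Self-generated: closed-loop body-free/body-fixed batteries inverted with
    the decomposition algebra. External: motor replay with the mechanosensory
    gate at ``gate_external``. Returns both estimates and their gain ratio at
    the shared frequencies.
    """
    if components is None:
        components = flysim.default_fly()
    population = identify_population(components, n_flies, noise_std, seed,
                                     stim_freqs=stim_freqs)
    self_est = recover_gm(population)["estimate"].primary
    external = replay_study(components, gate_external, n_flies, noise_std,
                            seed + 77, stim_freqs=stim_freqs)
    ext_est = external["gm_estimate"]
    ratio = self_est.gain / ext_est.gain
    return {"gm_self": self_est, "gm_external": ext_est, "gain_ratio": ratio,
            "freqs": np.asarray(list(stim_freqs), dtype=float)}


def saccade_damping_study(tau_free: float = 0.2, tau_ratio: float = 8.0,
                          n_trials: int = 40, seed: int = 0,
                          vel_threshold: float = 100.0) -> dict:
    """Body-free vs body-fixed saccade damping comparison on synthetic trials.

    Generates both conditions (body-fixed return time constant =
    ``tau_ratio`` x the body-free one), detects saccades, fits post-saccade
    decay constants, and runs the group tests on tau.
    """
    events = {}
    for label, tau, offset in (("body_free", tau_free, 0),
                               ("body_fixed", tau_free * tau_ratio, 10 ** 6)):
        params = flysim.SaccadeGenParams(tau=tau)
        trials = flysim.generate_saccade_trials(params, n_trials,
                                                seed=seed + offset)
        evts = []
        for trial in trials:
            detected = saccades.detect_saccades(trial.H, vel_threshold)
            saccades.attach_taus(trial.H, detected)
            evts.extend(detected)
        events[label] = evts
    comparison = saccades.compare_groups(events["body_free"],
                                         events["body_fixed"], "tau")
    return {"events": events, "comparison": comparison,
            "tau_true": {"body_free": tau_free,
                         "body_fixed": tau_free * tau_ratio}}
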