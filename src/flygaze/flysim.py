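"""Closed-loop LTI simulator of head/body gaze stabilization.

The simulated animal minimizes retinal slip E = R - H - B, where R is the
visual perturbation, H the head angle (relative to the body) and B the body
angle. Four sensorimotor branches drive the loop: visual error to head
(G_head_V) and to body (G_body_V), each with a ~30 ms visual delay, and body
motion to head (G_head_M) and to body (G_body_M) mechanosensory branches with
a ~5 ms haltere delay. The head is clipped at the anatomical neck-joint limit
(+/-15 deg by default) and white Gaussian tracking noise is added to the
measured head/body angles.

Transfer functions are discretized by bilinear transform at an internal
simulation rate of 10x the recording rate (1 kHz for 100 Hz recordings) so
the 5 ms haltere delay is representable as an integer number of samples; the
result is decimated back to the recording rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .perturbations import PerturbationSpec
from .signals import TimeSeries

INTERNAL_OVERSAMPLING = 10
#: Passive neck coupling (unitless) used for the anesthetized replay variant;
#: a free constant chosen so passive head motion is a few percent of body motion.
PASSIVE_NECK_COUPLING = 0.03


# ---------------------------------------------------------------------------
# transfer functions with pure delay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DelayedTF:
    """Continuous-time rational transfer function with a pure delay.

    ``num``/``den`` are polynomial coefficients in s (highest power first);
    ``delay`` is in seconds.
    """

    num: tuple
    den: tuple
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("delay must be >= 0")
        object.__setattr__(self, "num", tuple(float(c) for c in self.num))
        object.__setattr__(self, "den", tuple(float(c) for c in self.den))

    def poles(self) -> np.ndarray:
        return np.roots(self.den) if len(self.den) > 1 else np.array([])

    def is_stable(self) -> bool:
        p = self.poles()
        return bool(np.all(p.real < 0)) if p.size else True

    def freq_response(self, freqs) -> np.ndarray:
        """Evaluate at s = 2j*pi*f, including the delay term e^{-s*tau}."""
        s = 2j * np.pi * np.asarray(freqs, dtype=float)
        resp = np.polyval(self.num, s) / np.polyval(self.den, s)
        return resp * np.exp(-s * self.delay)

    def __mul__(self, other: "DelayedTF") -> "DelayedTF":
        return DelayedTF(
            num=tuple(np.polymul(self.num, other.num)),
            den=tuple(np.polymul(self.den, other.den)),
            delay=self.delay + other.delay,
        )

    def scaled(self, k: float) -> "DelayedTF":
        return DelayedTF(num=tuple(k * np.asarray(self.num)), den=self.den,
                         delay=self.delay)

    def to_dict(self) -> dict:
        return {"num": list(self.num), "den": list(self.den), "delay_s": self.delay}

    @classmethod
    def from_dict(cls, d: dict) -> "DelayedTF":
        return cls(num=tuple(d["num"]), den=tuple(d["den"]), delay=d["delay_s"])


class _Branch:
    """Bilinear-discretized branch with an integer-sample input delay."""

    def __init__(self, tf: DelayedTF, fs: float):
        num, den = tf.num, tf.den
        if len(num) >= len(den) and len(den) == 1:
            # pure gain (possibly with delay)
            self.A = np.zeros((0, 0))
            self.B = np.zeros((0,))
            self.C = np.zeros((0,))
            self.D = float(num[0] / den[0]) if len(num) == 1 else None
            if self.D is None:
                raise ValueError("improper transfer function")
        else:
            A, B, C, D = sps.tf2ss(num, den)
            (Ad, Bd, Cd, Dd, _) = sps.cont2discrete(
                (A, B, C, D), 1.0 / fs, method="bilinear")
            self.A = np.asarray(Ad, dtype=float)
            self.B = np.asarray(Bd, dtype=float).ravel()
            self.C = np.asarray(Cd, dtype=float).ravel()
            self.D = float(np.asarray(Dd).ravel()[0])
        self.x = np.zeros(self.A.shape[0])
        # closed-loop causality requires at least one sample of delay
        self.delay_samples = max(1, int(round(tf.delay * fs)))

    def step(self, u: float) -> float:
        y = float(self.C @ self.x) + self.D * u
        self.x = self.A @ self.x + self.B * u
        return y

    def scale_state(self, factor: float) -> None:
        self.x *= factor


# ---------------------------------------------------------------------------
# loop components and configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopComponents:
    """Neural controllers, biomechanics, and their sensorimotor products.

    ``C_*`` are the neural controllers (visual and mechanosensory, for head
    and body), ``P_head``/``P_body`` the biomechanical plants. The products
    G = P*C are the branch transforms the loop simulation and the
    decomposition algebra operate on.
    """

    C_head_V: DelayedTF
    C_head_M: DelayedTF
    C_body_V: DelayedTF
    C_body_M: DelayedTF
    P_head: DelayedTF
    P_body: DelayedTF

    def __post_init__(self) -> None:
        for name in ("C_head_V", "C_head_M", "C_body_V", "C_body_M",
                     "P_head", "P_body"):
            tf = getattr(self, name)
            if not tf.is_stable():
                bad = tf.poles()[tf.poles().real >= 0]
                raise ValueError(f"{name} is unstable (pole(s) at {bad})")

    @property
    def G_head_V(self) -> DelayedTF:
        return self.P_head * self.C_head_V

    @property
    def G_head_M(self) -> DelayedTF:
        return self.P_head * self.C_head_M

    @property
    def G_body_V(self) -> DelayedTF:
        return self.P_body * self.C_body_V

    @property
    def G_body_M(self) -> DelayedTF:
        return self.P_body * self.C_body_M

    def to_dict(self) -> dict:
        return {name: getattr(self, name).to_dict()
                for name in ("C_head_V", "C_head_M", "C_body_V", "C_body_M",
                             "P_head", "P_body")}

    @classmethod
    def from_dict(cls, d: dict) -> "LoopComponents":
        return cls(**{k: DelayedTF.from_dict(v) for k, v in d.items()})


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation mode, noise, saturation, gating, and timing parameters."""

    mode: str = "body_free"  # body_free | body_fixed | motor_replay
    noise_std_head: float = 0.0
    noise_std_body: float = 0.0
    head_limit: float = 15.0
    mech_gate: float = 1.0
    sample_rate: float = 100.0
    transient_discard: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("body_free", "body_fixed", "motor_replay"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (self.head_limit > 0):
            raise ValueError("head_limit must be > 0")
        if self.noise_std_head < 0 or self.noise_std_body < 0:
            raise ValueError("noise std must be >= 0")
        if not (0.0 <= self.mech_gate <= 1.0):
            raise ValueError("mech_gate must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "noise_std_head": self.noise_std_head,
            "noise_std_body": self.noise_std_body, "head_limit": self.head_limit,
            "mech_gate": self.mech_gate, "sample_rate": self.sample_rate,
            "transient_discard": self.transient_discard, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class Trial:
    """One simulated (or loaded) trial: stimulus, body, head, retinal slip.

    ``E`` is the pre-noise loop error R - H - B (the true retinal slip); the
    measured ``H`` and ``B`` include tracking noise when configured. ``truth``
    carries the generating loop for synthetic trials; ``truth_events`` carries
    the injected-saccade log for synthetic saccade trials.
    """

    R: TimeSeries
    H: TimeSeries
    B: TimeSeries
    E: TimeSeries
    spec: PerturbationSpec | None = None
    config: SimulationConfig | None = None
    truth: LoopComponents | None = None
    truth_events: list | None = None

    def __post_init__(self) -> None:
        fs = self.R.sample_rate
        n = len(self.R)
        for name in ("H", "B", "E"):
            s = getattr(self, name)
            if s.sample_rate != fs or len(s) != n:
                raise ValueError(f"{name} does not share the stimulus time base")


# ---------------------------------------------------------------------------
# closed-form loop solution (analysis oracle and stability aid)
# ---------------------------------------------------------------------------

def closed_loop_truth(components: LoopComponents, freqs, mech_gate: float = 1.0
                      ) -> dict:
    """Closed-form frequency responses of the loop, from the true transforms.

    Solving H = Gv*E + g*Gm*B, B = Gbv*E + g*Gbm*B, E = R - H - B (g the
    mechanosensory gate) gives, with Q = Gbv/(1 - g*Gbm):

        B/R = Q*(1 - H/R)/(1 + Q),    H/R = (Gv + g*Gm*Q)/(1 + Q + Gv + g*Gm*Q)

    Returns all branch transforms plus the closed-loop H/R, B/R, E/R, the
    body-fixed H/R, and the combined error-to-head transform G_head_VM.
    """
    f = np.asarray(freqs, dtype=float)
    gv = components.G_head_V.freq_response(f)
    gm = mech_gate * components.G_head_M.freq_response(f)
    gbv = components.G_body_V.freq_response(f)
    gbm = mech_gate * components.G_body_M.freq_response(f)
    q = gbv / (1 - gbm)
    h_over_r = (gv + gm * q) / (1 + q + gv + gm * q)
    e_over_r = (1 - h_over_r) / (1 + q)
    b_over_r = q * e_over_r
    return {
        "freqs": f, "G_head_V": gv, "G_head_M": gm,
        "G_body_V": gbv, "G_body_M": gbm,
        "G_head_VM": gv + gm * q,
        "H_over_R": h_over_r, "B_over_R": b_over_r, "E_over_R": e_over_r,
        "H_over_R_fixed": gv / (1 + gv),
    }


def assert_stable(components: LoopComponents, config: SimulationConfig,
                  horizon: float = 8.0) -> None:
    """Numerical closed-loop stability check (impulse response decay).

    Component transfer functions are checked for right-half-plane poles
    (reported directly); the delayed closed loop is then simulated without
    saturation for ``horizon`` seconds and must decay.
    """
    probe = replace(config, noise_std_head=0.0, noise_std_body=0.0,
                    head_limit=1e12, mode="body_free")
    n = int(horizon * config.sample_rate * INTERNAL_OVERSAMPLING)
    impulse = np.zeros(n)
    impulse[0] = 1.0
    H, B, _ = _run_loop(components, impulse, probe)
    for name, y in (("H", np.abs(H)), ("B", np.abs(B))):
        peak = y.max()
        tail = y[int(0.75 * n):].max()
        if not np.isfinite(peak) or (peak > 1e-12 and tail > 0.05 * peak):
            raise ValueError(
                f"closed loop appears unstable: |{name}| impulse response does "
                f"not decay (peak {peak:.3g}, tail {tail:.3g})")


# ---------------------------------------------------------------------------
# time-domain simulation
# ---------------------------------------------------------------------------

def _internal_stimulus(stimulus, config: SimulationConfig
                       ) -> tuple[np.ndarray, np.ndarray, PerturbationSpec | None]:
    """Stimulus at the internal rate and at the recording rate."""
    factor = INTERNAL_OVERSAMPLING
    fs = config.sample_rate
    if isinstance(stimulus, PerturbationSpec):
        spec = stimulus
        if spec.sample_rate != fs:
            raise ValueError(
                f"spec sample_rate {spec.sample_rate} != config sample_rate {fs}")
        fine = replace_spec_rate(spec, fs * factor).synthesize().values
        coarse = spec.synthesize().values
        return fine, coarse, spec
    if stimulus.sample_rate != fs:
        raise ValueError(
            f"stimulus sample_rate {stimulus.sample_rate} != config "
            f"sample_rate {fs}")
    coarse = stimulus.values
    fine = sps.resample(coarse, coarse.size * factor)
    return fine, coarse, None


def replace_spec_rate(spec: PerturbationSpec, sample_rate: float) -> PerturbationSpec:
    return PerturbationSpec(
        kind=spec.kind, frequencies=spec.frequencies, amplitudes=spec.amplitudes,
        phases=spec.phases, duration=spec.duration, sample_rate=sample_rate,
        v_norm=spec.v_norm, seed=spec.seed)


def _run_loop(components: LoopComponents, r_fine: np.ndarray,
              config: SimulationConfig, b_imposed: np.ndarray | None = None
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-sample closed-loop simulation at the internal rate.

    Returns (H, B, E) at the internal rate, before decimation and noise.
    """
    fs_int = config.sample_rate * INTERNAL_OVERSAMPLING
    mode = config.mode
    gate = 1.0 if mode in ("body_free", "body_fixed") else config.mech_gate
    br_hv = _Branch(components.G_head_V, fs_int)
    br_hm = _Branch(components.G_head_M, fs_int)
    br_bv = _Branch(components.G_body_V, fs_int)
    br_bm = _Branch(components.G_body_M, fs_int)
    n = r_fine.size
    E = np.zeros(n)
    B = np.zeros(n)
    H = np.zeros(n)
    limit = config.head_limit
    d_hv, d_hm = br_hv.delay_samples, br_hm.delay_samples
    d_bv, d_bm = br_bv.delay_samples, br_bm.delay_samples
    for i in range(n):
        e_hv = E[i - d_hv] if i >= d_hv else 0.0
        if mode == "body_free":
            e_bv = E[i - d_bv] if i >= d_bv else 0.0
            b_bm = B[i - d_bm] if i >= d_bm else 0.0
            B[i] = br_bv.step(e_bv) + br_bm.step(b_bm)
        elif mode == "motor_replay":
            B[i] = b_imposed[i]
        b_hm = gate * (B[i - d_hm] if i >= d_hm else 0.0)
        h_raw = br_hv.step(e_hv) + br_hm.step(b_hm)
        if abs(h_raw) > limit:
            # state clamping: shrink head branch states so the realized
            # output sits at the anatomical limit (integrator anti-windup)
            factor = limit / abs(h_raw)
            br_hv.scale_state(factor)
            br_hm.scale_state(factor)
            H[i] = np.sign(h_raw) * limit
        else:
            H[i] = h_raw
        if mode == "motor_replay":
            # display co-rotates with the body: no body-induced visual slip
            E[i] = r_fine[i] - H[i]
        elif mode == "body_fixed":
            E[i] = r_fine[i] - H[i]
        else:
            E[i] = r_fine[i] - H[i] - B[i]
    return H, B, E


def _finalize_trial(components, config, r_coarse, H_f, B_f, E_f, spec,
                    truth=True) -> Trial:
    factor = INTERNAL_OVERSAMPLING
    fs = config.sample_rate
    H = H_f[::factor].copy()
    B = B_f[::factor].copy()
    E = E_f[::factor].copy()
    rng = np.random.default_rng(config.seed)
    if config.noise_std_head > 0:
        H = H + rng.normal(0.0, config.noise_std_head, H.size)
    if config.noise_std_body > 0:
        B = B + rng.normal(0.0, config.noise_std_body, B.size)
    mk = lambda v: TimeSeries(v, fs)
    return Trial(R=mk(r_coarse), H=mk(H), B=mk(B), E=mk(E), spec=spec,
                 config=config, truth=components if truth else None)


def simulate_trial(components: LoopComponents, stimulus, config: SimulationConfig,
                   _skip_stability_check: bool = False) -> Trial:
    """Simulate one closed-loop trial (body_free or body_fixed).

    ``stimulus`` may be a TimeSeries at the recording rate (band-limited
    resampling is used internally) or a PerturbationSpec (synthesized exactly
    at the internal rate). Identical (components, stimulus, config) give
    bit-identical trials.
    """
    if config.mode == "motor_replay":
        raise ValueError("use simulate_motor_replay for motor_replay mode")
    if not _skip_stability_check:
        assert_stable(components, config)
    r_fine, r_coarse, spec = _internal_stimulus(stimulus, config)
    if config.mode == "body_fixed":
        H_f, B_f, E_f = _run_loop(components, r_fine, config)
        B_f = np.zeros_like(B_f)  # body physically fixed
    else:
        H_f, B_f, E_f = _run_loop(components, r_fine, config)
    return _finalize_trial(components, config, r_coarse, H_f, B_f, E_f, spec)


def simulate_motor_replay(components: LoopComponents, body_motion: TimeSeries,
                          config: SimulationConfig, anesthetized: bool = False
                          ) -> Trial:
    """Replay prescribed body motion on a motor with the display co-rotating.

    Body-induced visual feedback is absent (the display turns with the body);
    head visual feedback remains because the head is free to move. The
    mechanosensory drive reaching the head is scaled by ``config.mech_gate``
    (externally generated body motion opens the gate; default 0.1 reflects the
    order-of-magnitude weaker response). ``anesthetized=True`` zeroes all
    neural controllers and couples the body to the head only through weak
    passive neck mechanics.
    """
    if config.mode != "motor_replay":
        raise ValueError("config.mode must be 'motor_replay'")
    if len(body_motion) == 0:
        raise ValueError("body_motion is empty")
    if body_motion.sample_rate != config.sample_rate:
        raise ValueError("body_motion sample rate must match config")
    factor = INTERNAL_OVERSAMPLING
    b_coarse = body_motion.values
    b_fine = sps.resample(b_coarse, b_coarse.size * factor)
    r_coarse = np.zeros_like(b_coarse)
    r_fine = np.zeros_like(b_fine)
    if anesthetized:
        zero = DelayedTF(num=(0.0,), den=(1.0,))
        passive = LoopComponents(
            C_head_V=zero, C_head_M=DelayedTF(num=(PASSIVE_NECK_COUPLING,), den=(1.0,)),
            C_body_V=zero, C_body_M=zero,
            P_head=components.P_head, P_body=components.P_body)
        run_cfg = replace(config, mech_gate=1.0)
        H_f, B_f, E_f = _run_loop(passive, r_fine, run_cfg, b_imposed=b_fine)
        return _finalize_trial(components, run_cfg, r_coarse, H_f, B_f, E_f, None)
    H_f, B_f, E_f = _run_loop(components, r_fine, config, b_imposed=b_fine)
    return _finalize_trial(components, config, r_coarse, H_f, B_f, E_f, None)


# ---------------------------------------------------------------------------
# default synthetic animal
# ---------------------------------------------------------------------------

#: Visual pathway delay (s); vision is the slow loop.
VISUAL_DELAY = 0.030
#: Haltere (mechanosensory) pathway delay (s); fast inner loop.
HALTERE_DELAY = 0.005

# Controller/plant constants for the default synthetic animal. These are
# module constants chosen to produce a stable loop with fly-like qualitative
# behavior (low-pass body near unity at low frequency, modest head visual
# gain, differentiating/high-pass mechanosensory head drive that opposes the
# visual drive), not measurements.
_HEAD_VIS_GAIN = 0.3
_HEAD_VIS_POLE_HZ = 3.0
_HEAD_MECH_GAIN_S = 0.04   # seconds: |Gm| ~ gain * 2*pi*f below the pole
_HEAD_MECH_POLE_HZ = 8.0
_BODY_VIS_GAIN = 3.0
_BODY_VIS_POLE_HZ = 0.8
_BODY_MECH_GAIN_S = 0.1
_BODY_MECH_POLE_HZ = 1.5


def _lowpass(gain: float, pole_hz: float, delay: float) -> DelayedTF:
    w = 2 * np.pi * pole_hz
    return DelayedTF(num=(gain * w,), den=(1.0, w), delay=delay)


def _differentiator(gain_s: float, pole_hz: float, delay: float) -> DelayedTF:
    # gain_s * s / (s/w + 1): differentiating at low f, flat above pole_hz
    w = 2 * np.pi * pole_hz
    return DelayedTF(num=(gain_s * w, 0.0), den=(1.0, w), delay=delay)


def default_fly() -> LoopComponents:
    """A documented default synthetic animal.

    The visual head branch is a delayed low-pass (slow, ~30 ms visual
    latency); the mechanosensory head branch is a delayed differentiator
    (~5 ms haltere latency) with negative sign so its head drive opposes the
    visual drive; the body visual branch is a low-pass with high gain so the
    closed-loop body response is near unity at low frequency; the body
    mechanosensory branch provides damping. Biomechanics are lumped into the
    branch transforms (P = 1).
    """
    unity = DelayedTF(num=(1.0,), den=(1.0,))
    return LoopComponents(
        C_head_V=_lowpass(_HEAD_VIS_GAIN, _HEAD_VIS_POLE_HZ, VISUAL_DELAY),
        C_head_M=_differentiator(-_HEAD_MECH_GAIN_S, _HEAD_MECH_POLE_HZ,
                                 HALTERE_DELAY),
        C_body_V=_lowpass(_BODY_VIS_GAIN, _BODY_VIS_POLE_HZ, VISUAL_DELAY),
        C_body_M=_differentiator(-_BODY_MECH_GAIN_S, _BODY_MECH_POLE_HZ,
                                 HALTERE_DELAY),
        P_head=unity,
        P_body=unity,
    )


# ---------------------------------------------------------------------------
# synthetic saccade trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaccadeGenParams:
    """Distributions and dynamics for synthetic saccade trials.

    Saccades are smooth single-peaked velocity pulses (peak velocity 2A/d for
    amplitude A and duration d) followed by an exponential return to the
    neutral position with time constant ``tau``; body-free animals return
    quickly (strong mechanosensory braking) while body-fixed animals return
    ~8x more slowly. Defaults keep the saccades themselves fast (peak
    velocities well above 100 deg/s) while the exponential returns stay
    below that speed, so the two movement classes remain kinematically
    separable.
    """

    amplitude_mean: float = 10.0
    amplitude_sd: float = 2.5
    amplitude_min: float = 5.0
    duration_mean: float = 0.06
    duration_sd: float = 0.01
    duration_bounds: tuple = (0.04, 0.09)
    tau: float = 0.2
    inter_saccade_interval: float = 2.0
    trial_duration: float = 20.0
    sample_rate: float = 100.0
    noise_std: float = 0.1
    head_limit: float = 15.0


def _saccade_profile(amp: float, duration: float, t: np.ndarray) -> np.ndarray:
    """Smooth displacement 0 -> amp over [0, duration] with sin^2 velocity."""
    x = np.clip(t / duration, 0.0, 1.0)
    return amp * (x - np.sin(2 * np.pi * x) / (2 * np.pi))


def generate_saccade_trials(params: SaccadeGenParams, n_trials: int, seed: int = 0
                            ) -> list:
    """Synthetic head traces with injected saccades and a ground-truth log.

    Each trial holds fixation noise plus saccades at (jittered) regular
    intervals; amplitudes beyond ``head_limit`` are clipped and counted in
    the per-trial truth log. Stimulus and body traces are zero (static
    display, as in saccade-culling experiments).
    """
    rng = np.random.default_rng(seed)
    fs = params.sample_rate
    n = int(round(params.trial_duration * fs))
    trials = []
    for _ in range(n_trials):
        t = np.arange(n) / fs
        head = np.zeros(n)
        events = []
        clipped = 0
        onset = 0.5 + rng.uniform(0.0, 0.5)
        while onset + 1.5 < params.trial_duration:
            amp = rng.normal(params.amplitude_mean, params.amplitude_sd)
            amp = max(amp, params.amplitude_min) * rng.choice([-1.0, 1.0])
            if abs(amp) > params.head_limit:
                amp = np.sign(amp) * params.head_limit
                clipped += 1
            dur = float(np.clip(rng.normal(params.duration_mean,
                                           params.duration_sd),
                                *params.duration_bounds))
            rel = t - onset
            in_sacc = (rel >= 0) & (rel <= dur)
            head[in_sacc] += _saccade_profile(amp, dur, rel[in_sacc])
            after = rel > dur
            head[after] += amp * np.exp(-(rel[after] - dur) / params.tau)
            events.append({
                "onset_s": float(onset), "offset_s": float(onset + dur),
                "amplitude_deg": float(amp), "duration_s": dur,
                "peak_velocity_dps": float(2 * abs(amp) / dur),
                "tau_s": params.tau,
            })
            onset += params.inter_saccade_interval * rng.uniform(0.8, 1.2)
        if params.noise_std > 0:
            head = head + rng.normal(0.0, params.noise_std, n)
        if clipped:
            warnings.warn(f"{clipped} saccade amplitude(s) clipped at the "
                          f"head limit", stacklevel=2)
        zeros = TimeSeries(np.zeros(n), fs)
        trials.append(Trial(R=zeros, H=TimeSeries(head, fs), B=zeros, E=zeros,
                            truth_events=events))
    return trials
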