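"""Non-parametric frequency-domain system identification.

Frequency-response functions (FRFs) are estimated without assuming a model
order: each signal is detrended, zero-phase low-pass filtered, transformed
with a chirp-z transform on a fine frequency grid (0-50 Hz, 0.05 Hz step by
default), and the complex output spectrum is divided by the complex input
spectrum. Gain is |X|, phase is the angle of X in degrees (positive = lead,
wrapped to (-180, 180]), and tracking performance is summarized by the
compensation error eps = |(1+0j) - X|: 0 is perfect compensation, 1 means the
response has no effect, >1 is deleterious.

Across-animal statistics average gain and compensation error arithmetically
and phase circularly; uncertainty for derived (composed) transforms is
propagated by seeded Monte Carlo because the composed quantities mix
transforms measured in different groups of animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signals import TimeSeries, check_same_base

DEFAULT_F_LO = 0.0
DEFAULT_F_HI = 50.0
DEFAULT_DF = 0.05
DEFAULT_INPUT_FLOOR = 1e-8
LOWPASS_CUTOFF_HZ = 40.0
LOWPASS_ORDER = 2


def wrap_phase_deg(phase: np.ndarray) -> np.ndarray:
    """Wrap phase in degrees to (-180, 180]."""
    wrapped = np.asarray(phase, dtype=float) % 360.0
    return np.where(wrapped > 180.0, wrapped - 360.0, wrapped)


def default_grid(f_lo: float = DEFAULT_F_LO, f_hi: float = DEFAULT_F_HI,
                 df: float = DEFAULT_DF) -> np.ndarray:
    """The analysis frequency grid (inclusive of both endpoints)."""
    n = int(round((f_hi - f_lo) / df)) + 1
    return f_lo + df * np.arange(n)


def grid_indices(freqs: np.ndarray, targets) -> np.ndarray:
    """Indices of ``targets`` on the grid ``freqs`` (must match within 1e-6 Hz)."""
    freqs = np.asarray(freqs, dtype=float)
    idx = []
    for f in np.atleast_1d(targets):
        i = int(np.argmin(np.abs(freqs - f)))
        if abs(freqs[i] - f) > 1e-6:
            raise ValueError(f"frequency {f} Hz is not on the analysis grid")
        idx.append(i)
    return np.asarray(idx, dtype=int)


@dataclass
class FrequencyResponse:
    """A non-parametric complex transform on a frequency grid.

    ``values`` holds the complex output/input ratio; ``valid`` flags
    frequencies where the estimate is trustworthy (input above the division
    floor, loop not near-singular). Dispersion arrays are populated by
    :func:`average_across_flies` and :func:`propagate_uncertainty`.
    """

    freqs: np.ndarray
    values: np.ndarray
    coherence: np.ndarray | None = None
    n_flies: int = 1
    gain_sd: np.ndarray | None = None
    phase_sd_circ: np.ndarray | None = None
    comp_err_sd: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.freqs.shape != self.values.shape:
            raise ValueError("freqs and values must have the same shape")
        if self.freqs.size > 1 and not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(self.freqs.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.coherence is not None:
            coh = np.asarray(self.coherence, dtype=float)
            if np.any((coh < -1e-9) | (coh > 1 + 1e-9)):
                raise ValueError("coherence must lie in [0, 1]")
            self.coherence = np.clip(coh, 0.0, 1.0)

    @property
    def gain(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        """Phase in degrees, positive = lead, wrapped to (-180, 180]."""
        return wrap_phase_deg(np.degrees(np.angle(self.values)))

    def at(self, freqs) -> "FrequencyResponse":
        """Restrict to the given frequencies (must lie on the grid)."""
        idx = grid_indices(self.freqs, freqs)
        pick = lambda a: None if a is None else np.asarray(a)[idx]
        return FrequencyResponse(
            freqs=self.freqs[idx], values=self.values[idx],
            coherence=pick(self.coherence), n_flies=self.n_flies,
            gain_sd=pick(self.gain_sd), phase_sd_circ=pick(self.phase_sd_circ),
            comp_err_sd=pick(self.comp_err_sd), valid=pick(self.valid),
        )

    @classmethod
    def from_gain_phase(cls, freqs, gain, phase_deg, **kw) -> "FrequencyResponse":
        gain = np.asarray(gain, dtype=float)
        values = gain * np.exp(1j * np.radians(phase_deg))
        return cls(freqs=np.asarray(freqs, dtype=float), values=values, **kw)


@dataclass
class CompensationError:
    """Distance on the complex plane from perfect compensation (1+0j)."""

    freqs: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be >= 0")


def preprocess(ts: TimeSeries, cutoff: float = LOWPASS_CUTOFF_HZ,
               order: int = LOWPASS_ORDER) -> TimeSeries:
    """Detrend (linear least squares) and zero-phase low-pass at ``cutoff``.

    The filter is a Butterworth design applied forward-backward (zero phase
    lag), so passband timing is untouched.
    """
    if ts.duration < 1.0:
        raise ValueError("need at least 1 s of data")
    if ts.sample_rate <= 2 * cutoff:
        raise ValueError(
            f"sample_rate {ts.sample_rate} Hz puts the {cutoff} Hz cutoff at/above Nyquist"
        )
    detrended = sps.detrend(ts.values, type="linear")
    b, a = sps.butter(order, cutoff, fs=ts.sample_rate)
    filtered = sps.filtfilt(b, a, detrended)
    return ts.with_values(filtered)


def czt_spectrum(ts: TimeSeries, f_lo: float = DEFAULT_F_LO,
                 f_hi: float = DEFAULT_F_HI, df: float = DEFAULT_DF
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude-normalized chirp-z spectrum on the grid [f_lo, f_hi] step df.

    Normalized so that ``A*sin(2*pi*f*t + phi)`` sampled over whole cycles
    returns the complex value ``A*exp(1j*phi)`` at the bin for f: magnitude is
    the sine's amplitude and the angle is its sine-convention phase.
    """
    if df <= 0:
        raise ValueError(f"df must be > 0, got {df}")
    if f_hi <= f_lo:
        raise ValueError(f"f_hi ({f_hi}) must exceed f_lo ({f_lo})")
    freqs = default_grid(f_lo, f_hi, df)
    n = len(ts)
    fs = ts.sample_rate
    w = np.exp(-2j * np.pi * df / fs)
    a = np.exp(2j * np.pi * f_lo / fs)
    raw = sps.czt(ts.values, m=freqs.size, w=w, a=a)
    # 2/N amplitude scaling; the factor 1j rotates the DFT of sin() onto the
    # positive real axis so a zero-phase sine has phase 0.
    return freqs, (2j / n) * raw


def frf(input_ts: TimeSeries, output_ts: TimeSeries, stim_freqs,
        f_lo: float = DEFAULT_F_LO, f_hi: float = DEFAULT_F_HI,
        df: float = DEFAULT_DF, input_floor: float = DEFAULT_INPUT_FLOOR
        ) -> FrequencyResponse:
    """Frequency-response function output/input on the full grid.

    The ratio is formed at every grid point; frequencies where the input
    magnitude falls below ``input_floor`` are flagged invalid rather than
    silently divided. ``stim_freqs`` must lie on the grid (they are where the
    estimate is meaningful; the rest of the grid is diagnostic).
    """
    check_same_base(input_ts, output_ts)
    freqs, x_in = czt_spectrum(input_ts, f_lo, f_hi, df)
    _, x_out = czt_spectrum(output_ts, f_lo, f_hi, df)
    grid_indices(freqs, stim_freqs)  # validate stim freqs lie on the grid
    valid = np.abs(x_in) >= input_floor
    safe_in = np.where(valid, x_in, 1.0)
    values = np.where(valid, x_out / safe_in, np.nan + 0j)
    return FrequencyResponse(freqs=freqs, values=values, valid=valid)


def compensation_error(fr: FrequencyResponse) -> CompensationError:
    """eps = |(1+0j) - X| per frequency: 0 = perfect, 1 = no effect."""
    return CompensationError(freqs=fr.freqs, epsilon=np.abs((1 + 0j) - fr.values))


def coherence(input_ts: list, output_ts: list, stim_freqs,
              f_lo: float = DEFAULT_F_LO, f_hi: float = DEFAULT_F_HI,
              df: float = DEFAULT_DF) -> np.ndarray:
    """Magnitude-squared coherence at ``stim_freqs`` from trial-averaged spectra.

    Averaging across repeated trials provides the spectral averaging that
    makes coherence informative; a single trial is degenerate (identically 1)
    and is rejected.
    """
    if len(input_ts) != len(output_ts):
        raise ValueError("need matching numbers of input and output trials")
    if len(input_ts) < 2:
        raise ValueError("coherence requires >= 2 trials (single trial is degenerate)")
    sxx = syy = sxy = None
    freqs = None
    for x, y in zip(input_ts, output_ts):
        check_same_base(x, y)
        freqs, fx = czt_spectrum(x, f_lo, f_hi, df)
        _, fy = czt_spectrum(y, f_lo, f_hi, df)
        if sxx is None:
            sxx = np.zeros(freqs.size)
            syy = np.zeros(freqs.size)
            sxy = np.zeros(freqs.size, dtype=complex)
        sxx += np.abs(fx) ** 2
        syy += np.abs(fy) ** 2
        sxy += np.conj(fx) * fy
    idx = grid_indices(freqs, stim_freqs)
    denom = sxx[idx] * syy[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(sxy[idx]) ** 2 / denom
    return np.clip(np.where(denom > 0, coh, 0.0), 0.0, 1.0)


def lssa_fit(ts: TimeSeries, f: float, exclude_mask: np.ndarray | None = None
             ) -> tuple[float, float, float]:
    """Least-squares fit of a*sin(2*pi*f*t) + b*cos(2*pi*f*t) + c.

    Returns (amplitude, phase_deg, offset) with the same sine-phase
    convention as :func:`czt_spectrum`. Samples where ``exclude_mask`` is True
    are ignored, which is what makes the fit robust to saturated segments.
    """
    t = ts.time
    y = ts.values
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.shape != y.shape:
            raise ValueError("exclude_mask must match the series length")
        keep = ~exclude_mask
        t, y = t[keep], y[keep]
    if t.size < 10 or (t.size and (t.max() - t.min()) < 1.0 / f):
        raise ValueError("need >= 10 unmasked samples spanning >= 1 cycle")
    design = np.column_stack([
        np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t), np.ones_like(t)
    ])
    (a, b, c), *_ = np.linalg.lstsq(design, y, rcond=None)
    amplitude = float(np.hypot(a, b))
    phase = float(wrap_phase_deg(np.degrees(np.arctan2(b, a))))
    return amplitude, phase, float(c)


def saturation_correct(head_ts: TimeSeries, f: float, limit: float,
                       vel_floor: float | None = None
                       ) -> tuple[float, np.ndarray]:
    """Gain-correction factor for a response clipped at an anatomical limit.

    Samples sitting at the limit (|angle| > 0.95*limit and |velocity| below
    ``vel_floor``) are masked and a sine is refit by LSSA on the rest; the
    returned factor is (LSSA amplitude)/(chirp-z amplitude) and rescales FRF
    *gain only* at f — the phase estimate is left untouched.
    """
    if not (limit > 0):
        raise ValueError(f"limit must be > 0, got {limit}")
    if vel_floor is None:
        # a sine that just reaches the limit has peak speed 2*pi*f*limit
        vel_floor = 0.1 * 2 * np.pi * f * limit
    vel = head_ts.velocity()
    mask = (np.abs(head_ts.values) > 0.95 * limit) & (np.abs(vel) < vel_floor)
    if mask.mean() > 0.9:
        raise ValueError("more than 90% of samples saturated; response unrecoverable")
    amp_lssa, _, _ = lssa_fit(head_ts, f, exclude_mask=mask)
    freqs, spec = czt_spectrum(head_ts)
    amp_czt = float(np.abs(spec[grid_indices(freqs, [f])[0]]))
    if amp_czt == 0:
        raise ValueError("zero chirp-z amplitude at the requested frequency")
    return amp_lssa / amp_czt, mask


def _circular_mean_sd_deg(phases_deg: np.ndarray, axis: int = 0
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Circular mean and circular SD (sqrt(-2 ln Rbar)) in degrees."""
    phasors = np.exp(1j * np.radians(phases_deg))
    mean_vec = np.mean(phasors, axis=axis)
    mean_deg = wrap_phase_deg(np.degrees(np.angle(mean_vec)))
    rbar = np.clip(np.abs(mean_vec), 1e-300, 1.0)
    sd_deg = np.degrees(np.sqrt(-2.0 * np.log(rbar)))
    return mean_deg, sd_deg


def average_across_flies(frs: list) -> FrequencyResponse:
    """Across-animal mean/SD of gain, phase, and compensation error.

    Gain and compensation error are averaged arithmetically; phase uses
    circular statistics. The mean transform is reconstructed as
    mean_gain * exp(1j * circ_mean_phase).
    """
    if not frs:
        raise ValueError("need at least one frequency response")
    freqs = frs[0].freqs
    for fr in frs[1:]:
        if fr.freqs.shape != freqs.shape or not np.allclose(fr.freqs, freqs):
            raise ValueError("frequency grids do not match")
    gains = np.array([fr.gain for fr in frs])
    phases = np.array([fr.phase for fr in frs])
    eps = np.array([np.abs(1 - fr.values) for fr in frs])
    valid = np.all([fr.valid for fr in frs], axis=0)
    n = len(frs)
    gain_mean = gains.mean(axis=0)
    gain_sd = gains.std(axis=0, ddof=1) if n > 1 else np.zeros_like(gain_mean)
    phase_mean, phase_sd = _circular_mean_sd_deg(phases, axis=0)
    if n == 1:
        phase_sd = np.zeros_like(phase_mean)
    eps_sd = eps.std(axis=0, ddof=1) if n > 1 else np.zeros_like(gain_mean)
    coh = None
    if all(fr.coherence is not None for fr in frs):
        coh = np.mean([fr.coherence for fr in frs], axis=0)
    return FrequencyResponse.from_gain_phase(
        freqs, gain_mean, phase_mean, coherence=coh, n_flies=n,
        gain_sd=gain_sd, phase_sd_circ=phase_sd, comp_err_sd=eps_sd, valid=valid,
    )


def propagate_uncertainty(inputs: list, expression, n_draws: int = 1000,
                          seed: int = 0) -> FrequencyResponse:
    """Monte-Carlo uncertainty propagation through a transform composition.

    ``expression`` is a callable mapping the drawn complex arrays (one per
    input, in order) to a complex array, or one of the named compositions
    from :mod:`flygaze.decompose` (``"visual_only"``, ``"mechano_only"``,
    ``"gm_self"``, ``"weighting"``, ``"head_free"``). Per frequency, gain is
    drawn normal and phase wrapped-normal, independently per input group
    (the groups are different sets of animals).
    """
    if n_draws < 100:
        raise ValueError(f"n_draws must be >= 100, got {n_draws}")
    if isinstance(expression, str):
        from . import decompose
        expression = decompose.named_composition(expression)
    freqs = inputs[0].freqs
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n_draws):
        realized = []
        for fr in inputs:
            gsd = fr.gain_sd if fr.gain_sd is not None else 0.0
            psd = fr.phase_sd_circ if fr.phase_sd_circ is not None else 0.0
            gain = fr.gain + rng.standard_normal(freqs.size) * gsd
            gain = np.clip(gain, 0.0, None)
            phase = fr.phase + rng.standard_normal(freqs.size) * psd
            realized.append(gain * np.exp(1j * np.radians(phase)))
        draws.append(np.asarray(expression(*realized), dtype=complex))
    draws = np.array(draws)
    gains = np.abs(draws)
    phases = wrap_phase_deg(np.degrees(np.angle(draws)))
    eps = np.abs(1 - draws)
    phase_mean, phase_sd = _circular_mean_sd_deg(phases, axis=0)
    return FrequencyResponse.from_gain_phase(
        freqs, gains.mean(axis=0), phase_mean,
        n_flies=min(fr.n_flies for fr in inputs),
        gain_sd=gains.std(axis=0, ddof=1),
        phase_sd_circ=phase_sd,
        comp_err_sd=eps.std(axis=0, ddof=1),
        valid=np.all([fr.valid for fr in inputs], axis=0),
    )
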