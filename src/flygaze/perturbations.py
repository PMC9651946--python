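"""Velocity-normalized visual perturbation signals.

Stimuli are single sinusoids or nine-component sums of sines whose component
amplitudes are set so every component has the same peak angular *velocity*
``v_norm``: a component at frequency f gets amplitude ``v_norm / (2*pi*f)``.
This keeps the retinal-slip speed statistics comparable across frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import TimeSeries

#: The seven single-sine stimulus frequencies of the standard battery (Hz).
SINGLE_SINE_FREQS = (0.7, 1.0, 1.5, 2.1, 3.5, 5.3, 10.6)

#: Peak angular velocity of the single-sine battery (deg/s).
SINGLE_SINE_VNORM = 250.0

#: Component peak velocities of the three sum-of-sines stimuli (deg/s).
SUM_OF_SINES_VNORMS = (42.0, 70.0, 95.0)

#: Default nine sum-of-sines component frequencies (Hz): log-spaced over
#: 0.35-13.7 Hz, snapped to the 0.05 Hz grid, then minimally perturbed so no
#: frequency is an integer multiple of another (the stricter reading of the
#: "no prime harmonic" design rule).
SUM_OF_SINES_FREQS = (0.35, 0.55, 0.9, 1.45, 2.15, 3.45, 5.55, 8.65, 13.7)

#: Spatial wavelength of the displayed grating (deg).
GRATING_WAVELENGTH = 30.0

FREQ_GRID_STEP = 0.05


def _integer_multiple_pairs(freqs: np.ndarray, rtol: float = 1e-9) -> list[tuple[float, float]]:
    pairs = []
    for i, fi in enumerate(freqs):
        for fj in freqs[i + 1:]:
            ratio = fj / fi
            if abs(ratio - round(ratio)) < rtol and round(ratio) > 1:
                pairs.append((float(fi), float(fj)))
    return pairs


@dataclass(frozen=True)
class PerturbationSpec:
    """Specification of a velocity-normalized perturbation.

    ``kind`` is ``"single_sine"`` (one component) or ``"sum_of_sines"``
    (exactly nine components). Amplitudes must satisfy the velocity
    normalization ``A_i = v_norm / (2*pi*f_i)``.
    """

    kind: str
    frequencies: tuple
    amplitudes: tuple
    phases: tuple
    duration: float
    sample_rate: float
    v_norm: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single_sine", "sum_of_sines"):
            raise ValueError(f"unknown kind {self.kind!r}")
        f = np.asarray(self.frequencies, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        n_expected = 1 if self.kind == "single_sine" else 9
        if not (f.size == a.size == p.size == n_expected):
            raise ValueError(
                f"{self.kind} requires exactly {n_expected} component(s), "
                f"got {f.size} frequencies / {a.size} amplitudes / {p.size} phases"
            )
        if np.any(f <= 0):
            raise ValueError("all frequencies must be positive")
        if self.v_norm > 0:
            expected = self.v_norm / (2 * np.pi * f)
            if not np.allclose(a, expected, rtol=1e-9):
                raise ValueError("amplitudes violate velocity normalization v_norm/(2*pi*f)")
        if self.kind == "sum_of_sines":
            on_grid = np.abs(f / FREQ_GRID_STEP - np.round(f / FREQ_GRID_STEP)) < 1e-9
            if not np.all(on_grid):
                raise ValueError(f"sum-of-sines frequencies must lie on the {FREQ_GRID_STEP} Hz grid")
            pairs = _integer_multiple_pairs(f)
            if pairs:
                raise ValueError(f"harmonically related frequency pairs: {pairs}")

    def synthesize(self) -> TimeSeries:
        """Render the specified stimulus as a time series."""
        n = int(round(self.duration * self.sample_rate))
        t = np.arange(n) / self.sample_rate
        values = np.zeros(n)
        for f, a, p in zip(self.frequencies, self.amplitudes, self.phases):
            values += a * np.sin(2 * np.pi * f * t + p)
        return TimeSeries(values, self.sample_rate)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "frequencies_hz": list(self.frequencies),
            "amplitudes_deg": list(self.amplitudes),
            "phases_rad": list(self.phases),
            "v_norm": self.v_norm,
            "duration_s": self.duration,
            "sample_rate_hz": self.sample_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerturbationSpec":
        return cls(
            kind=d["kind"],
            frequencies=tuple(d["frequencies_hz"]),
            amplitudes=tuple(d["amplitudes_deg"]),
            phases=tuple(d["phases_rad"]),
            duration=d["duration_s"],
            sample_rate=d["sample_rate_hz"],
            v_norm=d["v_norm"],
            seed=d.get("seed"),
        )


def single_sine_spec(f: float, v_norm: float = SINGLE_SINE_VNORM,
                     duration: float = 20.0, sample_rate: float = 100.0) -> PerturbationSpec:
    """Spec for one velocity-normalized sinusoid A*sin(2*pi*f*t)."""
    if not (f > 0):
        raise ValueError(f"frequency f must be > 0, got {f}")
    if not (sample_rate > 0):
        raise ValueError(f"sample_rate must be > 0, got {sample_rate}")
    if duration < 1.0 / f:
        raise ValueError(f"duration {duration} s covers less than one cycle at {f} Hz")
    amplitude = v_norm / (2 * np.pi * f)
    return PerturbationSpec(
        kind="single_sine",
        frequencies=(float(f),),
        amplitudes=(amplitude,),
        phases=(0.0,),
        duration=float(duration),
        sample_rate=float(sample_rate),
        v_norm=float(v_norm),
    )


def make_single_sine(f: float, v_norm: float = SINGLE_SINE_VNORM,
                     duration: float = 20.0, sample_rate: float = 100.0) -> TimeSeries:
    """Single sinusoid with peak angular velocity ``v_norm``.

    Returns ``A*sin(2*pi*f*t)`` with ``A = v_norm/(2*pi*f)`` so the peak of
    ``|dR/dt|`` equals ``v_norm`` exactly.
    """
    return single_sine_spec(f, v_norm, duration, sample_rate).synthesize()


def make_sum_of_sines(v_norm: float, frequencies=SUM_OF_SINES_FREQS,
                      duration: float = 20.0, sample_rate: float = 100.0,
                      seed: int = 0) -> tuple[PerturbationSpec, TimeSeries]:
    """Nine-component sum of sines, each component velocity-normalized.

    Component phases are drawn uniformly on [0, 2*pi) from a seeded generator
    so identical seeds give identical stimuli.
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size != 9:
        raise ValueError(f"sum of sines requires nine frequencies, got {f.size}")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2 * np.pi, size=9)
    amplitudes = v_norm / (2 * np.pi * f)
    spec = PerturbationSpec(
        kind="sum_of_sines",
        frequencies=tuple(f),
        amplitudes=tuple(amplitudes),
        phases=tuple(phases),
        duration=float(duration),
        sample_rate=float(sample_rate),
        v_norm=float(v_norm),
        seed=int(seed),
    )
    return spec, spec.synthesize()


def mean_abs_speed(ts: TimeSeries) -> float:
    """Time-averaged absolute angular speed in deg/s.

    Uses a centered finite difference; for a sinusoid of peak velocity
    ``v_norm`` sampled over whole cycles this converges to ``2/pi * v_norm``.
    """
    if len(ts) < 3:
        raise ValueError("need at least 3 samples")
    return float(np.mean(np.abs(ts.velocity())))


def mean_temporal_frequency(ts: TimeSeries, wavelength: float = GRATING_WAVELENGTH) -> float:
    """Mean temporal frequency (Hz) of the moving grating: mean speed / wavelength."""
    if not (wavelength > 0):
        raise ValueError(f"wavelength must be > 0, got {wavelength}")
    return mean_abs_speed(ts) / wavelength
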