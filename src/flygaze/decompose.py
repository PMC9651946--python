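"""Closed-loop feedback-decomposition algebra for gaze stabilization.

The head response of a body-free animal tracking a visual perturbation R is
mediated by three feedback routes: visual feedback from the head's own
motion, visual feedback from body motion, and nested mechanosensory feedback
from body motion. With Gv the error-to-head visual transform, Gm the
body-to-head mechanosensory transform, and B/R the closed-loop body response,
the closed-loop head transform decomposes as

    H/R = Gv/(1+Gv)  -  Gv/(1+Gv) * B/R  +  Gm/(1+Gv) * B/R
          (head visual)  (body visual)       (body mechanosensory)

All operations are element-wise on a shared frequency grid. Near-singular
frequencies (|1+Gv| or a divisor magnitude below a floor) are flagged invalid
rather than regularized: estimates are reported only where responses are
strong.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sysid import FrequencyResponse

SINGULARITY_FLOOR = 1e-8
DEFAULT_COHERENCE_FLOOR = 0.2


@dataclass
class TransformSet:
    """The measured/derived transforms entering the decomposition.

    All members share one frequency grid. ``G_head_V`` is the error-to-head
    transform of body-fixed animals (visual feedback only); ``G_head_VM`` is
    the same transform in body-free animals (visual + nested mechanosensory);
    ``G_head_M`` is the hidden body-to-head mechanosensory transform.
    """

    G_head_V: FrequencyResponse | None = None
    G_head_VM: FrequencyResponse | None = None
    G_head_M: FrequencyResponse | None = None
    B_over_R: FrequencyResponse | None = None
    H_over_R_free: FrequencyResponse | None = None
    H_over_R_fixed: FrequencyResponse | None = None

    def __post_init__(self) -> None:
        members = [m for m in (self.G_head_V, self.G_head_VM, self.G_head_M,
                               self.B_over_R, self.H_over_R_free,
                               self.H_over_R_fixed) if m is not None]
        if members:
            freqs = members[0].freqs
            for m in members[1:]:
                if m.freqs.shape != freqs.shape or not np.allclose(m.freqs, freqs):
                    raise ValueError("TransformSet members must share one frequency grid")


@dataclass
class HeadDecomposition:
    """The three feedback terms of the closed-loop head transform plus their sum."""

    head_visual: FrequencyResponse
    body_visual: FrequencyResponse
    body_mechanosensory: FrequencyResponse
    total: FrequencyResponse


def _as_fr(x, template: FrequencyResponse | None = None) -> FrequencyResponse:
    if isinstance(x, FrequencyResponse):
        return x
    values = np.asarray(x, dtype=complex)
    if template is not None:
        freqs = template.freqs
        values = np.broadcast_to(values, freqs.shape).astype(complex)
    else:
        freqs = np.arange(values.size, dtype=float)
    return FrequencyResponse(freqs=freqs, values=values)


def _first_fr(*args) -> FrequencyResponse | None:
    for a in args:
        if isinstance(a, FrequencyResponse):
            return a
    return None


def _combine_valid(*frs) -> np.ndarray:
    return np.all([fr.valid for fr in frs], axis=0)


def closed_loop_head_free(Gv, Gm, B_over_R, mech_feedback_sign: int = +1
                          ) -> HeadDecomposition:
    """Decompose the body-free closed-loop head transform H/R into its terms.

    ``mech_feedback_sign`` selects the sign of the mechanosensory term; the
    canonical convention is +1 (mechanosensory drive *added* to the visual
    drive, with any opposition carried by the phase of Gm). -1 gives the
    subtractive variant.
    """
    template = _first_fr(Gv, Gm, B_over_R)
    Gv = _as_fr(Gv, template)
    Gm = _as_fr(Gm, Gv)
    B_over_R = _as_fr(B_over_R, Gv)
    freqs = Gv.freqs
    denom = 1 + Gv.values
    ok = np.abs(denom) >= SINGULARITY_FLOOR
    valid = _combine_valid(Gv, Gm, B_over_R) & ok
    safe = np.where(ok, denom, 1.0)
    t_head = Gv.values / safe
    t_bodyv = -t_head * B_over_R.values
    t_mech = mech_feedback_sign * Gm.values / safe * B_over_R.values
    mk = lambda v: FrequencyResponse(freqs=freqs, values=np.where(ok, v, np.nan + 0j),
                                     valid=valid)
    return HeadDecomposition(
        head_visual=mk(t_head), body_visual=mk(t_bodyv),
        body_mechanosensory=mk(t_mech), total=mk(t_head + t_bodyv + t_mech),
    )


def closed_loop_head_fixed(Gv) -> FrequencyResponse:
    """Body-fixed closed-loop head transform H/R = Gv/(1+Gv)."""
    Gv = _as_fr(Gv)
    denom = 1 + Gv.values
    ok = np.abs(denom) >= SINGULARITY_FLOOR
    values = np.where(ok, Gv.values / np.where(ok, denom, 1.0), np.nan + 0j)
    return FrequencyResponse(freqs=Gv.freqs, values=values, valid=Gv.valid & ok)


def predict_visual_only(Gv, B_over_R) -> FrequencyResponse:
    """Predicted H/R with head + body *visual* feedback only (no mechanosensory).

    This is the full decomposition with Gm = 0; it is the model prediction
    that the body-motion 'replay' experiment validates.
    """
    template = _first_fr(Gv, B_over_R)
    Gv = _as_fr(Gv, template)
    dec = closed_loop_head_free(Gv, np.zeros_like(Gv.values), B_over_R)
    return dec.total


def predict_mechano_only(GvM) -> FrequencyResponse:
    """Predicted H/R with head visual + body mechanosensory feedback.

    Expressed through the body-free error-to-head transform GvM:
    H/R = GvM/(1+GvM).
    """
    GvM = _as_fr(GvM)
    denom = 1 + GvM.values
    ok = np.abs(denom) >= SINGULARITY_FLOOR
    values = np.where(ok, GvM.values / np.where(ok, denom, 1.0), np.nan + 0j)
    return FrequencyResponse(freqs=GvM.freqs, values=values, valid=GvM.valid & ok)


@dataclass
class GmEstimate:
    """Estimate of the hidden mechanosensory transform with its cross-check.

    ``primary`` inverts the decomposition directly:
    Gm = (1+Gv)*(H/B) - Gv*(R/B) + Gv. ``cross_check`` is the algebraically
    equivalent form (GvM - Gv)*(E/B); the two agree exactly on noise-free
    inputs.
    """

    primary: FrequencyResponse
    cross_check: FrequencyResponse


def estimate_Gm_self(Gv, H_over_R_free, B_over_R) -> GmEstimate:
    """Estimate Gm from self-generated body motion (body-free trials).

    Frequencies where |B/R| is below the floor are flagged invalid: the
    body-to-head transform cannot be inferred where the body barely moves.
    """
    template = _first_fr(Gv, H_over_R_free, B_over_R)
    Gv = _as_fr(Gv, template)
    HR = _as_fr(H_over_R_free, Gv)
    BR = _as_fr(B_over_R, Gv)
    freqs = Gv.freqs
    ok = np.abs(BR.values) >= SINGULARITY_FLOOR
    valid = _combine_valid(Gv, HR, BR) & ok
    br_safe = np.where(ok, BR.values, 1.0)
    HB = HR.values / br_safe
    RB = 1.0 / br_safe
    gm = (1 + Gv.values) * HB - Gv.values * RB + Gv.values
    # cross-check via the error-to-head transform of body-free animals
    ER = 1 - HR.values - BR.values
    er_ok = np.abs(ER) >= SINGULARITY_FLOOR
    GvM = np.where(er_ok, HR.values / np.where(er_ok, ER, 1.0), np.nan + 0j)
    gm_alt = (GvM - Gv.values) * np.where(ok, ER / br_safe, np.nan + 0j)
    mk = lambda v, w: FrequencyResponse(freqs=freqs, values=np.where(w, v, np.nan + 0j),
                                        valid=valid & w)
    return GmEstimate(primary=mk(gm, ok), cross_check=mk(gm_alt, ok & er_ok))


def estimate_Gm_external(Gv, H_over_B_motor, sign_convention: str = "as_printed",
                         coherence_floor: float = DEFAULT_COHERENCE_FLOOR
                         ) -> FrequencyResponse:
    """Estimate Gm from externally imposed body motion (motor-replay trials).

    With the display co-rotating, body motion induces no visual feedback and
    the head sees only its own visual error. ``sign_convention``:

    - ``"as_printed"``: Gm = (1 - Gv) * (H/B)
    - ``"rederived"``:  Gm = (1 + Gv) * (H/B), the exact inverse of the
      replay loop H = Gv*(-H) + Gm*B.

    Frequencies where the H/B coherence falls below ``coherence_floor`` are
    flagged low-confidence via the ``valid`` mask.
    """
    template = _first_fr(Gv, H_over_B_motor)
    Gv = _as_fr(Gv, template)
    HB = _as_fr(H_over_B_motor, Gv)
    if sign_convention == "as_printed":
        gm = (1 - Gv.values) * HB.values
    elif sign_convention == "rederived":
        gm = (1 + Gv.values) * HB.values
    else:
        raise ValueError(f"unknown sign_convention {sign_convention!r}")
    valid = _combine_valid(Gv, HB)
    if HB.coherence is not None:
        valid = valid & (HB.coherence >= coherence_floor)
    return FrequencyResponse(freqs=Gv.freqs, values=gm, valid=valid)


def feedback_weighting(GvM, Gv) -> FrequencyResponse:
    """Effective weighting of nested mechanosensory vs visual feedback: GvM/Gv.

    Gain 1 / phase 0 everywhere is the null reference (mechanosensory
    feedback has no effect); gain below 1 indicates damping.
    """
    template = _first_fr(GvM, Gv)
    GvM = _as_fr(GvM, template)
    Gv = _as_fr(Gv, GvM)
    ok = np.abs(Gv.values) >= SINGULARITY_FLOOR
    values = np.where(ok, GvM.values / np.where(ok, Gv.values, 1.0), np.nan + 0j)
    return FrequencyResponse(freqs=GvM.freqs, values=values,
                             valid=_combine_valid(GvM, Gv) & ok)


def named_composition(tag: str):
    """Complex-array callables for Monte-Carlo uncertainty propagation."""

    def visual_only(gv, br):
        return gv / (1 + gv) * (1 - br)

    def mechano_only(gvm):
        return gvm / (1 + gvm)

    def gm_self(gv, hr, br):
        return (1 + gv) * hr / br - gv / br + gv

    def weighting(gvm, gv):
        return gvm / gv

    def head_free(gv, gm, br):
        return gv / (1 + gv) - gv / (1 + gv) * br + gm / (1 + gv) * br

    table = {"visual_only": visual_only, "mechano_only": mechano_only,
             "gm_self": gm_self, "weighting": weighting, "head_free": head_free}
    try:
        return table[tag]
    except KeyError:
        raise ValueError(f"unknown composition tag {tag!r}; known: {sorted(table)}")
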