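"""Single ultra-compact neuron (UCN) dynamics.

The UCN is a minimal leaky-integrate-and-fire circuit: a membrane capacitor
``C`` integrates dendritic current, the resistive divider ``R1``/``R2`` leaks
it and senses the membrane voltage at the gate of a thyristor (SCR), and the
SCR's hysteretic switching provides the *fire* primitive.  While the SCR
blocks, the membrane node relaxes exponentially toward the resistive-divider
steady state; when the divider tap reaches the SCR gate threshold ``V_th``
(i.e. the membrane reaches ``V_c* = V_th (R1+R2)/R2``) the SCR commutes to
its low-resistance state and the capacitor discharges through ``R_LO + R3``,
producing the action potential.  Conduction ends when the SCR current drops
below the holding current ``I_hold``, i.e. when the membrane voltage crosses
``I_hold (R_LO + R3)``.

Both SCR states leave the membrane equation linear, so every trajectory is a
single exponential and threshold crossings invert in closed form.  This
module is purely single-neuron and stateless; the network engine composes it.

All quantities are SI (seconds, volts, ohms, farads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Tuple

__all__ = [
    "ParameterError",
    "SCRDevice",
    "UCNParams",
    "SynapseSpec",
    "UCNState",
    "Drive",
    "DriveSet",
    "synapse",
    "firing_threshold",
    "extinction_voltage",
    "steady_state_voltage",
    "effective_tau",
    "advance_subthreshold",
    "advance_conducting",
    "next_event",
    "time_to_threshold",
    "output_level",
    "output_active",
]

FIRE = "fire"
EXTINGUISH = "extinguish"
NONE = "none"


class ParameterError(ValueError):
    """Invalid circuit parameter or drive configuration."""


@dataclass(frozen=True)
class SCRDevice:
    """Hysteretic switching element (thyristor / silicon controlled rectifier).

    Parameters
    ----------
    v_th : float
        Gate threshold voltage (V).  Reaching it latches the device.
    i_hold : float
        Holding current (A).  Conduction ends when the anode current
        drops below it.
    r_hi : float
        Blocking-state resistance (Ω); must exceed the leak pair R1+R2.
    r_lo : float
        Conducting-state resistance (Ω).
    """

    v_th: float = 0.8
    i_hold: float = 1e-3
    r_hi: float = 10e6
    r_lo: float = 10.0

    def __post_init__(self) -> None:
        if not self.v_th > 0:
            raise ParameterError("SCR gate threshold v_th must be > 0")
        if not self.i_hold > 0:
            raise ParameterError("SCR holding current i_hold must be > 0")
        if not (self.r_hi > self.r_lo > 0):
            raise ParameterError("SCR resistances must satisfy r_hi > r_lo > 0")


@dataclass(frozen=True)
class UCNParams:
    """Full component set of one UCN.

    ``c``, ``r1``, ``r2``, ``r3`` and ``scr`` are the physical circuit; the
    output stage (a transistor plus a supply that strengthens the brief R3
    spike into a drive capable of charging a downstream membrane) is modelled
    as a monostable: each fire event opens an active window of duration
    ``t_out`` during which downstream synapses are driven at ``v_drive``.
    The physical output line idles at ``v_logic_rest`` (logic '0' = 5 V) and
    sits at ``v_logic_active`` (logic '1' = 0 V) during the window.
    """

    c: float = 1e-9
    r1: float = 30e3
    r2: float = 20e3
    r3: float = 100.0
    scr: SCRDevice = field(default_factory=SCRDevice)
    v_drive: float = 5.0
    t_out: float = 25e-6
    v_logic_rest: float = 5.0
    v_logic_active: float = 0.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ParameterError("membrane capacitance c must be > 0")
        if self.r1 < 0:
            raise ParameterError("divider resistance r1 must be >= 0")
        if not self.r2 > 0:
            raise ParameterError("divider resistance r2 must be > 0")
        if not self.r3 > 0:
            raise ParameterError("sense resistance r3 must be > 0")
        if not self.scr.r_hi > self.r1 + self.r2:
            raise ParameterError(
                "SCR blocking resistance r_hi must exceed the leak pair r1 + r2"
            )
        if not self.t_out > 0:
            raise ParameterError("output window t_out must be > 0")


@dataclass(frozen=True)
class SynapseSpec:
    """Dendritic input path: a resistor from a gated drive to the membrane."""

    r_syn: float
    label: str = "axon_segment"

    def __post_init__(self) -> None:
        if not self.r_syn > 0:
            raise ParameterError("synaptic resistance r_syn must be > 0")

    @property
    def conductance(self) -> float:
        return 1.0 / self.r_syn


#: Preset synapses.  An ``axon_segment`` input alone drives the membrane well
#: above threshold (single-spike relay along the delay line); a
#: ``coincidence`` input alone stays subthreshold and two overlapping inputs
#: are needed to fire (two-dendrite coincidence detector).
_SYNAPSE_PRESETS = {
    "axon_segment": 10e3,
    "coincidence": 100e3,
}


def synapse(label: str) -> SynapseSpec:
    """Return a preset synapse (``axon_segment`` = 10 kΩ, ``coincidence`` = 100 kΩ)."""
    try:
        return SynapseSpec(_SYNAPSE_PRESETS[label], label)
    except KeyError:
        raise ParameterError(
            f"unknown synapse preset {label!r}; expected one of "
            f"{sorted(_SYNAPSE_PRESETS)}"
        ) from None


@dataclass
class UCNState:
    """Dynamic state of one neuron: membrane voltage, SCR state, last fire."""

    v_c: float = 0.0
    conducting: bool = False
    t_fire_last: Optional[float] = None
    t: float = 0.0


@dataclass(frozen=True)
class Drive:
    """One external injection path into the membrane node."""

    v_source: float
    conductance: float

    def __post_init__(self) -> None:
        if self.conductance < 0:
            raise ParameterError("drive conductance must be >= 0")


@dataclass(frozen=True)
class DriveSet:
    """External drives currently injecting into the membrane node.

    The fixed leak path (R1+R2 to ground) and the SCR path are *not* listed
    here; the node-equation helpers add them from ``UCNParams`` according to
    the SCR state.
    """

    drives: Tuple[Drive, ...] = ()

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[float, float]]) -> "DriveSet":
        return cls(tuple(Drive(v, g) for v, g in pairs))


EMPTY_DRIVES = DriveSet()


def _node_equation(
    params: UCNParams, drives: DriveSet, conducting: bool
) -> Tuple[float, float]:
    """Return (Σg_i, Σ g_i·v_i) over all paths into the membrane node."""
    g_total = 1.0 / (params.r1 + params.r2)  # leak, always present
    gv = 0.0
    if conducting:
        g_total += 1.0 / (params.scr.r_lo + params.r3)
    elif math.isfinite(params.scr.r_hi):
        g_total += 1.0 / (params.scr.r_hi + params.r3)
    for d in drives.drives:
        g_total += d.conductance
        gv += d.conductance * d.v_source
    return g_total, gv


def firing_threshold(params: UCNParams) -> float:
    """Membrane voltage at which the SCR latches: ``V_c* = v_th (r1+r2)/r2``.

    The divider R1/R2 presents ``V_c·r2/(r1+r2)`` at the SCR gate, so the
    gate reaches ``v_th`` exactly when the membrane reaches this value.
    """
    if params.r2 <= 0:
        raise ParameterError("divider resistance r2 must be > 0")
    return params.scr.v_th * (params.r1 + params.r2) / params.r2


def extinction_voltage(params: UCNParams) -> float:
    """Membrane voltage below which the SCR current falls under ``i_hold``."""
    return params.scr.i_hold * (params.scr.r_lo + params.r3)


def steady_state_voltage(
    params: UCNParams, drives: DriveSet = EMPTY_DRIVES, conducting: bool = False
) -> float:
    """Asymptotic membrane voltage ``V_inf = Σ(g_i v_i)/Σ g_i``.

    Grounded paths (leak, SCR) pull toward 0 V; each active dendrite pulls
    toward its source voltage.
    """
    g_total, gv = _node_equation(params, drives, conducting)
    return gv / g_total


def effective_tau(
    params: UCNParams, drives: DriveSet = EMPTY_DRIVES, conducting: bool = False
) -> float:
    """Relaxation time constant ``τ_eff = C/Σ g_i`` of the current SCR state.

    Reduces to the leak time constant ``(r1+r2)·c`` with no drives and
    ``r_hi = ∞``; in the conducting state it is of order ``(r3+r_lo)·c``.
    """
    g_total, _ = _node_equation(params, drives, conducting)
    return params.c / g_total


def _advance(
    state: UCNState, params: UCNParams, drives: DriveSet, dt: float, conducting: bool
) -> UCNState:
    if dt < 0:
        raise ParameterError(f"cannot advance by negative dt = {dt}")
    if dt == 0:
        return UCNState(state.v_c, state.conducting, state.t_fire_last, state.t)
    v_inf = steady_state_voltage(params, drives, conducting)
    tau = effective_tau(params, drives, conducting)
    v_new = v_inf + (state.v_c - v_inf) * math.exp(-dt / tau)
    return UCNState(v_new, state.conducting, state.t_fire_last, state.t + dt)


def advance_subthreshold(
    state: UCNState, params: UCNParams, drives: DriveSet, dt: float
) -> UCNState:
    """Advance a blocking-state neuron by ``dt`` using the exact exponential.

    The drives are assumed constant over ``dt`` (caller's contract); the
    result relaxes monotonically toward ``steady_state_voltage`` and never
    overshoots it.
    """
    if state.conducting:
        raise ParameterError("advance_subthreshold requires a blocking SCR")
    return _advance(state, params, drives, dt, conducting=False)


def advance_conducting(
    state: UCNState, params: UCNParams, drives: DriveSet, dt: float
) -> UCNState:
    """Advance a conducting-state neuron by ``dt`` (discharge through R_LO+R3)."""
    if not state.conducting:
        raise ParameterError("advance_conducting requires a conducting SCR")
    return _advance(state, params, drives, dt, conducting=True)


def _crossing_time(v0: float, v_target: float, v_inf: float, tau: float) -> float:
    """Time for ``v(t) = v_inf + (v0-v_inf) e^(-t/τ)`` to reach ``v_target``.

    Returns ``inf`` when the relaxation never crosses the target.
    """
    num = v0 - v_inf
    den = v_target - v_inf
    if num == den:
        return 0.0
    # crossing requires the target to lie strictly between v0 and v_inf
    if den == 0.0 or (num > 0) != (den > 0) or abs(den) >= abs(num):
        return math.inf
    return tau * math.log(num / den)


def time_to_threshold(
    params: UCNParams, drives: DriveSet, v0: float = 0.0
) -> float:
    """Closed-form charge time from ``v0`` to the firing threshold (blocking SCR).

    Returns ``inf`` when the drive steady state does not exceed the threshold.
    """
    v_star = firing_threshold(params)
    v_inf = steady_state_voltage(params, drives, conducting=False)
    tau = effective_tau(params, drives, conducting=False)
    if v0 >= v_star:
        return 0.0
    return _crossing_time(v0, v_star, v_inf, tau)


def next_event(
    state: UCNState, params: UCNParams, drives: DriveSet
) -> Tuple[str, float]:
    """Predict this neuron's next autonomous transition under constant drives.

    Returns ``(kind, t_abs)`` where kind is ``"fire"``, ``"extinguish"`` or
    ``"none"`` and ``t_abs`` is the absolute event time (``inf`` for none).
    The caller must re-query whenever any drive changes.
    """
    if state.conducting:
        v_end = extinction_voltage(params)
        if state.v_c <= v_end:
            return EXTINGUISH, state.t
        v_inf = steady_state_voltage(params, drives, conducting=True)
        tau = effective_tau(params, drives, conducting=True)
        dt = _crossing_time(state.v_c, v_end, v_inf, tau)
        if math.isinf(dt):
            return NONE, math.inf  # drives hold the SCR latched
        return EXTINGUISH, state.t + dt
    v_star = firing_threshold(params)
    if state.v_c >= v_star:
        return FIRE, state.t
    dt = time_to_threshold(params, drives, state.v_c)
    if math.isinf(dt):
        return NONE, math.inf
    return FIRE, state.t + dt


def output_active(state: UCNState, params: UCNParams, t: float) -> bool:
    """True while the output-stage window opened by the last fire is active."""
    if state.t_fire_last is None:
        return False
    return state.t_fire_last <= t < state.t_fire_last + params.t_out


def output_level(state: UCNState, params: UCNParams, t: float) -> float:
    """Physical output voltage at time ``t``: active-low pulse of width t_out.

    Rest level is 5 V (logic '0'); during the window after a fire the line
    sits at 0 V (logic '1').  Downstream synaptic drive is ON exactly during
    the active window.
    """
    if output_active(state, params, t):
        return params.v_logic_active
    return params.v_logic_rest
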