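"""Measurement procedures on the simulated circuits.

Covers: spike propagation along a long axon and its rate fit; capacitance
calibration of the per-segment delay; single-ITD runs and full ITD sweeps of
the Jeffress network; winner-takes-all decoding; resolution and offset
measurements; component-mismatch sampling; and a supervised tuning loop that
corrects a mismatched output layer by adjusting the gate-divider resistor
(the memristor surrogate) of wrongly-behaving output neurons.

User-facing times are in microseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .builders import JeffressSpec, LongAxonSpec, build_jeffress, build_long_axon
from .circuit import (
    DriveSet,
    Drive,
    ParameterError,
    SynapseSpec,
    UCNParams,
    firing_threshold,
    steady_state_voltage,
    synapse,
    time_to_threshold,
)
from .network import (
    Network,
    Pulse,
    SimulationConfig,
    StimulusSchedule,
    US,
    build_network,
    simulate,
)

__all__ = [
    "PropagationError",
    "CalibrationError",
    "AxonRunResult",
    "ItdRecord",
    "SweepResult",
    "MismatchModel",
    "TuningConfig",
    "TuneResult",
    "run_axon",
    "calibrate_capacitance",
    "calibrated_axon_unit",
    "default_jeffress_network",
    "run_itd_case",
    "run_itd_sweep",
    "decode_winner",
    "measure_resolution",
    "measure_offset",
    "apply_mismatch",
    "supervised_tune",
    "default_tuning_stimuli",
]


class PropagationError(RuntimeError):
    """A unit of the chain never fired."""


class CalibrationError(RuntimeError):
    """The calibration target cannot be reached."""


# ---------------------------------------------------------------------------
# long-axon propagation


@dataclass(frozen=True)
class AxonRunResult:
    """Per-segment first-fire times and the fitted propagation rate."""

    nodes: Tuple[str, ...]
    fire_times_us: Tuple[float, ...]
    rate_segments_per_us: float
    residual_max_us: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment": range(len(self.nodes)),
             "node": self.nodes,
             "fire_time_us": self.fire_times_us}
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()[["segment", "fire_time_us"]]
        df["fire_time_us"] = df["fire_time_us"].map(lambda v: f"{v:.6f}")
        df.to_csv(path, index=False)


def _single_input_charge_time_us(unit: UCNParams, syn: SynapseSpec) -> float:
    """Closed-form charge time (μs) from 0 V through one active synapse."""
    drives = DriveSet((Drive(unit.v_drive, syn.conductance),))
    t = time_to_threshold(unit, drives)
    if math.isinf(t):
        raise CalibrationError(
            "single-input steady state does not exceed the firing threshold; "
            "the unit can never fire through this synapse"
        )
    return t / US


def run_axon(
    spec: LongAxonSpec,
    stimulus_time_us: float = 0.0,
    stimulus_duration_us: Optional[float] = None,
    level: float = 5.0,
    t_end_us: Optional[float] = None,
) -> AxonRunResult:
    """Stimulate the soma once and fit the propagation rate.

    The first fire time of each unit is regressed on the segment index by
    least squares; the rate is the slope of index against time
    (segment/μs) and ``residual_max_us`` the largest deviation of the fire
    times from the inverse linear fit.
    """
    net = build_long_axon(spec)
    chain = net.meta["chain"]
    unit = net.nodes[chain[0]]
    delay_us = _single_input_charge_time_us(unit, spec.axon_synapse)
    if stimulus_duration_us is None:
        stimulus_duration_us = unit.t_out / US
    if t_end_us is None:
        t_end_us = (
            stimulus_time_us
            + (len(chain) + 1) * delay_us * 1.5
            + 3 * unit.t_out / US
        )
    stim = StimulusSchedule.single(
        spec.port, stimulus_time_us, stimulus_duration_us, level
    )
    traces = simulate(net, stim, SimulationConfig(t_end_us=t_end_us))

    times = []
    for name in chain:
        fires = traces.fire_times(name)
        if not fires:
            raise PropagationError(
                f"propagation failed: unit {name!r} never fired"
            )
        times.append(fires[0])
    idx = np.arange(len(chain), dtype=float)
    t = np.asarray(times)
    rate, intercept = np.polyfit(t, idx, 1)
    # residuals expressed in time: deviation of each fire time from the line
    t_fit = (idx - intercept) / rate
    residual = float(np.max(np.abs(t - t_fit)))
    return AxonRunResult(tuple(chain), tuple(times), float(rate), residual)


# ---------------------------------------------------------------------------
# calibration


def _two_unit_delay_us(unit: UCNParams, syn: SynapseSpec) -> float:
    """Measured inter-fire delay of an isolated two-unit chain (μs)."""
    spec = LongAxonSpec(n_segments=1, unit=unit, axon_synapse=syn)
    res = run_axon(spec)
    return res.fire_times_us[1] - res.fire_times_us[0]


def calibrate_capacitance(
    target_delay_us: float,
    base: Optional[UCNParams] = None,
    axon_synapse: Optional[SynapseSpec] = None,
    rtol: float = 1e-4,
) -> float:
    """Capacitance giving a two-unit chain the requested inter-fire delay.

    The delay is strictly increasing in ``c`` (every time constant scales
    with it), so a bisection converges unconditionally.  The drive window
    must persist past the crossing, so the search runs with ``t_out`` raised
    to at least 1.2× the target delay; :func:`calibrated_axon_unit` returns
    the full adjusted parameter record.
    """
    base = base or UCNParams()
    syn = axon_synapse or synapse("axon_segment")
    if not target_delay_us > 0:
        raise CalibrationError("target delay must be > 0")
    v_inf = steady_state_voltage(
        base, DriveSet((Drive(base.v_drive, syn.conductance),))
    )
    if v_inf <= firing_threshold(base):
        raise CalibrationError(
            f"infeasible: single-input steady state {v_inf:.3f} V does not "
            f"exceed the firing threshold {firing_threshold(base):.3f} V"
        )
    t_out = max(base.t_out, 1.2 * target_delay_us * US)

    def delay(c: float) -> float:
        # during the search the drive window must outlast the candidate's own
        # charge time, which the closed form gives up front
        unit = replace(base, c=c, t_out=t_out)
        t_meas = max(t_out, 1.5 * _single_input_charge_time_us(unit, syn) * US)
        return _two_unit_delay_us(replace(unit, t_out=t_meas), syn)

    # delay ∝ c: start from the linear estimate, then bracket and bisect
    d0 = delay(base.c)
    c_lo = base.c * target_delay_us / d0 * 0.5
    c_hi = base.c * target_delay_us / d0 * 2.0
    if not (delay(c_lo) < target_delay_us < delay(c_hi)):
        raise CalibrationError("failed to bracket the calibration target")
    for _ in range(100):
        c_mid = 0.5 * (c_lo + c_hi)
        d_mid = delay(c_mid)
        if abs(d_mid - target_delay_us) <= rtol * target_delay_us:
            return c_mid
        if d_mid < target_delay_us:
            c_lo = c_mid
        else:
            c_hi = c_mid
    raise CalibrationError("bisection did not converge")


def calibrated_axon_unit(
    target_delay_us: float,
    base: Optional[UCNParams] = None,
    axon_synapse: Optional[SynapseSpec] = None,
    rtol: float = 1e-4,
) -> UCNParams:
    """Axon unit with ``c`` calibrated and ``t_out ≥ 1.2 × target_delay``."""
    base = base or UCNParams()
    c = calibrate_capacitance(target_delay_us, base, axon_synapse, rtol)
    t_out = max(base.t_out, 1.2 * target_delay_us * US)
    return replace(base, c=c, t_out=t_out)


def default_jeffress_network(
    per_segment_delay_us: float = 20.0,
    n_side: int = 4,
    output_unit: Optional[UCNParams] = None,
) -> Network:
    """The study network: delay lines calibrated to a given per-segment delay.

    The default 20 μs delay and the 3-output topology give the 40 μs ITD
    resolution (two segments of travel separate neighboring detectors).
    """
    axon_unit = calibrated_axon_unit(per_segment_delay_us)
    spec = JeffressSpec(n_side=n_side, axon_unit=axon_unit)
    if output_unit is not None:
        spec = replace(spec, output_unit=output_unit)
    net = build_jeffress(spec)
    net.meta["per_segment_delay_us"] = per_segment_delay_us
    return net


# ---------------------------------------------------------------------------
# ITD runs, sweeps, decoding


@dataclass(frozen=True)
class ItdRecord:
    """Response of the output layer to one ITD (μs).

    ``itd_us > 0`` means the right ear leads (source on the right).
    """

    itd_us: float
    outputs: Tuple[str, ...]
    pulse_widths_us: Mapping[str, Tuple[float, ...]]
    total_width_us: Mapping[str, float]
    peak_v_c: Mapping[str, float]
    fired: Mapping[str, bool]
    fire_times_us: Mapping[str, Tuple[float, ...]]
    winner: Optional[str]


def _output_order(net: Network) -> Tuple[str, ...]:
    outputs = net.meta.get("outputs")
    if outputs is None:
        raise ParameterError(
            "network has no output-layer metadata; build it with build_jeffress"
        )
    return tuple(outputs)


def run_itd_case(
    net: Network,
    itd_us: float,
    stimulus_duration_us: Optional[float] = None,
    level: float = 5.0,
    t_end_us: Optional[float] = None,
) -> ItdRecord:
    """Stimulate the two ears with the given ITD and record the output layer.

    Positive ITD = right ear leads, so the right stimulus starts first.  The
    winning output fires only after integrating the coincident windows, a
    lag set by its two-input time constant.
    """
    outputs = _output_order(net)
    left_chain = net.meta["left_chain"]
    axon_unit = net.nodes[left_chain[0]]
    syn = next(e.synapse for e in net.edges if e.target == left_chain[1])
    delay_us = _single_input_charge_time_us(axon_unit, syn)
    t_out_us = axon_unit.t_out / US
    if stimulus_duration_us is None:
        stimulus_duration_us = t_out_us
    t_left = max(itd_us, 0.0)
    t_right = max(-itd_us, 0.0)
    if t_end_us is None:
        n_side = net.meta["n_side"]
        t_end_us = (
            abs(itd_us) + (n_side + 1) * delay_us + 4 * t_out_us + 20.0
        )
    stim = StimulusSchedule(
        {
            "L": (Pulse(t_left, stimulus_duration_us, level),),
            "R": (Pulse(t_right, stimulus_duration_us, level),),
        }
    )
    traces = simulate(net, stim, SimulationConfig(t_end_us=t_end_us))

    widths = {o: tuple(traces.pulse_widths(o)) for o in outputs}
    record = ItdRecord(
        itd_us=itd_us,
        outputs=outputs,
        pulse_widths_us=widths,
        total_width_us={o: float(sum(widths[o])) for o in outputs},
        peak_v_c={o: traces.peak_v_c(o) for o in outputs},
        fired={o: bool(traces.fire_times(o)) for o in outputs},
        fire_times_us={o: tuple(traces.fire_times(o)) for o in outputs},
        winner=None,
    )
    return replace(record, winner=decode_winner(record, net))


def decode_winner(record: ItdRecord, net: Optional[Network] = None) -> Optional[str]:
    """Winner-takes-all readout of one ITD record.

    The largest total output pulse width wins; ties fall back to the largest
    peak membrane voltage, then to the label closest to the center of the
    array.  If no output fired and every peak stays below half the firing
    threshold the stimulus is undetected (``None``).
    """
    outputs = record.outputs
    if net is not None:
        half_threshold = 0.5 * min(
            firing_threshold(net.nodes[o]) for o in outputs
        )
    else:
        half_threshold = 1.0
    if not any(record.fired[o] for o in outputs) and all(
        record.peak_v_c[o] < half_threshold for o in outputs
    ):
        return None
    center = (len(outputs) - 1) / 2
    ranked = sorted(
        outputs,
        key=lambda o: (
            -record.total_width_us[o],
            -record.peak_v_c[o],
            abs(outputs.index(o) - center),
            outputs.index(o),
        ),
    )
    return ranked[0]


@dataclass(frozen=True)
class SweepResult:
    """One :class:`ItdRecord` per swept ITD value (grid sorted ascending)."""

    records: Tuple[ItdRecord, ...]

    @property
    def itds_us(self) -> np.ndarray:
        return np.array([r.itd_us for r in self.records])

    @property
    def winners(self) -> List[Optional[str]]:
        return [r.winner for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for o in r.outputs:
                rows.append(
                    (r.itd_us, o, r.total_width_us[o], r.peak_v_c[o],
                     r.winner if r.winner is not None else "none")
                )
        return pd.DataFrame(
            rows, columns=["itd_us", "output", "pulse_width_us", "peak_vc", "winner"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_itd_sweep(net: Network, itd_grid_us: Sequence[float]) -> SweepResult:
    """One :func:`run_itd_case` per grid point; deterministic."""
    grid = list(itd_grid_us)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ParameterError("ITD grid must be sorted strictly ascending")
    return SweepResult(tuple(run_itd_case(net, itd) for itd in grid))


def _transition_positions(sweep: SweepResult) -> List[float]:
    """ITD positions where the winner identity changes.

    Each transition is located by linearly interpolating the zero crossing
    of the peak-voltage margin between the outgoing and incoming winner over
    the straddling grid interval (the actual decision boundary, independent
    of the grid step).  When either label fired on either side — so the
    decision was made on pulse widths, which step discontinuously — the
    interval midpoint is used instead.
    """
    recs = sweep.records
    positions = []
    for i in range(1, len(recs)):
        a, b = recs[i - 1], recs[i]
        if a.winner == b.winner:
            continue
        x0, x1 = a.itd_us, b.itd_us
        la, lb = a.winner, b.winner
        mid = 0.5 * (x0 + x1)
        if la is None or lb is None:
            positions.append(mid)
            continue
        fired = any(r.fired[lab] for r in (a, b) for lab in (la, lb))
        if fired:
            positions.append(mid)
            continue
        # margin m(x) = peak_incoming − peak_outgoing crosses zero in [x0, x1]
        m0 = a.peak_v_c[lb] - a.peak_v_c[la]
        m1 = b.peak_v_c[lb] - b.peak_v_c[la]
        if m1 == m0:
            positions.append(mid)
        else:
            x = x0 - m0 * (x1 - x0) / (m1 - m0)
            positions.append(min(max(x, x0), x1))
    return positions


def measure_resolution(sweep: SweepResult) -> float:
    """Mean ITD spacing (μs) between consecutive winner-identity changes."""
    pos = _transition_positions(sweep)
    if len(pos) < 2:
        raise ValueError(
            f"need at least 2 winner transitions to measure a spacing; got {len(pos)}"
        )
    return float(np.mean(np.diff(pos)))


def measure_offset(sweep: SweepResult, center_label: str = "OC") -> float:
    """Midpoint (μs) of the ITD interval won by the center output.

    Zero for a perfectly matched network; component mismatch shifts it.
    """
    winners = sweep.winners
    if center_label not in winners:
        raise ValueError(f"center output {center_label!r} never wins in this sweep")
    pos = _transition_positions(sweep)
    recs = sweep.records
    # edges of the center block among the transition list
    left_edge = None
    right_edge = None
    k = 0
    for i in range(1, len(recs)):
        if recs[i - 1].winner == recs[i].winner:
            continue
        if recs[i].winner == center_label:
            left_edge = pos[k]
        if recs[i - 1].winner == center_label:
            right_edge = pos[k]
        k += 1
    if left_edge is None:
        left_edge = recs[0].itd_us
    if right_edge is None:
        right_edge = recs[-1].itd_us
    return 0.5 * (left_edge + right_edge)


# ---------------------------------------------------------------------------
# component mismatch and supervised tuning


@dataclass(frozen=True)
class MismatchModel:
    """Maker-tolerance dispersion: independent uniform factors in [1−tol, 1+tol].

    Applied per component instance to the divider resistors, the membrane
    capacitor and the SCR gate threshold.  The seed is mandatory so every
    sampled network is reproducible.
    """

    seed: int
    r1: float = 0.05
    r2: float = 0.05
    c: float = 0.05
    v_th: float = 0.05
    nodes: Optional[Tuple[str, ...]] = None
    """Restrict the dispersion to these nodes (default: every node)."""

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "c", "v_th"):
            if getattr(self, name) < 0:
                raise ParameterError(f"tolerance {name} must be >= 0")


def apply_mismatch(net: Network, model: MismatchModel) -> Network:
    """Perturb the selected nodes' components by seeded uniform factors."""
    rng = np.random.default_rng(model.seed)
    selected = set(net.nodes if model.nodes is None else model.nodes)
    unknown = selected - set(net.nodes)
    if unknown:
        raise ParameterError(f"mismatch selects unknown nodes {sorted(unknown)}")
    nodes = {}
    for name in sorted(net.nodes):
        p = net.nodes[name]
        if name not in selected:
            nodes[name] = p
            continue
        f_r1, f_r2, f_c, f_vth = (
            rng.uniform(1.0 - tol, 1.0 + tol) if tol > 0 else 1.0
            for tol in (model.r1, model.r2, model.c, model.v_th)
        )
        nodes[name] = replace(
            p,
            r1=p.r1 * f_r1,
            r2=p.r2 * f_r2,
            c=p.c * f_c,
            scr=replace(p.scr, v_th=p.scr.v_th * f_vth),
        )
    return build_network(nodes, net.edges, net.ports, meta=dict(net.meta))


def default_tuning_stimuli(
    per_segment_delay_us: float,
    sweep_step_us: float = 1.0,
    labels: Tuple[str, str, str] = ("OL", "OC", "OR"),
) -> Tuple[Tuple[float, str], ...]:
    """Calibration set bracketing the nominal decision boundaries at ±delay.

    Correct decisions one sweep step inside and outside each boundary pin
    both boundaries to within a step, hence the post-tuning offset too.
    """
    d = per_segment_delay_us
    s = sweep_step_us
    ol, oc, orr = labels
    return (
        (0.0, oc),
        (-(d - s), oc),
        (d - s, oc),
        (-(d + s), ol),
        (d + s, orr),
        (-2 * d, ol),
        (2 * d, orr),
    )


@dataclass(frozen=True)
class TuningConfig:
    """Supervised correction loop settings.

    Each wrong decision nudges the gate-divider resistor ``r2`` (the
    memristor surrogate) of the offending output neurons by ``step``:
    raising ``r2`` lowers the firing threshold ``V_c* = v_th (r1+r2)/r2``
    and weakens the leak, making that neuron more excitable; lowering it
    does the opposite.
    """

    stimuli: Tuple[Tuple[float, str], ...]
    step: float = 0.02
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise ParameterError("tuning step must be > 0")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if not any(itd == 0.0 for itd, _ in self.stimuli):
            raise ParameterError("calibration stimuli must include itd = 0")


@dataclass(frozen=True)
class TuneResult:
    network: Network
    converged: bool
    iterations: int
    log: Tuple[Tuple[int, float, str, Optional[str], str, float], ...]
    """Rows: (iteration, itd_us, expected, decoded, adjusted node, factor)."""


def _scale_r2(net: Network, node: str, factor: float) -> Network:
    nodes = dict(net.nodes)
    nodes[node] = replace(nodes[node], r2=nodes[node].r2 * factor)
    return build_network(nodes, net.edges, net.ports, meta=dict(net.meta))


def _keeps_coincidence_tuning(net: Network, node: str, factor: float) -> bool:
    """Would scaling ``r2`` keep the node a two-input coincidence detector?

    A boost must not let the node latch on a single input window (its
    single-drive steady state must stay below threshold) and a cut must not
    push the threshold beyond the two-input steady state (it could then
    never fire at all).  Adjustments violating either bound are withheld.
    """
    cand = replace(net.nodes[node], r2=net.nodes[node].r2 * factor)
    gs = [e.synapse.conductance for e in net.edges if e.target == node]
    v_dr = [net.nodes[e.source].v_drive for e in net.edges if e.target == node]
    single = max(
        steady_state_voltage(cand, DriveSet((Drive(v, g),)))
        for v, g in zip(v_dr, gs)
    )
    both = steady_state_voltage(
        cand, DriveSet(tuple(Drive(v, g) for v, g in zip(v_dr, gs)))
    )
    v_star = firing_threshold(cand)
    return single < v_star < both


def supervised_tune(net: Network, cfg: TuningConfig) -> TuneResult:
    """Iteratively correct the output layer until all stimuli decode correctly.

    Runs every calibration stimulus each iteration; for each wrong decision
    the wrongly-winning output's ``r2`` is scaled by ``(1 − step)`` (raising
    its threshold) and the expected output's by ``(1 + step)`` (lowering
    it).  Only output-layer neurons are ever modified.  Non-convergence
    within ``max_iterations`` is reported, not silent.
    """
    outputs = set(_output_order(net))
    log: List[Tuple[int, float, str, Optional[str], str, float]] = []
    current = net
    for it in range(1, cfg.max_iterations + 1):
        wrong = []
        for itd, expected in cfg.stimuli:
            rec = run_itd_case(current, itd)
            if rec.winner != expected:
                wrong.append((itd, expected, rec.winner))
        if not wrong:
            return TuneResult(current, True, it - 1, tuple(log))
        # one net adjustment per output per iteration; an output that wrongly
        # won anywhere is cut, and only outputs that never wrongly won are
        # boosted — otherwise conflicting corrections cancel and stall
        cut = {got for _, _, got in wrong if got is not None and got in outputs}
        boost = {
            expected for _, expected, _ in wrong
            if expected in outputs and expected not in cut
        }
        adjusted = False
        for itd, expected, got in wrong:
            if got in cut:
                cut.discard(got)
                if _keeps_coincidence_tuning(current, got, 1.0 - cfg.step):
                    current = _scale_r2(current, got, 1.0 - cfg.step)
                    log.append((it, itd, expected, got, got, 1.0 - cfg.step))
                    adjusted = True
            if expected in boost:
                boost.discard(expected)
                if _keeps_coincidence_tuning(current, expected, 1.0 + cfg.step):
                    current = _scale_r2(current, expected, 1.0 + cfg.step)
                    log.append((it, itd, expected, got, expected, 1.0 + cfg.step))
                    adjusted = True
        if not adjusted:
            # every remaining correction would break the coincidence tuning:
            # the residual errors are not reachable through the output layer
            return TuneResult(current, False, it, tuple(log))
    return TuneResult(current, False, cfg.max_iterations, tuple(log))
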