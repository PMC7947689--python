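"""Networks of UCNs and the event-driven hybrid simulation.

The circuit is piecewise linear: between switching events every membrane
voltage is a single exponential, so event times (threshold crossings, SCR
extinctions, output-window closings, stimulus edges) can be inverted exactly.
The engine advances all neurons analytically from one global event to the
next — there is no step-size error.

Network times at this interface are in microseconds; component values inside
``UCNParams`` remain SI (so ``t_out`` is in seconds).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit import (
    Drive,
    DriveSet,
    ParameterError,
    SynapseSpec,
    UCNParams,
    UCNState,
    extinction_voltage,
    firing_threshold,
    next_event,
    steady_state_voltage,
    effective_tau,
)

__all__ = [
    "NetworkError",
    "SimulationError",
    "Edge",
    "Port",
    "Network",
    "Pulse",
    "StimulusSchedule",
    "SimulationConfig",
    "TraceSet",
    "build_network",
    "simulate",
    "fire_times",
    "pulse_widths",
]

US = 1e-6  # one microsecond in seconds

MAX_IN_DEGREE = 2  # the building blocks are one- and two-input UCNs


class NetworkError(ValueError):
    """Invalid network topology."""


class SimulationError(RuntimeError):
    """The event engine could not make progress (event-queue livelock)."""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    synapse: SynapseSpec


@dataclass(frozen=True)
class Port:
    """Named external stimulus injection point attached to one node."""

    name: str
    target: str
    synapse: SynapseSpec


@dataclass(frozen=True)
class Network:
    """Directed graph of named UCNs with synaptic edges and stimulus ports."""

    nodes: Mapping[str, UCNParams]
    edges: Tuple[Edge, ...]
    ports: Tuple[Port, ...]
    meta: Mapping[str, object] = field(default_factory=dict, compare=False)

    def in_degree(self, name: str) -> int:
        return sum(e.target == name for e in self.edges) + sum(
            p.target == name for p in self.ports
        )


def build_network(
    nodes: Mapping[str, UCNParams],
    edges: Sequence[Edge] = (),
    ports: Sequence[Port] = (),
    meta: Optional[Mapping[str, object]] = None,
) -> Network:
    """Validate and assemble a :class:`Network`.

    Node names must be unique, every edge/port endpoint must exist, and no
    node may have more than two inputs (edges and ports combined): the
    hardware building blocks are one- and two-input UCNs.
    """
    nodes = dict(nodes)
    seen_ports = set()
    for p in ports:
        if p.name in seen_ports:
            raise NetworkError(f"duplicate stimulus port name {p.name!r}")
        seen_ports.add(p.name)
        if p.target not in nodes:
            raise NetworkError(f"port {p.name!r} targets unknown node {p.target!r}")
    for e in edges:
        if e.source not in nodes:
            raise NetworkError(f"edge references unknown source node {e.source!r}")
        if e.target not in nodes:
            raise NetworkError(f"edge references unknown target node {e.target!r}")
    net = Network(nodes, tuple(edges), tuple(ports), dict(meta or {}))
    for name in nodes:
        deg = net.in_degree(name)
        if deg > MAX_IN_DEGREE:
            raise NetworkError(
                f"node {name!r} has in-degree {deg}; the UCN blocks support at "
                f"most {MAX_IN_DEGREE} dendritic inputs"
            )
    return net


@dataclass(frozen=True)
class Pulse:
    """One rectangular stimulus pulse (times in μs, level in volts)."""

    start_us: float
    duration_us: float
    level: float = 5.0

    def __post_init__(self) -> None:
        if self.start_us < 0:
            raise ParameterError("stimulus pulse start must be >= 0")
        if not self.duration_us > 0:
            raise ParameterError("stimulus pulse duration must be > 0")

    @property
    def end_us(self) -> float:
        return self.start_us + self.duration_us


@dataclass(frozen=True)
class StimulusSchedule:
    """Per-port pulse trains; pulses on one port must not overlap."""

    pulses: Mapping[str, Tuple[Pulse, ...]]

    def __post_init__(self) -> None:
        for port, train in self.pulses.items():
            ordered = sorted(train, key=lambda p: p.start_us)
            for a, b in zip(ordered, ordered[1:]):
                if b.start_us < a.end_us:
                    raise ParameterError(
                        f"overlapping stimulus pulses on port {port!r}"
                    )

    @classmethod
    def single(cls, port: str, start_us: float, duration_us: float,
               level: float = 5.0) -> "StimulusSchedule":
        return cls({port: (Pulse(start_us, duration_us, level),)})


@dataclass(frozen=True)
class SimulationConfig:
    """Engine configuration (times in μs)."""

    t_end_us: float
    sample_interval_us: float = 0.5
    tol_us: float = 1e-6  # event-time coincidence tolerance (1 ps)

    def __post_init__(self) -> None:
        if not self.t_end_us > 0:
            raise ParameterError("t_end_us must be > 0")
        if not self.sample_interval_us > 0:
            raise ParameterError("sample_interval_us must be > 0")


@dataclass(frozen=True)
class _Segment:
    """One piecewise-exponential stretch of a node trajectory (seconds)."""

    t0: float
    t1: float
    v0: float
    v_inf: float
    tau: float

    def value(self, t: float) -> float:
        return self.v_inf + (self.v0 - self.v_inf) * math.exp(-(t - self.t0) / self.tau)

    @property
    def v1(self) -> float:
        return self.value(self.t1)


class TraceSet:
    """Simulation result: per-node events, analytic trajectories and samples.

    Event and sample times are in μs; membrane voltages and output levels in
    volts.  Fire/extinguish events are exact (event-engine times); sampled
    traces are evaluated from the closed-form segments on the sample grid.
    """

    def __init__(
        self,
        node_names: Sequence[str],
        node_params: Mapping[str, UCNParams],
        segments: Mapping[str, List[_Segment]],
        fires: Mapping[str, List[float]],
        extinctions: Mapping[str, List[float]],
        t_end_us: float,
        sample_interval_us: float,
    ) -> None:
        self.node_names = list(node_names)
        self._params = dict(node_params)
        self._segments = {n: list(segments[n]) for n in node_names}
        self._fires_us = {n: [t / US for t in fires[n]] for n in node_names}
        self._ext_us = {n: [t / US for t in extinctions[n]] for n in node_names}
        self.t_end_us = t_end_us
        self.sample_times_us = np.arange(0.0, t_end_us, sample_interval_us)

    def _check(self, node: str) -> None:
        if node not in self._segments:
            raise NetworkError(f"unknown node {node!r}")

    def fire_times(self, node: str) -> List[float]:
        """Ordered fire-event times (μs) of ``node``."""
        self._check(node)
        return list(self._fires_us[node])

    def extinguish_times(self, node: str) -> List[float]:
        self._check(node)
        return list(self._ext_us[node])

    def pulse_widths(self, node: str) -> List[float]:
        """Output pulse widths (μs), one per fire event (t_out, clipped at t_end)."""
        self._check(node)
        t_out_us = self._params[node].t_out / US
        return [
            min(t + t_out_us, self.t_end_us) - t for t in self._fires_us[node]
        ]

    def v_c(self, node: str, t_us: float) -> float:
        """Membrane voltage at an arbitrary time, from the closed-form segments."""
        self._check(node)
        t = t_us * US
        segs = self._segments[node]
        if not segs or t <= segs[0].t0:
            return segs[0].v0 if segs else 0.0
        for seg in segs:
            if t <= seg.t1:
                return seg.value(t)
        return segs[-1].v1

    def peak_v_c(self, node: str) -> float:
        """Exact trajectory maximum: each segment is monotone, so the peak
        lies at a segment endpoint."""
        self._check(node)
        peak = 0.0
        for seg in self._segments[node]:
            peak = max(peak, seg.v0, seg.v1)
        return peak

    def output_level(self, node: str, t_us: float) -> float:
        self._check(node)
        p = self._params[node]
        t_out_us = p.t_out / US
        for f in self._fires_us[node]:
            if f <= t_us < f + t_out_us:
                return p.v_logic_active
        return p.v_logic_rest

    def samples(self, node: str) -> Tuple[np.ndarray, np.ndarray]:
        """(v_c, v_out) sampled on ``sample_times_us``."""
        self._check(node)
        vc = np.array([self.v_c(node, t) for t in self.sample_times_us])
        vout = np.array([self.output_level(node, t) for t in self.sample_times_us])
        return vc, vout

    def to_frame(self) -> pd.DataFrame:
        """Long-format samples: columns ``t_us, node, v_c, v_out``."""
        frames = []
        for n in self.node_names:
            vc, vout = self.samples(n)
            frames.append(
                pd.DataFrame(
                    {"t_us": self.sample_times_us, "node": n, "v_c": vc, "v_out": vout}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def events_frame(self) -> pd.DataFrame:
        """Long-format events: columns ``node, kind, t_us``."""
        rows = []
        for n in self.node_names:
            for t in self._fires_us[n]:
                rows.append((n, "fire", t))
            for t in self._ext_us[n]:
                rows.append((n, "extinguish", t))
        rows.sort(key=lambda r: (r[2], r[0]))
        return pd.DataFrame(rows, columns=["node", "kind", "t_us"])

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["t_us"] = df["t_us"].map(lambda v: f"{v:.6f}")
        df.to_csv(path, index=False)

    def events_to_csv(self, path) -> None:
        df = self.events_frame()
        df["t_us"] = df["t_us"].map(lambda v: f"{v:.6f}")
        df.to_csv(path, index=False)


def fire_times(traces: TraceSet, node: str) -> List[float]:
    """Ordered fire-event times (μs) of ``node`` — accessor on :class:`TraceSet`."""
    return traces.fire_times(node)


def pulse_widths(traces: TraceSet, node: str) -> List[float]:
    """Output pulse widths (μs) of ``node`` — accessor on :class:`TraceSet`."""
    return traces.pulse_widths(node)


class _NodeRt:
    """Mutable per-node runtime record for the engine (times in seconds)."""

    __slots__ = (
        "params", "v_star", "v_end", "t_out", "inputs",
        "v_c", "conducting", "window_until", "fires", "extinctions", "segments",
    )

    def __init__(self, params: UCNParams):
        self.params = params
        self.v_star = firing_threshold(params)
        self.v_end = extinction_voltage(params)
        self.t_out = params.t_out
        self.inputs: List[Tuple[str, object, float]] = []  # (kind, ref, conductance)
        self.v_c = 0.0
        self.conducting = False
        self.window_until = -math.inf
        self.fires: List[float] = []
        self.extinctions: List[float] = []
        self.segments: List[_Segment] = []


def simulate(
    net: Network, stim: StimulusSchedule, cfg: SimulationConfig
) -> TraceSet:
    """Run the hybrid event-driven simulation.

    Between consecutive global events every node follows its closed-form
    exponential; at each event the drive sets are rebuilt and the per-node
    crossing times re-inverted.  Simultaneous events (within ``tol_us``) are
    processed in lexicographic node-name order, which makes runs with
    identical inputs bit-identical.

    A neuron's dendritic inputs are disconnected while its own output window
    is active (the monostable output stage is busy reshaping the spike), so
    one upstream window elicits at most one downstream spike; sustained
    drive produces tonic firing at a period ≥ ``t_out``.
    """
    names = sorted(net.nodes)
    tol = cfg.tol_us * US
    t_end = cfg.t_end_us * US

    rt: Dict[str, _NodeRt] = {n: _NodeRt(net.nodes[n]) for n in names}
    for e in net.edges:
        rt[e.target].inputs.append(("edge", e.source, e.synapse.conductance))
    port_pulses: Dict[str, List[Tuple[float, float, float]]] = {}
    for p in net.ports:
        train = stim.pulses.get(p.name, ())
        pulses = sorted(
            (pl.start_us * US, pl.end_us * US, pl.level) for pl in train
        )
        port_pulses[p.name] = pulses
        rt[p.target].inputs.append(("port", p.name, p.synapse.conductance))

    # static boundary times: stimulus edges (window closings are dynamic)
    static_bounds = sorted(
        {tb for pulses in port_pulses.values() for s, e, _ in pulses for tb in (s, e)
         if tb < t_end}
    )

    def upstream_active(src: str, t: float) -> bool:
        r = rt[src]
        return bool(r.fires) and r.fires[-1] <= t < r.fires[-1] + r.t_out - tol

    def port_level(port: str, t: float) -> Optional[float]:
        for s, e, level in port_pulses[port]:
            if s - tol <= t < e - tol:
                return level
        return None

    def assemble(n: str, t: float) -> DriveSet:
        r = rt[n]
        if t < r.window_until - tol:  # own output stage busy: inputs gated off
            return EMPTY
        drives = []
        for kind, ref, g in r.inputs:
            if kind == "edge":
                if upstream_active(ref, t):
                    drives.append(Drive(rt[ref].params.v_drive, g))
            else:
                level = port_level(ref, t)
                if level is not None:
                    drives.append(Drive(level, g))
        return DriveSet(tuple(drives))

    EMPTY = DriveSet()
    t = 0.0
    bound_idx = 0
    stall = 0
    for _ in range(1_000_000):
        # next static/dynamic boundary strictly ahead of t
        while bound_idx < len(static_bounds) and static_bounds[bound_idx] <= t + tol:
            bound_idx += 1
        t_bound = static_bounds[bound_idx] if bound_idx < len(static_bounds) else math.inf
        for n in names:
            wu = rt[n].window_until
            if t + tol < wu < t_bound:
                t_bound = wu

        drive_now: Dict[str, DriveSet] = {}
        cand: Dict[str, Tuple[str, float]] = {}
        t_next = min(t_bound, t_end)
        for n in names:
            d = assemble(n, t)
            drive_now[n] = d
            r = rt[n]
            st = UCNState(r.v_c, r.conducting, None, t)
            kind, te = next_event(st, r.params, d)
            cand[n] = (kind, te)
            if te < t_next:
                t_next = te
        t_next = max(t_next, t)

        # advance every node analytically over [t, t_next]
        for n in names:
            r = rt[n]
            v_inf = steady_state_voltage(r.params, drive_now[n], r.conducting)
            tau = effective_tau(r.params, drive_now[n], r.conducting)
            seg = _Segment(t, t_next, r.v_c, v_inf, tau)
            if t_next > t:
                r.segments.append(seg)
            r.v_c = seg.value(t_next)

        if t_next >= t_end - tol:
            break

        fired_any = False
        for n in names:  # deterministic name order for simultaneous events
            kind, te = cand[n]
            if te <= t_next + tol:
                r = rt[n]
                if kind == "fire":
                    r.v_c = r.v_star
                    r.conducting = True
                    r.fires.append(t_next)
                    r.window_until = t_next + r.t_out
                    fired_any = True
                elif kind == "extinguish":
                    r.v_c = r.v_end
                    r.conducting = False
                    r.extinctions.append(t_next)

        if t_next <= t + tol and not fired_any:
            stall += 1
            if stall > 10_000:
                raise SimulationError(
                    f"event-queue livelock near t = {t / US:.6f} μs: repeated "
                    f"events closer than the {cfg.tol_us} μs tolerance"
                )
        else:
            stall = 0
        t = t_next
    else:
        raise SimulationError("event budget exhausted (1e6 events)")

    return TraceSet(
        names,
        {n: rt[n].params for n in names},
        {n: rt[n].segments for n in names},
        {n: rt[n].fires for n in names},
        {n: rt[n].extinctions for n in names},
        cfg.t_end_us,
        cfg.sample_interval_us,
    )
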