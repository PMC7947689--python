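"""Brute-force fixed-step reference integrator.

Independent cross-check for the event-driven engine: no closed-form event
inversion, just a dense time grid (default 10 ns) with per-step exponential
updates of each membrane node and threshold tests at grid points.  Event
times are accurate to one step, which is far below the 0.05 μs agreement
bound the engine is checked against.
"""

from __future__ import annotations

import math
from typing import Dict, List

from ucnsim.network import Network, StimulusSchedule, US


def fixed_step_events(
    net: Network,
    stim: StimulusSchedule,
    t_end_us: float,
    dt_us: float = 0.01,
) -> Dict[str, Dict[str, List[float]]]:
    """Simulate on a fixed grid; return per-node fire/extinguish times (μs)."""
    names = sorted(net.nodes)
    dt = dt_us * US
    n_steps = int(round(t_end_us / dt_us))

    v = {n: 0.0 for n in names}
    conducting = {n: False for n in names}
    window_until = {n: -math.inf for n in names}
    fires: Dict[str, List[float]] = {n: [] for n in names}
    exts: Dict[str, List[float]] = {n: [] for n in names}

    in_edges = {n: [] for n in names}
    for e in net.edges:
        in_edges[e.target].append((e.source, e.synapse.conductance))
    in_ports = {n: [] for n in names}
    pulses = {}
    for p in net.ports:
        train = stim.pulses.get(p.name, ())
        pulses[p.name] = [(pl.start_us * US, pl.end_us * US, pl.level) for pl in train]
        in_ports[p.target].append((p.name, p.synapse.conductance))

    thresholds = {}
    v_ends = {}
    for n in names:
        prm = net.nodes[n]
        thresholds[n] = prm.scr.v_th * (prm.r1 + prm.r2) / prm.r2
        v_ends[n] = prm.scr.i_hold * (prm.scr.r_lo + prm.r3)

    for k in range(n_steps):
        t = k * dt
        new_v = {}
        for n in names:
            prm = net.nodes[n]
            g = 1.0 / (prm.r1 + prm.r2)
            if conducting[n]:
                g += 1.0 / (prm.scr.r_lo + prm.r3)
            elif math.isfinite(prm.scr.r_hi):
                g += 1.0 / (prm.scr.r_hi + prm.r3)
            gv = 0.0
            if t >= window_until[n]:  # inputs gated off during own window
                for src, g_syn in in_edges[n]:
                    if fires[src] and fires[src][-1] * US <= t < fires[src][-1] * US + net.nodes[src].t_out:
                        g += g_syn
                        gv += g_syn * net.nodes[src].v_drive
                for port, g_syn in in_ports[n]:
                    for s, e, level in pulses[port]:
                        if s <= t < e:
                            g += g_syn
                            gv += g_syn * level
                            break
            v_inf = gv / g
            tau = prm.c / g
            new_v[n] = v_inf + (v[n] - v_inf) * math.exp(-dt / tau)
        t_next = (k + 1) * dt
        for n in names:
            v[n] = new_v[n]
            if not conducting[n] and v[n] >= thresholds[n]:
                conducting[n] = True
                fires[n].append(t_next / US)
                window_until[n] = t_next + net.nodes[n].t_out
            elif conducting[n] and v[n] <= v_ends[n]:
                conducting[n] = False
                exts[n].append(t_next / US)
    return {n: {"fire": fires[n], "extinguish": exts[n]} for n in names}
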