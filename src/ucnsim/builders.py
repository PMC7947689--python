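"""Constructors for the two studied architectures.

* the **long-axon neuron**: a soma S0 followed by a one-dimensional chain of
  axon-segment UCNs (S1…Sn), each relaying the previous unit's spike — a
  spiking delay line analogous to saltatory conduction between nodes of
  Ranvier;
* the **Jeffress network**: two such delay lines carrying spikes in opposite
  directions (left- and right-ear inputs) plus a layer of two-dendrite
  coincidence-detector UCNs, one per antisymmetric segment pair, which map
  the interaural time difference onto the identity of the firing output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

from .circuit import ParameterError, SynapseSpec, UCNParams, synapse
from .network import Edge, Network, Port, build_network

__all__ = [
    "LongAxonSpec",
    "JeffressSpec",
    "DEFAULT_OUTPUT_UNIT",
    "build_long_axon",
    "coincidence_pairs",
    "output_labels",
    "build_jeffress",
]

#: Output-layer neurons integrate the coincidence of two ~25 μs drive
#: windows; a smaller membrane capacitor than the delay-line units makes the
#: two-input charge time (τ·ln 5 ≈ 16 μs at 0.4 nF) fit inside the window
#: while a single input never fires them.
DEFAULT_OUTPUT_UNIT = replace(UCNParams(), c=0.4e-9)


@dataclass(frozen=True)
class LongAxonSpec:
    """Soma + ``n_segments`` identical axon-segment UCNs, chained."""

    n_segments: int
    unit: UCNParams = field(default_factory=UCNParams)
    axon_synapse: SynapseSpec = field(default_factory=lambda: synapse("axon_segment"))
    prefix: str = "S"
    port: str = "stim"

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ParameterError("a long axon needs n_segments >= 1")


def _chain_names(prefix: str, count: int) -> List[str]:
    width = len(str(count - 1))
    return [f"{prefix}{i:0{width}d}" for i in range(count)]


def build_long_axon(spec: LongAxonSpec) -> Network:
    """Chain S0→S1→…→Sn with axon_segment edges and one stimulus port into S0.

    The soma S0 uses the same preset as the segments (it fires on a single
    suprathreshold pulse); callers may substitute any tuning for S0 by
    editing the returned network's node record.
    """
    names = _chain_names(spec.prefix, spec.n_segments + 1)
    nodes = {n: spec.unit for n in names}
    edges = [
        Edge(a, b, spec.axon_synapse) for a, b in zip(names, names[1:])
    ]
    ports = [Port(spec.port, names[0], spec.axon_synapse)]
    return build_network(nodes, edges, ports, meta={"chain": tuple(names)})


def coincidence_pairs(n_side: int) -> List[Tuple[int, int]]:
    """Antisymmetric coincidence pairing (left segment, right segment).

    For ``n_side`` units per delay line (soma index 0 plus segments
    1…n_side−1) the detectors sit on the pairs ``(L_k, R_{n_side−k})`` for
    ``k = n_side−1 … 1``, ordered so that output 0 responds to left-leading
    sounds and the last output to right-leading ones.
    """
    if n_side < 2:
        raise ParameterError("coincidence pairing needs n_side >= 2")
    return [(k, n_side - k) for k in range(n_side - 1, 0, -1)]


def output_labels(n_outputs: int) -> List[str]:
    """Spatial labels for the output layer, left to right.

    Three outputs give the canonical ``OL, OC, OR``; an odd count keeps a
    central ``OC`` flanked by numbered ``OL*``/``OR*`` labels, an even count
    has no center.
    """
    if n_outputs < 1:
        raise ParameterError("need at least one output")
    if n_outputs == 1:
        return ["OC"]
    labels = []
    half, odd = divmod(n_outputs, 2)
    for i in range(n_outputs):
        offset = i - (n_outputs - 1) / 2
        if offset == 0:
            labels.append("OC")
        elif offset < 0:
            k = int(-offset + (0 if odd else 0.5))
            labels.append("OL" if n_outputs == 3 else f"OL{k}")
        else:
            k = int(offset + (0 if odd else 0.5))
            labels.append("OR" if n_outputs == 3 else f"OR{k}")
    return labels


@dataclass(frozen=True)
class JeffressSpec:
    """Two antiparallel delay lines plus a coincidence output layer.

    ``n_side`` counts the UCNs per delay line (soma + n_side−1 segments);
    the output layer has ``n_side − 1`` two-dendrite neurons.  ``n_side=4``
    reproduces the studied topology exactly: L0–L3, R0–R3 and the three
    outputs OL (pair L3-R1), OC (L2-R2), OR (L1-R3) — 11 neurons.
    """

    n_side: int = 4
    axon_unit: UCNParams = field(default_factory=UCNParams)
    output_unit: UCNParams = DEFAULT_OUTPUT_UNIT
    axon_synapse: SynapseSpec = field(default_factory=lambda: synapse("axon_segment"))
    coincidence_synapse: SynapseSpec = field(
        default_factory=lambda: synapse("coincidence")
    )
    left_port: str = "L"
    right_port: str = "R"

    def __post_init__(self) -> None:
        if self.n_side < 2:
            raise ParameterError("a Jeffress network needs n_side >= 2")


def build_jeffress(spec: JeffressSpec) -> Network:
    """Assemble the Jeffress coincidence network.

    Both chains are built with the segment index increasing along the
    propagation direction; the left axon is laid out left-to-right and the
    right axon right-to-left, so the pairing table realizes the antiparallel
    (counter-propagating) geometry.  Stimulus ports ``L`` and ``R`` inject
    into the two somata.
    """
    n = spec.n_side
    left = _chain_names("L", n)
    right = _chain_names("R", n)
    pairs = coincidence_pairs(n)
    labels = output_labels(len(pairs))

    nodes = {name: spec.axon_unit for name in left + right}
    nodes.update({lab: spec.output_unit for lab in labels})

    edges = [Edge(a, b, spec.axon_synapse) for a, b in zip(left, left[1:])]
    edges += [Edge(a, b, spec.axon_synapse) for a, b in zip(right, right[1:])]
    for (lk, rk), lab in zip(pairs, labels):
        edges.append(Edge(left[lk], lab, spec.coincidence_synapse))
        edges.append(Edge(right[rk], lab, spec.coincidence_synapse))

    ports = [
        Port(spec.left_port, left[0], spec.axon_synapse),
        Port(spec.right_port, right[0], spec.axon_synapse),
    ]
    meta = {
        "outputs": tuple(labels),
        "pairs": tuple(pairs),
        "left_chain": tuple(left),
        "right_chain": tuple(right),
        "n_side": n,
    }
    return build_network(nodes, edges, ports, meta=meta)
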