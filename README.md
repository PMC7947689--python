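# ucnsim

Event-driven simulation of spiking networks built from **ultra-compact
neurons** (UCNs): a minimal leaky-integrate-and-fire circuit in which a
capacitor integrates, a resistor pair leaks, and a single thyristor (SCR)
fires.  The package is aimed at computational neuroscientists and
neuromorphic engineers who want a faithful software twin of these
lego-block circuits: it reproduces spike propagation along UCN delay lines
and the classic Jeffress mechanism of binaural sound localization, entirely
from circuit parameters — no recorded data required.

## The model in brief

A UCN membrane fires when its capacitor voltage reaches

    V_c* = V_th · (R1 + R2) / R2

(the divider R1/R2 presents the membrane voltage at the SCR gate), and the
spike ends when the SCR current falls below its holding current, at
`V_c = I_hold (R_LO + R3)`.  Between these switching events every membrane
voltage is a single exponential toward `V_inf = Σ g_i v_i / Σ g_i` with
`τ_eff = C/Σ g_i`, so the simulator inverts all threshold crossings in
closed form and carries **no step-size error**.

Two architectures are built in:

* **long-axon neuron** — a chain S0→S1→…→Sn of identical UCNs, a spiking
  delay line analogous to nodes of Ranvier, which propagates one spike at a
  constant rate set by the per-segment charge time;
* **Jeffress network** — two such delay lines running in opposite
  directions plus a row of two-dendrite coincidence detectors on the
  antisymmetric segment pairs (L3-R1, L2-R2, L1-R3 for the default
  4-unit sides, outputs OL/OC/OR, 11 neurons in total).  A plane-wave
  interaural time difference `Δt = (d/v)·sin α` selects which detector sees
  the two spike windows overlap, mapping azimuth onto neuron identity with
  a resolution of two segment delays (40 μs ≈ 4° at the default 20 μs
  calibration).

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.

## Worked example

Calibrate a delay line to 22.22 μs per segment and propagate one spike down
a 7-segment axon:

```
$ ucnsim simulate-axon --segments 7 --delay 22.22 --out out/axon
propagation rate: 0.0450 segment/μs (max residual 2.842e-14 μs)
wrote out/axon/axon_fire_times.csv
```

The rate is the least-squares slope of segment index against first-fire
time; identical units make the fit exact, and 1/22.22 μs = 0.045 segment/μs.

Localize a sound whose left-ear pulse leads by 40 μs (ITD = −40 μs, i.e. a
source ≈ 4° to the left):

```
$ ucnsim jeffress-run --itd -40 --out out/case
ITD = -40.0 μs → winner: OL
```

The spikes cross at the L3-R1 pair and the left output fires; the other two
detectors rise but stay below the ~2 V threshold.  Sweep the full ±60 μs
range:

```
$ ucnsim jeffress-sweep --out out/sweep
resolution: 40.00 μs, center offset: +0.00 μs
wrote out/sweep/itd_sweep.csv
```

The winner steps OL → OC → OR with transitions 40 μs apart (two segment
delays) and, with identical components, zero left-right offset.  The CSV
holds one row per output per ITD (`itd_us, output, pulse_width_us, peak_vc,
winner`).

Library use mirrors the CLI:

```python
import numpy as np
from ucnsim import default_jeffress_network, run_itd_sweep, measure_resolution

net = default_jeffress_network(per_segment_delay_us=20.0)
sweep = run_itd_sweep(net, np.arange(-60.0, 60.5, 1.0))
print(measure_resolution(sweep))   # 40.00 (μs)
```

Component-tolerance studies (`apply_mismatch`, seeded uniform dispersion)
and a supervised gate-tuning loop that corrects a mismatched output layer
(`supervised_tune`) are available in `ucnsim.experiments`; `ucnsim tune
--seed 1` runs one end to end.

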