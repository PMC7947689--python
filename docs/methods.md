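# Methods

## The circuit model

A single ultra-compact neuron (UCN) is a leaky-integrate-and-fire circuit
with four passive components and one thyristor (SCR):

* membrane capacitor `C` integrating dendritic current,
* resistive divider `R1`/`R2` that both leaks the membrane (time constant
  `τ = (R1+R2)·C`) and senses the membrane voltage at the SCR gate,
* sense resistor `R3` in series with the SCR, across which the action
  potential appears,
* the SCR itself, a hysteretic two-state switch: blocking (resistance
  `R_HI`) until its gate reaches `V_th`, conducting (`R_LO`) until its
  current drops below the holding current `I_hold`.

Because the divider presents `V_c·R2/(R1+R2)` at the gate, the membrane
fires at

```
V_c* = V_th · (R1 + R2) / R2
```

and conduction ends when `V_c` falls to `I_hold·(R_LO + R3)`.  The gap
between these two voltages is the hysteresis (memristive) loop that makes a
single SCR a complete "fire" primitive.

In both SCR states the membrane node is linear: the node sees the leak
(`R1+R2` to ground), the SCR path (`R_HI+R3` or `R_LO+R3` to ground) and one
conductance `1/R_syn` per active dendrite toward the 5 V drive rail.  Every
trajectory is a single exponential toward `V_inf = Σ g_i·v_i / Σ g_i` with
`τ_eff = C / Σ g_i`, so threshold crossings invert in closed form.  The
blocking SCR path is kept in the node equation (it is ~10 MΩ against tens of
kΩ elsewhere, a ≤0.1 % correction); setting `r_hi = inf` removes it exactly.
SCR gate current is neglected — the divider is treated as a pure voltage
sensor — which is what keeps the system piecewise linear.

### Output stage

The physical spike across `R3` lasts ~0.3 μs — far too brief to charge a
downstream membrane whose time constant is tens of μs.  The hardware
strengthens it with a transistor and a voltage source; we model that stage
as a non-retriggerable monostable: each fire event opens an active window of
duration `t_out` (default 25 μs) during which (i) the output line is at the
active-low level (0 V; rest = 5 V, matching the logic convention of the
measured traces) and (ii) downstream synapses are driven at `v_drive = 5 V`.
While a neuron's own window is open its dendritic inputs are disconnected
(the stage is busy reshaping the spike).  This input lockout is what makes
one upstream window elicit exactly one downstream spike; without it, a 25 μs
drive window would retrigger the downstream SCR every ~11 μs and a single
traveling spike would turn into a burst.  Under sustained drive the model
fires tonically with period `t_out` + recharge time, which is the expected
LIF behavior.  After extinction the SCR itself is immediately ready again;
there is no refractory mechanism beyond the output window.

### Default components

`C = 1 nF`, `R1 = 30 kΩ`, `R2 = 20 kΩ`, `R3 = 100 Ω`, `R_HI = 10 MΩ`,
`R_LO = 10 Ω`, `V_th = 0.8 V`, `I_hold = 1 mA`.  These give the ~2 V firing
threshold of the measured output neurons (0.8 V gate behind a 0.4 divider)
and 5 V / 0 V logic levels.  Synapse presets: `axon_segment` = 10 kΩ (one
active input drives `V_inf ≈ 4.16 V > 2 V`: a single spike reliably relays),
`coincidence` = 100 kΩ (one input gives `V_inf ≈ 1.67 V < 2 V`, two give
`≈ 2.5 V > 2 V`: a genuine two-input coincidence detector).

## Networks and the event-driven engine

Networks are directed graphs of named UCNs with at most two inputs per node
(the hardware building blocks are one- and two-input neurons; stimulus ports
count toward the limit).  The engine advances every node analytically from
one global event to the next — fire, extinction, output-window closing,
stimulus edge — re-inverting each node's next crossing whenever any drive
changes.  There is no step-size error; a dense fixed-step integrator exists
in the test suite purely as an independent oracle (agreement ≤ 0.05 μs
required, typically ≤ 0.01 μs = one oracle step).  Simultaneous events
(within 1 ps) are processed in lexicographic node order, making every run
bit-reproducible.  Trace sampling is done after the fact from the stored
closed-form segments, so sampled output never influences event times, and
per-node peak membrane voltages are exact (each segment is monotone, so the
maximum sits at a segment endpoint).

## The two architectures

**Long-axon neuron.**  A soma `S0` followed by `n` identical axon segments,
each relaying the previous unit's spike — the delay-line analog of saltatory
conduction along nodes of Ranvier.  With identical units the first-fire
times are exactly arithmetic, so the propagation rate (slope of segment
index against first-fire time) equals the reciprocal of the single-link
delay.

**Jeffress network.**  Two such delay lines carry the left- and right-ear
spikes in opposite directions; `n_side − 1` two-dendrite output neurons sit
on the antisymmetric segment pairs `(L_k, R_{n_side−k})`.  For `n_side = 4`:
pairs L3-R1, L2-R2, L1-R3 under outputs OL, OC, OR — 11 neurons.  A sound at
azimuth α reaches the ears with `Δt = (d/v)·sin α` (plane-wave model,
`d = 0.2 m`, `v = 343 m/s`; positive Δt = right ear leads).  The ITD maps
onto which detector sees the two counter-propagating windows overlap:
neighboring detectors are two segments of travel apart, so the angular
resolution is twice the per-segment delay (40 μs ≈ 4° at the default 20 μs
calibration).

### Output-layer capacitance

Output neurons default to `C = 0.4 nF` (the `JeffressSpec.output_unit`
record), not the 1 nF of the delay-line units.  With two active 100 kΩ
dendrites the two-input charge time is `τ·ln 5 ≈ 16 μs` at 0.4 nF, which
fits inside the 25 μs overlap window at perfect coincidence; at 1 nF it
would be 40 μs and the detector could never fire.  The value also keeps the
fire band narrow (arrival offsets ≳ 15 μs leave the detector subthreshold),
so away from perfect coincidence the winner is read from the graded
subthreshold peak — the regime in which the winner boundary sits exactly at
the midpoint between detectors and the 40 μs resolution emerges.

### Winner-takes-all decoding

Largest total output pulse width wins; ties fall back to largest peak
membrane voltage, then to the label nearest the center.  A stimulus with no
fired output and all peaks below half threshold decodes as "none".  Pulse
width is the primary code (as in the hardware), but the simulated window is
fixed-width, so the graded quantity across a sweep is the peak membrane
voltage; both are recorded in sweep results and exports.

### Locating winner transitions

`measure_resolution` and `measure_offset` locate each winner change by
interpolating the zero crossing of the peak-voltage margin between the two
straddling grid points (falling back to the interval midpoint if either
contender fired there, since widths step discontinuously).  On an integer
grid a mirror-symmetric network otherwise quantizes the spacing to an odd
number of steps (39 or 41 for a 20 μs delay at 1 μs steps); the margin
crossing is the actual, grid-independent decision boundary and lands at
40.00 μs.

## Stimuli

A stimulus pulse is modeled exactly like an upstream output window: a gated
5 V drive through the port's synapse.  Its default duration equals the
unit's `t_out`, because the soma must stay driven past its own charge time
(equal to the calibrated per-segment delay — a 5 μs pulse could never fire a
soma calibrated to a 20 μs delay).

## Calibration

`calibrate_capacitance` bisects on `C` (every time constant scales with it,
so the two-unit delay is strictly increasing in `C`) until an isolated
two-unit chain reproduces the target delay to 0.1 %.  The drive window is
raised to at least 1.2× the target so the drive persists past the crossing.
Targets: 22.22 μs → 4.076 nF (the 0.045 segment/μs chain),
20 μs → 3.669 nF (the 40 μs-resolution network).

## Component mismatch and supervised tuning

`apply_mismatch` multiplies `r1`, `r2`, `c` and the SCR `v_th` of each
selected node by independent uniform factors in `[1−tol, 1+tol]`
(maker-tolerance style, seeded; default 5 % on every node).  Mismatch skews
the per-segment delays, so the detector row's response shifts sideways; the
center-interval midpoint (`measure_offset`) is the scalar summary.  Over
many seeds the offset is dispersed but unbiased.

`supervised_tune` emulates feedback correction at the SCR gate: every wrong
decision on a small calibration stimulus set nudges the gate-divider
resistor `r2` of the offending output neurons by ±2 % (raising `r2` lowers
`V_c*` and the leak, making the neuron more excitable).  Two safeguards
shape the loop: (i) per iteration each output receives at most one net
adjustment, with "wrongly won → cut" taking priority over "failed to win →
boost" (otherwise conflicting corrections cancel and the loop stalls), and
(ii) an adjustment is withheld if it would break the coincidence tuning
(single-input steady state must stay below threshold, two-input above),
which prevents the loop from "fixing" a decision by turning a detector into
a single-spike follower.  Non-convergence is reported, never silent, and
axon units are never touched.

**Known limitation.**  The output-layer knob moves a decision boundary by at
most ~2 μs (peak-scale leverage ±0.1 V plus ~1 μs of fire-band travel within
the coincidence guard).  Dispersion restricted to the output layer is fully
correctable, and the ITD = 0 decision itself is robust (its coincidence has
~0.5 V of margin; no failure observed over 40 seeds at 5 %).  But full
5 % dispersion also desynchronizes the delay lines by several μs, and that
timing asymmetry is outside the output layer's authority: post-tuning
offsets of 2–4 μs remain for such seeds.  Correcting them would require
tuning the axon units' own gate dividers, which this procedure deliberately
does not touch.

## What the synthetic scenarios do and do not show

All inputs are generated programmatically (pulse schedules, sweeps, seeded
mismatch); there is no recorded data.  The model reproduces the *mechanism*:
constant-rate propagation, coincidence detection with ~2 V thresholds,
ITD → place mapping with 2-segment resolution, and unbiased mismatch
offsets.  It does not reproduce hardware-absolute quantities that depend on
the unpublished component list and stimulus offsets — absolute arrival times
of specific measured traces, the specific ~10 μs offset of one physical
board, or intrinsically graded output pulse widths (our output stage is a
fixed-width monostable; grading appears in the peak voltages instead).

## Numerical choices

Internal units are SI; user-facing times are μs and voltages V.  Event
coincidence tolerance 1 ps; livelock (repeated zero-advance events) raises a
diagnostic error rather than hanging.  Default trace sampling 0.5 μs (does
not affect event times).  Default sweep ±60 μs in 1 μs steps.  Calibration
tolerance 0.1 %; tuning step 2 %, at most 200 iterations.  Problem sizes
throughout (8-unit chains, 11-neuron network, 121-point sweeps, ≤100
mismatch seeds) keep any experiment in this package under a couple of
minutes on one core.
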