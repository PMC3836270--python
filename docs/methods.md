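# Methods

## Model and assumptions

The simulator reproduces, in software, a digital-hardware style CPG: a
clock-driven spiking network updated once per millisecond by a single
logical computation core. Three assumptions shape everything else:

1. **Fixed 1-ms resolution.** The neuron difference equations are the
   forward-Euler form with dt = 1 ms folded in; there is no sub-step
   integration and no event-driven shortcut. Spike times are integers
   (ms), so instantaneous frequencies are quantized to 1000/k Hz.
2. **Split currents.** Each neuron's input is `I_bias + I_exc + I_inh`.
   The two synaptic terms are per-neuron accumulators (as in a hardware
   RAM that stores three currents per neuron), not per-synapse state.
   Consequently the current decay rate 1/τ_syn is a neuron/network-level
   quantity; configs that specify it per synapse must agree network-wide.
3. **Three-phase step.** EXT (external injections) → NEUR (membrane
   update reading the currents as of the end of EXT, plus all exponential
   decays) → SYN (spike-triggered injection + depression deepening).
   A spike therefore affects postsynaptic membranes exactly one step
   later. On a spike step a synapse applies only the depression increment
   δ ← δ + P(1 − δ); on spike-free steps only the recovery
   δ ← δ(1 − 1/τ_reg) — the two rules are mutually exclusive, following
   the two-column spiking/non-spiking behavior of the synapse block.
   The effective weight injected by a spike uses the *pre-increment* δ
   (this spike releases from the currently available pool).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| a | recovery rate (1/ms) | 0.02 | standard RS value; see below |
| b | recovery sensitivity | 0.2 | RS |
| c | reset potential (mV) | −65 | RS |
| d | post-spike recovery increment | 8 | RS |
| v_thresh | spike threshold (mV) | 30 | tested on the computed value |
| W_syn | synaptic weight | −5.1 (elemental) / −7 (segmental, rat) | sign routes E/I |
| P | dissipation per spike | 1.49 % / 2.65 % / 12 % | accepted as "1.49%" or 0.0149 |
| 1/τ_syn | current decay (1/ms) | 0.01 | τ = 100 ms |
| 1/τ_reg | depression recovery (1/ms) | 0.0002 | τ = 5000 ms; the reciprocal form is authoritative where quoted values disagree |
| I_bias | bias current | 8 (leech) / 7 (rat) | model units |

**On a = 0.02 vs 0.002.** The parameter table this model derives from
prints a = 0.002, but that value is dynamically inconsistent with every
reported firing statistic: at I_bias = 8 the neuron then fires at ~1.6 Hz
(ISI ≈ 618 ms, the recovery variable relaxing with τ = 1/a = 500 ms) and
the half-center produces no bursts at all, whereas the reported
within-burst rates are 11–13 Hz. With the standard regular-spiking value
a = 0.02 the tonic ISI is 79–80 ms (12.5–12.7 Hz), matching the reported
mean and peak frequencies. We treat the printed 0.002 as a dropped-digit
typo and default to 0.02; any value can be set explicitly in configs.

**Symmetry breaking.** A perfectly symmetric half-center started from a
symmetric state stays synchronous forever — and the discrete-time
dynamics also *converge* to exact synchrony from nearby states (a 1 mV
offset is absorbed before the mutual inhibition can separate the cells).
The default initial condition spreads the membrane potentials evenly over
20 mV below rest (v_i = c − 20·i/(n−1), u_i = b·v_i, δ = 0, currents 0),
which reliably lands on the antiphase attractor. The steady rhythm is
independent of this choice (verified over randomized initial states); an
optional seeded jitter is available.

**Segmental wiring.** The eight-neuron oscillator couples two half-centers
(L3/R3, L4/R4) through coordination neurons (L1/R1, L2/R2) with 12
inhibitory synapses in total. The exact coordination wiring is not
uniquely determined by the printed description, so it is a named option:
`reciprocal` (default) gives each coordination neuron a mutual-inhibition
pair with an ipsilateral oscillator neuron (L1↔L3, L2↔L4, mirrored),
matching the reciprocal coordination of the biological timing network;
`ring` is a directed inhibitory loop through the coordination neurons.
Both respect the 12-synapse count and left/right mirror symmetry and both
give the same statistics at the default operating point; `reciprocal`
keeps oscillating over a wider range of 1/τ_reg.

## Numerical choices

* **Float vs fixed mode.** The default is IEEE double. Fixed mode
  emulates a signed 26-bit Q9.16 datapath: parameters are quantized at
  compile time and every state update (v, u, currents, δ, W_s) is
  re-quantized. Rounding defaults to round-nearest (half up); a
  truncate-toward-negative policy is available but noteworthy: pure
  truncation biases the knife-edge escape dynamics of the half-center
  enough to destroy alternation entirely (one neuron permanently wins).
  Overflow saturates by default (wrap is available) and is counted and
  logged.
* **Spike handling.** The threshold is tested on the freshly computed
  membrane value; the stored value at a spike step is the reset value c.
  u is advanced from the pre-reset v, then incremented by d.
* **Injection ordering.** Same-accumulator injections are applied in
  (presynaptic index, synapse position) order, making float-mode results
  bit-for-bit reproducible; the test suite verifies equality with a naive
  dense-matrix reference at that strength.
* **Burst analysis.** ISI-threshold detector (max ISI 300 ms, min 4
  spikes, both exposed); with ~80 ms intra-burst ISIs versus multi-second
  gaps the segmentation is insensitive to the threshold. The first two
  bursts are discarded as startup transient. Period is start-to-start;
  duty cycle divides each burst's duration by its own period; frequencies
  use the standard conventions (mean = (spikes−1)/duration, initial/final
  = 1000/first or last ISI, peak = max 1000/ISI).

## What the reference simulations show — and what they do not

The 300-s reference runs (≈ 15–17 analyzable bursts) reproduce most of
the hardware-measured rhythm of the original digital implementation with
the printed parameter sets: elemental duty cycle 50.6 % (reported
54.7 ± 6), mean frequency 12.4 Hz (12.1 ± 1), peak 12.66 Hz (13), initial
8.9 Hz (8.5 ± 0.2); segmental duty 45.7 % (46.1 ± 6). The burst *periods*
come out longer than reported: 17.4 s vs 12.6 ± 1.4 s (elemental) and
15.8 s vs 11.2 ± 1 s (segmental).

This discrepancy is a genuine sensitivity, not a loose tolerance. Burst
termination here is an escape process: the suppressed neuron fires again
only when depression has weakened the active neuron's inhibitory pulses
past a knife-edge, and the operating point of the printed parameters sits
close to a winner-take-all bifurcation (raising 1/τ_reg from 0.00015 to
0.0002 more than doubles the period; at 0.00022 alternation can fail
outright). Near such a point the period is hypersensitive to arithmetic
minutiae of the original fixed-point pipeline and to the unstated
measurement protocol — the reported duty cycles above 50 % indicate
overlapping-burst transitions that the literal equations do not produce
at this operating point. A systematic screen over the defensible
micro-variants of the update semantics (injection/decay ordering, δ
indexing, rounding modes, parameter quantization) moves the elemental
period only between ~14 and ~38 s, so the implementation keeps the
literal reading and reports its numbers as computed. The same proximity
to the bifurcation limits the period-vs-1/τ_reg sweep: the trend
(longer periods at larger 1/τ_reg) holds where the rhythm exists, but
the top setting can fail to alternate.

These runs exercise deterministic, noise-free dynamics from a fixed
initial condition. They do not emulate biological variability (channel
noise, graded synaptic transmission, conductance dynamics), so agreement
here validates the arithmetic and the network semantics — not the
biological fidelity of the rhythm beyond what the original hardware
comparison established.

## Known limitations

* No graded (non-spiking) synaptic transmission; the depressing
  spike-mediated synapse deliberately replaces it.
* The cycle-budget model takes the available cycle count Nc as an input;
  no clock frequency is assumed.
* Fixed-point mode quantizes *all* state uniformly in Q9.16; the original
  hardware may have used different widths outside the depression
  computation.
* Chains reuse the parent CPG's weight and dissipation for the inter-CPG
  couplings; no independent coupling parameters are published.
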