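# Model and methods

`dorsalflow` simulates the dorsal visual pathway as a hierarchy of spiking
layers — retina → LGN (with TRN/IN feedback inhibition) → V1 → MT → MST →
LIP — and uses it to turn synthetic optic-flow movies into two-alternative
(left/right) heading decisions.  This note documents the model equations,
the free parameters and their defaults, the numerical choices, and the known
limitations; everything quantitative stated here is computed by the test
suite or the acceptance script.

## Layers and geometry

All retinotopic layers live on a common coordinate system in *grid units*:
the 20 × 20 excitatory grids occupy integer-spaced positions spanning the
visual field (one grid unit = 30 px = 1° of visual arc at the fixed scale of
30 px/deg), and the 10 × 10 inhibitory grids of V1 and MT are dispersed among
them at twice the spacing.  Layer sizes: LGN, IN, TRN (ON and OFF channels
each), MSTe, MSTc — 400 neurons each; V1 and MT — 400 excitatory + 100
inhibitory (the 4:1 ratio); LIP — 2 decision neurons; 4202 neurons in all.

LGN relay cells use a conductance-based leaky integrate-and-fire model with a
spike-triggered after-hyperpolarization conductance in place of a hard reset
(upward threshold crossings emit spikes and increment `g_ahp`, reversal
−90 mV, τ = 10 ms).  All other neurons are current-based LIF with exponential
postsynaptic currents (τ_m = 10 ms, threshold 15 mV above rest, 2 ms
refractory period).  Cortical PSC time constants default to 10 ms — with 400
sparse afferents per layer the 2 ms textbook value leaves no temporal
summation and the cortex never fires; MT uses 5 ms excitatory PSCs (it
operates as a coincidence detector, below) and LIP 40 ms (slow evidence
integration).  Integration is exponential-Euler with the exact per-step
propagator, dt = 0.1 ms; spike times are assigned to step boundaries.

## Retina

Each of the 400 RGCs per channel applies a center–surround
difference-of-Gaussians to the luminance frames,

    w(Δ) = a_c exp(−Δ²/σ_c²)/σ_c² − a_s exp(−Δ²/σ_s²)/σ_s²,

(a_c = 1, a_s = 0.9, σ_c = 0.8, σ_s = 2.4 grid units; note the exponent uses
σ², not 2σ², and the 1/σ² prefactors make each Gaussian term integrate to π),
followed by a biphasic temporal kernel — the difference of two Gamma
densities (shape 2, scales 24 and 48 ms, weights 1 and 0.7, support 250 ms).
The ON channel uses the kernel as written, OFF its sign inversion.  The
output, scaled so that a full-contrast luminance step drives LGN relay cells
near 50 Hz (gain 10⁴ pA per unit response), is injected one-to-one into the
LGN relay cells and interneurons as a signed continuous current.

Numerically, the spatial stage block-averages the 600 × 600 px frames by 5,
applies the DOG as two separable Gaussian blurs (the printed kernel equals
π·[a_c N(σ_c/√2) − a_s N(σ_s/√2)] with N a normalized Gaussian), and samples
the field at the exact grid centers by bilinear interpolation — this keeps
the retinal stage exactly mirror-symmetric, which the decision stage relies
on.  The temporal stage is an FFT convolution at the simulation step.

## Preference maps

Orientation (V1, period π) and direction (MT, period 2π) preference maps are
superpositions of plane waves with a common wavenumber 2π/λ and random
angles/phases; the argument of the complex field, mapped onto the period,
yields the pinwheel layout, and an independent realization provides the RF
phase map.  λ = 5 grid units with 80 waves: coarser maps leave the 400-cell
orientation histogram lumpy enough to bias the population decode by tens of
degrees (the suite checks histogram uniformity by χ²).

Both maps are generated **mirror-symmetric** about the vertical midline
(every wave paired with its reflection partner, so preferences at (−x, y)
are the exact reflections of those at (x, y)).  This is a deliberate design
choice: with unconstrained maps the left and right MST template populations
gate unequal numbers of MT cells, and that fixed asymmetry — amplified by
recurrent MST excitation — dominated the stimulus and froze the decision to
one side.  Mirror symmetry makes the two decision channels structurally
identical; the map *realization* (seeds 11 and 21) is part of the model
architecture, like a published map figure, not per-run randomness.

## Connectivity

* **LGN → V1.** Each V1 cell's Gabor RF (σ_x = 2, σ_y = 0.75 grid units,
  carrier 0.3 cycles/unit, orientation and phase from the map) is sampled at
  the LGN grid: ON cells under positive lobes and OFF cells under negative
  lobes excite the cell in proportion to |Gabor|.  The network enables the
  classic *push–pull* complement (each channel inhibits over its anti-phase
  subregions at equal strength): the summed drive then approximates a signed
  Gabor filtering of the retinal signal.  Without push–pull the total
  ON+OFF weight per cell is phase-blind and V1's spike-count tuning is
  measurably flat.
* **V1/MT lateral.** Excitatory weights are proportional to the positive
  part of the normalized Gabor-field correlation between the pair (circular
  envelopes, σ = 1); inhibitory weights follow a von-Mises profile peaking
  at RF phase differences of 180° with a Gaussian spatial envelope — the
  push–pull motif continued into the cortex.
* **V1 → MT.** `w_ij = k_c · w_cs(Δx, Δy) · cos φ_ij` for 0 ≤ φ ≤ π/2 and 0
  otherwise, with w_cs the same DOG form (a_c = 1, a_s = 0.5, σ_c = 2,
  σ_s = 6) and φ the unsigned angle between the two cells' orientation
  preferences folded to [0, π).  The MT map stores *direction* preferences;
  a direction-selective cell responds to contours orthogonal to its
  preferred direction, so its orientation axis is θ_MT + π/2 — the
  convention under which the cosine gate selects exactly the V1 cells that
  respond to motion along θ_MT.
* **V1 → MT delays.** The weight rule alone cannot make MT
  direction-selective — any function of positions and orientations is
  invariant under reversing the motion.  Direction selectivity comes from
  *graded conduction delays*: `delay_ij = 100 ms − (offset · d̂)/v_pref`
  (v_pref = 20 grid units/s, clipped to [1, 200] ms), so a feature moving
  along the preferred direction reaches the afferents in the order that
  makes their volleys arrive at the MT cell together, while reversed motion
  disperses them over ~hundreds of ms.  With 5 ms PSCs and a spiking
  threshold, MT fires preferentially on the coincident volleys
  (Reichardt-style detection); the measured preferred/anti response ratio
  for single translating dots is ~2–3.
* **MT → MST.** Each MST cell carries an expansion or contraction template
  with focal point (x_e, 0): a binary direction gate (the MT cell's
  preferred direction must lie within ±π/4 of the radial direction away
  from / toward the focal point) times `exp(−d·r_focal²)` (d = 0.005) times
  a Gaussian of the MT–MST offset (σ_I = 6) — near-global templates, as
  MST receptive fields are in primate.  Focal points sit at x ∈ {−7, 0, +7}
  grid units, outside the ±4.67-unit displacement range of the task: the
  flow-field singularity is a pronounced local *minimum* of MT activity, and
  when a focal point can coincide with it (e.g. at ±5) that magnitude dip
  couples into the decision with inverted sign.  Each MST cell's afferent
  vector is normalized to a common total, so its drive measures how well the
  MT activity *pattern* matches its template rather than how many map cells
  happened to pass its gate.
* **MST lateral.** Intra-layer pairs sharing a focal point excite
  (+exp(−Δ²/2σ_ts²), σ_ts = 3), different-focal pairs inhibit; all
  expansion↔contraction connections are inhibitory with an additional
  focal-similarity factor.  The recurrent gain is kept low (the layer must
  relay evidence, not run winner-take-all on its own biases).
* **MST → LIP.** The left LIP neuron is excited by expansion cells with the
  left focal point and inhibited by every other MST cell; the right neuron
  is the exact mirror image; the two neurons inhibit each other.
* **V1 → TRN/IN → LGN.** Retinotopically aligned one-to-one feedback:
  V1 excites the reticular and interneuron grids, which inhibit the
  matching LGN relay cells.

All builders are deterministic given maps and parameters; weights below
10⁻³ of each projection's maximum are pruned.

## Stimuli

* **Dot flow.** 50 bright anti-aliased dots (radius 8 px) on black, 36
  moving radially away from an expansion center displaced ±20…±140 px
  (0.67–4.67°) from the screen center and 14 with fixed random directions;
  dot lifetime 100 ms with uniform age staggering (so one third renews per
  33.3 ms frame), re-positioning uniform, radial dots re-aimed from the
  center after renewal so the subfield stays pure expansion.  Dot speed is
  600 px/s (20 °/s): at the 20 × 20 retinal resolution a dot must cross at
  least a couple of grid cells within its lifetime for its motion to be
  resolvable at all, and 600 px/s is the slowest speed at which the
  delay-coincidence mechanism has a usable signal.  The generator is
  mirror-symmetric in distribution: negating the displacement and reflecting
  x gives statistically identical stimuli.
* **Two-region bars.** Dashed bright bars (spacing 100 px — the V1 carrier
  period — width 30 px, dash period 300 px at 60% duty) drifting parallel to
  their own orientation at 120 px/s.  The standard test stimulus splits the
  field along a diagonal border: a smaller region (32.3% of the area) of
  near-horizontal bars at 10° drifting down-left, and a larger region of
  diagonal bars at 64.9° drifting up-right.  The geometry is chosen so the
  area-weighted circular mean orientation is ≈50.8° and the mean drift
  direction ≈93.3° — the values the population decoders are expected to
  recover.  (Bars are dashed so that motion parallel to the orientation is
  visible at all; the drift is slow so the sustained bar structure, not the
  moving dash edges, dominates the transient-loving retina; bars are 10°
  rather than exactly horizontal because axis-aligned bars alias against the
  retinotopic grid.)

## Readout

Population decoding is the spike-count-weighted vector average of preferred
angles, with angle doubling for orientation (period π) — the standard
circular-statistics treatment of axial data; a vanishing resultant is
reported as undefined rather than a number.  LIP rates use a 200 ms sliding
window stepped by 20 ms; the decision is the side with the higher final
rate, and the decision latency is the earliest time from which the winner's
rate never falls below the loser's.  The experiment summary reports
per-condition accuracy and mean latency plus the Spearman correlation of
mean latency against displacement magnitude.

## What the defaults do and do not show

With the default configuration the full sweep (7 magnitudes × 2 sides × 3
trials, 600 ms each) completes in ≈2.5 minutes.  Decisions are correct in
roughly 55–62% of trials, improving with displacement magnitude, and
decision latencies tend to shorten for larger displacements — but the
effect sizes are small relative to per-trial variability.  This is a
physical ceiling of the modelled system, not a tuning failure: a 50-dot
kinematogram sampled by a 20 × 20 retina carries little per-trial heading
information, V1 cannot resolve local motion direction at that resolution
(its motion-axis tuning for coherent dot translation is flat; this is
verified numerically), and MT's delay-coincidence selectivity is modest.
Correspondingly, the decoded MT *direction* for the bar stimulus reflects
the stimulus orientation axis (≈ mean orientation + 90°) rather than the
drift sign, because the feedforward weight rule transmits axial information
only.  The V1 orientation decode lands within a few degrees of the
area-weighted stimulus mean.

The synthetic stimuli emulate the geometry of self-motion displays, not
their photometry: no contrast adaptation, no speed gradient across the flow
field, no eye movements, no photoreceptor nonlinearity.  Passing tests show
that the implemented equations behave as written and that the pathway turns
flow asymmetries into statistically correct-leaning decisions; they do not
show that this architecture reaches human-level heading discrimination.

## Numerical and degenerate-input choices

* Exact-exponential updates; currents/conductances held constant within a
  step; threshold detection at step boundaries.
* The engine aborts with layer diagnostics if any membrane potential
  exceeds +50 mV or turns non-finite (deep hyperpolarization of
  current-based cells under strong inhibition is legitimate and not
  trapped).
* A dot exactly at the expansion center has no defined radial direction and
  is re-aimed after its next renewal; an MT cell exactly at a focal point
  has weight 0 (undefined radial angle).
* Synaptic delays are 1 ms everywhere except the graded V1→MT projection.
* All randomness flows through seeded `numpy` generators; identical seeds
  give bit-identical spike rasters.
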