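# Methods

`tiesim` simulates transcutaneous interferential electrical stimulation
(TIES) of glabrous skin at two coupled scales: a quasi-static
volume-conductor model of the tissue and an extracellularly driven
Hodgkin–Huxley (HH) cable model of mechanoreceptive Aβ fibers. This
note records the model, its numerical treatment, and the design choices
made where the problem was genuinely open.

## Volume-conductor model

The tissue is a layered 10 × 10 × 9 mm box: cortical bone (1.5 mm) at
the bottom, subcutaneous adipose tissue (SAT, 5.9 mm), and skin
(1.6 mm) on top. Three circular surface electrodes (1 mm diameter,
2 mm center-to-center) sit in a row along x on the top face; the
central electrode is grounded (Dirichlet V = 0 over the disc) and the
two flanking electrodes inject currents under current-controlled
conditions. All other boundaries are insulating.

The potential obeys ∇·(σ∇V + ∂/∂t(ε∇V)) = 0 with per-layer,
frequency-dependent σ and ε_r tabulated at the four carriers
1–4 kHz and linearly interpolated in between. Because the medium is
linear and time-invariant at fixed properties, each sinusoidal stimulus
component is solved once as a complex-admittance Laplace problem
∇·(σ*∇V̂) = 0 with σ* = σ + j2πfε, and the two components are
superposed in the time domain. σ and ε are read at the carrier
frequency for both components, but each component keeps its own ω in
the capacitive term; this reproduces the ~1% skin-admittance
difference between the two tones at f_b = 100 Hz. The full
time-dependent equation is retained as an implicit-Euler time-stepping
oracle on tiny (≤ 11³-node) grids, and the phasor composition is
required to agree with it within 1% RMS.

Discretisation is a node-centred finite-volume 7-point stencil on a
uniform grid (spacing h dividing the box; h ≤ 0.5 mm). Edge
conductances are σ*·A/ℓ with the series (harmonic) combination of σ*
along edges that cross a layer interface, and boundary-edge faces carry
half/quarter areas so surface sources see the correct half-space solid
angle. Electrode discs are mapped to surface nodes with
area-overlap weights (4 × 4 subsampling). The complex-symmetric system
is solved by incomplete-LU-preconditioned BiCGStab to a relative
residual of 10⁻⁸; the solve is deterministic and discrete current
conservation holds to < 10⁻⁶ of the injected current.

Against the analytic surface point-source formula V = I/(2πσr) the
solver is validated in difference form: a uniform 8 mm box with a small
source disc and a separated ground disc, comparing potential drops
(constant offset removed) against the superposition of the source and
ground-sink terms. Absolute agreement is not meaningful on a desk-scale
box — with a 1 A injection the whole domain rides on the ground disc's
spreading-resistance offset and box-wall effects scale as r/L — whereas
the difference-form error is 1.9% at h = 0.25 mm over distances 3h–10h
and decreases monotonically as h halves.

## Axon model

Each fiber is a straight 5 mm cable of 51 nodes (Δr = 0.1 mm) with
classic squid-axon HH membrane dynamics (ḡ_Na = 120, ḡ_K = 36,
g_l = 0.3 mS/cm², E_Na = 50, E_K = −77, E_l = −54.3 mV,
c_m = 1 μF/cm²) in the −65 mV resting convention, no temperature
correction. The extracellular potential enters through the activating
function: with intracellular conductance g_i = 0.0282 S/cm (axial
resistivity 35.46 Ω·cm) and diameter d = 8.7 μm, the axial coupling
coefficient is d·g_i/4 and the membrane equation is

    c_m ∂V_m/∂t = (d g_i/4) ∂²(V_m + V_e)/∂r² − I_ion(V_m, m, h, n).

Axon tips are sealed (zero axial current, mirror ghost nodes). The
initial state is V = −65 mV with gate values m = 0.00804, h = 0.931,
n = 0.129; these are not the equilibrium values at −65 mV, so the
first ~2 ms produce a synchronous onset spike that the temporal guard
absorbs — AP counting never sees it.

Integration is operator-split at Δt = 10 μs: gates advance by the
exponential (Rush–Larsen) update, then a Crank–Nicolson step treats
axial diffusion and the frozen-conductance membrane currents with one
tridiagonal (Thomas) solve per step. The scheme is unconditionally
stable; halving Δt changes AP counts by 0 and AP times by < 0.1 ms.
The voltage passed to the rate functions is clamped to [−200, 300] mV
so that supra-physiological forced potentials explored by the gain
search cannot overflow the rate exponentials (the gates saturate there
regardless); integration aborts only on non-finite values.

Three orthogonal fiber orientations are modelled at 1 mm depth
(skin-parallel x and y, skin-perpendicular z), arrayed at 0.1 mm pitch
across the central 5 mm. The z-oriented fibers span from the skin
surface (z = 9 mm) to 5 mm depth so that one node lies exactly at the
1 mm-depth reference point (5.0, 5.0, 8.0) mm.

## Stimulus, guards and counting

The stimulus is two sinusoids I_k = A_k sin(2πf_k t + φ_k) with
f₁ = f_c, f₂ = f_c + f_b, A₁ = A₂ = 0.5 mA, φ = 0. The evaluation
window is T_w = 100 ms — an integer number of periods for every tested
(f_c, f_b) — with 20 ms temporal guards built by periodic wrapping, and
1 mm spatial guards at both cable ends.

APs are upward crossings of −20 mV grouped into propagating waves: a
crossing joins a wave that has already crossed a neighbouring node
within 1 ms (conduction across one node interval takes ≪ 0.5 ms and HH
refractoriness keeps genuine APs several ms apart). A wave counts when
its earliest crossing lies inside the evaluation window and region and
the wave reaches an axon end within the run. A consequence worth
noting: when the drive is strong enough to force the membrane across
threshold at the carrier rate (a non-spiking, forced-oscillation
regime), successive forced crossings chain into a single wave whose
initiation falls in the pre-guard, so forced oscillations are not
miscounted as APs.

## Amplitude normalization

For each carrier and orientation the stimulus gain is scaled by
S(f_c, 30 Hz): the minimum k ∈ [10⁻⁴, 10] at which the reference axon
fires at least N_AP,ref = f_b·T_w = 3 APs in the window. Because the
count versus gain is non-monotone at kHz carriers (conduction block),
the search first scans 13 log-spaced gains per decade for the lowest
upward crossing and then bisects in log-gain space to 0.1% relative
tolerance, re-checking minimality just below the bracket. At carriers
≥ 2 kHz the count can be non-zero only on narrow gain "islands"
between threshold and block; the search lands on the lowest island the
scan resolves. One consequence is that S is not strictly
non-decreasing in f_c on coarse grids even though it rises steeply
(×10–×100) from 1 to 2 kHz; the corresponding trend test records this
known limitation. The x-oriented reference axon cannot reach 3 APs
within the k ≤ 10 ceiling at carriers ≥ 2 kHz on the verification
grids; sweeps record the condition as unattainable and continue.

## Perception metrics

Per axon array and condition: the activated set A is every axon with
≥ 1 counted AP; the activation threshold is the mean count over A;
qualifying axons (count ≥ threshold) at adjacent lateral positions form
contiguous regions; the primary region R is the region containing the
global maximum count (ties: longest region, then smallest starting
index). PF is the spatial length x_max(R) − x_min(R) (0 for empty or
singleton R) and PI the summed count over R. Secondary qualifying
regions are flagged as potential multiple-location percepts.

## Problem sizes and fidelity

The production sampling rule is "no spatial interpolation": at
h = 0.1 mm every axon node is a grid node. Verification and sweep runs
use h = 0.25 mm (0.5 mm for the carrier-attenuation ratio) with
off-grid axon nodes sampled by an order-3 spline. A trilinear fallback
exists but is not the default: a trilinear interpolant has zero second
derivative inside cells and concentrates curvature at cell boundaries,
which directly corrupts the activating function and produces strongly
quantised AP counts across an array; the C²-continuous spline avoids
this. Beat sweeps additionally thin the arrays to every second axon
(0.2 mm pitch). Phasor fields are cached per (grid, frequency, source)
and shared across beats and gains by linearity, so a full sweep at one
carrier costs ~12 field solves.

At these settings the package reproduces: the normalization contract
(exactly 3 APs at the 1 kHz/30 Hz reference after scaling), the ~50%
skin-admittance rise from 1 to 4 kHz and the ~1% two-tone admittance
split, the carrier attenuation of drive RMS (ratio ≈ 1.5–2 from 1 to
4 kHz), beat-frequency tunability of PF at 3 kHz over more than 1 mm,
and a maximum PF of ≈ 1.4 mm (the full-scale reference value is
1.6 mm). Quantities tied to fine spatial structure — per-orientation
PF/PI values, strict monotonicity of S in f_c — are resolution
sensitive and should be read qualitatively at desk scale.

## What the toy fixtures do and do not show

The validation fixtures (homogeneous half-space, 11³ oracle grid,
hand-computed AP rasters, step-function gain oracle) exercise each
stage against independent references: analytic electrostatics, the full
time-domain PDE, hand-worked counting rules, and a known search target.
They establish correctness of the numerics, not physiological realism:
real skin has microstructure, contact impedance and curved geometry
outside this model's scope, and psychophysical validation is beyond
simulation.

## Known limitations

- Structured grids at h ≥ 0.25 mm under-resolve the electrode-edge
  field; PF/PI values carry a quantisation of one axon pitch.
- The HH membrane at its classic 6.3 °C rates is less excitable at kHz
  carriers than mammalian Aβ nodes; S values are model-internal gains,
  not ampere-calibrated thresholds.
- Threshold-crossing AP detection is ill-defined in the forced
  (supra-physiological) oscillation regime; the wave-grouping rule
  deliberately refuses to count such activity.
- Myelination, mechanoreceptor end organs, C/Aδ fibers, and electrode
  contact impedance are not modelled.
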