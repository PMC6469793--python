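# Methods

`biegm` simulates what a bipolar mapping catheter records when it touches
activating atrial tissue, and quantifies how the recorded morphology depends
on catheter orientation, contact angle, conduction velocity, action-potential
duration, scar size, rhythm (paced vs fibrillatory), and catheter design.
This note documents the models, the numerical choices, and the places where
the design was genuinely open.

## Membrane model

Every tissue node carries the 21-variable human atrial membrane model of
Courtemanche, Ramirez & Nattel (1998): the fast Na+ current, the inward
rectifier, transient-outward and ultrarapid/rapid/slow delayed rectifiers,
L-type Ca2+ current, Na/K pump, Na/Ca exchanger, background and pump Ca2+
currents, and a three-compartment intracellular Ca2+ system. Units are mV,
ms, mM and pA/pF; the whole-cell capacitance is 100 pF.

Two implementations coexist deliberately. `biegm.ionic.ionic_rhs` is a
plain NumPy transcription used for diagnostics. The production engine
(`biegm._kernels`) integrates gates with the Rush–Larsen exponential scheme
and Vm/concentrations with forward Euler at `dt = 0.02 ms`, reading every
purely voltage-dependent quantity from tables precomputed on a 0.05-mV grid
(linear interpolation); this removes nearly all transcendental calls from
the hot loop. A third, fully independent scalar transcription integrated
with SciPy's LSODA lives in the test suite as an oracle: one paced beat
from the published resting state agrees with the table engine to
about 0.15 mV RMS at the default step (the test bound is 0.5 mV).

**APD calibration.** The action-potential duration at 90% repolarization
(APD90) is measured from the instant of maximum dVm/dt to the first
downward crossing of rest + 10% of the peak-to-rest excursion, with linear
interpolation between samples. To reach a target APD90 the rapid and slow
delayed-rectifier conductances are multiplied by one common factor found by
bisection in [0.1, 10]; the common factor is a choice — the underlying
report adjusts both currents without stating a ratio. At a 600-ms cycle
length the unscaled model settles near 288 ms; factors of ≈1.84 and ≈2.85
give the two study settings of 223 and 180 ms (each within 1 ms).

## Tissue model

Wave propagation follows the monodomain equation

    dVm/dt = 1/(beta * Cm) * div(D grad Vm) - (I_ion + I_s)/Cm

with an isotropic scalar D, membrane surface-to-volume ratio
`beta = 140 mm^-1` and capacitance per unit area `Cm = 0.01 uF/mm^2`
(standard values; only the combination D/(beta*Cm) matters and the
conduction velocity is re-calibrated anyway, but both are exposed in
config). Stimuli are whole-cell currents of −2900 pA for 1.5 ms applied to
explicit node sets; each stimulated node receives the full current density
(distributing one −2900 pA over many nodes would dilute it below capture
threshold). A planar-wave pacing site is a 1-mm-deep edge band — a single
node column cannot capture because it loses its stimulus charge to the
diffusive sink of the neighbouring tissue.

**Discretization.** Sheets are structured grids triangulated into right
triangles; curved patches are cylindrical bends of the same grid. One
assembly covers both: cotangent finite-element edge weights with lumped
(barycentric) vertex areas, which on right-triangle grids reduce exactly to
the classical 5-point stencil with mirrored no-flux boundaries. The
operator is symmetric with zero row sums, so the area-weighted diffusion
flux sums to zero over the mesh to machine precision. Edges with a scarred
endpoint get zero weight (scar = non-conductive, uncoupled); fibrotic
endpoints multiply an edge weight by 0.5 each (configurable), and fibrotic
nodes additionally remodel their membrane (I_Na ×0.9, I_CaL ×0.5, I_K1
×0.8 by default — explicit configuration, not hidden constants). Explicit
stepping is guarded by a Gershgorin bound on the diffusion eigenvalues.

**Conduction-velocity calibration.** `calibrate_cv` finds the D that makes
a planar wave on a strip travel at a target speed, measured between two
interior probes 10 mm apart, using the cable-theory fixed point
`D <- D * (target/cv)^2` (converges in a few iterations). The CV realized
at a fixed D depends noticeably on the lattice: at 0.5-mm spacing a fixed D
conducts ~15% slower than at 0.125 mm, because the Na+ upstroke spans only
a couple of cells. This is why calibration is always performed at the node
spacing of the experiment that consumes it; the calibrated-then-measured
CV is spacing-independent to < 1%. The square-root law CV ∝ sqrt(D) is
recovered within 5% on a finely resolved strip (0.125 mm, dt = 0.005 ms).
Experiments run at 0.5-mm spacing, except the 0.13 m/s slow-conduction
condition, which blocks at 0.5 mm (its depolarization front is narrower
than one cell) and runs at 0.25 mm.

**Conditioning.** Rate adaptation is paid for at the single-cell level:
tissue runs start from the state of a cell paced for 8 (configurable)
beats at the protocol's cycle length, then stimulate the tissue once and
record. This makes a 40 × 40 mm experiment a ~300-ms simulation instead of
a multi-second one at no observable cost to the recorded beat.

## Fibrillation

Self-sustained re-entry is induced by cross-field stimulation: a planar S1
from the left edge, then an S2 over the lower-left quadrant timed into the
repolarization tail. The S2 timing is derived from the S1 run itself (the
instant the quadrant reference point repolarizes below −65 mV, plus 5 ms),
with a small deterministic schedule of fallback offsets; the first timing
that yields re-entry (≥ 2 re-activations at interior probes) is extended to
the full 6-s recording. Induction requires a remodelled substrate whose
wavelength fits the sheet: the defaults (APD90 120 ms via the same
delayed-rectifier scaling, CV 0.30 m/s) give a wavelength of ≈36 mm on the
40-mm sheet and sustain throughout the window with a cycle length of
~165 ± 10 ms at the reference node. The recording is declared fibrillatory
only if activations continue into the final 1.5 s and the cycle length is
non-constant. The S1–S2 recipe and the remodelling levels are this
package's own choices, stated here because the study chain does not fix
them.

## Virtual catheters

Three two-electrode designs are built in:

| design | electrodes | tip | spacing | shaft |
|---|---|---|---|---|
| Thermocool | cylindrical | 3.5 mm (dome tip) | 2.0 mm | 2.3 mm |
| Pentaray | cylindrical | 1.0 mm (dome tip) | 2.0 mm | 1.0 mm |
| Orion | flat, 0.4 mm² | — | 2.5 mm | 1.0 mm |

Tip length, flat-electrode area and inter-electrode spacing are the
published dimensions; shaft diameters, the 1-mm proximal ring and the
square flat face are this package's completions, exposed in the design
record. Spacing is interpreted edge-to-edge. The distal cylindrical
electrode ends in a hemispherical dome (the physical shape of an ablation
tip); this matters — with a flat end cap, perpendicular contact would press
several mm² of metal against the tissue at minimum clearance and the
contact-angle trend would invert.

Electrode surfaces are tessellated into patches of ≤ 0.07 mm² (count-first
subdivision, so halving the ceiling at least doubles the patch count); the
extracellular potential is evaluated at every patch and averaged per
electrode. Poses are defined by the contact angle CA (axis vs tangent
plane) and orientation CO (tangential axis projection vs the local
activation-wavefront direction, estimated from a least-squares
activation-time gradient). The rigid body is lowered along the surface
normal until its nearest patch sits at a 0.05-mm clearance, which also
bounds the 1/r kernel.

## Forward model

Each node is a current monopole of strength `source × area × thickness` in
an infinite homogeneous volume conductor, where `source` is the recorded
diffusion term (mV/ms) — zero row sums make the mesh globally
charge-neutral, so the far field is dipolar as it should be. The global
gain K (default 3.2 × 10⁻²) is the one deliberately non-physical constant:
the absolute voltage scale depends on conductivities the study chain does
not constrain, so K is set to put the flat-lying Thermocool on the
homogeneous sheet near 1.8 mV peak-to-peak, the clinically familiar scale.
Every ordering and ratio the experiments report is invariant to K (tested).
Bipolar traces are distal − proximal at 1 kHz; fibrillation strips are
band-passed 30–150 Hz with a 4th-order zero-phase Butterworth before
feature extraction, paced beats are analysed raw.

## Experiments and their design choices

* **Features.** Amplitude = max − min of the bipolar channel in the beat
  window; width = time between the (earliest) positive and negative
  extrema.
* **Orientation/contact sweeps.** 10 replicate interior sites (margin-
  excluded, sampled without replacement, fixed seed), CO and CA at
  0/30/60/90°.
* **Scar series** (diameters 0/5/7/9 mm). The catheter is laid flat with
  its bipole midpoint on the scar centre against the macroscopic wave
  direction, replicate sites jitter by ±0.6 mm. The series is reported for
  the small flat-electrode design (Orion): its footprint (3.8 mm) fits
  inside all three scars, so both electrodes sense the wave entering and
  leaving the zone and the peak-to-peak width stretches with the detour
  time. Larger catheters overhang the small scars, their live-tissue
  electrode dominates the trace, and the width trend is not monotone at
  this sheet scale — a genuine limitation of the scaled-down geometry, not
  of the forward model.
* **Fibrillation vs paced.** Same sites and catheter pose in both rhythms;
  AF amplitudes are means over deflections detected on the rectified
  band-passed signal at 3× its median absolute deviation with a 50-ms
  refractory.
* **Voltage maps.** Random sites with independent uniform CO/CA on
  [0°, 90°], inverse-distance interpolation (k = 6, power 2, exact at
  sampled nodes), and a 10-segment k-means partition of node coordinates
  for segment averaging.
* **Scar cut-offs.** Placements uniform over the zone plus a 2-mm margin;
  a placement is in-scar when both electrodes are fully inside. The three
  orientation modes (parallel / perpendicular / random vs the local
  activation flow — for a fully in-scar catheter that is the wave
  detouring along the boundary) are compared on a common (paired)
  placement set per design where the geometry allows it; the largest
  catheter cannot fit a 9-mm zone in two orthogonal directions at once, so
  it falls back to per-mode sets. The cut-off is the maximum in-scar
  amplitude, i.e. the smallest threshold classifying every in-scar
  placement as scar. Cut-offs are max-statistics over a few dozen
  placements and correspondingly noisy; the paired design removes the
  between-mode sampling asymmetry that otherwise dominates.

## Fibrosis model

Fibrosis probability is the cubic `Y = -40 X^3 + 155 X^2 - 206 X + 99.8`
in the local bipolar voltage X (mV), read on the percent scale — its value
at X = 0 is 99.8, which is only coherent as a percentage — and clamped to
[0, 100] outside that range (the cubic goes negative above ≈0.9 mV and
exceeds 100 nowhere on x ≥ 0; whether the original work clamped or
re-normalized is not stated). Node states are independent Bernoulli draws
against Y/100 with an explicit seed. The synthetic "clinical" voltage map
feeding this stage is Gaussian-smoothed uniform noise rescaled to
0.1–6 mV with an 8-mm correlation length: only its role — a smooth positive
spatial voltage field — matters, not its provenance, and passing tests on
it says nothing about registration or interpolation of real catheter data.

## What the synthetic conditions do and do not show

All experiments run on homogeneous 40 × 40 mm sheets (or cylindrical bends
of them) rather than a patient left atrium. Trends — orderings across
orientations, angles, velocities, scar sizes, designs and rhythms — are the
reproducible content; absolute millivolt statistics are not, because they
depend on patient geometry, wall thickness variation and volume-conductor
conductivities outside this chain. The model is a surface: no transmural
heterogeneity, no fiber anisotropy (single scalar D), no contact-force or
electrode-interface effects, no noise. Sheet-scale widths are several-fold
smaller than atrial ones since they are set by electrode spacing over CV
without curvature or wall-thickness contributions.

## Problem sizes and determinism

Default experiment sizes were chosen to keep a full study desk-scale: one
paced 40 × 40 mm sheet at 0.5 mm is a ~300-ms simulation (≈20 s of compute);
the slow-CV condition at 0.25 mm is ~2 min; the 6-s fibrillation episode
~10 min. Every random choice (site sampling, random orientations, fibrosis
draws) flows from explicit integer seeds through `numpy.random.default_rng`,
and rerunning any driver or CLI command with the same configuration and
seed reproduces outputs bit for bit.
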