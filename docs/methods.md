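# Methods

## Model

Magnetization is propagated through a preparation module as a product of 3×3
real matrices acting on **M** = (Mx, My, Mz) in the rotating frame, starting
from the ground state (0, 0, 1).  Rotations are *clockwise in a left-handed
frame*: `Rx(ψ)` has rows (1,0,0), (0,cosψ,sinψ), (0,−sinψ,cosψ), and
analogously for y and z.  This convention is pinned by regression tests
because every closed form in the package depends on it.

Rotating-frame relaxation during a lock segment of duration τ is diagonal,
`Eρ(τ) = diag(e^{−τ/T2ρ}, e^{−τ/T1ρ}, e^{−τ/T2ρ})`, with the T1ρ decay on
the y (lock) axis.  Hard pulses are instantaneous: a nominal 90° excitation
rotates about x by (π/2)·s and a 180° refocusing pulse about y by π·s, where
s is the B1 scale (1 + ΔB1).  Relaxation during hard pulses and T1 recovery
before readout are neglected; the readout is an ideal sampler of the prepared
Mz.  Full time-stepped Bloch integration is out of scope — the propagator
algebra is exact under these assumptions and orders of magnitude faster.

Off-resonance tilts the effective lock field by θ = arctan(Δω0/ω_SL) and
changes its magnitude to ω_e = √(ω_SL² + Δω0²).  A lock segment of phase +y
is `Rx(−θ)·Eρ(τ)·Ry(ωτ)·Rx(θ)`; the phase-reversed segment conjugates with
`Rx(π−θ)` instead, which reorients both the rotation axis and the relaxation
axis to the −y-tilted effective field, so no extra sign logic is applied to
`Eρ`.

### In-lock rotation rate (`angle_mode`)

Two conventions for the rotation angle during the lock are exposed:
`effective` (ω_e·τ, the physically consistent precession about the effective
field) and `literal` (ω_SL·τ).  They coincide at Δf0 = 0, and both reproduce
all eight limiting-case closed forms to 1e−15 — in both limiting cases the
in-lock rotation cancels out of Mz.  At mixed deviations they differ by well
under the run-to-run spread of the random-TSL protocol (<0.2 pp at the
benchmark condition).  The default is `effective`.

### B1 error model (`couple_sl_amplitude`)

A B1 deviation always scales the hard-pulse flip angles.  Whether it *also*
scales the lock amplitude (hence θ and ω_e) is configurable:

* `couple_sl_amplitude=True` (constructor default) — physically complete
  single multiplicative B1 error.
* `False` — the flip-angle-only convention of grid simulations that sweep
  α and β directly, and of phantom experiments that provoke B1 errors by
  misprogramming the pulse flip angles.

The published per-module benchmark errors reproduce under the *decoupled*
convention (three of four modules to ≤0.8 pp); the benchmark protocol and the
acceptance suite therefore run with `couple_sl_amplitude=False`, while the
library default stays coupled for general use.

### Closed-form limiting cases

With only a B1 error (θ = 0): the odd-refocused modules (C-SL, TR-SL) give
`Mz = −E1 sin²α + E2 cos²α cosβ`, retaining a cosβ sensitivity to the
refocusing flip angle; the even-refocused modules (B-SL, QR-SL) give
`Mz = E1 sin²α + E2 cos²α` with no β dependence (opposite-phase refocusing
pairs cancel the 180° error).  With only a B0 error (α = π/2, β = π):
`Mz = ±(E1 cos²θ + E2 sin²θ)`, negative for C-SL/TR-SL, positive for
B-SL/QR-SL.  Here E1 = e^{−TSL/T1ρ}, E2 = e^{−TSL/T2ρ}.  These are
transcribed independently of the propagators and serve as the oracle.

## Quantification protocol

* **Random-TSL fitting.** Per repetition, 8 lock times are drawn i.i.d.
  uniform on [0, 2·T1ρ]; |Mz| at those times is fitted to S0·e^{−t/T1ρ}
  (two parameters, no offset).  The same draws are reused for every module
  within a repetition, so module comparisons are exactly paired.  Δq =
  T1ρ,fit/T1ρ,true − 1 per repetition; ΔQ is reported both as the signed
  mean and as the mean magnitude over 100 repetitions.  The published
  per-module percentages correspond to the mean-magnitude form, which is the
  default comparison (a signed mean lets oscillatory bias cancel).
* **Amplitude (Mz) error.**  Interpreted as |S0,fit − 1| against the true
  initial magnetization of 1 — the only other free parameter of the fit.
  This interpretation reproduces the published amplitude errors to ≤1.5 pp
  with the correct module ordering.
* **Banding score.**  |Mz| on 200 uniform TSL points in [0, 2·T1ρ] is fitted
  the same way and the *raw sum* of squared residuals is the RSS.  The raw
  sum (not the mean square) is the form whose <0.01 criterion reproduces the
  published proportion rankings; a normalized (mean-squared) variant is
  available.
* **Fitting.**  `fit_monoexponential` is unweighted nonlinear least squares
  (scipy `curve_fit`) initialized from a log-linear fit of the positive
  samples.  Sweep- and map-scale workloads use `fit_monoexponential_batch`,
  a vectorized variable-projection solver of the *same* least-squares
  problem: the amplitude is eliminated analytically and the decay rate is
  located by an 80-point log-spaced grid (rates 0.01–100 per max TSL),
  golden-section refinement, and a 4-step Newton polish.  The coarse grid
  guards against the multimodal objectives of oscillating trajectories; the
  polish brings exact-data recovery to ~1e−12 relative.  Rates at the grid
  edge, non-positive amplitudes and all-zero inputs are flagged failed, and
  failed repetitions/voxels are excluded and counted.  Agreement between the
  two routes is pinned by a test.

All error metrics are invariant to a common scaling of (T1ρ, T2ρ, TSL), so
the absolute T1ρ (default 50 ms) is a convenience, not a physical claim.

## Sweeps

Grids span Δf0 ∈ [−600, +600] Hz × B1 scale ∈ [0.5, 1.5], endpoints
included; an odd step count puts the ideal cell on the grid.  The production
grid is 100×100; tests and the scaled-down acceptance profile use 21×21 with
50 repetitions per cell, which leaves the module orderings stable while
keeping the whole suite inside a couple of minutes.  TSL draws are generated
once per sweep seed and shared across cells and modules, making per-cell and
cross-module comparisons deterministic and paired; cells are independent, so
any execution order (or chunking) yields identical results.  Proportion
summaries count cells with |ΔQ| < 1% (mean-magnitude form) and RSS < 0.01.

The refocusing-phase study builds 4-refocused modules for the six
self-compensating phase patterns (+y+y−y−y, −y−y+y+y, +y−y−y+y, −y+y+y−y,
+y−y+y−y, −y+y−y+y) with the standard rotary-echo lock cycling and ranks
grid-mean RSS under shared seeds.  The first four cluster within ~10% of each
other; the strictly alternating pair degrades by a factor of ~2.5.

## Digital phantom

Five 20-mm circular tubes (quincunx layout, 30 mm center spacing) on a
200×200 matrix over a 120×120 mm FOV.  The default per-tube T1ρ values
(120, 95, 75, 60, 50 ms) are *synthetic* placeholders emulating 2–6% agarose
at 3 T — stiffer gel, shorter T1ρ; they are package defaults, not measured
reference values, and nothing in the acceptance analysis depends on them.
T2ρ defaults to T1ρ (ratio 1) and is configurable per tube.  The default
field maps reproduce the provoked-inhomogeneity experiment: a linear
off-resonance ramp spanning −58…+58 Hz across the FOV in x, and a uniform
B1 scale of 0.8 (−20%).

Signal synthesis is proton density · |Mz| per voxel; optional noise is
complex Gaussian on two quadrature channels followed by a magnitude
operation (Rician), with noise off by default since the reference experiment
reports no SNR.  What the twin does *not* model: TSE echo-train blurring and
T2 decay during readout, fat suppression, slice profiles, coil sensitivities,
partial-volume effects.  Passing orderings on the twin therefore demonstrate
the preparation-module physics, not full acquisition realism, and the
published absolute map-RSS values from scanner data are deliberately not
targeted — only their orderings across modules and lock frequencies.

Field-map estimators implement the standard dual-TE phase-difference B0 map
(TE 2.5/3.5 ms, alias-free to ±500 Hz; wrapping is flagged, not corrected)
and the double-angle B1 map (60°/120°; voxels with |s2/(2·s1)| ≥ 1 flagged
invalid).

## RF metrics

Hard pulses are rectangular, 1 ms by default (250 Hz amplitude for 90°,
500 Hz for 180°); lock segments run at f_SL.  The RMS integral over a window
W is √(Σ amp²·dur / W).  Module comparisons use a common fixed window (the
longest module at that TSL), which isolates deposited RF energy from the few
milliseconds of length difference between modules; with the module's own
duration as window the comparison can go marginally negative at high f_SL.
The published scanner-recorded RMS values include readout RF and are treated
as a trend (the QR-over-C premium shrinks with rising f_SL), not an equality
target.

## Known limitations

* The quadruple-refocused module's mean T1ρ error at the benchmark condition
  simulates to ≈4.5 ± 0.5% versus the published 3.49%, although the other
  three modules and all amplitude errors agree closely; the published
  QR-vs-C T1ρ ordering (3.49 vs 3.73, a gap within that protocol's own
  seed noise) does not reproduce under any event ordering consistent with
  the published module definitions.  The amplitude-error ordering does
  reproduce.
* Adiabatic pulses, T1ρ dispersion, slice-selective pulse shapes and scanner
  sequence export are out of scope.
* The C-SL heat-map asymmetry under combined deviations is visible in sweep
  outputs but is not asserted as a test property.
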