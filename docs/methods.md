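# Methods

This note records the models, numerical choices and known limitations of
`flydose`, in the order the pipeline uses them.

## Voxel phantom

The digital fly is a parametric ellipsoid composite, not an image-derived
twin: three axially aligned body segments (head, thorax, abdomen) of
circular cross-section with axial fractions 0.28/0.36/0.36 of the body
length (default 2.5 mm, a typical adult female) and a segment overlap
factor of 0.85 so the body is a single connected solid.  The exoskeleton
is produced by discrete binary erosion of the body mask with
`round(cuticle_thickness / pitch)` iterations (default 60 µm, i.e. three
20 µm voxels — the minimum the generator accepts, so the thinnest layer
always spans at least three grid steps).  Brain, flight muscles and
gonads are concentric ellipsoids inside head, thorax and abdomen,
clipped to the eroded interior so they can never touch the shell; wings
are thin elliptical slabs tangent to the thorax, halteres small
half-embedded spheres.  Label precedence is organ > inner tissue, with
the exoskeleton applied last over the shell region.

Calibration: the transverse radii of all segments are scaled by one
factor s chosen in closed form so that the expected total tissue volume
(body + wings + halteres) equals `target_total_volume` (default
2.1 mm³, the printed whole-fly volume).  Because all cross-sections are
circular and coaxial, the union volume is a 1-D integral of
π·max_i r_i(x)², evaluated by a fixed 20001-point quadrature; the
voxelized default lands at 2.095 mm³ (−0.3 %).  Generation is fully
deterministic.

What the phantom does *not* emulate: real organ shapes, legs, antennae,
posture, or air-filled tracheae.  Tests that pass on this phantom
demonstrate correct bookkeeping and solver physics on a fly-sized,
fly-shaped heterogeneous object — not anatomical fidelity.

Mesh voxelization (for user-supplied watertight STL twins) labels a voxel
iff its centre is inside the surface, by parity of +z ray crossings with
a deterministic 1e-6·pitch tie-breaking offset so rays never graze
vertices.  Against the exact polyhedron volume the error falls
monotonically with pitch (1.1 % → 0.08 % from a/10 to a/40 for an
icosphere).

## Tissue dielectrics

All seven tissues share one property set — tissue-resolved dielectric
spectra for this species do not exist — with per-tissue overrides
possible wherever a `TissueProperties` is accepted.  The default model is
a single-pole Cole-Cole with a water-like relaxation (τ = 8.27 ps,
α = 0.1, ε_∞ = 5) whose dispersion strength and ionic conductivity are
solved linearly so the model passes exactly through the 3.6 GHz insect
anchor ε_r = 42, σ = 2.8 S/m; this yields Δε ≈ 40.0 and
σ_s ≈ 1.24 S/m, and plausible values across 1–240 GHz (ε_r 44 → 6,
σ 1.4 → 53 S/m).  The packaged CSV table is this model evaluated at the
ten standard dosimetry frequencies; `interpolate_properties` is
piecewise-linear in log-frequency and refuses to extrapolate.  The sign
convention is e^{+iωt}, so the effective conductivity handed to the
solver is σ(ω) = −ω ε₀ Im ε̂, folding dipolar and ionic losses into one
number — exactly what a single-frequency harmonic run needs (the solver
is deliberately non-dispersive within a run).

## FDTD solver

Uniform Yee lattice, leapfrog updates with semi-implicit conductivity
(ca/cb coefficients), cell-based material staircase: all three E
components at cell (i,j,k) use that cell's ε and σ.  This makes the
discrete Joule dissipation identical to the per-cell absorbed-power sum,
which is why the Poynting balance closes to 1.7 % on the validation
sphere; sub-cell material averaging would buy accuracy at the surface
but break that identity.

* Time step: dt = safety·Δ/(c√3) (default safety 0.99), then rounded
  down so one source period is an integer number of steps.
* Resolution guard: protocol-level runs refuse grids coarser than one
  tenth of the in-tissue wavelength λ₀/(10√ε_r).
* Boundaries: 10-cell CPML (Roden–Gedney, κ = 1, cubic σ grading with
  σ_max = 0.8(m+1)/(η₀Δ), α linearly graded from 0.24), PEC behind it.
* Sources: TF/SF box in the vacuum region around the phantom.  The plane
  wave uses the wavenumber of the discrete dispersion relation (Newton
  solve per direction), which keeps scattered-region leakage below
  −100 dB on the deeply subwavelength grids used here; incident E and H
  are evaluated at the exact staggered positions and half-step times.
  The near-field antenna is the closed-form field of a centre-fed
  thin-wire dipole with sinusoidal current (default half-wave), its feed
  current normalised so the free-space radiated power matches the
  requested value (surface-flux check agrees to numerical quadrature
  accuracy); injecting the analytic incident field avoids staircasing a
  metal wire at desk scale.
* Steady state: fixed period counts per frequency band (16 up to
  24 GHz, 23/27/33/38 at 60/90/120/240 GHz), with a single-frequency
  running DFT of all six components over the final period.  The counts
  are overridable: every grid in this package is small compared to the
  free-space wavelength (domain transit ≲ 2 % of a period), and a
  16→24-period extension moves sphere absorption by <1 %, so
  solver-level tests and the fly ensemble run 3–4 periods.
* Fields are single-precision (the update is memory-bandwidth bound);
  DFT accumulators are double.  Linearity is still exact for power-of-two
  amplitude ratios, which is how the P ∝ E² property is checked to
  1e-10.
* Instability guard: the run aborts if max|E| exceeds 10⁶× the source
  scale or goes non-finite.

Validation battery: absorbed power of a 1 mm insect-tissue sphere at
6 GHz, 50 µm pitch agrees with the Mie series to 5.8 % (12.3 % at
100 µm — refining the pitch reduces the error); the twelve-member
polarization ensemble agrees on a centred sphere to 0.03 %; the empty-box
interior RMS reproduces the incident 1 V/m to 2e-6.

## Exposure protocols and dose bookkeeping

Far field: twelve plane waves — six axis-aligned propagation directions,
each with both grid-axis polarizations orthogonal to it — at 1 V/m RMS.
For the fly phantom at 3.6 GHz the four members with E along the
anteroposterior axis absorb ~6× more than the others, the expected
depolarization-factor effect for an elongated body.

Near field: twelve phantom locations (six azimuths around the antenna ×
near ring 11 mm / far ring 34 mm from the antenna axis, at mid-arm
height) × two body orientations: parallel to the arm, or orthogonal
(pointing at the antenna).  Placements are expressed in the phantom
frame, so the phantom never rotates on the grid.  Known limitation: with
a centre-fed dipole the field at the far ring is predominantly
arm-parallel at any plausible height, so the orthogonal>parallel effect
holds at the near ring (which dominates the dose) but reverses at the
far ring; the experimental antenna was a monopole over a desk, whose
exact simulated geometry is not recoverable.  Summary statistics are the
arithmetic mean and population SD over placements.

Rescaling assumes free-space quadratic scaling
P = P_ref (E/E_ref)², ignoring standing waves, and
`equivalent_farfield_strength` is its inverse; the two are deliberately
independent operations, not cross-checks of each other.

## Circadian statistics

The synthetic locomotor generator draws independent Poisson counts per
30-min bin with rate m(1 + d·s(t)): m = 2 counts/bin, depth d = 0.8,
free-running period 22.5 h by default, s a zero-mean unit-amplitude
sinusoid or (for the bimodal male-type profile) two Gaussian bumps per
cycle at phases 0.25/0.75 with 1.5 h SD, mean-removed and renormalised.
It emulates rhythmicity, count noise and bimodality of monitor data — not
sleep bouts, weekend-style nonstationarity, inter-fly variance or death.

The periodogram folds the series at every integer bin count in the
scanned range (0.5 h steps; no sub-bin interpolation, so the statistic
is exactly reproducible) over K complete cycles and computes
Q_P = K·Σ_h(M_h − M̄)² / (Σ_i(x_i − M̄)²/N), chi-square with P−1 degrees
of freedom under a white-noise null.  The significance line is the Šidák
familywise quantile χ²((1−α)^{1/m}, P−1) over the m candidates: with a
pointwise 0.05 line, pure Poisson noise maximised over the ~13
candidates in 20–26 h crosses the line in roughly half of 15-day
recordings, which would make "RRP > 1" meaningless as a rhythmicity
call; with the familywise line the measured false-call rate is 5/100
seeds and the median null RRP 0.81, while depth-0.8 rhythms exceed the
line in 100/100 seeds.  Zero-variance series get Q ≡ 0.  Group-level
hypothesis testing (ANOVA and friends) is out of scope — standard
statistics packages do it.

## Problem sizes

The shipped validation configurations were chosen as the smallest grids
that still probe each property: the Mie sphere at 50 µm (75³ cells,
28 000 steps), the polarization ensemble on a 0.6 mm sphere at 24 GHz,
the fly protocols on a 100 µm phantom (≈31×29×25 voxels) with 3–4
source periods.  Full 20 µm broadband fly dosimetry is the same code at
larger dims/period counts and is cluster-scale, not laptop-scale.
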