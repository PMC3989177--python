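# Methods

This note documents the physical model, the numerical choices and the
known limitations of `tofsim`. Units throughout: millimeters,
milliseconds, radians; flow rates in mm³/ms (numerically equal to
ml/s); magnetization is dimensionless with equilibrium magnitude equal
to the relative proton density ρ.

## Flow model

The flow stage replaces a CFD solver with analytic laminar fields. For
a tube of local radius `R(s)` (arc length `s`) driven at volumetric
rate `Q`, the axial profile is parabolic with
`v_max(s) = 2Q/(πR(s)²)`, which fixes the flux through every
cross-section to `Q` exactly. In stenoses the radius varies and
incompressibility adds a radial component

    v_r(r, s) = (2Q/π) R'(s) (r / R³) (1 − (r/R)²),

whose effect is that streamlines ride surfaces of constant relative
radius `η = r/R(s)`: a fluid thread entering at `η` keeps `η` through
the throat, accelerating as `1/R²`. This preserves every flow feature
the MR kernel consumes — axial speed distribution, throat acceleration
and downstream relaxation, transit-time spread between axis and wall —
while deliberately omitting turbulence, post-stenotic jet asymmetry,
Dean vortices in bends, pulsatility and non-Newtonian rheology. Images
downstream of a tight stenosis are therefore more symmetric than real
acquisitions.

Geometries: straight cylinders; stenosed cylinders with a
cosine-tapered neck (C¹ radius profile, default extent 10 mm — the
neck shape is a modeling choice, only its throat diameter is
prescribed); U-bends made of two vertical legs joined by a
semicircular arc (flow modeled as locally parabolic along the bent
centerline). A "50 % of diameter" stenosis means the throat diameter
is half the nominal one, i.e. a four-fold area reduction.

Trajectories are integrated with the explicit midpoint rule (RK2).
Each trajectory may carry its own step: the bundle tracer sizes
`dt` per thread so every path resolves to ~1200 samples regardless of
speed, which keeps slow near-wall threads from dominating memory while
the linear interpolation error stays far below a voxel (paths are
straight or gently curved). The outlet crossing is located by linear
interpolation of the arc coordinate and stored as the transit time.
Sample speeds are field magnitudes evaluated at the sample positions.

## Particle seeding

Inlet seed points use a sunflower (Fibonacci) layout for even
low-discrepancy coverage; the layout is deterministic. The inlet disc
is tessellated by the Voronoi diagram of the seeds, each cell clipped
to the disc; cell areas `A_i` make the per-thread particle volume
`V_i = A_i·Δl_i` with `Δl_i` the inlet spacing (default 1/3 mm, i.e. 3
particles per millimeter of vessel length; default 256 trajectories
per tube). The disc boundary is approximated by a regular 8192-gon
(area error ≈ 4·10⁻⁷ relative) and the areas are rescaled by the
polygon/disc ratio so the tessellation closes to machine precision.

Particles on a thread are spaced uniformly in *time of flight*
(`Δt_i = Δl_i/v_i(inlet)`), so their spatial spacing stretches exactly
where the fluid accelerates while the cross-section contracts — the
per-particle volume is constant along the thread by construction, and
no 3D tessellation of the lumen is needed. Retired particles (past the
outlet) are replaced at the inlet at the same cadence with equilibrium
magnetization `(0, 0, ρ)`; fresh particles therefore contribute no
signal until the next excitation, which is the mechanism behind the
dark slab-entry voxels. Stationary tissue components are uniform
random particles (Poisson count at the requested density) outside the
lumens, each carrying volume `1/density`.

## Bloch kernel

The discrete-time analytic solution is used throughout: piecewise
constant fields, rectangular RF pulses. Operators:

* `relax`: transverse decay `E2 = exp(−dt/T2)`, longitudinal recovery
  `Mz' = M0 + (Mz − M0)·E1`. The recovery term is essential — without
  it there is no steady state and no inflow contrast.
* `precess`: rotation of `(Mx, My)` about z by `(Δω + γG·r)·dt`.
* `rf_excite`: rotation by `α_eff = τ√(ω₁² + Δω²)` about the effective
  field axis tilted `θ = atan2(ω₁, Δω)` from +z. Pulses are divided
  into substeps (default 8 for moving spins, 1 for stationary); at each
  substep the particle is re-localized and receives its sub-rotation
  only if inside the slab profile, so a spin that exits mid-pulse
  accumulates a partial flip. The slab profile is ideal-rectangular,
  consistent with the rectangular-pulse assumption.
* `tone_flip`: linear flip ramp over the slab, nominal angle at the
  slab center, total span (default 20°) oriented along the per-channel
  flow direction. Scanner vendors shape this ramp nonlinearly; linear
  is the documented approximation.
* `spoil`: ideal — transverse components zeroed at the end of each TR.

Convention: RF phase 0 puts the effective-field azimuth on +x and a
positive on-resonance flip takes +z to −y. Any self-consistent
convention produces identical magnitude images. On-resonance pulses
use a specialized x-rotation path; the general tilted-axis (Rodrigues)
path handles off-resonance. Both preserve |M| to 1e−12.

## Sequence and acquisition

One k-space line per TR. The TR schedule is: presaturation (if
enabled) → RF (TONE-modulated, subdivided) → phase encode → free
relaxation → readout comb → relaxation to TR → spoil. The echo center
sits at `rf_duration/2 + TE`; the readout window of duration
`Nx·dwell` is centered on it, with `dwell = readout_window/Nx`
(Nyquist-matched MRA clock; default window 2.56 ms).

Phase encoding is applied as an instantaneous per-particle rotation
`−2π(ky·y/FOVy + kz·z_slab/W)`. Flow compensation on a phase-encode
axis is modeled by evaluating the particle position at the *echo*
instant (what moment-nulled lobes encode) instead of the encode
instant; the gradient-lobe designer (`flow_comp_waveform`) computes
the actual two-lobe amplitudes by solving the 2×2 moment system and is
verified against an independent piecewise midpoint-rule integration of
γ∫G(t)x(t)dt. The frequency-encode axis is modeled sample-by-sample:
`kx` sweeps −Nx/2 … Nx/2−1, each unit step imparting `−2π·x(t)/FOVx`
with the particle's instantaneous position, so frequency-direction
flow effects arise naturally.

The readout inner loop is evaluated in closed form per line: because
z-rotations commute with the isotropic T2 scaling of the transverse
plane, particle *i*'s transverse value at sample `p` equals its
window-start value times `E2^p` times the accumulated phase. For
particles whose x-coordinate is constant over the 2.5-ms window (every
axial-flow section; tolerance 1e−9 mm ≈ 1e−9 rad) the phase is linear
in `p` and a complex-multiply recursion is used; others get the full
per-sample evaluation. Particles crossing the outlet mid-window stop
contributing from that sample on and are compacted at the next TR
boundary; particles injected mid-line would contribute zero (no
transverse magnetization) and are instantiated at the next TR. These
are exact restatements, not approximations, of the sequential
per-sample update.

Presaturation is an ideal 90°+spoil applied once per TR to every
particle inside a band (default 40 mm wide, 5 mm gap) above or below
the slab; saturated spins recover with T1 on their way into the slab,
so slow near-wall counter-flow re-enters with partially recovered
signal. Line ordering is sequential ky within kz (configurable);
ordering affects only transient-state artifacts. Acquisition starts
from thermal equilibrium; `dummy_trs` can prepend steady-state
preparation cycles (default 0, so the approach to steady state is
itself visible at the k-space periphery, as on a scanner without
disdaqs).

Chunked execution (`run_chunked`) partitions trajectory bundles into
independent simulations whose k-spaces are summed in index order — the
in-process restatement of a master/worker reduction over trajectory
bunches. Because the signal is a sum over particles, the result equals
the single-chunk run to floating-point re-association (~1e−15,
asserted at 1e−10).

## Reconstruction

Centered inverse FFT (DC at index N//2 pre-shift) with magnitude
output; optional separable Tukey window on the phase-encode axes
(unit DC gain; default off, taper 0.5 when enabled — the filter choice
is free, any low-pass qualifies); zero padding to a configurable
target (default 256×256 in-plane) implementing sinc interpolation;
MOTSA compositing by discarding half the overlap from each adjoining
slab (default) or maximum-intensity blending. Optional complex white
Gaussian k-space noise (seeded) yields Rician/Rayleigh magnitude
statistics.

## Validation toolkit

Practical 3D non-local means: each voxel is replaced by the weighted
mean of candidates in a search window (default radius 5; negative
radius = whole image, used to match the brute-force oracle on tiny
volumes), with weights `exp(−d²/h²)` from the mean squared difference
of patch neighborhoods excluding their centers; candidates are actual
image voxels only, patches may reach into reflective padding; `h`
defaults to a Laplacian-MAD noise estimate. The Gaussian noise model is
appropriate above SNR ≈ 3 (magnitude-image Rician ≈ Gaussian);
`estimate_snr` warns below that. Alignment is an exhaustive
integer-shift search maximizing normalized cross-correlation — full
mutual-information rigid registration is unnecessary for
synthetic/synthetic comparisons generated in a common frame.
`compare_vois` reports Pearson r, its 95 % Fisher-z interval
`tanh(atanh r ± 1.96/√(n−3))`, and the RMSE after min-max scaling both
volumes to [0, 1].

## Presets and problem sizes

The bundled presets reproduce a commercial flow-phantom setup: tubes
of 8/8/8/5 mm diameter and 207 mm length on 25 mm centers (75 % and
50 % diameter stenoses on two channels), a U-bend of 44 mm curvature
radius, blood-mimicking fluid (ρ = 1.00, T1 = 850 ms, T2 = 170 ms at
1.5 T; density 1020 kg/m³ and viscosity 4.1 mPa·s as metadata), and
four studies pairing flow rates 2.5/2.5/4.6/10 ml/s with TE/TR/flip of
4.7/40/20°, 4.7/40/15°, 4.6/27/15°, 4.6/27/15° and slab width/overlap
44/8 (study 4: 25/5), in-plane sampling 224×160 at 1-mm slices. Each
channel is driven at its nominal rate independently. The `scale`
factor shrinks only the matrix and trajectory counts; all physics
parameters stay full-scale, and the dwell/window coupling is
preserved.

The default test-suite and example runs use reduced sizes — 64
trajectories on short (60-mm) tubes, 64×64×(8–16) matrices, ~1.1·10⁴
particles — chosen so a full behavioral run (entry void, parabolic
profile, presaturation contrast) completes in tens of seconds on one
core while exhibiting the same contrast mechanisms as the full-scale
configuration.

## What the synthetic checks do and do not show

The oracle suite verifies the simulator against closed forms (spoiled
steady state, inflow limit, continuity, Fisher-z, Parseval) and
against behavioral orderings that any correct ToF implementation must
reproduce. Passing these does not certify agreement with real scanner
data: that comparison requires measured acquisitions and, with them,
sub-voxel rigid registration, coil/noise modeling and the turbulent
flow features excluded here.

## Numerical notes and edge cases

* Particle counts per thread use `floor(T/Δt − 1e−9) + 1` so integer
  boundaries (e.g. 207 mm at 3/mm → exactly 621) are stable against
  rounding.
* Retirement tolerance is 1e−9 ms on the transit time; counts per
  thread are conserved to ±1 during swap instants.
* Degenerate inputs fail fast: closed stenoses (f ≥ 1), seeds outside
  or duplicated on the inlet disc, zero inlet speed, TE too short for
  the readout window, constant images in correlation/alignment.
* `simulate_slab` keeps magnetization state continuous across all TRs
  of a slab; separate slabs restart from equilibrium (each MOTSA slab
  is an independent acquisition).
* With `n_chunks` fixed, runs are bit-reproducible for a fixed seed;
  changing `n_chunks` changes only the floating-point association
  order of the k-space sum.
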