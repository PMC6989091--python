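# Methods

This note documents the models, numerical schemes, parameter choices and
known limitations behind `cilioflow`, in the spirit of a methods supplement.

## Two-region flow model (`hydro`)

The central canal is idealized as a 2D channel: `x` rostro-caudal
(positive = caudal), `y` dorso-ventral with the ventral wall at `y = 0` and
the dorsal wall at `y = d`. Motile cilia line the ventral wall; their action
on the fluid is homogenized into a constant axial volume force density `f_v`
(N/m³) over the ciliated layer `0 ≤ y ≤ h`. Dimensional analysis gives
`f_v = α µ f / h` with `f` the mean beat frequency (default 40 Hz), `µ` the
CSF viscosity (default 1e-3 Pa·s, water-like) and `α` a dimensionless
efficiency of order unity (default 0.5, the value that matches the observed
±5 µm/s amplitude; there is no independent constraint on it).

At these scales (µm, µm/s) inertia is negligible and the Stokes balance per
region is `dP/dx − f_v = µ v''` (ventral) and `dP/dx = µ v''` (dorsal). Five
conditions close the problem: no slip at both walls, continuity of `v` and
`v'` at `y = h`, and zero net flux (the canal is closed, so a return flow
must exactly cancel the ciliary stream). The solver works with the linear
coefficients of the two parabolas and the pressure gradient as unknowns of
an explicit 3×3 linear system, valid for any `h ∈ (0, d)` (bounded away
from the degenerate limits by 1e-6·d); the classical integration constants
`y_A`, `y_B` are derived afterwards. For `h = d/2` the solution reduces to
`y_A = d/4`, `y_B = 3d/4`, `dP/dx = f_v/2`, and extremal velocities
`±f_v d²/(64 µ)`; these closed forms serve as regression oracles, not as
the implementation. Internally everything is SI; the CLI converts to µm/s.

## Numerical Stokes solver (`stokes`)

Structured forcing patterns (active spots of width `a` per period `w`,
per-spot amplitudes, constant or linear-in-`y` force shape) are solved with
a Fourier decomposition along the periodic `x` axis and second-order finite
differences across the canal. Each transverse mode of the streamfunction
satisfies the 1D biharmonic equation
`µ (D² − k²)² ψ_k = −∂f_k/∂y` with `ψ = ψ' = 0` on both walls; the mean
(`k = 0`) mode carries a free global pressure gradient fixed so that the
discrete (trapezoid) net flux vanishes — the same closure as the analytic
model, applied station by station. The force field is cell-averaged
(8× supersampling per cell) so the sharp layer and window edges are
represented to second order; with uniform forcing the discrete solution
coincides with the analytic biparabola to rounding because the FD operator
is exact on piecewise quadratics.

Defaults: 48 cells across `d`, 48 per period. The residual O(dy³) trapezoid
flux of the non-mean modes is projected out with a Poiseuille-shaped
correction (relative magnitude ~1e-6), preserving no-slip. Pressure is
reconstructed per mode from the axial momentum balance; the *mean* axial
slope is estimated by differencing the section-averaged pressure over one
full pattern cycle, which cancels the periodic component exactly (a plain
linear fit is biased by the intra-period sawtooth).

Vortices are reported as strict interior 8-connected extrema of the
streamfunction; a parallel flow (ψ constant along x) has none by
construction. "Vortex prominence" is the maximal x-fluctuating part of ψ
relative to the overall ψ scale, and "through-flow" is the largest |u| on
the mid-sections of passive gaps; both are our operationalizations — the
qualitative claims they quantify (vortices grow with `w/d`; gaps wider than
`d` carry no directed flow) are scale-free. With equal total force, a
linear-in-`y` force profile changes the velocity profile by ~30% in L2 but
preserves the bidirectional structure (a single interior sign change); the
package reports the computed difference rather than asserting a bound.

## Taylor–Aris transport (`transport`)

Particle concentration obeys `∂c/∂t + v(y) ∂c/∂x = D ∇²c` with no-flux
walls; `D` comes from Stokes–Einstein `D = k_B T/(6π r µ)` at T = 301 K
(28 °C rearing temperature). For any zero-flux profile the long-time axial
transport is diffusive with `D_eff = D (1 + C Pé²)`, `Pé = V d/D`, `V` the
profile maximum, and `C = ∫₀¹ G(ξ)² dξ`, `G(ξ) = ∫₀^ξ v(s d)/V ds`. The
implementation integrates the piecewise polynomials exactly; for the
symmetric biparabola `C = 13/315` (`1/C = 315/13 ≈ 24.23`, commonly quoted
rounded to 24).

The solver uses Strang splitting: advection plus axial diffusion are exact
per dorso-ventral row in Fourier space (`exp(−i k v(y) Δt − D k² Δt)`), and
spanwise diffusion is Crank–Nicolson on a cell-centered grid (mass exactly
conserved). All sub-steps are unconditionally stable; Δt defaults to
min(t_end/2000, 0.01 d²/D). Spectral advection can undershoot slightly below
zero near sharp features; undershoots (≲1e-12 of the peak for the default
smooth initial slug) are floored to zero each step, and the tracked mass
drift must stay below 0.1% or the run aborts. The initial condition is a
Gaussian slug (σ = d/2) uniform across the section; the periodic x domain is
sized so the boundary concentration stays below 1e-6 of the peak (checked).

`fit_effective_diffusivity` fits the axial-marginal variance versus time
over the asymptotic window `t ≥ 3 d²/D` (slope = 2 D_eff); at Pé = 5–20 the
fitted dispersion constant reproduces 315/13 within 0.2% at the default
resolution. `track_front` follows the furthest position where the marginal
exceeds 5% of its instantaneous peak — the threshold choice shifts the front
prefactor, not the t^0.5 exponent — and fits the log-log slope over at least
a decade. Propagation times over a distance L use the transparent
convention `t = L²/(4 D_eff)`.

## Kymograph velocimetry (`videoflow`)

The chain mirrors the experimental protocol: align the canal horizontally
(ventral at row 0), wavelet-denoise each frame, build one kymograph
(time × rostro-caudal position) per dorso-ventral row by averaging a moving
window of adjacent rows, normalize each column by its temporal mean
(bleaching/illumination correction), threshold, label connected regions,
and keep regions passing four filters: ≥ 15 pixels, eccentricity > 0.9, and
orientation not aligned with either axis (|cos θ|, |sin θ| ≥ 0.1 — rejecting
stuck beads and global flickers). Each surviving trace contributes a signed
velocity `v = tan θ · pixel / Δt` (caudal positive, calibrated against
planted slopes); per-row means ± SEM form the velocity profile. Counts are
trace events, not unique beads.

Numerical choices worth recording:

- **Threshold.** "Pixels above the average signal" is implemented as the
  kymograph mean plus a small robust margin (2× the MAD-estimated
  background scale). Without the margin, ~half of the near-flat normalized
  background exceeds the bare mean and percolates into sprawling regions
  that swallow the genuine traces; trace contrast is 30–60× the margin, so
  no real trace is affected.
- **Denoising.** Haar wavelets, 6 levels, soft thresholds, with
  subband-adaptive (BayesShrink) threshold selection via
  `skimage.restoration.denoise_wavelet`. A single universal threshold
  σ√(2 ln N) removes weak beads (peak SNR ~3) entirely — the opposite of
  the filter's purpose.
- **Row window.** Kymographs default to a 3-row moving average; the
  end-to-end analysis uses 5 rows. Brownian jitter of 20 nm beads moves a
  bead across rows between frames, and the wider window roughly halves the
  per-trace velocity noise without resolvable loss of profile structure
  (the window spans ~1 µm against a profile scale of d/4 ≈ 2.2 µm).
- **Landmarks.** Profile extrema and the zero crossing are located on a
  5-row moving average of the row means. The raw arg-max over ~50 noisy row
  means inflates |v_max| by 15–20% through selection bias; the smoothing
  flattens the true extremum by < 3%.
- **Boundary rule.** The canal extent is bounded by the most ventral row
  with ≥ 5 traces and mean v > +0.4 µm/s and the most dorsal row with ≥ 5
  traces and mean v < −0.4 µm/s — deliberately symmetric thresholds.
- **PTV.** Frame-to-frame linking minimizes total squared displacement via
  the Hungarian algorithm with a 5 px gating radius, bridges at most one
  missed frame, and keeps trajectories longer than 5 points. Detection runs
  on a lightly smoothed frame; subpixel centers come from local 2D Gaussian
  fits. Exact assignment replaces greedy heuristics and is testable against
  brute-force enumeration on two-bead scenes.
- **Diameter.** Maximum-intensity projection, Otsu threshold, largest
  region, width = extent along the minor principal axis (+1 px pixel
  footprint); widths below 4 px raise as unreliable.
- **Contractions.** Events are supra-threshold runs of the per-frame
  |ΔI| of the canal-mean transmitted intensity (default threshold 4,
  dimensionless); strength sums the supra-threshold values. Post-event flow
  integrals default to a 2.5 s window (5 s is equally defensible from the
  source protocol; both are exposed).

## Cilia frequency mapping (`ciliamap`)

A 4×4 spatial sliding average precedes a per-pixel temporal FFT
(rectangular window — spectral leakage is absorbed by the 5 Hz analysis
bands); the dominant non-DC peak above 2 Hz gives each pixel a frequency
and amplitude. Pixels whose peak amplitude is within 3 robust standard
deviations of the median peak amplitude are masked — with beating cilia
occupying a minority of the field, the median is the noise floor.
Constant-frequency regions are segmented per 5 Hz band (5–50 Hz,
8-connectivity, area ≥ 200 px) and fitted as ellipses: length L = major
axis, tilt Θ = signed angle to the dorso-ventral axis (positive = caudal),
beating height = L·|cos Θ|, side = centroid versus the canal midline.
A cilium whose per-pixel frequencies straddle a band edge is assigned
per-pixel and may split; the in-region frequency is summarized by the mean.
Cohort summaries report per-side medians with both the plain SD and the
half-SD convention. No frequency above Nyquist (frame rate/2) is ever
reported; at 100 Hz sampling a 60 Hz signal aliases to 40 Hz (tested).

## Synthetic data (`synth`)

The generators emulate the acquisitions the pipeline expects, with planted
ground truth and byte-for-byte reproducibility under a fixed seed:

- **Bead movies** (default 10 Hz, 30 s, 189 nm pixels, 8.9 µm canal,
  80 beads over a 48 µm segment): beads advect by `v(y) Δt` plus Gaussian
  Brownian steps `N(0, 2DΔt)` per axis, reflecting at the walls, periodic
  in x, rendered as Gaussian spots (σ = 1.2 px) over a constant background
  with Gaussian read noise (peak SNR ≈ 5, matching the low-signal regime of
  20 nm beads). The default bead diffusivity is 1.25 µm²/s, the *effective*
  value implied by the observed bead dynamics (instantaneous Brownian
  displacements of the same order as the flow displacement per frame);
  free-water Stokes–Einstein for these beads (~11–22 µm²/s) would carry a
  bead across the entire canal in seconds, leaving no row-resolved traces
  for any slope-based method — the hindered default is what makes the
  recorded kymographs (and their synthetic counterparts) analyzable. Pass
  `D_um2_s=None` to use Stokes–Einstein instead.
- **Cilia movies** (default 100 Hz, 3 s): each cilium is an elliptical
  footprint (major axis L along the tilt direction) whose intensity is
  modulated sinusoidally at the beat frequency. This models the periodic
  fluorescence signal a beating filament deposits over its swept area, not
  the moving filament shape itself; frequency, tilt, length, and side are
  exactly controlled, waveform details are not.
- **Canal phantoms**: tilted dye-filled bands of known width in a noisy
  z-stack. **Contraction series**: intensity ramps of prescribed per-frame
  derivative paired with a flow pulse followed by an exponential
  counter-flow of opposite sign (integral 60% of the pulse by default).
  **Front series**: transport-simulation marginals painted along a canal
  row at widefield resolution (1.5 µm pixels).

Passing tests on these generators shows the algorithms recover what was
planted under the stated noise models; they do not certify performance on
features the generators omit (tissue autofluorescence and motion, bead
aggregation and out-of-focus blur, cilium waveform dynamics, optical
sectioning).

## Problem sizes

Default test and acceptance runs use: Stokes grids of 48×(48–432) cells;
transport grids of 1024–2048 × 32–48 cells integrated to 12–30 spanwise
diffusion times (~2400–3000 splitting steps); one 300-frame 254×67 px bead
movie for end-to-end recovery; 300-frame cilia movies up to 540×96 px.
These sizes hold every tested tolerance with margin while keeping the full
suite in a few minutes on one CPU.

## Known limitations

- All flow models are 2D; the real canal is roughly cylindrical, so
  amplitudes map onto experiments through the fitted α rather than from
  first principles, and the dispersion constant of a cylindrical
  bidirectional flow would differ from 13/315.
- Cilia are a steady homogenized force: no beat-cycle time dependence, no
  metachronal coordination, no fluid–structure interaction.
- The kymograph method measures trace slopes, so velocities below
  ~0.2 µm/s (|sin θ| < 0.1) and above ~19 µm/s (|cos θ| < 0.1) are filtered
  out by design, and a bead wandering across rows can be counted several
  times.
- The dorsal landmark rule and the contraction-integration window follow
  one of two readings of an ambiguous protocol (symmetric ±0.4 µm/s; 2.5 s);
  both are parameters.
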