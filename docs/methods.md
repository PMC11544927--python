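# Methods

`ispt3d` implements three-dimensional single-particle tracking for wide-field
interferometric scattering (iSCAT) microscopy: a physical model of the
interferometric point-spread function (iPSF), a synthetic-video generator
that defines the package's study conditions, and the localization pipeline
that turns videos into nanometer-precision 3D trajectories over a
multi-micrometer axial range.

## The imaging model

A gold nanoparticle at height `z_p` above the coverslip scatters the
illumination; the scattered field interferes on the camera with the
reference field reflected at the water-glass interface,

    I_det = |E_ref|^2 + |E_sca|^2 + 2 |E_ref||E_sca| cos(phi),
    C     = (I_det - I_ref) / I_ref,

so frames are signed contrast images. The axial phase `phi` advances at
twice the medium wavenumber, which makes the contrast oscillate with the
carrier period `lambda / (2 n_m)` (193.6 nm at 515 nm in water) as the
particle moves axially — the central ambiguity the tracker must resolve.

`E_sca` is computed as a scalar angular-spectrum (pupil) integral over the
collection cone:

- solid-angle measure `sin(theta) d theta` expressed in the conserved
  transverse sine `s = n sin(theta)`;
- `sqrt(cos theta)` aplanatic apodization and s-polarization Fresnel
  transmission at the water-glass and glass-oil interfaces (the grazing
  divergence of the measure cancels against the transmission coefficient);
- propagation phase `k n_m z_p (1 + cos theta_m)` (illumination pass plus
  collection pass) and a defocus term referenced to the focal plane
  position `z_f` in sample coordinates;
- a Gibson-Lanni-type aberration phase from the mismatch between actual
  and design glass/oil parameters `(n_g, t_g, n_o, t_o)`, with piston and
  best-fit defocus projected out (amplitude-weighted least squares onto
  `{1, cos theta_m}`). The projection encodes that the focal plane is
  defined operationally — the user focuses the instrument — so only
  higher-order spherical aberration survives. That residual aberration is
  what breaks the mirror symmetry of the iPSF about `z_f` and lets the
  tracker distinguish above- from below-focus positions.

The scatterer amplitude is the Rayleigh prefactor
`s = k_m^3 (d/2)^3 (eps - eps_m)/(eps + 2 eps_m)` with gold's dielectric
function at 515 nm (`-3.95 + 2.58i`); the `d^3` scaling orders the tracking
range of 10-80 nm particles realistically. Optics losses beyond interface
transmission are not modeled, so absolute contrast is an upper bound; with
the defaults a 40 nm particle peaks near `|C| ~ 0.7` at focus and a few
percent several micrometers away.

Design choices deliberately out of scope: vectorial (Richards-Wolf)
polarization, Mie corrections for the largest particles, objective-specific
pupil masks. One known consequence of the scalar model: the stripe period of
the correlation map along `z_p` runs 2-4% above `lambda/(2 n_m)` because
ring structure maps to oblique rays whose axial phase advances at
`k n (1 + cos theta) < 2 k n`; the on-axis carrier itself is accurate to
better than 0.1%.

Pupil integration uses Gauss-Legendre quadrature with 256 nodes by default
(`OpticalConfig.n_pupil_samples`); halving or doubling the node count
changes profiles by less than 1e-9, so the default is comfortably converged.
Images are rendered by evaluating the field on a quarter-pixel radial grid
and interpolating onto the pixel raster, which enforces the exact circular
symmetry that circularly polarized illumination produces physically.

## Calibration

A measured focal stack (particle resting on the glass, focal plane scanned
over ~4 um) is compared against model stacks by a single global Pearson
correlation over all stack entries, and `(n_g, n_o, t_g)` are taken at the
grid argmax. The correlation surface shows the expected diagonal degeneracy
ridge in `(n_g, n_o)`: what matters most is the summed phase accumulated in
glass plus oil, so an index increase in one layer can be compensated in the
other. Per-plane normalization was the other plausible reading of the
stack-correlation figure of merit; the global form was chosen because it
also weights planes by their contrast content.

## Synthetic data: what it emulates and what it does not

The generator defines the package's reference study conditions:

- 40 nm gold particle in water, `D` from Stokes-Einstein at 297 K with
  viscosity 0.911 mPa s (water at 23.85 C) — 11.94 um^2/s; both
  temperature and viscosity are explicit inputs, and the hydrodynamic
  diameter is not assumed equal to the nominal diameter.
- 100 kHz frame rate, 128 x 128 px field covering 13 x 13 um
  (101.56 nm/px), focal plane 3.2 um above the interface.
- i.i.d. Gaussian steps of std `sqrt(2 D dt)` per axis (15.5 nm at 10 us
  for the 40 nm particle), reflecting boundary at the coverslip, optional
  reflecting lateral box. The generator warns when `sqrt(2 D dt)` exceeds
  an eighth of the carrier period, the regime where frame-to-frame stripe
  linking can fail.
- additive Gaussian noise of std `sigma_n = 1/sqrt(N_e)` on the normalized
  intensity, the Gaussian limit of Poisson counting at a 23,200-electron
  full well (`sigma_n = 6.56e-3`), applied after contrast formation.

Not emulated: motion blur within the exposure (positions are sampled
instantaneously; the blur scale is reported analytically instead), camera
read/fixed-pattern noise, background inhomogeneity, drift, and multiple
interacting particles (a second particle can be superposed linearly).
Passing tests therefore demonstrate the algorithm's behavior under
shot-noise-limited conditions, not robustness to every experimental
nuisance; on real data the measured error is expected to be dominated by
motion blur and residual background, as the MSD-intercept analysis shows.

## The localization pipeline

1. **Lateral:** radial variance transform (RVT) — annular means and
   variances over width-1 rings at radii 2-24 px, transform `Var_r(mean) -
   Mean_r(var)`, FFT ring convolutions with zero padding — peak refined by
   3x3 quadratic interpolation. Width-1 annuli matter: wider annuli mix the
   steep radial gradient of a near-focus iPSF into the azimuthal-variance
   term and flip the transform negative at the true center. Detection
   confidence is the ratio of the peak to the largest transform magnitude
   beyond `r_max` from it; a noise-only transform is weak and sign-mixed,
   so the ratio collapses toward or below zero without a particle (default
   floor 0.3). Within a few hundred nm of the focal plane the rings vanish
   entirely and the video localizer falls back to the smoothed |C| peak,
   which is sharp and bright exactly there. Gaps of up to 5 frames are
   bridged by linear center interpolation; longer gaps drop frames.
2. **Profiles:** azimuthal average about the sub-pixel center, 1 px annular
   bins out to 50 px by default; empty bins are interpolated, and rows are
   truncated to a common radial grid when a center sits near an edge.
   Both model rows and data rows are resampled from each bin's *mean pixel
   distance* onto the fixed bin-center grid: raw bin means are samples at
   center-dependent radii, and skipping this resampling leaves a
   systematic axial bias of several nm (tens of nm near focus) for
   sub-pixel centers.
3. **Correlation map:** Pearson correlation over radius between each frame
   profile and each model row (1 nm grid by default), computed as one
   standardized matrix product.
4. **Region selection:** threshold at zero, 8-connected labeling, score
   `S_j = sum_i max_z rho` per region, highest score wins (ties: larger
   pixel count, then smaller label).
5. **Branch graph:** the selected region is cut into sections of constant
   branch count (branches = contiguous z-runs per frame; sections also end
   where run pairing breaks); sections become parallel edges of a DAG with
   distance `b_m = sum_i (1 - max_z rho)`, nodes grouping 8-adjacent branch
   ends at the boundaries. Frames with no region pixels split the
   trajectory into independently solved segments.
6. **Debranching:** minimum-distance source-to-sink path by dynamic
   programming in topological order (Dijkstra-equivalent on this DAG, with
   all weights nonnegative by construction). Because every path covers
   every frame exactly once, the shortest path is exactly the maximizer of
   the summed per-frame correlation. Exact ties prefer the lower-z branch
   and are flagged.
7. **Refinement:** a polynomial fit to the winning branch's correlation
   within +-3 grid points of its peak; degree `min(4, n-1)` on grids of
   5 nm or finer, else `min(2, n-1)`; argmax constrained to the window.
   The narrow window was set with a dense-grid oracle: on asymmetric
   near-focus peaks, wide windows bias the quartic argmax by >1 nm,
   while +-3 points keeps the noiseless end-to-end error below the grid
   step everywhere. Flat windows return their center, flagged degenerate;
   single-point branches are returned unrefined.

## Numerical and tie-break conventions

- Lengths are nm and times s throughout; `z >= 0` from the water-glass
  interface, `z_f` signed in the same frame. Image coordinates are 0-based
  with the field center at `((W-1)/2, (H-1)/2)`.
- Model stacks default to a 1 nm axial step; ranges are set with margin
  beyond the expected excursion. Stacks are cached in memory by
  configuration hash and persist to NPZ archives.
- Pearson correlations of zero-variance rows are flagged, not NaN.
- All randomness flows through numpy Generators; a single seed is expanded
  into per-stage substreams so stages are independently reproducible.

## Error studies and their problem sizes

The studies mirror the robustness analyses a practitioner runs before
trusting the tracker, at desk scale:

- *Fixed-particle grid:* per `(z_f, z_p)` cell the noiseless frame is
  rendered once and independent noise realizations are localized against
  the stack; the cell reports the std of retrieved-minus-true heights
  (bias, typically well below the std, is reported separately). Default
  grid 5 focal planes x 8 heights x 100 realizations with a 60 px profile
  radius for the laterally fixed geometry.
- *Noise-level sweep:* axial (correlation) and lateral (RVT) errors at
  sigma_n from 1e-3 to 1.2e-2, averaged over an 8 um height range; axial
  precision beats lateral at every level, consistent with the phase
  information carried along z.
- *Lateral-offset sweep:* noiseless profiles extracted about deliberately
  displaced centers (0-150 nm); the mean absolute axial error grows
  monotonically and stays below 5 nm at 150 nm offset, i.e. the radial
  profile is forgiving of lateral localization error near the diffraction
  limit.
- *End-to-end tracking:* 3 independent 2,048-frame Brownian videos through
  the full pipeline (RVT centers, not ground truth), axial error std
  ~1 nm at the reference conditions.

## Known limitations

- The scalar model's stripe period deviates from the ideal carrier by a
  few percent at large defocus (see above); tracking is unaffected because
  experiment and model are compared through the same machinery, but the
  model should not be used as a metrology-grade phase reference.
- Absolute contrast assumes lossless optics; only relative/correlation
  quantities are calibration-free.
- The branch-pairing heuristic inside a section assumes non-crossing
  interval continuations (valid for 8-connected runs on a fine grid).
- Side discrimination at focus crossings needs the outer defocus rings:
  with the radial profile truncated below ~45 px the spherical-aberration
  asymmetry that separates above- from below-focus responses is weakened
  enough that a 150 nm lateral-center offset can steer the debranched path
  onto the mirror side. The default 50 px extent (and the 60 px extent of
  the fixed-particle study geometry) keeps the discrimination reliable.
- Segments split by empty frames are refined independently; no global
  stitching across segments is attempted.
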