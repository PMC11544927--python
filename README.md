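# ispt3d

Three-dimensional single-particle tracking for interferometric scattering
(iSCAT) microscopy.

iSCAT images a nanoparticle through the interference of its scattered field
with a reference reflection from the coverslip, so each frame is a signed
contrast pattern `C = (I_det - I_ref)/I_ref` whose ring structure encodes
the particle's height. The axial phase advances with period
`lambda/(2 n_m)` (~194 nm for 515 nm light in water), which makes
frame-by-frame height assignment ambiguous: stripes of near-identical
response repeat along `z` and mirror about the focal plane. `ispt3d`
resolves the ambiguity globally. It models the interferometric point-spread
function (iPSF) through the stratified water/glass/oil system, correlates
each frame's azimuthally averaged radial profile `RP_e(i, r)` against a
model stack `RP_m(z_p, r)` to build a correlation map `rho(i, z_p)`,
selects the connected suprathreshold region with the highest summed
per-frame maximum correlation, converts its branch structure into a
directed acyclic graph with edge distances

    b_m = sum_i (1 - max_z rho(i, z)),

takes the minimum-distance source-to-sink path (Dijkstra on the DAG — the
path that maximizes the total correlation along the video), and refines
each frame's height below the model's 1 nm grid with a local polynomial
fit. Lateral positions come from the radial variance transform (RVT).

The package contains, as first-class tested code, a synthetic-data
generator reproducing the reference study conditions: 10-80 nm gold
particles diffusing in water (Stokes-Einstein `D = k_B T/(3 pi eta d)`),
70-200 kHz frame rates on a 128 px / 13 um field, and camera shot noise
`sigma_n = 1/sqrt(N_e)` from the electron full well (6.56e-3 at 23,200
electrons). It is intended for microscopists developing or validating
iSCAT 3D tracking pipelines and for method studies of axial localization
precision.

## Worked example

Simulate a 40 nm particle for 2,000 frames at 100 kHz, track it, and
compare with the ground truth (about two minutes on one core; the model
stack is built once and cached next to the tracking output):

```bash
cat > run.yaml <<'EOF'
camera:
  frame_rate: 100000.0
  exposure: 1.0e-5
tracking:
  z_min: 0.0
  z_max_um: 6.0
  z_step: 1.0
EOF

ispt3d simulate --config run.yaml --seed 7 --out sim --n-frames 2000
ispt3d track    --config run.yaml --video sim/video.tif --out trk
ispt3d analyze  --trajectory trk/trajectory.csv \
                --reference sim/ground_truth.csv --out ana
```

The simulate step logs the physical scales it uses:

```
simulated 2000 frames, D=11.94 um^2/s, sigma_n=6.565e-03
```

(11.94 um^2/s is Stokes-Einstein for a 40 nm sphere in water at 297 K;
6.565e-3 is the normalized shot-noise std of a full 23,200-electron well.)
The track step reports coverage, and analyze prints the diffusion fit and
the per-axis error table against the ground truth, e.g.

```
tracked 100.0% of frames; wrote trk
D = 12.068 um^2/s, MSD intercept = 4.444e-05 um^2
step std per axis (nm): [16.07 15.63 15.63]
axial error std = 0.345 nm
```

— the recovered diffusion coefficient sits within the sampling scatter of
the input 11.94 um^2/s, the per-axis step standard deviations match the
15.5 nm Brownian prediction, and the axial localization error of the full
pipeline (RVT centers, correlation map, graph debranching, polynomial
refinement) is sub-nanometer here. Trajectories that wander close to the
focal plane, where the iPSF loses its radial features, track with a
nanometer-scale error instead.

`ispt3d study` runs the robustness sweeps (axial error versus focal plane
and height under shot noise); `ispt3d calibrate` fits the glass/oil
parameters of the iPSF model to a measured focal stack. See
`docs/methods.md` for the model, the algorithm, and the package's
conventions.

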