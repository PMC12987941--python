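# Methods

This note documents the models, numerics and design choices behind
`hemograph`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the shipped tests do and do not demonstrate.

## Problem setting

Transient, incompressible blood flow through an intracranial-aneurysm
geometry is governed by the Navier–Stokes equations

    rho (du/dt + u . grad u) = -grad p + div(2 mu eps(u)),    div u = 0,

with density rho = 1060 kg/m^3, dynamic viscosity mu = 3.5 mPa s (a
Carreau–Yasuda shear-thinning law is available; the constant-viscosity mode
is the default for losses and wall-shear-stress postprocessing), rigid
no-slip walls, a pulsatile parabolic inflow over a 0.8 s cardiac cycle, and
a resistive outlet in the originating CFD setting (not emulated here — it
only matters to a full pressure solve).

The package does not solve these equations.  It implements a *surrogate*:
a graph neural network that advances the nodal velocity field one timestep
at a time on an unstructured tetrahedral mesh, trained on precomputed flow
trajectories, plus the discrete operators, boundary handling, training
losses, rollout machinery and clinical postprocessing (WSS/TAWSS/SAWSS,
cross-sectional mass flux) that surround it.

Units are fixed package-wide: mm, mm/s, s, Pa, Pa s.  Velocity gradients
then come out in 1/s and WSS in Pa with no conversion factors; volumetric
flow is reported in mL/s (1000 mm^3/s).

## Surrogate architecture

The mesh is treated as a graph: nodes are mesh vertices, relations are
mesh edges (each undirected edge stored in both directions).  The model is
an encode-process-decode graph network:

- **Encoders**: one MLP for node features, one for edge features, mapping
  into a shared latent width (default 128).
- **Processor**: L graph-network blocks (default 15).  Each block updates
  every directed edge from its latent and the two incident node latents
  (phi_E), sum-aggregates updated edges at their receiver, and updates
  every node from its latent and the aggregate (phi_V).  Blocks have their
  own parameters; node and edge latents carry residual connections.
- **Decoder**: an MLP from the final node latent to a 3-component velocity
  update, added to the input state (residual next-step prediction).

All MLPs have two ReLU hidden layers at the latent width, with layer
normalization after every MLP except the decoder.  Aggregation is an
elementwise sum.  No global graph attributes are used.

Node features (baseline, 11): velocity (3), position (3), timestamp within
the cardiac cycle in seconds (1), node type one-hot in the fixed order
[inlet, wall, interior, outlet] (4).  The enhanced "in" set (17) adds the
backward-difference acceleration u_t − u_{t−1} (3) and the inflow context
(3): mean, minimum and maximum inlet speed at the *target* time t+1,
broadcast to every node.  The context is legitimate information, not
leakage: the inlet boundary condition is prescribed and known ahead of
time.  (Of the two possible readings of the acceleration feature, the
backward difference is implemented; the forward difference would contain
the prediction target.)

Edge features (4): receiver-minus-sender coordinates and their Euclidean
distance.

The deep-learning substrate is a small reverse-mode automatic
differentiation engine over numpy/scipy (`hemograph.autodiff`): dense
affine maps, ReLU, layer normalization, concatenation, gather/segment-sum,
fixed sparse-matrix products and scalar reductions, with an Adam optimizer
and global gradient-norm clipping.  Message passing is expressed with
sparse incidence matrices, so both directions of every operation are exact
sparse/dense products.  Gradients of the full training loss agree with
central finite differences to ~1e-6 relative (checked in development; the
test suite re-checks the structural consequences, e.g. exactly-zero
gradients at masked nodes).

## Boundary handling

Wall nodes are overwritten with zero velocity and inlet nodes with the
prescribed parabolic profile after every prediction, at training and at
rollout time.  The loss is computed only on interior and outlet nodes, and
the exclusion is structural: excluded rows enter the loss as constants, so
the gradient of any loss term with respect to the network output at those
rows is exactly zero, not merely small.

## Normalization

Input and output statistics are accumulated over the first epoch's sample
order and then frozen (a dedicated pass before the first optimizer step,
which makes runs deterministic and independent of early parameter noise).
Components of a physical vector — velocity, acceleration, the relative
edge coordinate, the predicted update — share one pooled standard
deviation.  Per-component scales would be degenerate for flows aligned
with a coordinate axis (a straight-tube flow has identically zero
transverse velocity), and any injected noise divided by such a floor-level
scale would dominate every genuine feature.

The data term of the loss is optimized on the normalized output scale,
which keeps gradient norms of order one so that gradient clipping (norm
1.0) acts as a mild stabilizer rather than a per-sample gradient
equalizer; loss histories additionally record the physical-unit value.

## Training noise

During one-step training, zero-mean Gaussian noise with per-component
standard deviation eta * sigma_v (sigma_v = pooled training-set velocity
std) is added to the dynamical input features only (velocity and, when
present, acceleration).  The target is the clean next-step state, so the
model learns to contract perturbations back toward the solution manifold —
the standard defense against compounding error in autoregressive rollout.
Inference adds no noise.

## Physics-informed loss

Discrete differential operators are built from mesh-edge neighborhoods
N_i.  The gradient estimator is the averaged rank-one form

    grad(u)_i = (1/|N_i|) sum_{j in N_i} (u_j − u_i)(x_j − x_i)^T / ||x_j − x_i||^2,

the divergence is its contraction, and the vector Laplacian applies the
same estimator to each nodal gradient component and takes the trace (the
unique contraction of the estimator-of-gradients form under which
constant-gradient fields map to zero).  These operators are implemented
*exactly in this form*, because the training losses must match it; a
least-squares gradient is available behind a flag for comparison only.

Two properties of the estimator matter for interpretation:

- It annihilates constants exactly and is translation invariant; rigid
  rotations are exactly divergence-free under it.
- It is **not** a consistent discretization: its h → 0 limit is
  ⟨grad u, M_i⟩ with M_i the second-moment matrix of neighbor directions,
  not the true derivative.  On a uniform 6-axis stencil the divergence of
  u = (x, y, z) evaluates to 1 rather than 3, and for curved profiles the
  residual is an h-independent stencil-anisotropy term (measured at ~5 %
  of u_max/R on the tube meshes, essentially unchanged from h = 0.6 mm to
  0.3 mm).  This is acceptable for its role — a relative regularization
  signal inside a loss — and the tests therefore check exact identities
  (div = trace grad, zero on constants and rigid rotations, agreement with
  a naive-loop oracle) and bounded residuals, not mesh convergence.

The loss terms, all through these operators, are

    L_continuity = mean_v | div(u~)_v |
    L_convection = mean_v || rho (u . grad)u − rho (u~ . grad)u~ ||^2
    L_viscous    = mean_v || mu lap(u) − mu lap(u~) ||^2

evaluated on the predicted field after boundary enforcement, with the
ground-truth convective and viscous terms precomputed per sample.  The
combined objective is

    L = w_d L_data + ((1 − w_d)/3) (alpha L_cont + beta L_conv + gamma L_visc),

w_d = 0.5 by default.  The scale factors are calibrated once: over the
first calibration window (200 steps, or two epochs for tiny runs) the
model trains on the data term alone while the physics terms are recorded;
alpha is then frozen at mean(L_data)/mean(L_continuity) (beta, gamma
analogously, capped at 1e8 with a warning if a term vanishes), so each
physics term enters at the data-term scale.

## Optimization

Adam (default settings), batch of one graph per step, one optimization
step per (trajectory, t) sample, seeded shuffling.  The reference schedule
holds 1e-4 for 16 epochs and decays exponentially per step to 1e-7 across
4 more; small runs may use a constant rate instead.  Gradient norms are
clipped at 1.0.  Training aborts with diagnostics on a non-finite loss.
Checkpoints are single `.npz` files embedding weights, configuration and
normalization statistics.

## Synthetic study conditions

The generators reproduce the benchmark conditions so the full pipeline
runs without any download:

- **Inflow**: Q(t) in mL/s with a 0.8 s period, a 0.2 s linear ramp from
  zero, and a systolic peak of exactly 6 mL/s near 15 % of the cycle,
  built from three cosine harmonics (amplitudes 0.52/0.20/0.10).  The peak
  value is normalized analytically; Q stays strictly positive (diastolic
  minimum ~1.9 mL/s, a realistic ICA diastolic-to-systolic ratio).
- **Inlet profile**: fully developed parabola u(r) = u_max (1 − r²/R²),
  u_max = 2Q/(pi R²), along the inward inlet normal; at Q = 6 mL/s and
  R = 2 mm, u_max = 954.93 mm/s (peak Reynolds number ≈ 400 with the
  default fluid).
- **Geometry**: structured tetrahedral meshing (triangulated disc extruded
  into prisms, each split into three tets by an index-ordered diagonal
  rule, hence conforming by construction).  The semi-idealized aneurysm
  bends the straight tube into a half torus (major radius 10 mm, vessel
  diameter 4 mm) and inflates the wall radially around the mid-arc toward
  +y with a Gaussian bump whose apex sits one bulge-diameter above the
  centerline; bulge diameters span 3–9 mm (default 7 mm, which places the
  apex above the standard y = 8.5 mm bulge plane).  The radial-inflation
  map is orientation-preserving, so cells stay valid; generated meshes are
  verified watertight-classified with positive volumes.  This parametric
  sac family stands in for patient-derived bulges; real geometries enter
  through the trajectory readers.
- **Flow**: analytic trajectories — quasi-steady Poiseuille (the inlet
  parabola scaled by Q(t) along the tube; divergence-free, no-slip),
  rigid rotation (u = omega × x), and linear fields (u = Ax) — sampled at
  a uniform dt (80 frames per cycle at the reference 0.01 s step).

What the generators do **not** emulate: secondary/dicrotic waveform
features beyond three harmonics, Womersley (non-parabolic) inlet profiles,
flow separation and intra-sac vortices, pressure fields, and the resistive
outlet.  Passing the shipped tests therefore demonstrates that the
pipeline's machinery (operators, losses, training dynamics, boundary
enforcement, rollout bookkeeping, postprocessing) is correct and that the
surrogate can learn smooth pulsatile dynamics at desk scale — not that a
full-scale model trained on real CFD trajectories reaches any particular
accuracy on real aneurysm flows.

## The desk-scale benchmark harness

`hemograph.harness` trains the narrow reference configuration (width 32,
4 rounds, enhanced features) on a straight tube of ~2.3k nodes with a
10-frame, one-full-cycle trajectory (dt = 0.08 s) and rolls it out for 50
steps against the periodic extension of the same analytic flow.  Sampling
the whole cycle with the 10 frames keeps every rollout step in
distribution (timestamp and inflow context are cycle-periodic); a 10-frame
window at the 0.01 s reference step was rejected because a 50-step rollout
would leave the training window after 9 steps and the remaining 41 steps
would probe extrapolation, which is not what a convergence harness should
measure.

The harness trains for a fixed 2000 steps (learning rate 1e-3, per-step
exponential decay to 1e-5 over the last 40 %) with an annealed noise
curriculum, eta from 0.4 down to 0.15 of the velocity std.  Two
observations force the curriculum at this scale.  First, a model trained
at a small noise scale fits the one-step task almost immediately (under
1 % of the peak inlet velocity within tens of steps) but diverges in
rollout: the autoregressive state drifts by tens of mm/s per cycle, far
outside the trained perturbation range, and the systolic steps amplify
the drift.  Second, a single large noise scale contracts the drift but
leaves a noise-induced floor in the noise-free next-step error.
Matching the noise to the rollout-perturbation scale early and annealing
it away late gives both: with the shipped configuration and seed, the
masked one-step RMSE is 0.65 % of the peak inlet velocity and the
50-step rollout RMSE 4.1 %.  The full-scale ModelConfig default stays at
eta = 0.02, appropriate when thousands of diverse training samples
regularize the map on their own.

Problem sizes were chosen so the whole harness (training plus rollout)
runs in minutes on one CPU; the physics-informed comparison run uses a
400-step budget, at which both variants have long since passed their
steep initial descent.

## Evaluation

1-RMSE is the root mean (over nodes) squared vector error of a single
next-step prediction; T-RMSE averages the per-step RMSE over T rollout
steps seeded only from the initial state.  Errors are reported in mm/s
(absolute, not normalized), with normalized per-node error fields
available as percent of the frame's maximum ground-truth speed.  Regional
errors split nodes at two planes normal to the bulge axis (defaults
y = 8.5 mm and y = 7 mm; bulge above, neck between, parent artery below,
ties assigned upward).  Probe series interpolate velocity
barycentrically at fixed points.

## Hemodynamic postprocessing

WSS is the tangential wall traction tau = sigma·n − ((sigma·n)·n)n with
sigma = −pI + mu(grad u + grad uᵀ); the pressure part is normal and drops
out of tau, so WSS is computed from the viscous stress alone (verified
against an oracle with explicit pressure).  TAWSS averages |tau| over a
window of frames (the full cycle by default); SAWSS averages |tau| over a
wall region with node weights of one third of the incident
boundary-triangle areas (area weighting, since plain node averaging would
bias toward refined patches).  Mass flux integrates u·n over the
marching-tetrahedra plane section by linear (exact-for-linear-fields)
quadrature; the conservation report tracks |Q_in − Q_out|/|Q_in| per
frame, skipping frames with inlet flow below 1 % of the cycle peak to
avoid near-zero division, and summarizes mean and max over the cycle.

## Numerical choices and degenerate inputs

- Mesh orientation is normalized on load (negative tets swapped); zero
  -volume cells are structural errors, as are zero-length edges and
  zero-area boundary faces (which make outward orientation ambiguous).
- Interpolation locates points via a centroid KD-tree with barycentric
  acceptance at 1e-6 mm; points outside fall back to nearest-element
  projection and are counted in a report.  Plane slicing nudges nodes
  lying exactly on the cutting plane by 1e-12 of the coordinate span to
  avoid degenerate polygons.
- Boundary nodes use the same operator formulas with whatever neighbors
  exist; nodes with fewer than 3 neighbors trigger a warning.
- Inlet discs must be planar within 1e-6 mm; the disc radius is taken
  from the farthest inlet node, so rim nodes receive exactly zero
  prescribed velocity.
- Waveform parameters must keep the harmonic amplitude sum below 1, which
  guarantees Q > 0 after the ramp.

## Known limitations

- The neighborhood operators are inconsistent estimators (see above);
  WSS from coarse-mesh nodal gradients inherits a mesh-dependent bias.
  Ground truth and prediction are post-processed with the same operators,
  so comparisons within the framework are fair.
- The autodiff engine is single-threaded numpy; the reference
  configuration (~2.3 M parameters by the closed-form count) runs forward
  on a 20k-node graph in seconds, but full-scale training is out of desk
  scope by design.
- The synthetic sac family is smooth and symmetric; it does not cover
  patient-specific neck morphology, and the fixed region planes only
  isolate a meaningful bulge region for sacs large enough to cross them.
- Trained-model quality is assessed on the synthetic conditions only; no
  claim is made about transfer to real CFD trajectories without
  retraining.
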