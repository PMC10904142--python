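# Methods

## The model

`gcpnet` implements a graph neural network for 3D point clouds (molecules,
charged particles) whose scalar outputs are invariant under rigid motions of
the input — rotations and translations, the group SE(3) — but *not* under
reflections, while its vector-valued outputs and updated coordinates
transform together with the input frame.  Reflection sensitivity is the
property that lets the scalar channels distinguish a chiral molecule from
its enantiomer, something any E(3)-invariant architecture is provably unable
to do.

### Edge frames and scalarization

The input cloud becomes a directed k-nearest-neighbor graph (ties broken
toward the lower node index, distances compared in double precision, so the
topology is bit-reproducible).  After subtracting the center of mass, each
directed edge (i, j) receives a local orthonormal frame

    a_ij = (x_i − x_j) / ‖x_i − x_j‖
    b_ij = (x_i × x_j) / ‖x_i × x_j‖
    c_ij = a_ij × b_ij

All three axes rotate with the cloud; under point inversion they pick up the
sign pattern (−, +, −).  Projecting equivariant feature vectors onto the
axes ("scalarization") therefore produces rotation-invariant numbers that
change under reflection — the chirality carrier.  The b axis depends on the
absolute (centered) endpoint positions, not only on their difference, which
is why centering comes first and why the frame spans a full basis for
generic geometry.

Degenerate edges — centered endpoints collinear with the origin, so
x_i × x_j ≈ 0 — get b = c = 0 rather than an arbitrary axis: a zero
contribution is symmetry-safe, and the configuration has measure zero in
generic data (the audit over 1000 Gaussian edges measures a degeneracy rate
of exactly 0).  All divisions are guarded as √(‖·‖² + ε²) with ε = 1e-8,
which perturbs non-degenerate values by less than 1e-8 relative error and
keeps gradients finite.

### The geometry-complete perceptron (GCP)

Every node and edge carries a tuple (s, V): t invariant scalar channels and
r equivariant 3-vector channels.  One GCP application maps (s, V) → (s′, V′):

1. z = V·w_dz — downscale vector channels to max(1, ⌈r/λ⌉), λ = 3 by default;
2. V_s = V·w_ds — three probe vectors per entity;
3. q = ⟨V_s, (a, b, c)⟩ ∈ R⁹ — frame projections, flattened channel-major
   with axis order (a, b, c); node entities average q over their out-edges,
   and a node with no out-edges gets q = 0;
4. s′ = σ_s(sv), sv = [s ∥ q ∥ ‖z‖₂]·w_s + b_s;
5. V′ = (z·w_uz) ⊙ σ_g(σ₊(sv)·w_g + b_g), the gate applied per channel so
   the three Cartesian components are scaled together.

Every map on vector channels acts on the channel axis only and never mixes
Cartesian components; that is the entire equivariance argument, and it is
verified numerically rather than assumed (audits drive deviations below
1e-10 in double precision).  σ_s = σ₊ = SiLU and σ_g = sigmoid: smooth
invariant activations and a (0, 1) gate.  Weights use fan-in uniform
initialization; gate offsets start at zero.

`use_frames=False` replaces q with a 9-wide zero block, which removes the
only reflection-odd input and makes the whole network E(3)-invariant — the
"frame-less" ablation used as a negative control.

### Message passing and position updates

A network forward pass is: center → build frames once → embed raw node and
edge features with one GCP each → L rounds of convolution → optional
re-localization → final GCP projection.  One convolution round computes a
message per directed edge from the concatenation (receiver ∥ sender ∥ edge)
on both channels, passes it through a stack of ω GCPs (one projecting GCP
followed by ω − 1 residual GCPs; a residual block needs equal input/output
widths, so the first block in the stack cannot itself be residual), mean-
aggregates messages at the receiving node, and applies a residual node
update.  Edge features are embedded once and reused by every layer.

When position updates are enabled, each layer also runs a single-vector-
channel GCP whose output is added to the coordinates.  After the last layer
the frames are rebuilt from the final coordinates and the original center
of mass is added back, which makes the output positions translation-
equivariant.  With updates disabled the network returns the input
coordinate array itself, bitwise.

Frames are treated as constants on the gradient tape (stop-gradient), both
at the input and when rebuilt from updated coordinates: gradients reach the
coordinates through the residual update path, and not differentiating
through the cross products keeps the autodiff vocabulary small.  This is a
deliberate design choice; it does not affect any symmetry property.

## Automatic differentiation

The environment provides no autodiff library, so the package carries a
small tape-based reverse-mode engine (`gcpnet.autodiff`) covering exactly
the operation vocabulary the network needs: affine maps, channel-wise
linear maps on vector stacks, concatenation, gather/segment-mean, guarded
norms, SiLU/sigmoid, softmax cross-entropy and MSE.  Every operation's
gradient is tested against central finite differences.  All computation is
double precision, single-threaded; fixed seeds reproduce runs bitwise.

## Synthetic tasks

### R/S chirality recognition

Each "molecule" is a central atom and four substituents near the vertices
of a randomly rotated tetrahedron (bond lengths uniform in 1.2–1.8 length
units, Gaussian coordinate noise σ = 0.05).  Substituents carry distinct
priority labels 1–4, encoded as atom types.  The label is the handedness of
the priority-ordered substituents: the sign of det[v₁−v₄, v₂−v₄, v₃−v₄]
(positive → R).  Draws whose signed volume falls below 1e−6, or where noise
flips the label relative to the clean geometry, are resampled, so the label
margin is never crossed by noise.  Every molecule is emitted with its mirror
image under the opposite label; the dataset is therefore exactly balanced,
and because a reflection-blind model produces identical predictions for the
two members of a pair, its accuracy on any pair-complete evaluation set is
exactly 50% — the chance floor the frame-less ablation must sit on.

Mirror pairs always share a split; splitting is by pair, 70/15/15.

The "sequence" that defines the orientation vectors is the priority order:
center first, then substituents from highest to lowest priority.  This is
the natural reading of sequence-based orientation features for a
stereocenter — handedness is defined with respect to the priority ordering
— and it puts the parity signal where the frame projections can reach it.
It gives the reflection-blind control no advantage whatsoever: reflection
flips every orientation vector, so an E(3)-invariant model still cannot
separate a mirror pair no matter how the nodes are ordered.

What the generator does *not* emulate: real covalent chemistry (bond
perception, hybridization, conformer ensembles).  Passing this task shows
the architecture can extract handedness from geometry, not that it ranks
real stereocenters.

### Newtonian many-body forecasting

Unit-mass particles with balanced charges ±1 interact through a softened
Coulomb force q_i q_j (x_i−x_j)/(‖x_i−x_j‖² + ε²)^{3/2}, ε = 0.1,
optionally composed with uniform gravity (0, 0, −g₀), g₀ = 0.2, or a
Lorentz-like force q(v × B), B = (0, 0, B₀), B₀ = 1.  Initial positions and
velocities are Gaussian (σ = 1.0 and 0.5).  Integration is velocity-Verlet
with dt = 1e−2 over 1200 steps; the velocity-dependent Lorentz force gets
one fixed-point refinement of the half-step.  Being symplectic, the
integrator conserves total momentum of the pure electrostatic system to
round-off (measured drift < 1e−10 over 1200 steps) and its energy drift
shrinks as dt decreases; a single charge in the magnetic field reproduces
the analytic cyclotron radius ‖v⊥‖/(|q|B₀) to well under 1% at dt = 1e−3.

The forecasting task pairs the full state at time t_in (positions,
velocities, charges) with the positions 1000 integrator steps later, five
offsets t_in ∈ {0, 50, 100, 150, 200} per trajectory, split by trajectory
70/15/15.  Two baselines calibrate the difficulty: "static" (positions
frozen) and "free flight" (x + v·horizon·dt).  The free-flight baseline is
exactly representable by the network's position-update path (velocity is a
vector channel), so a trained model should never do worse than it.

These constants emulate the *kind* of physics the benchmark family uses;
they are not a byte-level replica of any published dataset, and the
absolute MSE values depend on them.  Only the ordering
model < free flight < static is a portable claim.

## Training protocol

Adam with batch 32, early stopping on the validation metric, best
validation checkpoint restored after fitting.  Chirality uses lr 2e−3 for
up to 40 epochs with patience 15; forecasting uses lr 5e−3 for up to 80
epochs with patience 15.  Learning rates were set to reach convergence
within desk-scale epoch budgets on a single CPU; every knob is exposed in
`fit()`.

The chirality loss surface has a near-chance plateau that a minority of
random initializations never leave, while successful runs break through
within a handful of epochs.  `ChiralityClassifier.fit` therefore trains
with restart-on-plateau: an attempt whose best validation accuracy is still
below 0.7 after 12 epochs is abandoned and re-initialized from the next
derived seed (at most 5 restarts).  All randomness flows from the single
`seed` argument, so fits reproduce bitwise.  Problem sizes follow the study
design: 2000 molecules (1000 mirror pairs) for chirality, 200 five-body
electrostatic trajectories for forecasting; each fit completes in about a
minute on one CPU.

The "w/o scalars" ablation keeps a single constant scalar channel so the
architecture stays well-formed (the scalar pathway feeds the vector gate);
"w/o vectors" removes all vector channels and is unavailable for
forecasting, where the vector path *is* the predictor.

## Numerical choices and limitations

- Double precision everywhere; audit tolerances are 1e−10 for equivariance
  and self-consistency, 1e−6 for frame orthonormality.
- k-NN ties: lower node index wins (stable sort); duplicate coordinates are
  legal neighbors at distance 0.
- Mean aggregation over empty neighborhoods is defined as zero.
- The final projection uses the refreshed frames when positions were
  updated and the (unchanged) input frames otherwise.
- No dropout or normalization layers in the reference configuration, so the
  property audits are exact.
- Known limitations: brute-force O(N²) neighbor search (fine for desk-scale
  N, no cell lists), no periodic boundary conditions, no batching across
  threads, and no attempt to reproduce external-benchmark numbers
  (protein–ligand affinity, structure ranking), which require external
  datasets and GPU-scale training.
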