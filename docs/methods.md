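# Methods

This note records the models, conventions and numerical choices behind
`ampaflex`, and what the synthetic benchmarks do and do not demonstrate.

## Coordinate conventions

All coordinates are in Å in a right-handed frame; z is the vertical axis
and, by convention, the global two-fold symmetry axis of a receptor that
has been superposed into the common frame. Residue numbering follows input
files verbatim. Alternate locations are resolved by keeping the first
altloc in identifier order (deterministic; one logged warning per affected
residue). Superposition is least-squares rigid-body (Kabsch via SVD) with
the sign correction that forbids reflections; the returned RMSD is over
the fit selection only, and the whole mobile model is transformed.

## Tilt/splay angles

Principal axes are the eigenvectors of the equal-weight positional
covariance of Cα atoms about their centre of mass — not a mass-weighted
inertia tensor. The two coincide only for uniform masses, which holds for
Cα-only selections; the equal-weight form is used because every analysis
in this package operates on Cα ensembles.

The splay angle of an NTD dimer is the angle between the dimer's second
principal axis (which runs along the dimer's local two-fold axis: the
dimer is wider across its two protomers than it is tall) and the reference
receptor's first principal axis (its long, vertical axis). Eigenvectors
carry an arbitrary sign, so both axes are canonically oriented before the
angle is taken:

- the reference axis r̂ is oriented towards a `reference_top` point
  (default: one Å above the reference COM along +z, i.e. the NTD end);
- the dimer axis is oriented "outward/up": positive dot product with the
  vector from the whole-receptor COM to the dimer COM.

The reported angle is always measured from the outward-oriented dimer
axis. When the lexicographically sign-canonicalized eigenvector pointed
the other way (down towards the LBD), the raw arccos value was thereby
replaced with its 180° complement and the result is flagged `corrected`.
This convention keeps the full [0°, 180°] range — a dimer bent past
horizontal reports >90° rather than being folded back — and recovers
planted rigid rotations exactly over (0°, 180°). The choice of which dimer
is "a" and which is "b" is configuration-driven (sorted selection names),
since it is not derivable from geometry.

Angles are evaluated as 2·atan2(‖û−v̂‖, ‖û+v̂‖), which equals the arccos of
the clamped dot product but is numerically stable near 0° and 180°
(plain arccos loses ~1e-6° at identity from double rounding).

## Ensemble PCA and morphs

PCA operates on the 3N-vector of Cα coordinates per frame. By default no
superposition is applied first, so rigid rearrangements of the NTD layer
relative to the rest of the receptor appear as modes; with
`superpose_first` each frame is iteratively Kabsch-fitted to the evolving
mean (≤ 10 iterations or mean shift < 1e-6 Å). The covariance is
normalized by the number of frames M (population convention). This
convention is pinned by the two-frame identity: frames x and x + d
mean-centre to ±d/2 and give a single mode d/|d| with eigenvalue |d|²/4.
Eigen-pairs come from an SVD of the centred data matrix; degenerate or
sign-ambiguous eigenvectors are fixed deterministically (descending
eigenvalue, then first nonzero component positive).

Two amplitude conventions are supported for animating a mode, because both
are in practical use: a target RMSD (displacement = rmsd·√N·v̂, used e.g.
to scale a dominant mode to 20.0 Å), and a bare scale factor, declared
here to mean the variance-weighted form c·√λ·v̂ (achieved RMSD c·√(λ/N)).
For a unit 3N-vector, RMSD = |scale|/√N exactly.

Morph trajectories are closed cycles mean → +max → −max → mean over
n_frames (default 20). The schedule is cosine-eased in three segments with
the two extremes placed exactly on grid indices (≈ quarter points), so the
extreme frames achieve the requested amplitude exactly rather than to
sampling error; first and last frames equal the mean. A plain sinusoid on
20 frames would miss the extremes by ~0.3 %.

## LBD rotation angles

Each chain's rotation axis is vertical (parallel to z) and passes through
the pooled centre of mass of its anchor residue (K501 in GluA1, K505 in
GluA2 — the stable residue at the start of the S1–M1 linker). Pooled
("combined") COMs average per-structure COMs with equal weight per
structure, so models with different atom counts in a selection contribute
equally; the reference structure is included in the pooling. The vertex of
the measured angle is the reference point (anchor x, y; pooled helix-G z);
its rays go to the model's helix-G COM and to the reference structure's
helix-G COM for the matching chain.

Two modes are provided and can be reported side by side: `vertex3d`, the
plain three-point angle, and `projected_xy`, the same after zeroing z
components (a pure rotation about the vertical axis). They agree exactly
when the three points are coplanar in z; `vertex3d` is the default, and
`projected_xy` is the better estimator when vertical noise displaces the
helix-G COM. The residue span defining helix G is a required configuration
input; chain correspondence between models and reference is by chain label.

## Classification consensus

Category annotation (swapped / non_swapped / junk per class) is a user
input: calling a 3D class from its map cannot be automated here. The
category fraction of a run counts particles in classes of that category
over all non-junk particles. Co-migration between two runs with the same
class count k builds the k×k contingency matrix of shared particles and
solves the assignment problem exactly (Hungarian method via
`scipy.optimize.linear_sum_assignment`, maximizing matched particles); the
matched fraction is the number of particles in matched cells over all
particles. For k ≤ 6 this equals a brute-force search over all k!
matchings, which the test suite verifies.

The consensus summary takes runs with k in a configurable range (default
[6, 20]); a run is *consistent* when its matched fraction exceeds a
threshold (default 0.6) against at least half of the other in-range runs
with the same k — matched fractions are only defined between equal-k runs,
so the majority is over a run's comparable partners. The summary is the
mean and standard error (sample SD with n−1 denominator over √n) of the
category fraction across consistent runs, with n the number of consistent
runs. Fewer than two consistent runs is an error (the s.e. is undefined),
not a silent fallback.

## Kinetics

Times are ms, currents pA. Desensitization decay is fitted from the first
sample after the peak at which the baseline-subtracted current falls to
90 % of the peak, to the end of the agonist pulse, as one or two
exponentials plus a fitted steady-state offset. Exponential amplitudes are
referenced to the peak time (not the window start): the fit window start
depends on noise, and anchoring amplitudes at the peak makes planted
parameters — and hence the weighted τ — exactly recoverable on noiseless
model-class data. Peak detection takes the extremum of the
baseline-subtracted current inside the pulse window and requires
|peak| > 5× the baseline SD. The solver is bounded trust-region least
squares with three fixed deterministic starts (τ_f at 0.1/0.05/0.3 of the
window, τ_s at 1/0.5/2 windows, amplitude splits 0.7/0.5/0.9), which
avoids the classic bi-exponential identifiability trap without any RNG.
Amplitudes are bounded to the sign of the peak; components are reported
with τ_f ≤ τ_s, and τ_w is their amplitude-weighted mean (a convex
combination, so always within [τ_f, τ_s]).

Recovery fits ratio(t) = 1 − (1 − r₀)·e^(−t/τ_rec) to ≥ 4
(interval, peak-ratio) pairs; both τ_rec and the intercept r₀ are fitted,
with r₀ bounded to [0, 1) rather than pinned to a measured zero-interval
value — the intercept is rarely sampled directly and pinning it would
propagate a single noisy measurement into τ_rec. All-recovered inputs
(every ratio ≈ 1) are rejected as degenerate. The fit uses only ratios and
is therefore invariant to the current scale.

## Synthetic data: what it emulates, and what it does not

The scaffold is a four-chain dummy receptor of helical Cα traces: per
chain a 30-residue "LBD" body (containing an 11-residue "helix G" segment)
on a 10 Å ring, a single anchor residue on a 22 Å ring below it, and a
24-residue "NTD" protomer; protomers pair into two dimers (A/B and C/D) at
±16 Å from the dimer centre, and chains C/D are exact two-fold images of
A/B about z. Planted motions are rigid: each dimer tilts about a hinge at
its lower tip (the NTD–LBD linker position), each flagged chain's LBD body
rotates about the vertical anchor axis, and isotropic Gaussian noise is
added last. The dimensions were chosen so the measured quantities are
well-conditioned: the dimer is wider than tall with a comfortable
eigen-gap between its first two covariance eigenvalues (so the two-fold
axis direction is stable under 0.2 Å noise), and the helix-G COM sits
~12 Å from the anchor axis (so 0.3 Å coordinate noise moves the measured
rotation by well under 2°). These are receptor-like magnitudes, not fitted
to any structure.

Classification runs draw each particle's category once (shared by all
runs) together with a latent within-category score; a run assigns the
particle to the class its category and score determine, except with
probability `label_noise` it is scattered to a uniformly random class.
The scatter model is unbiased — the expected measured fraction equals the
planted fraction because the share of swapped classes tracks it — unlike a
symmetric category-flip model, which would bias the fraction by
ν·(1 − 2f). Replicates differ only in their RNG stream, so they co-migrate
at ≈ 1 − ν, comfortably above the consistency threshold.

Current sweeps have instantaneous rise at pulse onset, the planted
bi-exponential decay towards a 5 % steady state, 1 ms deactivation after
pulse end, and additive Gaussian noise scaled to the peak. Two-pulse
recovery sweeps scale the test-pulse peak by the planted recovery curve;
the default protocol covers intervals of 20–1500 ms in 20 ms steps at
5 kHz sampling (decay fitting uses 100 kHz single sweeps — the fit window
there is short and benefits from dense sampling, while recovery analysis
needs only peak amplitudes).

What passing these benchmarks does **not** show: the generators contain no
density, no projection images, no classification algorithm, no flexible
(non-rigid) deformations, no channel gating scheme and no cell. Recovery
of planted parameters validates the measurement pipeline — geometry,
eigen-analysis, matching, fitting — not the upstream cryo-EM
reconstruction or the biological interpretation of any particular angle.
Real fitted models carry correlated, anisotropic error from map fitting
that isotropic Gaussian noise does not emulate, and real classification
noise is not uniform scatter.

## Problem sizes and determinism

Benchmarks use a 10×10 planted (a, b) grid for tilt recovery, 6 planted
rotations × 4 chains for the LBD protocol, 50-frame ensembles for PCA
mode recovery, 20 000 particles × triplicate × k ∈ [6, 20] for consensus,
and 25–50 noise realizations for the kinetics medians — sizes at which
every stochastic bound holds with margin while a full run stays in the
tens of seconds. All generators are deterministic given a seed;
sub-streams are spawned per particle set and per run, so adding replicates
never reshuffles existing ones. The end-to-end CLI pipeline is
bit-reproducible: two runs with the same seed produce identical CSV and
PDB bytes.

## Known limitations

- Dimer identity ("a" vs "b") and helix-G residue spans are configuration,
  not inference; mislabelled configs are only caught when a chain is
  missing outright.
- The vertex-angle protocol measures displacement of one proxy point; it
  cannot distinguish rotation about the anchor axis from translation of
  the helix-G COM along the same arc.
- `scale_factor` morph amplitudes use the c·√λ convention; a bare
  multiplier on unit eigenvectors would need `target_rmsd` instead.
- The consensus consistency rule (majority of same-k partners above 0.6)
  is a declared convention; other reasonable rules select slightly
  different run sets when runs sit near the threshold.
- Bi-exponential fits with τ_f/τ_s ratios near 1 are weakly identifiable;
  τ_w is the robust summary there, and the per-component constants should
  not be over-interpreted.
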