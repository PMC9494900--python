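# Methods

## Model

The input is a symmetric, nonnegative interaction-frequency (IF) matrix
over n genomic bins, assumed already normalized (e.g. Knight–Ruiz);
normalization is out of scope. Contact counts are converted to target
spatial distances by the standard power law d(i,j) = 1/IF(i,j)^α. Pairs
with IF = 0 are treated as *missing* — they produce no wish distance and
never contribute to the objective — rather than as infinite distances.
Because raw 1/IF^α magnitudes vary by orders of magnitude across datasets
and α values, wish distances are max-normalized (divided by the largest
converted distance) and multiplied by a user-settable `scale`
(default 1.0), which keeps the optimization domain commensurate with the
swarm's [-1, 1] coordinate initialization. This normalization is a declared
convention of this implementation; only the relative geometry of a
distance-only reconstruction is identifiable anyway.

## Optimizer

Candidate structures are optimized by a particle swarm. Each particle
carries position and velocity vectors of length 3n (all bead coordinates
concatenated) updated by

    V(t+1) = w·V(t) + c1·R1 ⊙ (P − X) + c2·R2 ⊙ (G − X)
    X(t+1) = X(t) + V(t+1)

with fresh per-component draws R1, R2 ~ U(0,1) per particle per iteration.
There is no velocity clamping and no position bound after the uniform
[-1, 1] initialization; velocities start at zero.

Bests are **cooperative, tracked per bin**. A bin b of particle s is scored
by its bin-local cost: the per-pair penalty (squared residual for the
SSE/MSE/RMSE family, the Huber penalty for Huber) summed over the wish
pairs that touch b, with every other bin placed at the swarm's current
global-best ("context") coordinates. Per-bin personal bests move on strict
improvement of this cost; after all particles move, the context adopts,
bin by bin, the best personal best (again on strict improvement, all bins
judged against the same context snapshot). The decomposition means a
particle that has placed one region of the chromosome well contributes that
region to the swarm immediately instead of waiting for a whole-structure
improvement; empirically it converges to machine-precision SSE on
noise-free embeddable instances where whole-vector global-best updates
stagnate far from the optimum in the 3n-dimensional landscape.

The *reported* global best is a separate snapshot updated only when the
evolving context strictly improves the full selected loss, so the
global-best loss trace is exactly monotone non-increasing by construction.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| swarm_size | 15 | particles; performance/time balance |
| c1 | 0.3 | pull toward per-bin personal bests |
| c2 | 2.5 | pull toward the shared context |
| inertia w | 0.7 | see stability note below |
| max_iterations | 30 000 | cap; runs usually stop far earlier |
| threshold | 1e-6 | early-stop loss-change threshold |
| patience | 50 | consecutive sub-threshold iterations required |
| loss | sse | also mse, rmse, huber (δ default 0.5) |
| init range | [-1, 1] | per coordinate, uniform |

**Inertia stability.** For the per-component stochastic update the swarm is
order-2 stable roughly when c1 + c2 < 24(1 − w²)/(7 − 5w). With
c1 + c2 = 2.8 the bound allows w up to ≈ 0.78; at w = 0.9 the swarm
demonstrably diverges (positions grow without a single improvement). The
default w = 0.7 sits at the aggressive end of the stable region; it is
exposed as `--inertia`.

**Early stop.** The run ends when the reported global-best loss changes by
less than `threshold` for `patience` consecutive iterations, *counted only
after the first improvement*: before any improvement the trace is flat by
definition and an unarmed window would stop the run during the initial
exploration phase.

**Determinism.** All randomness flows from one seeded generator per run;
identical (input, config, seed) gives bit-identical structures. Repeat runs
derive seeds as `seed + run_index`; the α grid derives `seed + 1000·k` for
grid point k. Parallelism (joblib) exists only across α grid points and
independent runs, never inside a swarm step.

## Conversion-factor search

`alpha_search` reconstructs once per grid point (default [0.1, 1.5], step
0.1 — the range is standard, the step a granularity choice) and selects the
α whose model best reproduces its own wish distances. Selection uses the
Pearson correlation DPCC rather than the rank correlation DSCC: wish
ranks are invariant under the monotone transform D → D^α, so DSCC barely
separates neighbouring α values at all — and on regular synthetic
structures, whose distance sets contain large groups of exact ties, the
remaining DSCC differences are floating-point tie-breaking noise (~1e-5).
DPCC responds first-order to the non-linearity a mis-specified α induces
and separates neighbouring grid points by ~1e-3. Both correlations are
reported in the per-α table. Losses are not compared across α because each
α defines its own residual scale.

## Evaluation metrics

* **DPCC / DSCC** — Pearson / Spearman (midrank ties) correlation between
  two aligned pairwise-distance vectors, computed with scipy.stats. Both
  are invariant under rigid motions of either structure.
* **DRMSE** — root mean squared difference of the two distance vectors.
* **Superposition** — least-squares Kabsch/Umeyama alignment after centroid
  removal, with optional optimal uniform scaling and optional reflection,
  both enabled by default: a structure reconstructed from distances alone
  fixes neither global scale nor handedness.
* **TM-score** — after internal superposition, (1/L) Σ 1/(1 + (d_i/d0)²)
  over per-bead deviations d_i, with the standard length-dependent
  normalization d0(L) = max(0.5, 1.24·(L−15)^⅓ − 1.8) and all beads treated
  as aligned. 1 = identical shapes, > 0.5 same fold, ≈ 0.17 random. (Some
  write-ups print the denominator as "d0 · L_target", which is dimensionally
  inconsistent with the metric's defining literature; this implementation
  uses the standard d0(L).)

## Synthetic data

`generate_structure` provides ground truth: a **regular helix** (radius 1,
20 beads per turn, rise 0.2 per bead; smooth, non-self-intersecting, equal
consecutive-bead spacing, seed-randomized phase) or a **unit-step random
walk** for stress tests. `structure_to_if` simulates the contact map
exactly as the conversion model assumes: IF = 1/D^α, zero diagonal.
`add_noise` perturbs each unordered pair once by a factor (1 + u) with
u ~ U(−level, +level), clipped at zero — symmetric and deterministic per
seed. Levels of 0.03–0.40 mirror published robustness ladders; the
multiplicative-uniform mechanism itself is this package's declared
stand-in, since noise-injection protocols in prior benchmark datasets are
defined in their original publications.

What the generator does *not* emulate: sequencing-depth (Poisson) counting
noise, unmappable/sparse bins, distance-decay exponents other than the
power law itself, trans-contacts, and population heterogeneity (the map is
generated from a single conformation). Passing tests therefore demonstrate
correctness of the machinery and recoverability under the model's own
assumptions, not performance on experimental Hi-C.

Because the generated map satisfies IF = 1/D^g exactly, the conversion
d = 1/IF^a reproduces the true distances when a·g = 1; recovery tests use
the reciprocal pairing (a helix map generated at g = 1 must select α = 1.0,
the self-consistent fixed point).

## Numerical choices and edge cases

* Bin-local costs and pairwise distances run through numba-compiled
  kernels (~15× over vectorized numpy); a pure-numpy path provides the
  reference implementation and the fallback, and the two are asserted equal
  in tests.
* Ties in best-replacement are broken toward the incumbent (strict
  improvement), making the monotone-trace property exact.
* Square input matrices asymmetric beyond a relative 1e-6 are rejected, not
  averaged; within tolerance they are symmetrized exactly.
* A 3-column file is read as a square matrix only in the unambiguous
  3-rows-symmetric case, otherwise as sparse `pos_i pos_j IF`; sparse
  coordinates are binned as floor(pos/resolution) and shifted so the
  smallest bin is 0; without a resolution the columns must already be
  integer bin indices. Duplicate sparse entries must agree.
* Bins with no contacts are retained (numbering is preserved) and simply
  produce no wish distances; their coordinates are unconstrained.
* PDB output rescales coordinates by a single uniform factor only when a
  coordinate would overflow the fixed-width 8.3 field.
* Correlations raise on zero-variance input instead of propagating NaN.

## Problem sizes used in the shipped checks

The test suite and acceptance script validate on 30–100-bin instances
(100 bins, full 15-point grid for conversion-factor recovery; 50 bins for
reconstruction quality and 5-run consistency; 30 bins, 5 seeds for the
noise comparison; 610 bins for I/O round-trips). With the cooperative
update these converge in a few hundred iterations, so the whole suite runs
in seconds.

## Known limitations

* The per-bin cost is evaluated in the current context, so it is a
  coordinate-wise (Gauss–Seidel-like) approximation of the full objective;
  the reported best is nevertheless always scored by the full loss.
* The α grid search assumes a single genome-wide conversion factor;
  per-region α models are out of scope.
* Only gbest topology is implemented (no ring/pyramid/star neighbourhoods).
* TM-score is computed with all beads aligned; partial alignments are not
  supported.
* `.hic`/`.cool` binary formats are not read; inputs are plain-text dense
  or sparse matrices.
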