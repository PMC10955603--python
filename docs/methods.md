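# Methods

## Model and solution family

We study the two-layer linear network ŷ = W₂W₁x (W₁ ∈ ℝ^{Nh×Ni},
W₂ ∈ ℝ^{No×Nh}) trained by full-batch gradient descent on the mean squared
error, in the gradient-flow limit τ dW/dt = −∇L with τ = 1/η.  Time is
counted in iterations, so iteration k of discrete gradient descent at
learning rate η corresponds to flow time t = k with t/τ = kη.  (The
alternative convention t = kη with τ = 1 is equivalent; only t/τ enters any
formula.)

All closed forms track the statistics matrix QQᵀ with Q = [W₁ᵀ; W₂]: its
diagonal blocks are the weight correlations W₁ᵀW₁ and W₂W₂ᵀ, its
off-diagonal block the network function W₂W₁.  Individual weights are
recoverable only up to a time-varying orthogonal transformation of the
hidden layer; `factor_qqt` returns one balanced representative with a
seed-controlled gauge and makes no claim about the true gauge.

Standing assumptions, each validated numerically by
`tasks.validate_assumptions` (every flag is reported together with the
number that justified it):

1. whitened inputs, Σˣˣ = I (the generators guarantee this exactly by
   construction, to ≤1e-12);
2. zero-balanced weights, W₁(0)W₁(0)ᵀ = W₂(0)ᵀW₂(0) (conserved by the flow);
3. full rank: rank(Σʸˣ) = rank(W₂W₁(0)) = min(Ni, No), which requires
   Nh ≥ min(Ni, No);
4. for the stable general solution: the alignment matrix B = UᵀŨ + VᵀṼ is
   invertible, where USVᵀ and ŨS̃Ṽᵀ are the compact SVDs of the initial
   function and of Σʸˣ;
5. for the original Riccati form additionally Ni = No with Σʸˣ
   non-singular.

## When B is singular: a sign obstruction, not a measure-zero accident

In the square full-rank case, B is singular **iff** −1 is an eigenvalue of
the orthogonal matrix (ŨᵀU)(VᵀṼ), and the determinant of that matrix equals
sign(det W₂W₁(0) · det Σʸˣ).  An orthogonal matrix with determinant −1
always has a −1 eigenvalue, so *every* initialisation whose function
determinant has the opposite sign from the task's violates assumption 4 —
about half of unconstrained random draws, not a measure-zero set.
Dynamically these trajectories must pass through a rank-deficient function,
which the solution family excludes.  Helpers
(`experiments.draw_compatible_init`, `draw_solvable_sequence`) therefore
redraw random initialisations/sequences until min σ(B) > 0.1, the regime in
which the bracket solve is well-conditioned; experiment protocols state this
as part of their conditions.  Reversal learning (initial function −Σʸˣ) is
the extreme case B = 0: in odd dimensions no small perturbation can repair
the determinant sign, so the ε-perturbation diagnostic below is meaningful
only in even dimensions, which the reversal protocols use.

## Numerical choices

- Exponentials act elementwise on the diagonal of S̃; brackets are
  symmetrised and solved as symmetric linear systems, never inverted
  explicitly; a solve is refused when the bracket condition number exceeds
  1e12 (beyond double precision).
- Rank tolerance for compact SVDs: 1e-10 relative to the largest singular
  value; B is deemed singular below 1e-10 absolute.  Both sit far below any
  singular value used in experiments and far above float noise.
- Degenerate singular values are allowed; SVD tie-breaking follows the
  backend and is not semantically meaningful (only rotation-invariant
  products are exposed).  Orthogonal-complement bases are never
  materialised — only the projectors I − ŨŨᵀ and I − ṼṼᵀ enter.
- The ε-fallback for singular B perturbs the initial *function* by ε times
  a random unit-norm matrix, reports the ε used, and is never applied
  silently.  As ε → 0 at fixed large t the solution collapses onto the
  saddle (function → 0), which is the diagnostic content.
- Default time grids: 200 log-spaced points over [1e-3, 50]·τ/min(S̃).
- The simulator is discrete gradient descent (not an ODE integrator), so
  that the oracle has the same discretisation the model class is trained
  with; its deviation from the flow is O(η).  Divergence (loss above 1e6×
  initial) raises with advice to reduce η.  Convergence for continual legs
  is declared at loss excess ≤ conv_tol above the analytic minimum; the
  continual protocols use conv_tol = 1e-12 because a residual excess δ on
  the trained task leaks ≈ √(2δ)·‖Σ_j − Σᵢ‖ into other tasks' evaluated
  losses, and the prediction comparison is made at 1e-4.
- Saddle escape in simulation relies on float rounding only by default;
  `SimConfig.start_noise` can add an explicit Gaussian kick at t = 0.

## Approximation regimes of the 2×2 results

Writing μ₁, μ₂ for the eigenvalues of A(0)ᵀA(0) (so μ₁μ₂ = a₁a₂ − b(0)²,
μ₁ + μ₂ = a₁ + a₂), the exact peak of the cross-coupling |b(t)| for equal
task singular values s sits at τ/(4s)·ln[(s−μ₁)(s−μ₂)/(μ₁μ₂)].  The
peak-time formula exposed by `two_by_two_offdiag_peak` replaces
(s−μ₁)(s−μ₂) by s(s−μ₁−μ₂) — the small-initialisation form, accurate to
relative order (a/s)² in the log argument.  Tests and presets therefore
draw aₖ ~ s·U[0.01, 0.05], where the formula matches a dense grid argmax to
within one grid step.  Similarly, the sigmoidal mode is the exact (1,1)
element of the aligned solution only for rank-one A(0)ᵀA(0)
(b(0) = √(a₁a₂), the structure of effectively rank-one small random
weights); for b(0) = 0 it agrees at early times but limits to s·a₁/(a₁+a₂).
Cross-checks use b(0) = √(a₁a₂)(1 − 1e-6) on t ∈ [0, 5τ], covering the whole
sigmoidal transition while the deflated second mode is still dormant.

## Observables

The hidden-layer representational similarity over inputs X is the kernel
K = Xᵀ(W₁ᵀW₁)X (input side) or Xᵀ(W₂W₁)ᵀ(W₂W₂ᵀ)⁺(W₂W₁)X (output side, ⁺ the
pseudoinverse); balancedness makes the two coincide, which is tested.  The
finite-width NTK in sample-major ordering is
Θ = (XᵀX) ⊗ (W₂W₂ᵀ) + (XᵀW₁ᵀW₁X) ⊗ I_No; both observables are pinned by
brute-force oracles (explicit parameter-Jacobian contraction for the NTK)
rather than trusting the assembled forms.

The relative NTK movement ‖Θ(∞) − Θ(0)‖/‖Θ(0)‖ decreases monotonically with
initialisation scale only while the initial function norm stays below the
task scale.  Beyond it the network must *unlearn* the oversized initial
function (the endpoint is scale-independent), and the ratio turns back
towards 1.  The lazy-contrast protocol therefore fixes task singular values
(60, 45, 30, 20) above its largest initialisation scale (10); that regime is
the actual content of the monotonicity claim.

## Synthetic tasks: what they emulate and what they do not

`make_random_whitened_task` draws X = √P·O (O orthogonal, P = Ni) so that
Σˣˣ = I holds exactly, and synthesises Σʸˣ from random orthonormal factors
with singular values U[0.5, 1.5] — order-one tasks.  This scale is part of
the study conditions: the discrete-GD-vs-flow deviation is proportional to
the loss amplitude, and the agreement calibration (max deviation ≤ 1e-3 at
η = 5e-4 over t ∈ [0, 30τ/min S̃]) presumes order-one losses; at these
conditions the worst-case deviation is ≈8e-4 and the median deviation
decreases ≈10× per decade of η.

`make_hierarchy_task` builds the P = 2^depth-item balanced-tree semantic
task: one-hot item codes scaled by √P (whitened exactly), and a signed-Haar
feature system — one constant root-ancestry feature plus one feature per
internal node assigning ±σ_ℓ to the items under its left/right child,
σ_ℓ = 1/√(level+2).  Rows are mutually orthogonal, giving Ni = No = P and
full rank, and the input-side similarity ṼS̃Ṽᵀ decays with tree distance
(siblings 0.19, cousins 0.11, cross-root 0.04 at depth 3).  The
construction has degenerate singular values per level; only
rotation-invariant products of the SVD are meaningful.

These generators produce exactly whitened, exactly realisable (noise-free)
tasks.  Real datasets have non-white input correlations, label noise and
unbalanced initialisations; passing tests here validate the closed forms
and their oracles under the stated assumptions, not robustness to those
violations (non-whitened dynamics are outside the solution family by
design).

Default initialisation scale for "small" inits is 0.3 (entry standard
deviation of the random function before balanced factorisation); "large"
means scale ≳ task singular values.  There are no separate code paths —
scale is the only dial, as the theory prescribes.

## Balancedness under discretisation

Zero-balance is conserved exactly by the flow, but each discrete GD step
injects an O(η²) defect: the gap rises from float level (~1e-15) to a
discretisation floor and saturates (measured ≈4e-4 at η = 5e-4 over 1e4
steps, bounded by η times the initial gradient scale).  With a tanh hidden
layer the conservation law genuinely breaks: the gap grows thousands of
times larger on the same task, which is why pre-computed forgetting
predictions fail for nonlinear networks.

## Problem sizes

Desk-scale protocols are used throughout: dimensions 2–6, hidden width
max(Ni,No)+1, 10–20 random draws per property, η ∈ {5e-2, 5e-3, 5e-4},
horizons 30–50 τ/min(S̃).  These sizes were chosen because every phenomenon
of interest (regime contrasts, saddle slowing, forgetting structure) is
fully expressed in them while keeping the whole verification suite
executable in well under a minute.

## Known limitations

- No exact solution for singular B (only the ε diagnostic and the
  simulator); no unbalanced or non-whitened initial conditions; no networks
  deeper than two layers; no mini-batch or stochastic gradients.
- The Fukumizu reference form loses precision beyond a few τ by
  construction (growing exponentials) and is only used for cross-checks at
  moderate times.
- Weight recovery is gauge-ambiguous (see above); trajectories of
  individual weight entries are not an output of this library.
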