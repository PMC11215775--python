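# Methods

## Model and scope

The package treats time-discretized underdamped Langevin dynamics

    M q̈ = -∇V(q) - ξ M q̇ + sqrt(2 RT ξ M) η(t)

in molar MD units (nm, ps, amu, kJ/mol, K; R = 8.314e-3 kJ/(mol·K)).
Integration uses the splitting approach: per degree of freedom, a drift
update A (`q += a p`, `a = Δt/M`), a kick B (`p -= Δt ∇V(q)`), and an
Ornstein–Uhlenbeck thermal update O (`p <- d p + f η`, `d = exp(-ξΔt)`,
`f = sqrt(RT·M(1-d²))`).  A scheme string fixes the order; a letter
occurring twice is applied with Δt/2.  The RVO (position/velocity) notation
is accepted as an alias (R↔A, V↔B) and a genuine velocity-form twin
implementation is provided for cross-validation; the two forms differ only
in floating-point operation order.

Supported schemes are ABO, ABOBA, AOBOA, BOAOB and OBABO (plus RVO
aliases).  All five can be simulated.  Path reweighting is implemented and
certified for the one-noise schemes ABO and ABOBA only: for the two-noise
schemes the transition endpoint fixes only the combination
`d'η⁽¹⁾ + η⁽²⁾`, and the per-channel split of the random-number difference
required by the two-noise path-probability ratio is deliberately not
guessed.  Requesting reweighting for them raises a clear error; the
endpoint combination is still exposed through the inversion oracle for
testing.

## Sign conventions

The perturbation connects target and simulation potentials as
`Ṽ = V + U`.  An enhanced-sampling bias enters as `U = -U_bias`, i.e. the
simulation runs on the biased surface `V = Ṽ + U_bias`.  The convention is
resolved once, when a `PotentialPair` is constructed; all reweighting code
sees only `U`.  Consequences used throughout:

* initial-state ratio `log g = -U(q_0)/RT` (= `+U_bias(q_0)/RT`); the
  Maxwell–Boltzmann momentum factors cancel identically and the
  partition-function ratio Z/Z̃ is omitted because row normalization of the
  MSM cancels it;
* the per-step increment is `s_k = Σ_l (η Δη + ½Δη²)` with
  `M = exp(-Σ_k s_k)`.  The sign is *certified*, not assumed: per step and
  degree of freedom, `exp(-s_k)` must equal the Gaussian density ratio
  `φ(η̃)/φ(η)` with `η̃` recovered independently by replaying the operator
  sequence and solving for the noise that connects the recorded endpoints
  at the target potential.  The test suite enforces agreement to 1e-9
  relative over 10³ random steps; in practice agreement is at rounding
  level (~1e-13).

## Random-number differences

Derived by operator algebra from the splitting definitions and verified by
the inversion oracle:

* ABO: all kicks precede the noise; matching endpoints at `Ṽ` versus `V`
  shifts the noise by `Δη = (d·Δt/f)·∇U(q_drift)`, with ∇U evaluated at the
  position after the drift.
* ABOBA: the two half-kicks at the mid-step position contribute before and
  after the O update, giving `Δη = ((1+d)·Δt/(2f))·∇U(q_mid)`.

The gradient evaluation point is a *tag* on the parsed scheme, not
duplicated code.  With a bias force as input, the sign flips
(`∇U = -∇U_bias`).  Reweighting is refused when `f = 0` (ξ = 0 or T = 0),
where the noise shift is undefined.

## On-the-fly accumulation and files

During a simulation the per-step `s_k`, summed over degrees of freedom, is
accumulated in a buffer; every `n_out` steps the buffer value ΔS is written
to the reweighting record aligned with the trajectory frame and reset.  The
record at frame k′ therefore holds the interval *ending* at k′ (the record
at frame 0 is zero), which lets windows start at any recorded frame without
look-ahead.  Each record also stores `U(q_k′)` so the initial-state ratio
of any window is available.  Files are TSV with columns
`frame_index, time_ps, dS, U_kJ_per_mol` (positions:
`frame_index, time_ps, q0, q1, …`); an HDF5 container with the same schema
is available for large runs.  All weights are carried as logs; windows are
exponentiated only inside the count estimator after subtracting the global
maximum log weight, which cancels in row normalization.

## Reweighted MSM estimation

Positions are discretized on a regular grid (row-major state index,
half-open bins with the last bin closed; out-of-box frames are clipped to
edge bins with a warning, or optionally dropped).  For lag τ (in recorded
frames) every window start m contributes its rescaled weight to
`C[s_m, s_{m+τ}]`, stride 1.  Replicas are pooled with a single shared
max-log shift so their weights remain on a common scale.  Window weights
are recomputed per lag from the stored per-interval ΔS (cheap cumulative
sums), never cached as exponentials.

Rows with zero outgoing weight are dropped (iteratively, re-indexed with a
stored mapping); no self-loops are added and reversibility is *not*
enforced — the estimator is nonreversible by design.  Spectral analysis
sorts eigenpairs by descending modulus with ties broken by descending real
part; the leading left eigenvector is normalized to a probability vector,
the others to unit 2-norm with the largest-magnitude entry positive.
Nonnegligible imaginary parts (>1e-10) are surfaced with a warning, never
silently truncated.  Implied timescales use `t_i(τ) = -τ/ln|λ_i(τ)|`; a
real eigenvalue ≤ 0 or a modulus ≥ 1 yields a NaN marker rather than an
exception.

## Built-in systems and study conditions

* **Müller–Brown** (2-D, four-exponential sum, built-in parameter table):
  global minimum near (-0.56, 1.44) nm, two shallower minima, barriers of a
  few RT at 300 K.  Biases along x: linear with k = 1 kJ/mol/nm, or the
  degree-13 polynomial with k = 50 kJ/mol/nm and the built-in coefficient
  table (evaluated by Horner's scheme).  Study conditions: ABOBA,
  Δt = 0.5 fs, ξ = 5 ps⁻¹, T = 300 K, unit mass, frames every 10 steps,
  6×6 MSM grid over [-3.5, 1.5]×[-1.5, 3.5] nm, lags 0.5–4.5 ps.
* **Double well** (1-D surrogate for a bistable ion-dissociation
  coordinate): quartic `h((q-q₀)²/w² - 1)²` with barrier h = 8 kJ/mol
  (≈3.2 RT), minima at 0.35/0.55 nm, mass 40.08 amu, ξ = 2 ps⁻¹,
  Δt = 1 fs, linear bias k = 5 kJ/mol/nm, 50-state grid over
  [0.3, 0.6] nm.  The geometry was chosen so that the well separation,
  grid, and bias strength give a clearly measurable density shift
  (analytic total variation ≈ 0.09) and a relaxation time (~10 ps) that is
  well sampled within a desk-scale run.

Desk-scale sampling defaults — 5 replicas × 5×10⁶ steps (Müller–Brown) and
3 × 2×10⁶ steps (double well), with burn-ins of 100 ps / 50 ps discarded
before MSM estimation — keep the full paired study in the tens of seconds
on one core while leaving hundreds of barrier crossings per replica; the
`scaled()` config method and the CLI `--scale` flag shrink or grow
everything together.  Initial positions are uniform over the grid box and
initial momenta Maxwell–Boltzmann at T; the burn-in length is an explicit
parameter because the estimator assumes Boltzmann-distributed window
starts.

## Reproducibility and numerics

One seeded generator drives each simulation; noise draws are ordered
(step, O-occurrence, degree of freedom), and a committed 20-step golden
fixture pins the stream across releases.  Production runs use numba
kernels specialized to ABO/ABOBA on the built-in potential families; the
pure-Python operator composition is the reference, and the test suite
asserts the two engines produce identical trajectories and reweighting
records from the same stream.  Blow-ups (non-finite energy or |q| beyond a
configurable bound) abort with the offending step index.  Time steps are
accepted in fs at the config/CLI boundary and converted to ps exactly once.

## What the synthetic systems do and do not show

The built-in potentials are low-dimensional with analytic gradients and
biases along a single coordinate.  They exercise the full reweighting
chain — integrator bookkeeping, weight assembly, estimator — under exactly
known conditions with closed-form or quadrature references, which is what
makes the acceptance checks sharp.  They do not probe force-field
evaluation, constraints, solvent degrees of freedom, or the
weight-degeneracy regimes of high-dimensional biases; the per-window
effective sample size reported in every experiment summary is the
diagnostic to watch when the bias is strong or windows are long, and the
reweighted implied timescales carry visibly larger statistical uncertainty
than the reweighted eigenvectors (the per-replica bootstrap in the study
runner quantifies this).

## Known limitations

* No per-channel Δη for the two-noise schemes (AOBOA/BOAOB/OBABO):
  simulation yes, reweighting no.
* No constraint algorithms, barostats, multiple time stepping, or
  periodic boundaries.
* No reversible maximum-likelihood MSM estimation, tICA/variational/core-set
  models, or transition-path-sampling rate reweighting.
* The direct estimator's statistical efficiency degrades exponentially
  with window length (log-domain arithmetic keeps it *computable*, not
  accurate); keep MSM lags much shorter than the slow relaxation times.
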