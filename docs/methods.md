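# Methods

## Model

`olfbayes` simulates unsupervised odor learning as online variational
Bayesian inference mapped onto the circuitry of the mammalian olfactory bulb.

**Generative model.** A trial presents a concentration vector
`c ∈ R^M` drawn from a spike-and-slab prior: each odor is independently
present with probability `c_o` (default `3/M`), and present amplitudes follow
a gamma distribution of shape 3 with unit mean (amplitudes stand for
log-concentration; all-zero trials are resampled). Glomerular input is
`x = W c + σ_x ξ` with `ξ ~ N(0, I)`. The true mixing matrix `W` is
log-normal, `log w̃_ij ~ N(−log(c_o M), 1)`, followed by a row rescaling
(each row multiplied by grand mean / row mean) that forces every row sum to
be identical; the factor is 1 up to an `O(CV²/M)` Jensen bias.

**Inference and learning.** The posterior over odors and weights is
approximated by a fully factorized variational distribution. For a single
odor the update reduces to a Gaussian pseudo-likelihood `(μ_j, λ_j)` times
the prior; with the shape-3 slab the posterior mean `F`, second moment `G`
and presence probability `H` have closed forms in the standardized argument
`α = √λ μ − 3/√λ` and the Gaussian hazard `φ(α)/Φ(α)`. The network realizes
this with mitral/tufted cells carrying the residual `m = x − w^L c̄` and
granule cells carrying `c̄ = F(·)`; the dendro-dendritic weights `w^F`, `w^L`
store the posterior mean of `W`, with per-granule precision `ρ_j` (weight
posterior variance `1/(t ρ_j)`). Each trial: (1) integrate the rate dynamics
to steady state with weights frozen; (2) update `ρ` by a running average of
`G/σ_x²`; (3) apply the discounted Hebbian weight update with learning rate
`1/(t ρ_j σ_x²)`. If `w^L` starts as the transpose of `w^F` the two remain
transposes forever; weights are clipped at zero.

**Piriform readout.** Four circuit variants estimate the presence
probability `p̄_j = Pr[c_j > 0]`: (a) a non-biological reference that copies
`w^F` into the readout, (b) locally learned readout weights, (c) plus learned
lateral inhibition `ΔJ_jk = 0.1 p̄_k(−5 c_o J_jk + p̄_j)` (`J ≥ 0`, zero
diagonal, initialized at 0.02), and (d) plus top-down feedback in which
`p̄_j` replaces `c_o` inside the granule gain functions F and G. The lateral
strength multiplier `κ_J` scales `J` inside the dynamics only; plasticity
always sees the unscaled `J`.

**Reward learning.** A scalar error neuron receives the delayed reward
(`R̂ = 0` for the first 2.5 s of a 5 s trial, then `R`) minus a learned
prediction `Σ_j ā_j p̄_j` (piriform route, `η_a = 0.5`) or `Σ_i h_i x_i`
(direct glomerular route, `η_h = 0.0015`). `−e` read at 2.45 s is the reward
prediction; the post-reward value of `e` drives the Hebbian association
update. The go/no-go task presents one of two odors (reward amplitudes 1.0
and 0.0, observation noise variance 0.01) at unit-mean gamma concentrations.

**Sparse-coding baseline.** MAP inference of `ĉ` by gradient ascent on the
gamma-smoothed log posterior (`k_c = 3`, `θ_c = c_o/3`; step size
`η_c = 1e−5`, budget 100,000 steps with an early exit on the gradient
sup-norm), followed by one stochastic-gradient dictionary step (`η_w`,
default 0.5) and per-column L2 normalization to root-mean-square
`e/(c_o M)` — read as Euler's number, matching the log-normal scale of the
true weights (the alternative reading, a misprint for `e^{1/2}`, would only
change a global scale that the weight-error metric divides out anyway).

## Parameters

| name | meaning | default |
|---|---|---|
| `M`, `N` | odors / glomeruli | 100 / 400 (50 / 200 for the reward task) |
| `c_o` | prior presence probability | `3/M` |
| `σ_x` | glomerular noise sd | 1.0 |
| `m_sp` | spontaneous M/T rate (floor `m ≥ −m_sp`) | 5 Hz |
| `τ_r` | rate time constant | 50 ms |
| `T_max` | trial duration cap | 5000 ms |
| `t_min` | initial trial counter (damps early learning) | 100 |
| `Z_ρ` | precision init scale, `ρ_0 = c_o/(σ_x² Z_ρ)` | 0.5 (0.3 for the sparseness analysis) |
| `η_a`, `η_h` | reward learning rates | 0.5 / 0.0015 |

## Numerical choices

- **Hazard evaluation.** All closed forms are expressed in `1/Ψ(α)`
  (`Ψ = √2π e^{α²/2} Φ(α)`), so `Ψ` itself is never formed. `inv_psi`
  implements the classic three-branch approximation (−α below `−10√2`, the
  exact ratio inside, 0 above) and is exposed as the fast network-grade
  variant; the moment functions use the exact hazard via `erfcx`, which is
  stable at all α and identical to the middle branch inside the window. The
  outer branches differ from the exact hazard by `O(1/|α|)` relative — only
  where the moments are themselves `≲ 1e−5` — so the closed forms can be held
  to the quadrature oracle at `1e−4` relative everywhere.
- **Quadrature oracle.** Composite 16-point Gauss–Legendre on
  `[0, max(μ, 0) + 12/√λ]` with panel doubling until successive estimates
  agree to `1e−8` relative; spike and slab are jointly rescaled by the
  Gaussian tilt's maximum over the domain so neither side under- or
  overflows. Comparisons against it use a `1e−12` absolute floor: in
  spike-dominated corners the closed form cancels to zero in double
  precision while the true moments are `~1e−17`.
- **Integration.** Forward Euler with a staggered (Gauss–Seidel) sweep: `m`
  advances against the old `c̄`, then `c̄` (and `p̄`) against the new `m`.
  The simultaneous sweep is unstable at practical `dt` for the rotational
  modes of the excitation–inhibition loop; the staggered sweep has the same
  fixed points and is stable there. Defaults: `dt = 1` ms, early exit when
  the largest rate derivative falls below `1e−7`/ms. Steady states are
  integrator-independent, so the long training ensembles use a desk-scale
  profile — `dt = 4` ms, exit at `5e−5`/ms, presentation capped at 3 s,
  single-precision rate loop (`dyn_dtype="float32"`; weights and plasticity
  stay double) — whose residual rate error (~`1e−2` at worst) is far below
  the `σ_x = 1` sensory noise, and whose truncation of occasional
  slow-converging presentations is covered by the model's stated robustness
  to presentation duration. Rates are floored
  (`m ≥ −m_sp`, `c̄ ≥ 0`, `p̄ ∈ [0, 1]`) after each step; `c̄` restarts at
  `c_o` (and `p̄` at `c_o`, `m` at 0) on every trial. Error-neuron dynamics
  are first-order with constant drive once the sensory rates settle, so they
  are advanced by the exact exponential relaxation over each phase of the
  reward trial.
- **Top-down clamp.** In the feedback variant `p̄` is clamped to
  `[1e−6, 1 − 1e−6]` before replacing `c_o`, keeping the spike/slab mixture
  proper.
- **Update order.** Within a trial: dynamics with the previous trial's
  weights and precisions → piriform precision/weight update → lateral
  inhibition update → bulb precision/weight update (with `p̄` as prior
  weight in the feedback variant) → counter increment. `G` for each
  precision update is evaluated with pre-update weights.
- **Selectivity ties.** The covariance bootstrap breaks argmax ties by the
  lowest odor index. Because it uses covariance (not correlation), it can
  mis-assign cells when a foreign affinity column has much larger variance;
  this is a property of the metric, not of learning.
- **ROC grid.** Thresholds `θ_{k+1} = 1.2 θ_k` from `1e−6` past `1e1`
  (~20% steps), written into the output.

## Problem sizes

Training ensembles advance in lockstep through a batched array layout
(leading ensemble axis), which is what makes multi-seed runs tractable on
one CPU. The bundled study conditions: learning-curve and baseline
comparison at `M=20, N=100, c_o=0.15`, 1500 trials, 5 seeds; the
sparseness–learning-rate analysis at `M=100, N=400, Z_ρ=0.3`, 300 stimuli,
5 seeds; the reward pipeline at `M=50, N=200`, feedback variant,
2000–2200 unsupervised trials and 50 circuits (the headline script runs
four independent task sessions per circuit, 200 task simulations in all),
with the sparse-coding baseline
inference run at 10,000 steps / `1e−4` gradient tolerance. The reference
study trained the reward pipeline 2× longer (4000 unsupervised trials) and
ran the baseline inference at the full 100,000 steps; the desk-scale
numbers here are the smallest sizes at which the qualitative orderings and
the sixth-trial reward-learning level are stable across seeds.

## What the synthetic world does and does not capture

The generator reproduces the statistical structure the learning rules are
derived for — sparse presence, unit-mean amplitude variation, odor-specific
affinity columns, isotropic Gaussian sensor noise — and nothing else. Real
olfactory input has temporally correlated plumes, sniff-cycle structure,
receptor nonlinearities and correlated noise; passing tests here show the
algorithmic claims (data-efficient unsupervised learning, adaptive learning
rates, concentration-invariant readout, fast reward association) hold under
the model's own assumptions, not that they survive those complications.

## Known limitations

- Closed-form moments exist only for slab shape 3; other shapes route
  through the quadrature oracle and are far slower (the shape-1 variant is
  supported but not an optimized path).
- The covariance-bootstrap selectivity map can leave some odors unclaimed
  early in training; decoded estimates for those odors are defined as 0.
- Reward prediction is capped by the quality of the piriform presence code:
  odors never acquired during the unsupervised phase cannot be associated
  with reward afterwards, which is the main cost of desk-scale pretraining.
- Amplitudes near 0.1 sit below the circuit's detection threshold under the
  default sparse prior: the presence estimate (and hence any downstream
  reward prediction) collapses there. This is the correct Bayesian answer,
  not a training artifact — it persists at full-scale training — and it
  bounds how "concentration invariant" the piriform code can look when
  sub-threshold presentations are averaged in.
- `scipy.special.erfcx` is the only non-elementary special function used;
  there is no GPU path.
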