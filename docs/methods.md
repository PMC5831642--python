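# Methods

## Model and assumptions

The tissue is a linear hierarchy of `n + 1` well-mixed compartments
`C_0 … C_n` of fixed sizes `N_0 … N_n`: a stem pool, intermediate
transit-amplifying stages, and a terminally differentiated top stage. Time
is discrete; one **update** removes `2^n` cells from `C_n` and restores all
compartment sizes through a cascade of symmetric divisions resolved from the
top down. Each opening in `C_i` is filled by a self-renewal division inside
`C_i` with probability `v_i`, otherwise by differentiation from `C_{i-1}`;
because two daughters fill two openings, an odd differentiation leftover is
rounded down by one extra self-renewal. `v_0 = 1` and `v_n = 0` are
structural, not tunable. Mutants are selectively neutral, compartment sizes
never change, and there is no spatial structure within a compartment —
deliberate simplifications shared by the metapopulation view the model
takes.

The cascade's differentiation counts `(a_0, …, a_{n-1})` form the division
tree; its probability is the product over levels of the
`Binomial(a_{i+1}, 1 − v_{i+1})` mass at `{2a_i, 2a_i + 1}`. This is the
unique reading of the per-opening Bernoulli process with odd-correction,
and `trees.py` enumerates, scores (optionally in exact rationals), samples
and summarizes these trees.

## Expected dynamics

`dynamics.py` builds the per-update expected change of mutant counts per
tree from binomial moments (sampling **with replacement**), weights by tree
probability, and exposes the result as a continuous-time right-hand side:
one unit of `t` is one update. Because hypergeometric and binomial draws
share their mean and every term is linear in the mutant counts, the system
is also the exact expectation of the without-replacement simulator; the
distinction only affects variances.

Two bookkeeping variants of the loss term exist. The default charges a
compartment only the expected number of its own mutants that differentiate
out (`a_k μ_k`); this reproduces the low-`n` closed-form systems
term-by-term and is what `method="brute"`/`"closed"` implement (they agree
to 1e-12 and are tested against each other). The alternative
`method="printed_beta"` charges the full downstream gain `2i + l` and is
retained for documentation only — it double-counts the de-novo daughters
and does not reproduce the closed-form systems. Similarly, the reference
single-level (`n = 1`) system lacks the overall factor 2 of the generic
construction; `printed_rhs(..., corrected=False)` reproduces it verbatim,
the default restores the factor.

Derived quantities:

* **generation probabilities** `g = rhs(0) / Σ rhs(0)` — where a de-novo
  mutant first appears; independent of `u` and of compartment sizes.
* **flush-out rates** `K_k = 2 E[a_{k-1}]`, the couplings of the `u = 0`
  lower-bidiagonal clonal system, with `K_1 = 2(1−v)^(2^n−2)` for constant
  interior `v` and leading exponents `γ_i = 2^(n−i+1) − 2` near `v = 1`
  (recovered numerically as a log-log slope on `v ∈ {0.99, 0.999}`).
* the clonal steady state `m_k = m_0 N_k / N_0` (stem fixation probability
  times downstream size).

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-8, atol
1e-12); the systems are linear and non-stiff at these sizes. Trajectories
are never clipped inside the solver.

## Stochastic simulator

`simulator.py` implements the update rule cell-by-cell. Event counts per
compartment are drawn first (per-opening Bernoulli with the
odd-correction); dividing-cell identities are then drawn without
replacement (`numpy.random.hypergeometric`) from the compartment
composition at the start of that compartment's replacement phase, so newly
created cells never divide within the same update. A with-replacement mode
(binomial draws, clamped to the available counts) matches the
expected-dynamics derivation exactly and is used for the ODE-comparison
experiments.

Mutation conventions (`u` is the mutation probability):

* **De-novo (first) hits**: `per_daughter` (default) — each daughter of a
  wild-type division mutates independently; this is the convention under
  which ensemble means coincide with the expected-dynamics system.
  `per_division` — a single trial per division — is available by flag.
* **Second hits**: `per_division` (default) — each division of a one-hit
  parent yields a two-hit daughter with probability `u`, one trial per
  division, and the run stops at the first such event. We adopted the
  single-trial convention for the secondary process because it is the one
  that reproduces the reference two-hit waiting-time panels (both the group
  means and the effect sizes); the per-daughter variant shortens all
  waiting times by about a factor √2 and is kept behind
  `second_hit_model="per_daughter"`. Wild-type cells acquiring two hits in
  a single division (probability `u²`) are excluded.

Replicate `r` of an ensemble uses seed `seed + r` through numba's
`np.random.seed`, making every run bit-reproducible and replicates
order-independent. Censoring at `max_updates` (default 10⁶) is reported
explicitly; ensemble drivers fail loudly if more than 1% of replicates
censor. The inner loop compiles with numba; without it the identical code
runs in pure Python, only slower.

## Experiments and statistics

Two-hit comparisons use the classic pooled-variance two-tailed Student
t-test and a pooled-SD Cohen's d reported as a magnitude (Welch's test is
available by flag). The reference histograms' absolute display unit is not
stated; `calibrate_time_unit` scores two candidates — thousands of update
steps, and log10 of the update count — against the reference panel means
and effect sizes jointly and records both scores. With the defaults the
log10 calibration wins by three orders of magnitude in score, so reported
means are means of `log10(t2)` and effect sizes are computed on log-times
(under which d is not scale-invariant, which is what lets the data
arbitrate). The calibration is performed once, on the four self-renewal
comparison panels, and applied to all reported means.

`compare_ode_sim` reports, per compartment, the worst
`|ensemble mean − ODE| / SE` over the recorded grid, where SE is the
Monte-Carlo standard error floored at `sqrt(ode_mean / n_replicates)` — a
Poisson-scale floor that prevents division by zero where the prediction and
all replicates are essentially zero (e.g. the stem compartment at
`v = 0.9`, where the creation rate is `2u(1−v)^6 ≈ 2·10⁻⁹` per update).

## Problem sizes

The quantitative reproduction runs 5000 replicates per scenario at `n = 3`,
`u = 10⁻³` — the reference ensemble size. The ODE-vs-simulation check uses
compartment sizes (100, 200, 400, 800) with 100 replicates over 10⁴
updates: large enough that compartments accumulate tens-to-hundreds of
mutants (so the 3-SE band is meaningful) while keeping the whole suite's
stochastic load at roughly 10⁸ update steps. Property tests on the
simulator use deliberately tiny systems (e.g. sizes (4, 8, 12)) where
fixation and flush-out equilibrate within a few hundred updates.

## Known limitations

* The mean-division-position statistic is implemented exactly as defined
  (`2^{-n} Σ 2^i (a_i − a_{i-1})` with `a_{-1} = 0`, `a_n = 2^n`), although
  its range exceeds `n` at `v = 0`; no alternative normalization is
  guessed.
* The decreasing size profile (120, 80, 40, 20) is the reversal of the
  increasing one, chosen to preserve the total cell count; the original
  decreasing sizes are not part of the reference parameter set.
* The `v = 0.9` expected system saturates the stem compartment on a 10⁹-
  update timescale; finite-horizon experiments only probe the transient.
* No mutant fitness effects, replication-capacity limits, asymmetric
  divisions, or explicit spatial structure: the synthetic process is the
  model, so passing tests certify internal consistency and reproduction of
  the model's reference statistics, not agreement with real lineage data.
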