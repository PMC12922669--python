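# Methods

This note documents the generative model behind the synthetic studies, the
analysis conventions, the numerical choices, and what the validation suite
does and does not establish about real data.

## Task and transition process

Three screen positions (left, middle, right) double as response keys.  The
stimulus sequence is a first-order Markov chain with an absolute no-repeat
constraint: from each position, a designated *high-probability* successor
follows with probability `p_hi` (default .8) and the remaining position with
`1 − p_hi`.  Contingency set 1 makes left→middle, middle→right and
right→left the likely transitions; set 2 is its mirror image, and the two
sets alternate across participants (odd participant numbers get set 1).
Sessions consist of `n_blocks` blocks (default 3) of `n_practice` practice
plus `n_test` test trials (defaults 10 + 300).  Each block restarts the
chain from a uniformly drawn position — blocks are separated by self-paced
breaks, and per-block bookkeeping is what the first-pair exclusion (below)
presumes.  Practice and test trials form one unbroken chain within a block,
which is why first-pair exclusions are rare: by the first test trial,
almost every response has already occurred as a pair onset.  Whether the
chain should instead continue across breaks is not decidable from the task
description; the per-block restart is this package's documented choice.

## Generative RT model

The expected RT of a trial is

```
mu0 + u_i + b_cl·s(CL) + b_pcl·s(PCL) + b_rev·s(REV) + b_er·s(ER)
    + b_ca·s(CA) + 2·b_cl_ca·s(CL)·s(CA) + 2·b_er_ca·s(ER)·s(CA)
```

with `u_i ~ Normal(0, tau)` the participant intercept and `s(·)` the signed
half-difference code: +½ for the hf / match / correct / reversal level, −½
for the complementary level, 0 where the label is undefined.  Each
main-effect `b` therefore equals the marginal condition difference in ms.
With the doubled product terms, the fitted coefficient of a product contrast
column and the difference of subgroup effects both equal `2·b_**`.

Crucially, the condition codes entering the mean are computed from the
*actual generated history* by the same coding rules used at analysis time.
ER is never injected as an independent factor: whether the retrieved episode
matches emerges from the sequence itself, which is what produces the natural
confound — P(match | hf) → p_hi and P(match | lf) → p_lo — and hence the
omitted-variable identity β_CL(M1) ≈ β_CL(M2) + (p_hi − p_lo)·β_ER(M2).

Errors occur independently per trial with probability `err_rate` (default
.04); an error presses one of the two wrong keys uniformly and leaves the RT
model untouched (errored trials are excluded downstream).  Awareness
judgments are independent Bernoulli per sequence type with success
probability `pi_ca` (default .629, yielding above-chance but far from
perfect classification accuracy).

Default effect sizes (ms): `b_cl = −33` (residual contingency effect),
`b_pcl = −23`, `b_rev = +26` (reversal cost; the CL×PCL product coefficient
is `−2·b_rev ≈ −52`), `b_er = −56`, `b_ca = −9`, `b_cl_ca = −12` (fitted
CL×CA ≈ −24), `b_er_ca = +2`, `tau = 45` (which puts the intercept's 95% CI
at roughly ±14 ms with 40 participants).

### Residual noise and calibration

Residual noise is a zero-mean shifted lognormal,
`sigma·(exp(shape·Z) − E)/SD`, standardized so its SD is `sigma` exactly;
`noise_shape = 0` degrades to Gaussian.  `sigma = 90` and
`noise_shape = 0.55` were calibrated once, jointly with `mu0 = 460`, so that
a default-size study lands near the reference summary of valid trials:
mean ≈ 419 ms (the baseline `mu0` sits ~40 ms higher because the fast
levels dominate under the .8/.2 bias and the half-difference codes are not
mean-zero over trials), SD ≈ 90 ms, upper-fence outliers ≈ 2.6 %, valid
fraction ≈ 0.86.

One feature of real data is deliberately not reproduced: pooled post-trim
skewness.  With Normal participant intercepts (the model's contract), the
per-participant Tukey fence caps within-participant skewness near 0.55 at a
2.6 % trim rate, and pooling across symmetric participant means dilutes
pooled skewness to ≈ 0.40.  A pooled skewness of 0.60 at that trim rate
would require right-skewed *between*-participant structure (slow
participants both shifted and stretched), which the generator does not
model.  Likewise the generator produces no anticipatory (<100 ms) responses,
so the 100 ms floor exists but essentially never fires at defaults.

## Trial coding

* **CL**: classification of the ordered stimulus pair (n−1, n) against the
  scheme's high-successor map; undefined on a block's first trial.  CL and
  PCL are coded from stimuli — the contingency is defined on dot positions —
  which equals response coding on correct trials.
* **PCL**: CL of trial n−1; undefined on a block's first two trials.
* **REV**: stimulus(n) = stimulus(n−2); equivalently the hf–lf / lf–hf
  cells of CL×PCL (checked exhaustively over all 12 two-step paths).
* **ER**: the most recent earlier pair *in the same block* starting with the
  same response as the current pair; `match` if its second response equals
  the current response.  The search runs over executed responses, not
  stimuli (they differ on error trials — the construct is response–response
  binding), and includes practice trials.  Undefined when no earlier pair
  started with this response.
* **CA**: the participant's end-of-session judgment for the current ordered
  pair type; undefined wherever CL is.

Undefined labels are represented explicitly (missing), never imputed, and
excluded from contrast construction.

Contrasts use weighted effect coding computed on the analysis set of each
fit: with `n_hi` high and `n_lo` low trials, weights are `+n_lo/N` and
`−n_hi/N` — mean exactly zero, difference exactly 1 — so coefficients are
condition differences in ms.  Interaction columns are products of the
centered main-effect columns.  Two consequences worth knowing: products are
orthogonal to their parents only under independent/balanced predictors, and
under imbalance the product columns shift the main-effect estimands slightly
away from the generative `b` (e.g. the CL main effect absorbs
`2·b_cl_ca·(P(CA+) − ½)`).  The recovery harness accounts for this by
projecting the injected surface onto the realized design.

## Exclusion cascade

Applied to test trials only, in order, each trial tagged with the first
criterion it triggers (so counts are disjoint and reconcile with the total):

1. **current_pair_error** — the current response is an error.  Trials
   *following* an error are retained if answered correctly; with ~4 %
   errors this reproduces the reference pipeline's accounting (≈3.9 %
   error exclusions, ≈8 % retrieved-pair exclusions, ≈85 % valid), which a
   pair-wise rule (dropping both the error trial and its successor) cannot.
2. **first_pair_in_block** — no episode can be retrieved (ER undefined), or
   the pair contingency itself is undefined on a block-initial trial.
3. **prior_pair_error** — an error occurred on either trial of the
   retrieved pair, contaminating the retrieval code.
4. **rt_outlier** — RT below a fixed 100 ms floor or above Q3 + 1.5·IQR of
   the participant's own distribution of trials surviving 1–3.  Quartiles
   use linear interpolation between order statistics (the most common
   convention; the report records it).  The fence is computed in a single
   pass, not recursively.

Which trials survive does not depend on the cascade order — only the
attribution of reasons does.

## Inference

Models are linear mixed models with one random intercept per participant,
estimated by maximum likelihood (not REML) so BIC values are comparable
across fixed-effect structures; `BIC = −2·llf + (p_fixed + 2)·ln(n)`.
Random slopes are not modeled.  Fixed-effect t statistics use
`df = n_obs − p_fixed`; at tens of thousands of trials this is
indistinguishable from finer approximations, and no attempt is made to
reproduce any particular printed df convention.  95% CIs are
`coef ± t_crit(df)·se`.  All three stepwise models are fitted on one common
analysis set (trials with every label of the largest model defined), with
contrasts recentered on that set.  The subgroup analysis refits
`CL + PCL + CL×PCL + ER` separately for awareness-correct and
awareness-incorrect trials; including PCL and its product in the subgroup
models is this package's choice.  Exactly noiseless data (an interpolating
fit, for which the ML objective is unbounded) short-circuits to the exact
least-squares solution with zero variance components and undefined BIC.

Awareness is tested with a one-sample t test of per-participant judgment
accuracy against .5 (df = n − 1).  Power for the residual-effect design uses
the noncentral t distribution (noncentrality `d·√n`, df `n − 1`); the
default is one-tailed because the hypothesis is directional — at d = .5,
n = 40, α = .05 the exact power is 0.9281 (two-tailed: 0.8694).

### Parameter recovery and selection-aware estimands

`recover_parameters` repeats simulate → code → exclude → fit on fresh
studies and reports per-coefficient bias, RMSE and 95%-CI coverage.  Two
subtleties make the naive comparison against the injected `b` misleading,
and both are handled by computing per-replicate *estimands*:

1. Weighted-effect product columns under imbalance shift main-effect
   estimands (see above).  The estimand is the projection of the injected
   noiseless surface onto the realized contrast design.
2. Upper-fence trimming removes the slowest surviving trials; conditions
   whose mean sits closer to the fence (mismatch, lf) lose more right tail,
   attenuating every coefficient (the ER effect by ~4 ms at defaults).
   Since the harness knows the ground truth, it computes the conditional
   mean of surviving trials exactly — injected surface plus the closed-form
   truncated mean of the shifted-lognormal residual at each trial's fence —
   and projects that.

Coverage is evaluated against these estimands; bias is reported against
both the estimand and the raw injected value, so the attenuation itself is
visible in the report rather than hidden.  At default effect sizes, 200
replicates of a 10-participant × 300-trial design give coverage 0.90–0.98
for all coefficients and |bias| vs. estimand below 2 ms.

The decomposition identity is validated on an error-free 200,000-trial
simulation, where the retrieval-probability gap between hf and lf pairs is
exactly `p_hi − p_lo`; with keying errors the executed-response process
drifts slightly off the stimulus-coded contingency (gap ≈ 0.56 rather than
0.60 at 4 % errors), which correspondingly inflates the identity residual.

## Problem sizes used in the validation suite

Simulation-based tests run at the smallest sizes that make their assertions
sharp: the transition calibration uses one 100,000-trial sequence, the
retrieval-coder cross-check 1,000 sequences of length 100, the decomposition
identity 20 participants × 10,000 trials, recovery 200 replicates of
10 × 300, and the cascade/descriptives checks one full 40 × 930 study.

## Limitations

* No sequential dynamics: no learning curves, fatigue, post-error slowing
  or speed–accuracy trade-off; trials are exchangeable given their codes.
* Awareness judgments are independent across the six sequence types and
  share one accuracy parameter; real judgments are likely correlated within
  the hf/lf pair of a triadic family and more accurate for frequent
  sequences.
* Condition-independent errors only; the error-rate analysis of conditions
  is therefore out of scope.
* Between-participant variation is symmetric (see calibration note), so
  pooled-skewness statistics undershoot skewed real samples.
* First-order contingencies only; second-order (triplet) retrieval and
  deterministic sequence grammars are out of scope.
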