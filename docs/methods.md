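# Methods

## Task generator

The generator reproduces the statistical structure the analysis assumes: two
contexts × 30 individuals × 10 trials (600 trials, 60 alternating blocks
starting with GC), each individual choosing its preferred color with
probability 0.8. In the GC all individuals share one preferred color
(purple by convention; purple = 1 throughout); in the AC exactly half prefer
each color, with the assignment shuffled per seed.

Two outcome modes are provided. `bernoulli` (default) draws each outcome
i.i.d. at the individual's preference probability. `balanced` places exactly
round(0.8 × 10) = 8 preferred-color outcomes in every block in shuffled
order — the mode used when a check needs exact frequencies.

The original task was self-paced; the synthetic session uses a fixed event
grid instead: choice onsets every `iti` = 4.0 s with the outcome 1.5 s after
each choice. These onsets matter only to the fMRI design (they set regressor
spacing relative to TR 2.6 s and the 128 s filter cutoff) and are
configurable. One master seed spawns independent named streams (group
assignment, outcomes, agent choices, BOLD noise) so any stage can be re-run
in isolation.

Simulated subjects guess via a sigmoid rule, P(purple) =
σ(β(V_purple − V_blue)) with V_blue = 1 − V_purple, where β ≥ 0 is the
choice precision (β = 0: uniform guessing). A `matching` rule
(P(purple) = V_purple) is also available; see *Learning-rate fitting* for
why it matters. What the generator deliberately does not emulate: reaction
times, timeouts, face stimuli, payment — nothing downstream consumes them.
Passing tests therefore validate the statistical machinery on data that
match the task's *design*, not idiosyncrasies of real subjects (lapses,
serial biases, scanner physiology).

## The DP-mixture learner (M1/M4)

Counts per cue are kᵢ purple outcomes of nᵢ trials. The model is a Dirichlet
process mixture of Binomials: θᵢ | G ~ G, G ~ DP(α, Beta(1, 1)). Marginal
likelihood of a cue under the base is the Beta-Binomial
C(n, k)·B(k + 1, n − k + 1) = 1/(n + 1).

Gibbs sampling resamples each θᵢ from its full conditional: copy an existing
atom θⱼ (j ≠ i) with probability ∝ Binomial(kᵢ; nᵢ, θⱼ), or draw from the
single-cue posterior Beta(1 + kᵢ, 1 + nᵢ − kᵢ) with probability
∝ α/(nᵢ + 1). Weights are computed in log space (guarding against underflow
when atoms sit near 0/1); the shared Binomial coefficient cancels. The inner
loop is a numba kernel; the chain is initialized from the independent
single-cue posteriors. Correctness is established two ways: single-cue
conjugacy (where the sampler draws i.i.d. from the exact posterior) and,
for ≤ 4 cues, exhaustive enumeration over all set partitions scored by
CRP(partition; α) × per-block Beta-Binomial marginals
(`exact_partition_posterior`), against which Gibbs partition probabilities
and predictive means agree within Monte-Carlo error.

Per trial, the chain is re-run from a fresh state on all outcomes strictly
before that trial, with a per-trial seed derived from the config seed —
reproducible and embarrassingly parallel, at the cost of re-burning each
trial. M1 restricts the chain to the current context's cues; M4 pools all
cues (`pool_contexts=True`). Derived quantities per trial:

- value v = posterior-predictive mean of θ for the current cue (its θ column
  if observed, the CRP predictive mixture for a new cue);
- ambiguity H = Shannon entropy of the predictive θ samples histogrammed
  into B equal-width bins on [0, 1] (half-open bins, last closed;
  0 ln 0 = 0; 0 ≤ H ≤ ln B). B defaults to 10; no absolute entropy value is
  asserted anywhere, only bin-robust orderings (AC > GC);
- surprise s = −ln p̂(realized outcome), with p̂ clamped at 1e−12;
- prediction error δ = realized reward − choice-conditioned value
  (v if the subject chose purple, 1 − v otherwise); NaN without choices;
- risk r = v(1 − v), the Bernoulli outcome variance at the predicted value.
  The posterior variance of θ is available via
  `risk_measure="posterior_variance"` — the two capture different notions
  (objective outcome randomness vs. parameter uncertainty) and the outcome
  variance is the default because "risk" conventionally denotes the former.

α is fixed at 1.0 (exposed in config; hyperparameter learning is out of
scope). Chain defaults are S = 2000 samples after 500 burn-in sweeps.
Trajectory-heavy simulation studies use lighter chains — S = 500/100 burn-in
for the ambiguity-pattern and fMRI studies, S = 300/60 for behavioral cohort
value streams — since a value stream's Monte-Carlo error (~0.02) is
negligible relative to choice noise. These problem sizes are stated here as
the package's own simulation-design choices.

One documented discrepancy: a published description of this sampler's
"simplest algorithm" says to copy a *uniformly* chosen existing atom; the
normative full conditional weights existing atoms by likelihood, which is
what this package implements and what the enumeration oracle confirms.

## Rival models

M2 and M3 are delta-rule learners (V ← V + α_lr(λ − V), all values
initialized at 0.5) with counterfactual coupling. M3 also maintains values
for the two context cues; only cues present on a trial are updated, and the
trial value is the *mean* of face and context values — a sum would break the
V₀ = 0.5 initialization and leave [0, 1]; the mean keeps both. M5 is the
per-cue conjugate mean (1 + k)/(2 + n). When every context contains a single
observed cue, M1's predictive collapses to the same conjugate posterior —
the regime tying the two model families together.

## Learning-rate fitting

α_lr is fit by exhaustive grid search (default step 0.01 on [0, 1], ties to
the smaller rate) minimizing E = Σₜ (cₜ − Vₜ)², with cₜ = 1 coding a purple
guess. A property worth knowing: the population minimizer of E matches the
generating rate only when E[cₜ] = Vₜ, i.e. when choices *probability-match*
the value. Under a steep sigmoid rule the choice probabilities are a
steepened distortion of V and the fit is biased toward faster rates
(noise-free analysis: truth 0.3 → argmin ≈ 0.55 at β = 20). Recovery
studies therefore simulate probability-matching agents, and assess recovery
on a 0.1 grid — one grid step at the estimator's sampling resolution for a
600-trial session (fitted-rate sd ≈ 0.03–0.06). In the cohort analysis,
where fitted M2/M3 streams serve only as nuisance regressors, the bias is
immaterial.

## Behavioral model comparison

Per subject, choices are regressed on the selected models' value streams
plus a constant. Predictors are z-scored within subject (the streams are
highly correlated, r ≈ 0.9 between M1/M4/M5; standardization keeps the
design conditioned and makes coefficients comparable; the design's condition
number is reported). Fitting is Newton/IRLS (statsmodels) to 1e−8
log-likelihood tolerance; on separation or rank deficiency the model is
refit with a small quadratic penalty (λ = 1e−3, intercept unpenalized) and
flagged — never silently. Subjects that still fail are dropped with a logged
reason. Group level: two-tailed one-sample t (df = n − 1) per coefficient —
a zero-spread coefficient vector is flagged degenerate (p = 0 when its mean
is nonzero) — and Pearson r between the M1 coefficient and total reward.
Simulated cohorts default to 19 subjects (behavioral) and 14 (fMRI second
level), sharing one outcome sequence per cohort as in the original paradigm;
this also means M1's value stream (which depends only on outcomes) is
computed once per cohort.

## fMRI design and recovery

Six modulated delta-event streams: risk, choice-conditioned value and
entropy at choice onset; surprise, signed prediction error and the
correct/incorrect outcome at outcome onset. Modulators are mean-centered per
run before convolution (separating parametric from onset main effects);
serial orthogonalization is deliberately not applied (a switch exists via
column choice — OLS on the full design already yields partial effects).
Delta events (not boxcars) are used throughout.

The HRF is the canonical double-gamma: gamma densities peaking at 6 s
(response) and 16 s (undershoot), unit dispersions, undershoot ratio 1/6,
32 s support, evaluated on a microtime grid of TR/16 and peak-normalized;
events are binned at microtime, convolved, and sampled at scan onsets
(events past the last scan are truncated with a warning). High-pass
filtering residualizes against a unit-norm discrete-cosine basis with
periods ≥ 128 s (constant included); the cutoff must exceed 2·TR and leave
positive residual dimensions. Estimation is per-voxel OLS with df =
n − rank(X); rank deficiency is an error naming the dependent columns. AR(1)
noise can be simulated but estimation stays OLS.

The recovery study plants a per-subject entropy effect
~ Normal(0.5, 0.2) (arbitrary BOLD units) in a 20-voxel "hippocampus-like"
group of a 60-voxel synthetic brain with unit white voxel noise, builds one
shared design from a simulated session (~196 scans at TR 2.6 s), fits first
levels for 14 subjects per replicate, averages the entropy coefficient over
the ROI and applies the second-level t-test (df = 13). With these settings
the entropy effect is recovered with power ≈ 1 while the five unplanted
regressors reject at ≈ 5%, and the null (effect 0) rejection rate is ≈ 5%.
The between-subject effect sd (0.2) dominates the within-subject OLS error,
so the second-level test is effectively exact under its normality
assumption. Optionally the planted effects can be coupled to each subject's
total reward to exercise the effect-vs-reward correlation analysis.

## Known limitations

- Re-running the chain per trial makes trajectory cost quadratic-ish in cues
  per context; a warm-start option would trade reproducibility for speed.
- The synthetic BOLD has no spatial structure, motion, or physiological
  noise; motion confound columns are placeholders carrying no signal.
- Absolute entropy values depend on the bin count B; only orderings are
  meaningful.
- No hierarchical coupling across contexts (M1 treats them independently),
  and α is not learned.
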