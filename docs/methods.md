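# Methods

## Model

Observations are per-scan matrices Y ∈ R^{T×R} of parcellated BOLD time
series (T timepoints, R regions). The generative model is an
explicit-duration hidden semi-Markov chain with multivariate Gaussian
emissions:

- K latent states, each with mean μ_s ∈ R^R and SPD covariance Σ_s;
  Y_t | S_t = s ~ N(μ_s, Σ_s), conditionally independent across t.
- On entering state s, a dwell d is drawn from a pmf p_s(d) on d ≥ 1;
  the chain emits d observations from state s, then jumps to state
  s' ≠ s with probability A_{ss'} (A has a zero diagonal and stochastic
  rows). The first state is drawn from an initial distribution π.
- Dwell pmfs are truncated to 1..`max_dwell` and renormalised.
  `max_dwell` defaults to 50 timepoints (100 s at TR = 2 s), far beyond
  any plausible dwell at the default dwell means; truncation bounds the
  recursions at O(T·K·max_dwell) per scan.

The default dwell family is the **shifted Poisson**: d − 1 ~ Poisson(λ_s),
so d ≥ 1 always and E[d] = 1 + λ_s. It is the standard explicit-duration
choice with a one-parameter closed-form M-step; a truncated nonparametric
(`TabularDwell`) family is available through the same interface (and is how
the test suite reduces the model to an ordinary HMM by putting all dwell
mass at 1).

### Boundary conventions

The first dwell is assumed to start at t = 0 (no left censoring). The
final dwell is **right-censored**: a final run of length d contributes the
survival probability P(D_s ≥ d) rather than the pmf. This matches the
sampler, which truncates the last drawn dwell at T, so the likelihood is
exactly the marginal law of the generative process. Downstream summaries
drop the first and last dwell of each decoded scan for the same reason:
their true lengths are unobserved.

### Estimation

Parameters are fit by EM on all scans pooled; scans are independent
sequences sharing parameters and are never concatenated.

- **E-step**: explicit-duration forward and backward recursions in log
  space (no scaling-factor variant; this keeps the implementation directly
  comparable to the exhaustive-enumeration oracle used in tests). Segment
  posteriors yield per-timepoint state weights, expected transition counts,
  expected initial-state counts, and an expected duration histogram. For
  the censored final segment the duration weight is distributed over true
  durations d' ≥ d proportionally to the conditional pmf, which keeps the
  duration update a proper EM step and the log-likelihood trace monotone
  (asserted to tolerance 1e−6 in tests).
- **M-step**: closed forms for μ, Σ (with a ridge of 1e−6 × mean diagonal
  added every iteration to guard small-responsibility states), A
  (normalised expected transition counts, zero diagonal), π, and the dwell
  parameters (weighted-mean duration − 1 for shifted Poisson). A state
  whose total responsibility falls below 1e−8 is re-seeded from the
  worst-fit timepoints and logged.
- **Initialisation**: k-means on pooled timepoints for means/covariances,
  uniform off-diagonal transitions, dwell mean 5, uniform π.
- **Multi-start**: `n_starts` (default 5) k-means seeds derived from the
  master seed; the best final log-likelihood wins. Tests and the
  acceptance script use 1–2 starts because their simulated states are well
  separated and EM converges to the same optimum from any start there.
- **Stopping**: relative log-likelihood change below `tol` (default 1e−5)
  or `max_iter` (default 100).

Viterbi decoding runs the same recursion with max in place of sum; ties
break toward the lower state index, then the shorter current dwell (both
realised by first-occurrence argmax scan order). The decoded path's log
joint probability is returned alongside the labels.

### State-count selection

Candidates K in a range (default 3–7) are each fit by the same multi-start
protocol; the selected K maximises the minimum pairwise Euclidean distance
between fitted state means ("maximin distinctiveness"), ties toward
smaller K. Distances use raw mean vectors; a z-scored variant is exposed
by flag. This heuristic presumes that merging two genuinely distinct
states costs separation while splitting one state produces two nearby
means. For equidistant states the cost of merging is exactly the
√3/2 vertex-to-midpoint factor, which is why the recovery simulations
place generating means on a regular simplex (`geometry="simplex"`); with
strongly elongated mean configurations the heuristic can legitimately
prefer a smaller K, a known limitation of the rule itself.

## Dynamics summaries and inference

From each decoded scan: occupancy (100·count/T per state), transition
frequency (entries per state; the state at t = 0 is not an entry —
an inclusive flag exists), and dwell times (run lengths with the first and
last runs dropped). Occupancy and transition counts are averaged over a
participant's scans to give one value per participant; dwells are pooled.

Group tests are permutation tests at the **participant** level (both scans
of a participant move together):

- occupancy / transitions: two-sided test on |mean(mindfulness) −
  mean(control)|, add-one p-value (1 + #{|null| ≥ |obs|})/(B + 1),
  B = 500 by default. Note the add-one formula's smallest attainable
  p-value is 1/(B+1) ≈ 0.002 at B = 500.
- dwell distributions: pooled group dwells are smoothed onto the integer
  grid 1..max_dwell with a Gaussian kernel (Silverman's-rule bandwidth on
  the integer data, floored at 1e−10 and renormalised so KL is finite
  everywhere); the statistic is the symmetrized KL divergence
  (KL(p‖q)+KL(q‖p))/2 — symmetrization removes the arbitrary direction
  choice; directed variants are available by flag. Permutations that leave
  a group without dwells are redrawn and counted.
- Benjamini–Hochberg FDR (statsmodels) is applied within each property
  family (the K states of occupancy; of transitions; of dwell-KL).

## State characterization

Each state's Σ_s is converted to a correlation matrix (the weighted
network); negative off-diagonal weights are dropped ("positive network",
weighted, not binarised — only the sign is thresholded). Communities come
from Newman's leading-eigenvector spectral bisection of the
resolution-scaled modularity matrix B = A − γ kkᵀ/2m (γ = 1 by default),
with deterministic greedy single-vertex fine-tuning after each split and
recursion until no split increases Q. Spectral bisection is a heuristic:
tests assert Q ≤ the exhaustive maximum on small graphs and exact recovery
on canonically modular ones. Activity maps z-score each region's K state
means across states (SD floor 1e−12 maps constant regions to 0), i.e.
activity relative to the other states, not to a baseline.

## Outcome association

For each state × measure (occupancy %, transition count), a linear mixed
model `stress ~ measure + group + measure:group + avg_drinks` with a
per-participant random intercept is fit by REML (statsmodels MixedLM),
reference group mindfulness. Wald t statistics use the residual
degrees-of-freedom approximation df = n_obs − n_fixed. If the
random-intercept variance collapses (or the REML likelihood is degenerate,
e.g. noiseless data or singleton participants), the fit proceeds as its
OLS boundary case with a warning. Interaction p-values are FDR-screened
across the state × measure family; flagged models are refit within each
group (`measure + avg_drinks` + random intercept).

## Synthetic cohorts

`CohortDesign` defaults emulate the target study: 15 + 17 participants,
2 scans each, T = 281 usable volumes (297 acquired − 10 settle-in − 3 + 3
edge trim) at TR = 2 s, R = 36 regions, K = 6 states, mean dwell 5
timepoints. Emission parameters are shared across groups; groups differ
only in dynamics, via two knobs applied to one designated state for
group 1: a longer dwell mean (9 vs 5) and extra transition mass into it
(each other state's row puts 0.45 on it). The baseline transition matrix
is uniform off-diagonal so that the contrast is concentrated where it is
designed, not where a random draw happens to put it. Stress scores are
intercept + Σ_k slope_k·occupancy_k% + participant random intercept +
noise, clipped to the 1–10 instrument scale; the default intercept (4.5)
and designated slope (−0.06/pp) keep scores inside the scale over the
realised occupancy range, matching the magnitude of the association the
pipeline is meant to recover.

The contrast design was chosen from the closed-form stationary occupancy
of the semi-Markov chain (occupancy_k ∝ π̃_k·E[d_k], π̃ the embedded-chain
stationary distribution): because occupancies sum to 100%, raising the
designated state's occupancy necessarily pushes every other state down by
roughly Δ/(K−1), and entry rates are coupled through the mean segment
length. Exact nullity of all other states is therefore impossible in this
model family — the designed signature is "only the designated state is
significant on all three properties", and the end-to-end test checks
exactly that.

What the generator does **not** emulate: hemodynamic convolution,
autocorrelated within-state noise, scanner drift or motion artifacts, and
subject-specific emission parameters. Passing tests therefore demonstrate
correctness of the estimation and inference machinery under the model's
own assumptions, not robustness to real fMRI noise structure.

## Problem sizes and numerical choices

Simulation-based tests run at reduced dimension so the full suite
completes in minutes on one CPU: recovery uses K=3, R=6, 20 scans of
T=200; selection uses candidates 2–5 over 8 scans of T=150; the
end-to-end designed-effect check uses 20 replicates of a 10+10 × 2-scan,
T=200, R=6, K=6 cohort with 500 permutations. These sizes keep every
group-size-driven power calculation qualitatively faithful to the study
design while staying cheap. Other numerics: all recursions in log space;
covariance ridge 1e−6 × mean diagonal; dwell pmf floor via truncation
renormalisation; KDE floor 1e−10; activity-map SD floor 1e−12; modularity
split threshold 1e−12.

## Known limitations

- The maximin selection rule is geometry-sensitive (see above).
- The dwell M-step fits the untruncated shifted-Poisson MLE to the
  expected duration histogram; with `max_dwell` far above the dwell mean
  the truncation bias is negligible, but a `max_dwell` close to the mean
  dwell would bias λ downward.
- Hard Viterbi labels feed all summaries (by design); posterior-weighted
  occupancy is available via `posterior_marginals` but is not part of the
  analysis path.
- MixedLM Wald p-values use a residual-df approximation, not
  Satterthwaite/Kenward–Roger.
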