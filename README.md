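# brainstates

State-based dynamic functional-connectivity analysis of multi-subject fMRI
ROI time series, built around an explicit-duration hidden semi-Markov model
(HSMM).

## The problem

Static functional connectivity summarises a whole scan with one correlation
matrix, assuming relationships between brain regions never change. During a
10-minute recovery scan — for instance after an acute stressor, with or
without a guided mindfulness exercise — that assumption is implausible:
participants drift between regimes of focus and distraction. A state-based
model instead posits a small set of recurring latent **brain states**, each
a multivariate activity pattern with its own covariance (hence its own
weighted network), and asks *when* each participant visits each state, *how
long* they stay, and whether those dynamics differ between groups or track
a behavioural outcome.

## The model

Each scan's observation at timepoint *t* is an R-vector of ROI signals
Y_t. Conditional on the hidden state S_t = s,

    Y_t ~ N(mu_s, Sigma_s),        s = 1..K

and the latent process is *semi-Markov*: on entering state s the chain
draws a dwell time d from a state-specific distribution on {1, 2, ...}
(shifted Poisson by default), stays d timepoints, and then jumps to a
different state according to a zero-diagonal transition matrix. Unlike an
ordinary HMM, dwell times are modelled explicitly rather than forced to be
geometric. One parameter set is fit to all scans pooled (states are
population-level); scans remain independent sequences.

The pipeline stages, each an importable module:

| stage | module | what it does |
|---|---|---|
| I/O & types | `brainstates.io` | manifests, scan matrices, trimming conventions, config |
| simulation | `brainstates.synthetic` | ground-truth cohorts with a designed group contrast |
| model | `brainstates.hsmm` | forward/backward/Viterbi recursions, EM fitting |
| state count | `brainstates.selection` | maximin pairwise state-mean distance over a K range |
| summaries | `brainstates.dynamics` | occupancy %, entries per state, dwell-time lists |
| inference | `brainstates.inference` | participant-level permutation tests, KL divergence, BH-FDR |
| networks | `brainstates.characterize` | covariance→correlation, Newman spectral modularity, activity z-maps |
| outcome | `brainstates.associate` | mixed-effects models of stress vs occupancy/transitions |

A thin CLI (`brainstates simulate | fit | select-k | decode | summarize |
group-test | characterize | associate | pipeline`) wraps the same
functions for shell use.

## Worked example

`examples/01_simulate_fit_decode.py` simulates a 16-scan cohort from a
known 3-state model, refits it by EM and decodes every scan:

```
cohort: 16 scans, T=150, R=6, true K=3
EM converged=True after 3 iterations; loglik -20995.6 -> -20959.2
min pairwise state-mean distance: 8.15 (generator separation was 6.0)
Viterbi label accuracy vs ground truth: 100.0% (2400 timepoints)
```

The fitted state means sit 8.15 apart (in within-state noise units), and
the decoded paths reproduce the generating paths exactly — with
well-separated states the model identifies both the states and their
timing. The other examples walk the group-difference tests
(`02_group_dynamics_tests.py`), the modularity/activity characterization
(`03_characterize_states.py`), and the stress association
(`04_stress_association.py`); each prints its result table with a line of
interpretation.

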