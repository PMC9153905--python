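# Methods

## The task being modelled

The stop-signal task (SST) is a two-choice reaction paradigm for
measuring response inhibition. Participants press the key matching a go
stimulus (the letter X or O) as fast as possible; on 25% of trials a
stop signal (a box around the stimulus) follows the go stimulus after
the stop-signal delay (SSD), instructing them to withhold the response.
The SSD adapts by a 1-up/1-down staircase — +50 ms after a successful
stop, −50 ms after a failed one — so successful stopping converges on
~50%. At that point the mean-method estimator of the stop-signal
reaction time (SSRT),

    SSRT = mean go RT − mean SSD,

recovers the latency of the inhibitory process under the independent
horse-race model: the response escapes on a stop trial iff the go
process finishes before SSD + stop latency.

The engine reproduces the web-based variant this package models:
a 32-trial practice block plus 3 × 64 experimental trials; per-block
stop counts exact, stop trials never consecutive within a block;
practice trials with trial-by-trial feedback (4250 ms inter-trial
interval = 1000 blank + 250 fixation + 1000 stimulus + 2000 feedback)
and experimental trials with block-end feedback only (2250 ms ITI).
Two SSDs are recorded per stop trial: the staircase-scheduled
("programmed") value and the "meta" value as a participant machine's
real-time clock would measure the actual stop-signal onset. Scoring
uses the meta SSD by default (`ssd_source="programmed"` switches).

## Design choices where the task description is open

- **SSD bounds**: floor 0 ms, ceiling 950 ms. Observed SSD ranges in
  practice stay far from both; the ceiling keeps the stop signal inside
  the 1000 ms stimulus window with a 50 ms margin.
- **Staircase reset**: the experimental staircase restarts at the
  250 ms initial SSD after practice, making sessions comparable
  regardless of practice performance (`carry_practice_ssd=True`
  reverses this).
- **Response window**: the 1000 ms stimulus presentation. Responses
  that would fall later are counted as omissions; no responses are
  accepted during the post-stimulus blank.
- **Adjacency rule scope**: "no consecutive stop trials" is enforced
  within blocks; the block-feedback screens break adjacency across
  boundaries (`stops_span_blocks=True` extends the rule across them).
- **Schedule construction**: stop positions are drawn uniformly over
  all arrangements with exact counts and no adjacency, using the
  bijection between k non-consecutive positions among m and k-subsets
  of m−k+1 slots. This is exact and O(n); naive shuffle-and-reject
  has vanishing acceptance probability for long blocks.
- **Go stimulus**: independent uniform X/O, not forced 50/50.
- **Exclusion inequalities** are strict (stop accuracy <25 or >75%,
  go errors >10% of go trials, SSRT <50 ms, failed-stop RT mean — per
  key-accord stratum — greater than the go RT mean); boundary values
  retain. One violating stratum suffices for the race rule; sessions
  with no trials in a stratum skip that rule.
- **Go-RT mean**: correct go responses only; wrong-key RTs are
  reported as their own variable (`include_go_errors_in_rt` folds them
  in). The intraindividual SD is the n−1 sample SD of the same RTs.

## The participant model

Go finishing times are ex-Gaussian — Normal(go_mu, go_sigma) plus
Exponential(go_tau) — the standard positively-skewed RT model. The stop
process latency is Normal(stop_mu, stop_sigma). Failure channels:
`p_go_omission` (the go process never launches; on stop trials this
yields a trivially inhibited trial), `p_choice_error` (wrong key), and
`p_trigger_failure` (the stop process never launches; default 0, since
the mean-method SSRT ignores trigger failures — the knob exists to
study that bias).

Cohorts draw per-participant parameters from Normal cohort
distributions (clipped to their valid ranges). The latent stop latency
is drawn jointly for the two sessions of a test-retest design from a
bivariate normal with configurable correlation (default 0.6); the
"independent" (out-of-lab) condition adds a stop-latency shift
(default +22 ms) and a choice-error increment (default +0.008), the
directions observed when web-based testing leaves the laboratory.
Counterbalanced order alternates participants between arms. The clock
model adds Normal(offset_mean, offset_sd) ms to each programmed SSD
(optional frame quantization), emulating browser/OS timing error; the
race is run against the meta SSD, because that is when the stop signal
actually appeared.

Cohort defaults were set from the descriptive regime of healthy young
adults on this task — mean go RT ≈ 490 ms (go_mu 420, go_tau 70),
within-session RT SD ≈ 83 ms (σ² = go_sigma² + go_tau²), SSRT ≈ 240 ms,
go errors ≈ 1.4%, omissions ≈ 0.6% — and are configuration, not
constants.

### What the simulator does and does not emulate

It reproduces the statistical structure the analysis pipeline consumes:
skewed go RTs, a race-consistent relation between stop accuracy, SSD
and failed-stop RTs, staircase dynamics, cross-session correlation, a
condition effect, and clock offsets between programmed and measured
SSD. It does not model practice/fatigue drifts within a session,
attention lapses beyond a constant omission rate, context-dependent
strategy shifts (e.g. post-stop slowing), or hardware-specific frame
timing. Passing recovery tests therefore validates the estimator and
pipeline logic under the stated generative assumptions, not the
behaviour of any human sample.

## Estimator properties worth knowing

The mean-method SSRT is exactly mean go RT − mean SSD, and the
staircase equilibrates near the *median* of the race margin. With
skewed go RTs the estimate therefore carries a positive bias of roughly
(mean − median) of the go distribution: ≈ +8 ms at the default
ex-Gaussian (τ = 70), ≈ +18 ms at a heavier tail (τ = 90). The
parameter-recovery tests bound the error at the defaults (±15 ms over
10 participants); the integration method, which avoids this bias, is
deliberately out of scope because the pipeline mirrors the mean-method
design.

## Statistics

- Paired comparisons: one-sample t on condition differences; 95% CI
  from the t quantile; effect size d_z = |mean diff| / SD(diff) =
  |t|/√n — the only convention consistent with the published (t, df, d)
  triples this package reproduces. Significance is flagged at the fixed
  critical P = .005 used for multiplicity control (no FDR).
- JZS Bayes factor (paired/one-sample): BF10 = ∫ f(t; ν, δ√n) dC(δ) /
  f(t; ν, 0), with C a Cauchy(0, 0.707) prior on the standardized
  effect δ and f the (non)central-t density. The two prior tails are
  folded and integrated by adaptive quadrature (SciPy `quad`,
  relative tolerance 1e-8, convergence checked at 1e-4); tests verify
  agreement with an independent fine-grid trapezoid evaluation of the
  equivalent mixing-variance (g) integral under the tan² substitution,
  and with `pingouin.bayesfactor_ttest`, to well below 0.1%.
- Evidence bands: BF10 ≥ 1 → anecdotal [1, 3), moderate [3, 10),
  strong [10, 30), very strong [30, ∞); BF10 < 1 mirrors with the
  reciprocal cuts (1/3, 1/10, 1/30 read as 0.33/0.10/0.03). Boundary
  values go to the stronger band; BF10 = 1 is labelled anecdotal for H1
  by convention.
- Correlations: Pearson r, two-sided p, Fisher-z CI with SE 1/√(n−3).
  Subgroup (order-arm) CIs use the subgroup n. |r| = 1 is clamped to
  keep the transform finite (point interval).
- Welch t with Satterthwaite df; Fisher exact two-sided p by
  hypergeometric summation (the p-summation convention); Shapiro-Wilk
  is exposed as a convenience normality check.
- Study analysis uses pairwise-complete participants per variable
  (strata like incorrect-key failed stops are missing for some
  participants), reducing df per row; rows with <2 complete pairs or
  zero-variance differences are reported as not estimable rather than
  dropped.

## Numerical / degenerate-input conventions

Zero-variance differences, all-zero contingency tables, empty logs or
logs missing a trial stratum raise typed errors naming the problem.
Staircase clamping at the floor/ceiling is defined behaviour, not an
error. Trial-log CSVs round-trip byte-identically (floats written with
`repr`), and every cross-field rule (RT iff responded, SSD iff stop
trial, key accord matching the outcome) is enforced both at
construction and on read, with offending line numbers reported.

## Reproducibility and problem sizes

All randomness flows from numpy `SeedSequence`; studies derive
per-participant, per-session streams with counter-based spawn keys
(participant index, session index), so enlarging a cohort never
perturbs existing participants' data. The test suite simulates up to
1,000 default sessions for conservation properties, 200 sessions for
the staircase convergence property, and ten-participant cohorts for
recovery checks; `scripts/acceptance.py` re-derives the Bayes factors
by quadrature and the staircase property from 200 fresh sessions.

## Known limitations

- The mean-method skew bias above is inherited by design.
- Cohort parameter draws are independent across fields (no go/stop
  parameter correlations across people).
- No within-session nonstationarity; no dropout mechanism, so the
  recruited → completed-both funnel is flat in simulated studies.
- The Bayes factor covers the paired/one-sample design only.
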