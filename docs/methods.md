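# Methods

## The generative process

A session is a sequence of N = 380 binary stimuli (A/B) from a first-order
Markov chain with two free parameters, the transition probabilities
θ_A|B = p(A after B) and θ_B|A = p(B after A). The parameters are
piecewise constant: "chunks" of the sequence share one (θ_A|B, θ_B|A)
pair, and at hidden changepoints ("jumps") both are redrawn. The
constants, all configurable on `GenerativeParams`:

| parameter | default | meaning |
|---|---|---|
| `session_length` | 380 stimuli | one block |
| `mean_chunk_length` | 75 stimuli | geometric chunk-length mean |
| `max_chunk_length` | 300 stimuli | rejection bound on chunk draws |
| `theta_low`, `theta_high` | 0.1, 0.9 | uniform prior support of each θ |
| `min_odds_ratio_change` | 4 | required change of p/(1−p) across a jump, for at least one transition |
| `question_period` ± jitter | 15 ± {1,2,3} | spacing of probability/confidence questions |

Chunk lengths are geometric on {1, 2, …} with success probability
1/75 (mean exactly 75 before truncation); draws above 300 are rejected and
redrawn, which also guarantees at least one jump per 380-stimulus block.
The final chunk is truncated at the session end. The first stimulus is
drawn fair (its likelihood is treated as θ-independent throughout, so any
fixed rule is consistent; the fair draw preserves A↔B symmetry). Question
jitter magnitude is uniform on {1, 2, 3} with uniform sign and is never
zero, following the "± 1, 2 or 3" convention; the resulting spacings cover
12–18 with mean 15. A full simulated study is 18 subjects × 4 blocks.

## The ideal observer

The observer computes, online, the posterior over (θ_A|B, θ_B|A) given
the stimuli seen so far, under the true generative model with a flat Beta
prior on each θ and an independent per-position jump probability p_J.
Its probability estimate is the posterior mean μ of the queried
transition; its confidence is the log-precision −log σ² of that
posterior. The generative rate 1/75 is used for p_J by default (the
inference prior is not otherwise identifiable from a single session;
`p_jump` is exposed everywhere and results should be read as conditional
on it).

Two independent algorithms implement the same posterior.

**Partition Gibbs sampler** (`tpinfer.gibbs`). A partition is a binary
vector J over positions 2..t; conditional on a partition the posterior
factorizes over chunks, each chunk contributing the closed-form marginal
likelihood ML = B(N_A|B+1, N_B|B+1) · B(N_B|A+1, N_A|A+1) of its
transition counts (the first stimulus of every chunk is unscored). A
single-site Gibbs sweep resamples each J_i from the two-hypothesis odds
ML(c₁)ML(c₂)p_J : ML(c)(1−p_J), in ascending position order, starting
from the no-jump configuration; 200 sweeps with 20 discarded as warm-up
are the defaults. θ posteriors are exact mixtures of last-chunk Beta
posteriors over the kept samples; windowed jump probabilities and
current-chunk-length statistics are sample averages. All marginal
likelihoods are computed in log space with log-gamma; uniform variates
are pre-generated so runs are reproducible given a seed. The sweep kernel
is numba-compiled.

**Forward–backward on a θ grid** (`tpinfer.fb`). The two θs are
discretized onto a K × K grid of interval midpoints (K = 40 by default;
midpoints avoid the {0,1} singularities and reproduce the uniform prior
variance 1/12 to 0.1%). The state transition matrix is
T = (1−p_J)·I + p_J·1·priorᵀ, so one forward step costs O(K²). The jump
branch carries a constant observation likelihood (the first stimulus of a
fresh chunk is unscored, exactly as in the chunk marginal likelihoods);
with that convention the grid observer agrees with exhaustive partition
enumeration to machine precision on short sequences, and with the Gibbs
sampler to Monte-Carlo accuracy on full sessions (question-trial means:
correlation > 0.99, RMS difference < 0.02). The backward recursion
β_{k−1} = (1−p_J)·L_k·β_k + p_J·(prior·β_k) combines with the jump/no-jump
split of the forward message into the jump posterior
γ_t(k) = p(jump at k | y_1:t); the full matrix over all horizons costs
O(N²K²), about a second per session. α and β are renormalized every step.
Windowed jump probabilities under the grid observer use the independence
approximation 1 − Π(1 − γ); exact windowed values come from the sampler.

Both observers are validated against a third, brute-force implementation
(`tpinfer.exact`) that enumerates all 2^(t−1) partitions for t ≤ 12 under
either the analytic Beta marginal likelihood or the same grid quadrature.

With p_J = 0 both algorithms collapse to the conjugate Beta posterior, and
on stationary sequences confidence grows with unit slope in the log count
of relevant observations (σ² ≈ θ(1−θ)/n).

## Jump detection

The γ matrix is thresholded (default posterior 0.25, the value selected
by maximizing informedness in a 0.01-step threshold search, exposed as
`select_threshold`); supra-threshold cells form 4-connected patches in
the (position, horizon) plane, and each patch is read out as one report
(W, Z): W is the patch's earliest horizon (the detection moment), Z the
smallest position present at that horizon. Reports are matched one-to-one
to generative jumps, greedily by |Z − jump| within a ±5 tolerance window.
Each stimulus position gets one label: a matched report's Z is a hit, an
unmatched report's Z a false alarm, an unmatched jump's position a miss,
everything else a correct rejection. Informedness is
hits/(hits+misses) − FAs/(FAs+CRs), pooled over a subject's blocks.

Under these denominators, uniformly random reports have a small *positive*
expected informedness (≈ n_reports · 2w / N), because a random report is
~(2w+1)× more likely to fall near one of the few jumps than its false-alarm
rate suggests. Chance is therefore referenced not to zero but to a
surrogate null: reports are held fixed while each block's jump structure is
regenerated (10,000 draws at full scale), and the group t-value of
informedness is compared with this null's upper tail. The surrogate
p-values are calibrated (uniform under truly random reports).

For the outcome-sorted posterior traces, hits and false alarms are
evaluated at the reported position given the stimuli available at report
time; misses and correct rejections have no report time, so the windowed
posterior at their position is averaged over the subject's observed
report latencies W − Z (falling back to a fixed latency when a subject
never reported).

## Confidence analyses

All group statistics use the two-level scheme: per-subject OLS on a
constant plus per-subject z-scored regressors, then a two-tailed
one-sample t-test of the coefficients across subjects (shuffle tests are
one-tailed). Trials with undefined regressors are dropped listwise.
Natural logarithms are used throughout.

Per-question regressors (`build_regressors`):

- **io_mean / io_confidence** — the observer's mean for the queried
  quantity p(next = A) and the log-precision of the queried transition
  (θ_A|B after a B, θ_B|A after an A).
- **model_revision** — |Δμ| of the queried transition between its two
  most recent observations (consecutive same-type transitions, not
  consecutive stimuli); undefined before the second observation.
- **log_sample_count** — log count of queried-type transitions since the
  observer's most recent detected jump location Z among reports with
  W ≤ t (counts are per transition type; a variant using agent/subject
  reports drops in by passing their report list instead).
- **entropy_relevant / entropy_irrelevant** — binary entropy of the
  generative θ of the queried / non-queried transition.
- **jump_location_uncertainty** — the posterior variance of the current
  chunk length *relative to its posterior mean*, normalized to mean 1
  over matched question ordinals pooled across sessions and subjects.
  Raw variance is unusable here: long, well-delimited chunks have large
  raw variance and high confidence, a positive confound that swamps the
  effect; the variance-to-mean ratio isolates how ill-defined the last
  jump's location is, and reproduces the expected strongly negative
  relation with the observer's own confidence.

The U-shape analysis regresses confidence on the z-scored
(estimate − 0.5)². The four-factor analysis (revision, log count,
relevant and irrelevant entropy) computes per-subject residuals of
confidence and regresses them on the observer's log-precision: a
positive residual effect indicates readout of the full posterior beyond
any heuristic combination of the four factors.

Accuracy correlations: per subject, estimation (confidence) accuracy is
the across-trial Pearson correlation with the observer's series; the two
accuracies are correlated across subjects. Trial-level accuracy is the
unsigned error, with subject confidence first affine-aligned (least
squares, idempotent) to the log-precision scale. Shuffle #1 permutes
(estimate, confidence) pairs jointly — separately for the subject and
observer series — preserving any estimate→confidence mapping while
destroying trial identity; shuffle #2 additionally permutes estimates and
confidence independently. Both nulls are distributions of the group
t-value over permutations; p is the upper-tail fraction, floored at
1/(n_perm+1). The confidence-vs-error statistic (correlation of
confidence with |estimate − generative probability|) is tested against
three reassignment nulls, each shuffling exactly one of the three
variables within subject.

## Simulated subjects

The noisy-readout agent (`AgentParams`) answers with the observer's
posterior mean plus N(0, 0.05) noise (clipped to [0,1]), confidence
−0.6 + 0.25·log-precision + N(0, 0.1) (clipped; the affine map places the
typical log-precision range ≈ 2.5–5.5 on the unit scale), a 5% lapse rate
(uniform responses), and the observer's thresholded jump reports. These
values are a plausible "attentive subject" operating point chosen for the
recovery analyses; the agent is a validation device, not a cognitive
model. What passing recovery shows: the analysis stages detect readout
structure when it is present and stay null when it is absent (the
heuristic agent). What it does not show: anything about real subjects'
noise structure — human data have response biases, probability
distortion, scale use and sequential effects the agent does not emulate.

## Problem sizes and numerical choices

Tests run the full study design (18 subjects × 4 blocks × 380 stimuli)
for the group-level analyses; cross-algorithm agreement uses 20 sessions;
enumeration oracles use sequences of ≤ 12 stimuli; surrogate and
permutation nulls use 500/200-draw versions of the 10,000-draw full-scale
nulls, and null-calibration replicates use 200-stimulus sessions with
mean chunk length 40. Gibbs summaries at the default 200 iterations carry
a seed-to-seed Monte-Carlo error of ~0.005 RMS (occasionally ~0.02–0.03
at trials with multimodal partition posteriors); tests and analyses that
need tighter oracle agreement raise the iteration count instead of the
tolerance.

## Known limitations

- p_J and the grid size K are not identified by the source task; both are
  reported sensitivity parameters, with defaults 1/75 and 40.
- The γ-matrix windowed probability is an independence approximation;
  windowed statistics that matter use the sampler.
- The MAT importer targets the deposited dataset's documented record
  layout and fails loudly otherwise; the human-data benchmarks require
  that dataset at `data/subject_dataset.mat` and are not reproducible from
  this repository alone.
- Chunk-length statistics at question times are Monte-Carlo estimates;
  their noise propagates into the jump-location-uncertainty regressor
  (attenuating, not biasing, its group effect).
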