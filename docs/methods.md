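# Methods

This note documents the models, conventions and design choices behind
`cvepstop`, in the spirit of a package methods appendix: what is assumed,
what is tunable, and what passing tests do and do not demonstrate.

## Stimulus codes

M-sequences are produced by Fibonacci linear feedback shift registers;
`PRIMITIVE_TAPS` ships a known maximal-length tap set per degree 2–16, and
a non-primitive polynomial triggers a warning (or an error with
`require_maximal=True`) when the measured period falls short of 2^d − 1.
The default Gold family combines the degree-6 preferred pair with
polynomial octals 103 (taps 6,1) and 147 (taps 6,5,2,1), giving 65
pairwise-distinct codes of length 63.

Two-duration modulation duplicates every frame and XORs with the
alternating clock 0,1,0,1,…. This exact construction is a convention: it
reproduces the published geometry (126 = 2·63 frames, 8.33 ms and 16.67 ms
flashes at 120 Hz) and bounds every run of ones to one or two frames, but
other schemes with the same run-length property could be substituted.

Subset selection minimizes the maximum absolute pairwise Pearson
correlation between template responses, greedily: seed with the globally
best pair, then add whichever candidate keeps the running maximum lowest.
An exhaustive search is available as an oracle for small problems; the
greedy result is not guaranteed optimal, and which subset the original
speller study used is unknowable from the publication, so the selection is
a generic re-implementation, not a reproduction.

Structure matrices tile the code over the requested number of cycles
*before* extracting events, so a flash spanning a cycle border counts as a
single event — matching continuous presentation. Events are classified by
run length (1 frame = short, 2 = long; longer runs are rejected), and each
event kind contributes `response_len` shifted indicator rows, clipped at
the trial end. All indices are 0-based samples; windows are half-open.

## Reconvolution CCA

The spatial filter w and temporal kernel r solve the leading canonical
pair between the channel-wise concatenation of training trials and the
stack of label-matched structure matrices. The generalized eigenproblem is
regularized with a trace-scaled ridge (1e−8) on both auto-covariance
blocks because structure matrices are rank-deficient at short windows.
Only the first canonical component is kept.

Scale and sign are conventions, fixed deterministically: w has unit norm,
its largest-magnitude entry is positive, and the canonical correlation is
positive; r then absorbs the remaining scale through a least-squares fit
of the template stream onto the projected data, which puts templates on
the amplitude scale of the projected EEG. Consequently the calibrated α is
≈ 1 by construction and the physically meaningful, identifiable quantity
is the product α·t — parameter-recovery tests therefore compare α against
ground truth via the true spatial pattern and source templates, or via the
scale of α·t.

Scoring supports the unnormalized inner product (required by the stopping
theory) and the Pearson correlation. Argmax ties break to the lowest class
index. A cumulative-sum scorer evaluates all decision windows of a trial
in one pass.

## Bayesian dynamic stopping

Calibration follows five steps: learn the classifier; estimate α by least
squares of the concatenated projected training trials onto the
concatenated templates of their true labels, once at full trial length;
estimate σ as the population standard deviation (ddof = 0 — at calibration
scale the ddof choice is far below any other error source) of the
residual; compute the Gaussian moments b₀, b₁, σ₀², σ₁² from the truncated
template Gram matrix at every decision window; and solve the quadratic for
the boundary η per window. A negative α is permitted but logged, since the
CCA sign convention should prevent it.

The quadratic's constant term is
c = −α²(σ₀²b₁² − σ₁²b₀²) + 2σ₀²σ₁²·ln(σ₀/(σ₁(N−1)ζ)): expanding
2σ₀²σ₁²(lnΛ(f) − ln((N−1)ζ)) confirms the minus sign inside the first
parenthesis and the coefficient a = σ₁² − σ₀². A dedicated oracle test
checks sign agreement of the quadratic with the directly evaluated
likelihood ratio on 10⁵ random parameter draws.

Root selection: the "+" branch of the quadratic formula, the larger root
in the typical case a > 0 (target-norm spread inflates σ₁²). When a > 0
the exact acceptance region also contains a second branch at very negative
scores; that pathological region is deliberately ignored in favour of the
single threshold f > η. When a < 0 the exact region is an interval; the
implementation still uses the single "+"-branch threshold and logs a
diagnostic. Near-degenerate quadratics (|a| below 1e−12 relative) fall
back to the linear solution −c/b; if b also vanishes the model is
degenerate and an error is raised. A quadratic with no real root is
constant-sign: η becomes −∞ (always accept) or +∞ (never accept).

The decision grid defaults to 100 ms steps from 100 ms to the maximum
trial length (42 windows at 4.2 s / 120 Hz). At each window the trial
stops if any score exceeds η; among several passing classes the one with
the highest target-distribution likelihood wins, which with equal target
variances across classes is the score closest to αb₁. At the forced stop
the plain argmax is emitted, and that emission counts as a positive
decision in the evaluation by default (toggleable).

α and σ are estimated once at full length rather than per window; the
per-window moments then inherit them through the truncated Gram. This
matches the concatenation-based calibration recipe; a per-window
re-estimate would be a straightforward extension.

## Baseline stopping rules

Static rules derive from an inner 5-fold cross-validated decoding curve on
the training split. The targeted-accuracy rule falls back to the
maximum-accuracy window when the target is never reached. The information
transfer rate uses the Wolpaw definition, bits/selection = log₂N +
P·log₂P + (1−P)·log₂((1−P)/(N−1)) with the P ∈ {0,1} limits, negative
bits clipped to zero, and a configurable inter-trial overhead (default
0 s).

The margin rule learns, per window, the smallest observed training margin
m\* such that trials with margin ≥ m\* are classified at or above the
targeted accuracy; an unattainable target yields +∞ (never stop there),
and a target of 0 yields −∞ (always stop immediately). Candidates are the
observed margins, making the threshold deterministic; no interpolation
between windows is performed.

The Beta rule maps Pearson scores through (ρ+1)/2, clips to
[1e−6, 1−1e−6], fits a Beta distribution by maximum likelihood
(method-of-moments initialized) to the N−1 non-maximum scores, and stops
when the fitted CDF at the mapped maximum reaches the target. The
alternative outlier reading 1 − CDF^(N−1) of the same prose would shift
thresholds but not the mechanism; the CDF form is the implemented default.
Windows whose non-maximum scores are all equal cannot support a fit and
never stop. The rule is undefined for the unbounded inner product and
rejects it.

## Synthetic data

The generator emulates the study geometry: 36 classes × 3 repetitions of
4.2 s trials (4 cycles of a 126-frame modulated Gold code) at 120 Hz — one
sample per frame, keeping desk-scale runtimes; real recordings at 2048 Hz
are not emulated. The ground-truth temporal response is a damped sinusoid
per flash kind (defaults: 8 Hz, 80 ms decay, long-flash amplitude 1.3×),
made zero-sum over its support because band-passed evoked responses
integrate to approximately zero; without this, all templates share a
dominant common component and uncentered inner-product matching is
uninformative. The 36 codes are the greedy low-correlation subset of the
65-member family under this kernel.

A trial is x = α·t_y + ε on the source channel, spread across C = 8
channels by a fixed unit-norm random spatial pattern (identical across
datasets; only noise varies with the seed), plus iid per-channel
background noise of the same standard deviation as the source noise by
default. The default σ = 0.5 puts full-pipeline single-cycle (1.05 s)
accuracy near 80% — a moderate-SNR operating point where stopping rules
have room to act. Note that with iid background noise the noise standard
deviation seen on the optimally filtered virtual channel is
√(σ² + σ_bg²); recovery tests compare against that quantity.

Not emulated, hence not validated by passing tests: eye blinks, drifts,
1/f spectra, spatially correlated noise, non-stationarity, and
participant-to-participant variability. Passing tests demonstrate internal
consistency of the method under its own generative assumptions, not
performance on recorded EEG.

## Evaluation

Every visited window is a decision. Pre-stop windows are negative
decisions: current argmax equal to the true label is a miss (fn),
otherwise a correct rejection (tn). The stopping window is the single
positive decision: a correct prediction is a hit (tp), otherwise a false
accept (fp). Precision, recall, specificity and F-score follow the usual
definitions, with zero denominators reported as 0 and logged. Because each
trial contributes one positive and many negative decisions, recall and
F-score are structurally small — the imbalance is the point of the
relevance-based view. Fixed and static rules are logged the same way (the
windows before their stopping point count as negative decisions), so their
metrics are comparable.

Cross-validation is stratified by class when every class has at least as
many trials as folds, plain K-fold otherwise, always seeded. Sweeps return
one mean row per hyper-parameter value for accuracy-vs-time and
precision-vs-time curves.

## Known limitations

- The single-threshold test is only an approximation of the exact
  likelihood-ratio acceptance region when a < 0 (interval case); this is
  inherent to the published single-boundary formulation.
- In the σ → 0 limit the template-spread terms of σ₁², σ₀² remain, so the
  score "distributions" stay overlapping in a ratio fixed by the template
  Gram geometry: noise-free decoding is not perfect at very short windows
  under the inner product, and stopping does not collapse to the first
  window. Accuracy saturates only once the target norm dominates the cross
  products (≈0.4 s under default geometry).
- Per-class priors are equal throughout; unequal priors would enter the
  test threshold but are not implemented.
- ζ offers a trade-off dial, not a guarantee: no calibration to a targeted
  accuracy or error rate is provided.
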