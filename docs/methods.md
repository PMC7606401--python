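# Methods

## Task structure and triplet taxonomy

A session is `n_blocks` × `trials_per_block` trials (default 36 × 85).
Each block opens with `n_warmup = 5` warm-up trials in random positions,
then `unit_repeats = 10` repetitions of the eight-trial alternating unit:
pattern trials at odd main-trial positions follow a cyclic permutation of
{1, 2, 3, 4}; random trials in between are i.i.d. uniform over the four
positions with no repetition constraints. The pattern cycle continues
across unit repeats within a block and restarts at the permutation's first
element each block — the phase convention is a package choice, fixed for
reproducibility. Timing defaults (500 ms stimulus, 120 ms ITI, 200 ms
lead-in) give a 52.9 s block. Counterbalancing assigns a seed-shuffled
ordering of the 24 permutations cyclically across participant indices.

A trial's condition comes from the triplet it terminates. Triplets never
span blocks; any triplet containing a warm-up trial is excluded, so in a
default block exactly trials 1–7 are unclassified. Of the 64 position
identities (a, x, b), the 16 with b = next(a) are high-probability and the
48 others low-probability; combined with the terminal trial's role this
gives Pattern-High, Random-High and Random-Low with expected shares
50% / 12.5% / 37.5% of classified trials, and a per-identity occurrence
ratio of 5:1 (high:low). No trill/repetition exclusions (e.g. 1-2-1,
1-1-1) are applied — some ASRT pipelines drop them, this one deliberately
does not.

## SL scores and their scale

Per participant and block, condition means use correct trials only;
accuracies use all classified trials. The raw SL score is
|mean RT(RL) − mean RT(RH)| in ms. Because overall speed differs between
people and blocks, the score can be *normalized* (divided by the block's
overall correct-trial mean RT). Normalization makes the score
dimensionless while the saturation parameter A is naturally read in ms, so
the default mode is **rescaled**: the normalized score multiplied by the
participant's grand-mean RT, which removes block-level speed drift yet
keeps an ms-comparable scale. All three modes (`raw | normalized |
rescaled`) are available; the group series is the per-block mean over
participants, with missing participant-blocks skipped and logged.

## Effects regressions

Group-averaged block × condition data (72 rows for the default design) are
fit by OLS with `outcome ~ block_c + code + block_c:code`, where block
order is centered at its mean (18.5) and the condition dummy codes
Random-High = 0 vs Random-Low = 1 (probability contrast) or Pattern-High =
0 vs Random-High = 1 (type contrast). On this balanced centered design the
intercept equals the reference condition's grand mean. Reference coding and
centering are inferences from the reporting conventions of this design
family; they are what make the constants interpretable as condition grand
means. AICc/BIC for a regression use the Gaussian log-likelihood with
k = 5 (four coefficients plus the error variance).

## Curve fitting

The negative log-likelihood assumes independent Gaussian observations with
a free noise SD, so each model carries k = 4 parameters. Minimization uses
L-BFGS-B from the all-ones start (w₁, w₂, w₃, σ) = (1, 1, 1, 1) within
bounds; if that run fails or converges on a non-σ bound, up to 10 restarts
jitter the start log-uniformly within positive bounds (uniformly where a
bound spans zero) and the best likelihood is kept. Off-domain evaluations
(e.g. the power base x − w₂ ≤ 0) return a large finite penalty rather than
raising, which keeps the bounded optimizer stable; the public `predict`
raises a `DomainError` instead. A run that stalls with σ at its floor and
near-zero residuals is classified as converged — that is the degenerate
perfect-fit corner of the likelihood, not a failure. The power model is
implemented as w₁·(x − w₂)^{w₃}; the sign convention on w₂ is arbitrary
(negating w₂ gives the additive form) and the domain guard applies either
way.

Individual fits use the empirical bounds A ∈ [−500, 500], x₀ ∈ [0, 50],
τ ∈ [1, 50], σ ∈ [0, 30] (σ's lower bound implemented as 1e-6). The group
fit widens x₀ to [−50, 50], since a group curve may rise before block 1 —
with the individual bound the published-scale group intercept (≈ −0.4)
would pin at 0. The group fit runs on the per-block mean series (n = 36)
by default; pooling all participant-block points is available via
`pooling="stacked"`. A true τ outside its bound pins at the bound with a
`bounds_hit` flag; flagged or non-converged participants are excluded from
correlations with a log entry, never silently.

AICc = 2k·n/(n−k−1) − 2·log L (algebraically identical to the standard
AIC + 2k(k+1)/(n−k−1) correction), BIC = k·ln n − 2·log L, natural
logarithms throughout — required for the Bayes factor exp(−0.5·ΔBIC) to be
e-based. ΔAICc(m1 vs m0) = AICc(m0) − AICc(m1), positive favoring m1.
Evidence bands: BF ≤ 1 supports M0; 1–3 bare mention; 3–20 positive; 20–150
strong; > 150 very strong (ΔAICc bands at 2/4/7/10 analogously). The best
model is the one minimizing both AICc and BIC, with disagreement flagged.

Because all three forms share k = 4, AICc/BIC ranking reduces to
likelihood ranking, and the more flexible exponential model approximately
nests a line (τ → its upper bound). Model recovery is therefore one-sided:
exponential-generated series are correctly selected (≥ 80% of replicates
at n = 36, noise SD 2 ms), but linear-generated series are essentially
never attributed to the linear form, and power-generated series only about
half the time. This is an arithmetic property of equal-k information
criteria, not an implementation defect; conclusions that hinge on
*rejecting* the exponential form should not rely on this selection rule.

## Individual differences

Scores are z-transformed (sample SD; ranks and hence tau are unaffected —
the standardized table is for downstream consumers). Correlations use
Kendall's tau-b with tie correction and the tie-adjusted normal
approximation for two-sided p values (an exact method is available for
n ≤ 10 without ties). Each of the ten tests is correlated with A and with
τ, plus the A–τ pair; p values are uncorrected by default, with
Benjamini–Hochberg available as an explicit opt-in extension. Direction
conventions of the tests (e.g. higher ANT score = worse inhibition) are a
matter of interpretation; the package reports signed r without relabeling.

## The synthetic-data generator

Per participant, RT(trial) = base − slope·(block − 1) + gap(block)·1{RL} +
N(0, σ_trial), with gap(b) = A·(1 − e^−(b−x₀)/τ), truncated below at
100 ms; correctness is Bernoulli per condition (defaults PH 0.927, RH
0.929, RL 0.902); error responses land uniformly on a wrong position and
their RTs are discarded downstream. Cohort defaults: 40 participants; A ~
N(13.25, 4), x₀ ~ N(−0.39, 0.5), τ ~ N(10.28, 3) clipped to [1, 50]; base
RT ~ N(285, 6) ms; practice slope 1 ms/block; trial noise SD 5 ms.
Neuropsych scores come from a Gaussian copula on the designated parameter's
normal scores with ρ = sin(π·τ_K/2), hitting a requested Kendall
correlation in expectation; default targets designate each test to the
parameter with which it correlates more strongly in the reference battery.

What the generator does *not* emulate: right-skewed RT distributions,
sequential dependencies (post-error slowing, fatigue within blocks),
rest-period consolidation, explicit awareness, or non-exponential
individual learning shapes. Passing tests demonstrate that the pipeline's
arithmetic and inference machinery are correct and that parameters are
recoverable under the generative model — not that real cohorts follow
that model.

With zero noise the realized raw SL score equals gap(b) exactly. With
noise, the absolute value folds the score's sampling distribution near
zero (early blocks, where the true gap is small), inflating early scores
slightly; group-level fits therefore show a mild upward bias in τ at
trial-level noise. The parameter-recovery checks operate on group-level
series with additive Gaussian noise (SD 2 ms, 50 replicates, n = 36
blocks), where the median recovered A and τ land within a few percent of
their generative values; problem sizes throughout (40 participants, 36
blocks, 50–200 replicates) match the study-scale design the package
emulates.

## Determinism

Every stochastic step draws from a named substream of one master seed
(SeedSequence over (seed, crc32(name))), so stages are independently
reproducible and a (config, seed) pair reproduces all CSV/JSON artifacts
byte-identically.
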