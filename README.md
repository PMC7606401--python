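# slcurves

Simulation and learning-curve analysis of implicit **statistical learning
(SL)** in the **alternating serial reaction time (ASRT) task**, for
researchers who want a tested, fully reproducible pipeline from raw
per-trial logs (real or simulated) to per-participant learning parameters
and their correlates.

## The problem and the model

In the ASRT task a fixed four-position sequence (e.g. 3–2–4–1) alternates
with uniformly random trials, hiding a deterministic pattern inside
apparent noise. Every trial terminates a *triplet* with its two
predecessors; a triplet is **high-probability** if its third position is
the pattern successor of its first, otherwise **low-probability**. This
yields three observable conditions — Pattern-High, Random-High, Random-Low
(50% / 12.5% / 37.5% of classified trials) — and the per-block **SL score**

> SL(b) = | mean RT(Random-Low, b) − mean RT(Random-High, b) |,

optionally normalized by the block's mean RT. Learning shows up as growth
of SL(b) across the 36 blocks, modeled by three candidate curves fitted by
bounded maximum likelihood (L-BFGS-B, Gaussian noise, init (1, 1, 1, 1)):

| form | y(x) | interpretation |
|---|---|---|
| exponential | A·(1 − e^−(x−x₀)/τ) | first-order step response |
| power | w₁·(x − w₂)^w₃ | diminishing-returns growth |
| linear | w₁·(x − w₂) + w₃ | constant-rate growth |

For the exponential winner, **A** (saturation level, ms) is the
*potential* of learning, **τ** (time constant, blocks) its *efficiency* —
the curve reaches 1 − 1/e ≈ 63.2% of A at x = x₀ + τ. Models are compared
by AICc = 2k·n/(n−k−1) − 2·log L, BIC = k·ln n − 2·log L, and the BIC
approximation of the Bayes factor, exp(−0.5·ΔBIC). Per-participant A and τ
are then rank-correlated (Kendall's tau-b, two-sided p) with ten
executive-function test scores.

Because no public trial-level ASRT dataset ships with the package, a
synthetic-data module generates complete sessions with known ground truth
(counterbalanced pattern permutations, exponential RT-gap growth, ~92%
accuracy, Gaussian-copula neuropsych scores with requested rank
correlations), so every downstream stage is testable end to end.

## Worked example

```python
from slcurves import (SessionDesign, CohortSpec, simulate_cohort,
                      summarize_blocks, compute_sl_scores, fit_group,
                      compare_models)

design = SessionDesign()                 # 36 blocks x 85 trials
spec = CohortSpec(n_participants=40)     # group curve A=13.25, x0=-0.39, tau=10.28
trials, truths, patterns = simulate_cohort(design, spec, seed=42)
scores = compute_sl_scores(summarize_blocks(trials), mode="rescaled")
fits = fit_group(scores, restarts=10, seed=42)
sel = compare_models(list(fits.values()))
```

prints (via the obvious f-strings):

```
best model by AICc: exponential (AICc exp=24.5, power=47.5, linear=108.8)
A = 13.63 ms, x0 = -1.26, tau = 14.20 blocks
63.2% of A reached at block 12.9
exponential vs linear: dAICc = 84.3, BF = 2.1e+18 (Very strongly supports the M1)
```

The exponential form wins decisively on exponential-generated data; the
fitted saturation (13.63 ms) sits close to the generative group value
(13.25 ms), while τ is biased upward a little by cohort heterogeneity and
the folded noise in the absolute-value score (see `docs/methods.md`).

The same pipeline runs from the shell, stage by stage or end to end:

```bash
slcurves all --seed 7 --out runs/r1            # simulate -> ... -> report
slcurves fit --seed 7 --out runs/r1 --config cfg.yaml   # re-run one stage
```

Each stage writes tidy CSV/JSON plus a manifest (input hashes, config
snapshot, seed); identical (config, seed) reproduce byte-identical outputs.

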