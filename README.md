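# beastmix

Cognitive modelling of how people integrate disparate social
information, built around the Berlin Estimate AdjuStment Task (BEAST):
participants estimate the number of animals in an image, observe the
estimates of three peers, and estimate again.  The package provides

* the **task design** — the four social-information conditions that vary
  the variance and skewness of the peer distribution at a fixed mean
  offset, the relative-adjustment metric
  `s = (E2 − E1)/(X̄ − E1)`, and keep/adopt/compromise strategy
  classification;
* a **mixture cognitive model** — logistic keep and adopt heuristics
  driven by the distance to the nearest peer, plus Bayesian compromise
  in which each peer's weight falls with its distance to one's own
  estimate (confirmation-based weighting) and to the other peers
  (proximity-based weighting), all wrapped into a discretized
  point-mass-plus-normal likelihood on the slider grid;
* **hierarchical Bayesian inference** for the 16-model feature family
  (keep × adopt × confirmation × proximity), with PSIS-LOO (`looic`)
  model comparison, parameter recovery and model recovery;
* a **synthetic-study generator** reproducing the full design — 95
  participants, 30 rounds (5 per condition + 10 filler) in a shared
  order plus a 4-peer control block, 100-estimate pre-recorded pools;
* **agent-based simulations** of belief dynamics: 1000 agents observing
  ten peers in five scenario compositions, including strong- vs
  weak-confirmation subsets, probing filter-bubble and polarization
  effects.

The science and the numerical design are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a small cohort from the calibrated population fixture, look at
the condition effect, and fit the best model variant:

```python
import numpy as np
import beastmix as bm

trials, truth = bm.simulate_population(n_participants=30, seed=7)

for cond in bm.CONDITIONS:
    sub = trials[trials.condition == cond]
    s = [bm.compute_s(r.E1, r.E2, [r.X1, r.X2, r.X3]) for r in sub.itertuples()]
    print(cond, round(float(np.mean([v for v in s if v is not None])), 3))

fit = bm.fit_hierarchical(
    trials, bm.ModelSpec(use_adopt=False),
    bm.McmcConfig.reduced(), seed=1,
)
print("looic", round(fit.looic, 1), "+-", round(fit.looic_se, 1))
print(fit.group_summary().head(7).to_string(index=False))
```

prints (seeds fixed as above):

```
LN 0.343
HN 0.186
HF 0.163
HC 0.197
looic 5722.7 +- 122.9
     parameter level  post_mean        lo        hi
keep_intercept  mean   1.044403  0.661155  1.400880
    keep_slope  mean  -7.068782 -9.232914 -4.920367
   log_sigma_E  mean  -2.265267 -3.002930 -1.815098
      var_base  mean  -4.263239 -5.474074 -3.313295
      var_conf  mean   2.539076  0.991678  4.295446
      var_prox  mean   1.149691  0.075657  2.494835
log_sigma_resp  mean  -2.140134 -2.420552 -1.947633
```

Read-out: the cohort adjusts most under low-variance social information
(`LN`) and more when two peers cluster near the first estimate (`HC`)
than far from it (`HF`) — the signature of confirmation-based weighting,
echoed in the fitted group means: a negative keep slope (keeping is for
closely confirming peers), a strongly positive confirmation coefficient
and a weaker proximity coefficient.  An equal-weight observer would have
`s = 0.75` everywhere; the shortfall is egocentric discounting.

Belief dynamics at the same parameters:

```python
for name in bm.SCENARIO_NAMES:
    r = bm.run_scenario(name, None, n_agents=1000, seed=3)
    print(f"{name:20s} median {r.summary.median:+5.1f} "
          f"keep {r.summary.keep_fraction:.2f}")
```

```
majority_agree       median  +0.0 keep 0.72
half_agree           median  +0.0 keep 0.72
minority_agree       median  +0.0 keep 0.72
strong_conf_split    median  -2.5 keep 0.28
weak_conf_split      median  +0.0 keep 0.28
```

Agents whose first estimate is confirmed by even a minority of peers
mostly keep it (filter-bubble retention); between two opposing camps,
agents with strong confirmation-based weighting drift towards the
nearer, more extreme camp while weak-confirmation agents move towards
the global mean — the seed of polarization.

A command-line interface mirrors the library:

```bash
beastmix simulate --seed 1 --out trials.csv --truth-out true_params.csv
beastmix fit trials.csv --model keep+conf+prox --out-dir fits
beastmix fit trials.csv --all-specs --out-dir fits     # 16-model family
beastmix compare fits/*.npz --out comparison.json
beastmix recover --seed 1 --out recovery.json
beastmix scenarios --seed 1 --out scenarios.json
```

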