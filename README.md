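# fosplace

Analysis of hippocampal CA1 calcium imaging relating immediate-early-gene
(Fos) induction to place coding, for experiments in which head-fixed mice
run a 200-cm circular virtual track and lick for rewards in a hidden 20-cm
zone. The package is aimed at systems-neuroscience analysts who have
extracted dF/F traces (e.g. from Suite2p), frame-synchronized behaviour and
per-cell Fos-reporter fold-induction values, and want the full chain from
trace preprocessing to cross-day stability as reusable, tested functions.

The core quantities:

- **Significant transients** — on the standardized trace, a positive run of
  `n` frames above threshold `t` (t = 1.0-4.0σ in 0.2σ steps) is accepted
  when `FPR(t, n) = #(runs < −t, len ≥ n) / #(runs > +t, len ≥ n) < 0.001`;
  the masked trace keeps dF/F on significant frames and is zero elsewhere.
- **Place fields** — smoothed 40-bin tuning exceeding, for ≥ 3 consecutive
  bins, the per-bin 99th percentile of 1,000 circular-shift + six-block
  permutation shuffles of the behaviour.
- **Spatial information** — `H = Σᵢ pᵢ aᵢ log₂(aᵢ / a)` (bits), normalized
  by its shuffle mean.
- **Position decoding** — Poisson naive Bayes with uniform prior:
  `P(pos|a) = C (Πᵢ fᵢ(pos)^{aᵢ}) e^{−τ Σᵢ fᵢ(pos)}`, trained on
  even-numbered trials, scored by circular error (0-100 cm).
- **Fold induction** — post/pre reporter-image ratio, normalized by its own
  ~50-µm median filter; per-cell means over 10-µm ROIs; top/bottom 20% per
  session define Fos-high/Fos-low.
- **Ensembles** — trial-wise in-field activation correlations, affinity-
  propagation clustering (preference −1), co-clustering versus label
  permutation.
- **Stability maps** — per-bin activity-weighted mean of per-cell cross-day
  tuning correlations, weights from the sum-normalized reference tuning.

A synthetic generator (`fosplace.synthetic`) produces sessions with all of
the structure above planted with known ground truth — lap behaviour,
place-tuned transients with per-cell reliability, induction coupled to
integrated activity, and multi-day field persistence — so every stage is
testable without animal data.

## Worked example

```python
import numpy as np
from fosplace.synthetic import SimConfig, generate_session
from fosplace.pipeline import AnalysisConfig, analyze_session

cfg = SimConfig(n_cells=100, n_trials=20)      # defaults: 200-cm track, 30 Hz
data = generate_session(cfg, seed=1)
a = analyze_session(data, AnalysisConfig(), seed=1)

hi, lo = a.group_cells("high"), a.group_cells("low")
pc = a.tuning.is_place_cell
print(f"licking selectivity        {a.selectivity:.3f}")
print(f"place-cell fraction        high {pc[hi].mean():.2f}   low {pc[lo].mean():.2f}")
print(f"normalized spatial info    high {np.nanmean(a.tuning.H_norm[hi]):.2f}   low {np.nanmean(a.tuning.H_norm[lo]):.2f}")
print(f"decoding error (cm)        high {a.decode_errors['high']:.1f}    low {a.decode_errors['low']:.1f}")
print(f"within-group correlation   high {a.ensemble['within_high']:.3f}  low {a.ensemble['within_low']:.3f}")
```

prints

```
licking selectivity        1.000
place-cell fraction        high 1.00   low 0.65
normalized spatial info    high 6.50   low 2.02
decoding error (cm)        high 7.2    low 32.3
within-group correlation   high 0.510  low -0.030
```

The synthetic mouse licks selectively before the reward zone (selectivity 1).
Cells whose induction ranks in the top 20% ("high") were generated with
reliable, co-fluctuating fields, and the pipeline recovers that: they are
all place cells, carry ~3× the normalized spatial information, decode the
animal's position ~4× more accurately than the bottom-20% group, and share
trial-to-trial activation fluctuations (within-group correlation 0.51 vs
~0). Multi-day cohorts (`generate_multisession` + `analyze_multisession`)
additionally yield per-group cross-day stability maps and zone contrasts.

There is also a CLI:

```sh
fosplace simulate --config sim.yaml --seed 0 --out bundles/
fosplace run bundles/ --seed 0 --out results/
```

`simulate` writes session bundles (HDF5 traces/behaviour, CSV tables, YAML
config echo); `run` executes the full chain and writes per-stage CSVs plus
a machine-readable `summary.json` embedding the configuration hash.

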