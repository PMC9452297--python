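# Methods

`fosplace` re-implements, as a tested pipeline, the analysis chain used to
relate immediate-early-gene (Fos) induction to hippocampal place coding in
head-fixed mice running a virtual 200-cm circular track: significant-transient
calling on dF/F traces, place-field detection against a block-permutation
null, spatial information, Poisson naive-Bayes position decoding, activity
matching, fold-induction image quantification, trial-wise ensemble
correlation and clustering, and activity-weighted cross-day stability maps.
Because no public dataset accompanies the analyses, a synthetic generator
produces sessions with the statistical structure the chain assumes, with full
ground truth, so every stage is scoreable.

## Significant transients (`signals`)

dF/F is `(F - b) / b` with `b` the 30th percentile of raw fluorescence in a
60-s moving window, centred on each frame and truncated at the trace edges
(whether the window is centred or trailing is an open choice; centred is the
default and config-exposed). Transients are detected on the standardized
trace (median subtracted, divided by the plain sample SD): for each threshold
`t` in 1.0-4.0 sigma in 0.2 steps, maximal runs strictly above `+t` are
candidates, and a candidate of `n` frames is accepted when
`FPR(t, n) = #(runs < -t, length >= n) / #(runs > +t, length >= n)` is below
0.001. Baseline noise is symmetric while real transients are positive, so
negative excursions estimate the noise-only rate. The denominator counts the
candidate itself, so the ratio is always finite. The final mask is the union
over thresholds; runs separated by a gap shorter than two frames are merged
(gap frames recover their dF/F) and runs under two frames are dropped. Run
counts for the FPR are taken before merging. The output trace keeps dF/F on
significant frames and is zero elsewhere; `alpha`, the integrated significant
dF/F (sum x frame period), is the activity measure used for induction
coupling and activity matching. The detector is invariant to positive affine
rescaling of its input. Note the masked trace can carry small negative
values on merged gap frames; downstream formulas defined on nonnegative
activity (spatial information, the decoder) clip these at zero.

## Behaviour (`behavior`)

Trials are laps, cut at position wraps. Licks inside the reward zone after
that trial's reward are consumption licks; all others are test licks. A trial
is eligible for place-field analyses when it has at least 3 test licks, lasts
4-60 s, contains no experimenter-triggered reward, and starts before 1.2 ml
of cumulative reward. Licking selectivity compares test licks in the 10 cm
before the reward-zone start with an equal zone diametrically opposite:
`(pre - opposite) / (pre + opposite)`, NaN when both are zero (excluded from
averages). Sessions from the first one reaching selectivity 0.6 are "stable
performance". The generic two-sided permutation test pools the two samples,
relabels 1,000 times, and reports an add-one-smoothed p-value.

## Spatial tuning (`tuning`)

Only running frames (speed > 5 cm/s) of eligible trials contribute. The
track is divided into 40 bins of 5 cm; per-bin activity is the frame mean of
the masked transient trace, smoothed with a circular Gaussian of sigma = 1
bin (the kernel renormalizes over visited bins, bridging unvisited ones).
The null: on each of 1,000 shuffles the behaviour stream is circularly
shifted by a uniform random offset, cut into six blocks whose lengths differ
by at most one frame (remainder on the leading blocks), and the block order
permuted; binning and smoothing are recomputed. Equivalently the pairing of
activity and position is what is randomized; the implementation permutes
within the retained-frame set, which leaves occupancy invariant and makes
the per-bin test exchangeable and exact. One shuffle stream is shared by all
cells of a session (the behaviour is common to them). The per-bin threshold
is the 99th percentile over the shuffled curves *including the observed
curve* — the identity pairing is a member of the permutation group, and
including it keeps the test at or below its nominal level, the same add-one
convention as the permutation p-values. A place field is a maximal circular
run of at least 3 bins strictly above the threshold; ties are not
significant.

Spatial information is `H = sum_i p_i a_i log2(a_i / a)` (bits) on the
unsmoothed binned means (config-switchable), with `x log x -> 0` at silent
bins and H = 0 for silent cells; it is reported raw and normalized by the
mean over the same 1,000 shuffles. Expected per-cell false-positive rate of
the field test on position-independent cells is ~1% per event bump;
untuned synthetic cells carry a handful of bumps, so population specificity
sits near (and is required to stay within) 5%.

Per-field properties: trial-to-trial correlation is the mean off-diagonal of
the trial x trial Pearson matrix of trial-wise binned activity (entries with
an inactive trial, or undefined correlations, set to zero; unvisited bins
excluded pairwise); fraction active is the share of eligible trials with at
least one significant frame inside the field; selectivity contrasts mean
in-field and out-of-field binned activity.

## Decoding (`decoding`)

Templates are per-cell mean binned activity over even-numbered eligible
trials (1-based, so the first eligible trial is a test trial); odd trials
test. Bins unvisited in training are excluded from the posterior support;
template values are floored at 1% of the population-mean positive template
value before logs (config-exposed). Per frame,
`log P(pos|a) = sum_i a_i log f_i(pos) - tau sum_i f_i(pos) + const` with
`tau` one frame (1/30 s), a uniform prior, log-sum-exp normalization, and
argmax ties resolved to the lowest bin. Per-frame activity is the raw
significant-transient dF/F (neither thresholded nor binarized — the most
literal reading of the posterior). Error is the circular bin-centre distance
(0-100 cm). Group comparisons subsample each group to the smaller group's
size clamped to [10, 100] cells, train/test on identical frames, and average
over 100 repetitions; sessions whose smaller group is under 10 cells are
excluded. Decile decoding trains and tests each induction decile
independently; "low"/"high" average deciles 1-2 and 9-10.

Activity matching bins log10(alpha) of the pooled population into ten
equal-width bins; within each bin it alternately draws one cell per group
from the more- or less-active half of that group's remaining members,
depending on the sign of the running mean-alpha difference of the matched
sets, until either group's bin members are exhausted.

## Fold induction (`induction`)

The post/pre GFP ratio image is divided by its own 2-D median filter
(square window of ~50 µm rounded to an odd pixel count; reflective padding
at the borders). Excluded (artefact) pixels propagate NaN and
are replaced by the global ratio median inside the filter so they do not
drag the background. Per-cell values average the fold map over a 10-µm disc
(clipped at borders; cells with >50% excluded disc pixels are flagged).
Deciles come from the rank order among non-excluded cells, ties broken by
cell id for determinism; high = deciles 9-10, low = 1-2. For time courses,
each image is standardized by its median and MAD, then rescaled by the
pooled MAD (A) and pooled median (B) of the whole series; fold maps are
computed against the first image and per-cell values averaged in 1-h bins.

## Ensembles (`ensembles`)

The activation matrix holds each place cell's mean in-field binned activity
per eligible trial (NaN when no field bin was visited). Within-group
correlation averages pairwise Pearson correlations over shared non-missing
trials (pairs with <3 shared trials or zero variance skipped). For
clustering the similarity is the pairwise correlation with missing entries
imputed to zero; affinity propagation runs with preference −1, max 5,000
iterations and damping 0.9 (damping is an open choice; the high iteration
cap suggests a high-damping regime). The sklearn convention replaces the
self-similarity with the preference. Group co-clustering is scored as the
within-group same-cluster pair probability divided by its mean under random
same-size cell draws (equivalent to permuting induction labels). Cross-day:
groups are fixed by reference-session induction; the within-group
correlation is evaluated on the target session's activation matrix over
members present and fielded there.

## Stability (`stability`)

For each session pair (positive delta, each unordered pair used once),
`x_c` is the Pearson correlation between the cell's binned tuning on
reference and target (zero-variance cells skipped). Stability at bin `i` is
the `x`-weighted mean with weights proportional to each cell's reference
tuning at `i`, after normalizing every cell's reference tuning to unit sum
so each field contributes equally; weights come from the smoothed reference
curve by default (config-switchable to unsmoothed). Maps require at least
20 contributing cells per group, else the pair is excluded. Zone summaries
average non-missing bins in the peri-reward zone (reward zone ±20 cm; the
exact margin is a design choice and config-exposed, never hard-coded as
ground truth) and the remaining no-reward zone. Group differences are tested
per bin and as a peri-vs-no-reward contrast with a paired sign-flip
permutation over session comparisons (the only exchangeable structure in
paired maps), 1,000 shuffles, two-sided add-one p-values. The remapping
contingency compares P(high induction in environment 2) between cells that
gained vs never had, and lost vs kept, a field across environments, with
label permutations within each stratum.

## Synthetic generator (`synthetic`)

Behaviour: per-trial piecewise-constant speed drawn from a lognormal
(mean 25 cm/s, log-sd 0.25, floored at 6 cm/s so laps stay inside the 4-60-s
eligibility window), halved inside the reward zone; trial types drawn from
the configured fractions (defaults 65/25/10% standard/crutch/probe);
expert licking concentrates test licks in the 10 cm before the zone plus
one or two in-zone licks (a standard-trial reward needs an in-zone lick;
delivery is one frame after the trigger so the trigger remains a test
lick); novice licking is uniform. Rewards: standard at first in-zone lick,
crutch at zone entry, probe never; consumption licks follow delivery.

Traces: a tuned cell fires on each trial with probability `reliability_p`;
the clean signal is amplitude x a Gaussian envelope of circular distance to
the field centre (field width ~4 sigma, default 20 ± 5 cm; amplitude
2 ± 0.5 dF/F), scaled by a per-trial gain shared within the group when
`shared_trial_gain_sd > 0`, then smoothed with a unit-area causal
exponential (decay 0.5 s — single-exponential indicator kinetics). Untuned
cells emit Poisson events at 0.02 Hz. Gaussian noise (sd 0.15) is added.
The ground truth retains per-trial activations and a per-frame event mask
(clean signal above half the cell's peak) so detector sensitivity is
scoreable. Induction is `baseline + gain x z(alpha) + noise`, floored at a
small positive value; with gain 0 it is independent of activity. Effect
sizes for the alpha-induction coupling are not reported in the source;
defaults (gain 0.5, noise 0.15 on baseline 1) are order-of-magnitude
choices and config-exposed.

Multi-day sets evolve ground truth per session step: a tuned cell keeps its
field with its group's persistence probability, otherwise relocates it
(probability `remap_fraction`) or loses it; untuned cells gain a field with
a small probability; a configurable fraction of cells is absent per session
(imperfect cross-day matching) via the alignment table. All randomness
derives from one master seed through named substreams, so each artefact
regenerates independently and bit-identically.

The default cohort plants the contrast the analyses are meant to recover:
"high" cells are reliable (0.85), co-fluctuating (shared gain sd 0.4) and
stable (persistence 0.9); "low" cells are unreliable (0.3), independent and
unstable (0.4); both groups are 90% tuned. These are generative choices,
not measurements; what passing tests show is that the chain recovers
planted structure of realistic magnitude, not that real data behave this
way. The generator also omits drift, neuropil contamination, motion
artefacts, non-place coding and bursty within-field spiking, so detector
and decoder performance on it is optimistic relative to real recordings.

## Problem sizes and numerical choices

The end-to-end recovery suite uses 20 replicates of a 300-cell, 20-trial,
two-session cohort — sized so each 20%-induction group retains at least 20
reference-session place cells, as the stability analysis requires. The
specificity suite uses 500 untuned cells at 1,000 shuffles; the decoder
recovery uses a noiseless 100-cell session. Degenerate inputs raise:
zero-variance traces (standardization), non-positive baselines, all-equal
induction values, groups under 10 cells (decoding) or 20 cells (stability).
Percentiles use linear interpolation; all permutation p-values are add-one
smoothed; argmax and rank ties break deterministically (lowest bin, lowest
cell id).
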