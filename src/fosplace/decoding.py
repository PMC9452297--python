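"""Poisson naive-Bayes position decoding and activity matching.

The decoder assumes Poisson emission and independence between cells, with a
uniform prior over the 40 spatial bins.  Templates ``f_i(pos)`` are mean
binned activity on even-numbered eligible trials (1-based numbering: trial 2,
4, ... train; 1, 3, ... test).  For a frame with per-cell activity ``a_i``
the posterior over position is

    P(pos | a) = C * prod_i f_i(pos)^{a_i} * exp(-tau * sum_i f_i(pos))

with ``tau`` the frame duration.  The decoded bin is the posterior argmax;
error is the circular distance between bin centres (0-100 cm on a 200-cm
track).  Group comparisons always decode equally sized, randomly subsampled
populations on identical train/test frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .behavior import SessionTimeseries
from .tuning import BinnedActivity, bin_activity

__all__ = [
    "TemplateSet",
    "DecodingResult",
    "split_trials_even_odd",
    "fit_templates",
    "decode_frames",
    "decode_session",
    "compare_groups",
    "activity_match",
]

MIN_GROUP_CELLS = 10
MAX_GROUP_CELLS = 100
DEFAULT_FLOOR_FRAC = 0.01


@dataclass
class TemplateSet:
    """Per-cell spatial activity templates from training trials.

    ``templates`` is (cells, bins), floored at ``floor`` to keep the
    log-likelihood finite; ``valid_bins`` marks bins visited during training
    (others are excluded from the posterior support).
    """

    templates: np.ndarray
    valid_bins: np.ndarray
    tau: float
    bin_width: float

    @property
    def n_cells(self) -> int:
        return self.templates.shape[0]


@dataclass
class DecodingResult:
    posterior: np.ndarray  # (frames, bins), rows sum to 1 over valid bins
    decoded_bin: np.ndarray
    true_bin: np.ndarray
    error_cm: np.ndarray

    @property
    def mean_error_cm(self) -> float:
        return float(self.error_cm.mean())

    def error_by_bin(self, n_bins: int) -> np.ndarray:
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            sel = self.true_bin == b
            if sel.any():
                out[b] = self.error_cm[sel].mean()
        return out


def split_trials_even_odd(eligible_trials: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(train, test) trial ids: even-numbered eligible trials train, odd test.

    Numbering is 1-based over eligible trials in session order, so the first
    eligible trial is odd (test)."""
    t = np.asarray(eligible_trials)
    return t[1::2], t[0::2]


def fit_templates(
    binned: BinnedActivity,
    train_trials: np.ndarray,
    frame_rate: float,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
) -> TemplateSet:
    """Templates = mean binned activity over training trials, floored.

    The floor is ``floor_frac`` times the population mean of positive
    template values, applied before logs so that silent template bins do not
    produce -inf log-likelihoods.  Bins unvisited on every training trial are
    marked invalid and excluded from the posterior support.
    """
    sel = np.isin(binned.trial_ids, np.asarray(train_trials))
    if not sel.any():
        raise ValueError("no training trials")
    with np.errstate(invalid="ignore"):
        f = np.nanmean(binned.per_trial[:, sel, :], axis=1)
    valid = np.isfinite(f).any(axis=0)
    if not valid.any():
        raise ValueError("no bin visited in training")
    f = np.where(np.isfinite(f), f, 0.0)
    pos_vals = f[f > 0]
    floor = floor_frac * (pos_vals.mean() if pos_vals.size else 1.0)
    f = np.maximum(f, floor)
    return TemplateSet(
        templates=f, valid_bins=valid, tau=1.0 / frame_rate,
        bin_width=binned.bin_width,
    )


def decode_frames(
    templates: TemplateSet, activity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior and decoded bin for each frame.

    ``activity`` is (cells,) for a single frame or (frames, cells).  Computed
    in the log domain and normalized with log-sum-exp; argmax ties resolve to
    the lowest bin index.
    """
    a = np.atleast_2d(np.asarray(activity, dtype=float))
    if a.shape[1] != templates.n_cells:
        raise ValueError("activity has wrong number of cells")
    # masked transient traces are nonnegative up to merged gap frames; the
    # Poisson exponent is defined on a >= 0, so clip the stray negatives
    a = np.maximum(a, 0.0)
    if not templates.valid_bins.any():
        raise ValueError("no valid template bins")
    f = templates.templates
    logf = np.log(f)
    logpost = a @ logf - templates.tau * f.sum(axis=0)
    logpost[:, ~templates.valid_bins] = -np.inf
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    post = np.exp(logpost)
    decoded = np.argmax(post, axis=1)
    if np.asarray(activity).ndim == 1:
        return post[0], int(decoded[0])
    return post, decoded


def circular_error_cm(
    bin_a: np.ndarray, bin_b: np.ndarray, n_bins: int, bin_width: float
) -> np.ndarray:
    d = np.abs(np.asarray(bin_a) - np.asarray(bin_b))
    return np.minimum(d, n_bins - d) * bin_width


def decode_session(
    templates: TemplateSet,
    binned: BinnedActivity,
    test_trials: np.ndarray,
    cell_index: np.ndarray | None = None,
) -> DecodingResult:
    """Decode every running frame of the test trials and score circular error.

    ``binned`` supplies the retained-frame activity and true bin per frame;
    ``cell_index`` optionally restricts decoding to a subset of cells (the
    templates must already be restricted to the same subset).
    """
    sel = np.isin(binned.trial_of_frame, np.asarray(test_trials))
    if not sel.any():
        raise ValueError("no test frames")
    act = binned.activity[:, sel]
    if cell_index is not None:
        act = act[np.asarray(cell_index)]
    post, decoded = decode_frames(templates, act.T)
    true_bin = binned.bin_of_frame[sel]
    err = circular_error_cm(decoded, true_bin, binned.n_bins, binned.bin_width)
    return DecodingResult(
        posterior=post, decoded_bin=decoded, true_bin=true_bin, error_cm=err
    )


def _decode_subset(
    binned: BinnedActivity,
    cells: np.ndarray,
    train_trials: np.ndarray,
    test_trials: np.ndarray,
    frame_rate: float,
    floor_frac: float,
) -> float:
    sub = BinnedActivity(
        per_trial=binned.per_trial[cells],
        mean=binned.mean[cells],
        occupancy=binned.occupancy,
        counts=binned.counts,
        trial_ids=binned.trial_ids,
        frame_index=binned.frame_index,
        bin_of_frame=binned.bin_of_frame,
        trial_of_frame=binned.trial_of_frame,
        activity=binned.activity[cells],
        bin_width=binned.bin_width,
    )
    tpl = fit_templates(sub, train_trials, frame_rate, floor_frac)
    return decode_session(tpl, sub, test_trials).mean_error_cm


def compare_groups(
    binned: BinnedActivity,
    groups: dict[str, np.ndarray],
    frame_rate: float,
    n_reps: int = 100,
    seed: int | np.random.Generator | None = None,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
    min_cells: int = MIN_GROUP_CELLS,
    max_cells: int = MAX_GROUP_CELLS,
) -> dict[str, float]:
    """Mean decoding error per cell group with size-matched subsampling.

    Each group is randomly subsampled to the size of the smallest group
    (clamped to [``min_cells``, ``max_cells``]); a decoder is trained on even
    and tested on odd eligible trials; the subsample-train-test cycle is
    repeated ``n_reps`` times and errors averaged per group.  Train and test
    frames are identical for every group.  Raises if the smallest group has
    fewer than ``min_cells`` cells (the session is then excluded upstream).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = {g: np.asarray(ix).size for g, ix in groups.items()}
    smallest = min(sizes.values())
    if smallest < min_cells:
        raise ValueError(
            f"smallest group has {smallest} cells (< {min_cells}); session excluded"
        )
    n_use = min(smallest, max_cells)
    train, test = split_trials_even_odd(binned.trial_ids)
    if train.size == 0 or test.size == 0:
        raise ValueError("need at least one even and one odd eligible trial")
    errs = {g: [] for g in groups}
    for _ in range(n_reps):
        for g, ix in groups.items():
            ix = np.asarray(ix)
            pick = ix if ix.size == n_use else rng.choice(ix, n_use, replace=False)
            errs[g].append(
                _decode_subset(binned, pick, train, test, frame_rate, floor_frac)
            )
    return {g: float(np.mean(v)) for g, v in errs.items()}


def decode_deciles(
    binned: BinnedActivity,
    deciles: np.ndarray,
    frame_rate: float,
    floor_frac: float = DEFAULT_FLOOR_FRAC,
) -> dict:
    """Train and test a decoder on each induction decile independently.

    ``deciles`` assigns each cell to 1..10.  Returns per-decile mean errors
    plus the decile 1-2 ("low") and 9-10 ("high") averages.  Decile groups
    are equal-sized by construction, so no subsampling is needed.
    """
    train, test = split_trials_even_odd(binned.trial_ids)
    per_decile = {}
    for d in range(1, 11):
        cells = np.flatnonzero(np.asarray(deciles) == d)
        if cells.size == 0:
            per_decile[d] = float("nan")
            continue
        per_decile[d] = _decode_subset(binned, cells, train, test, frame_rate, floor_frac)
    low = float(np.nanmean([per_decile[1], per_decile[2]]))
    high = float(np.nanmean([per_decile[9], per_decile[10]]))
    return dict(per_decile=per_decile, low=low, high=high)


def activity_match(
    alpha_high: np.ndarray,
    alpha_low: np.ndarray,
    n_bins: int = 10,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subsample two cell groups to balance integrated-dF/F (alpha) levels.

    Bin edges come from ten equal-width bins of log10(alpha) over the pooled
    population (cells with alpha = 0 are excluded).  Within each bin, one
    cell per group is drawn per iteration; each group draws from the more- or
    less-active half of its remaining bin members depending on the sign of
    the running mean-alpha difference between the matched sets, stopping when
    either group's bin members are exhausted.  Returns index arrays into the
    two input vectors; the matched sets have equal size per bin and closely
    balanced mean alpha.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ah = np.asarray(alpha_high, dtype=float)
    al = np.asarray(alpha_low, dtype=float)
    keep_h = np.flatnonzero(ah > 0)
    keep_l = np.flatnonzero(al > 0)
    pooled = np.log10(np.r_[ah[keep_h], al[keep_l]])
    if pooled.size == 0:
        return np.empty(0, int), np.empty(0, int)
    lo, hi = pooled.min(), pooled.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # closed top edge

    sel_h: list[int] = []
    sel_l: list[int] = []
    sum_h = sum_l = 0.0
    for b in range(n_bins):
        in_h = [i for i in keep_h if edges[b] <= np.log10(ah[i]) < edges[b + 1]]
        in_l = [i for i in keep_l if edges[b] <= np.log10(al[i]) < edges[b + 1]]
        if not in_h or not in_l:
            continue
        rem_h = sorted(in_h, key=lambda i: ah[i])
        rem_l = sorted(in_l, key=lambda i: al[i])

        def draw(rem: list[int], upper: bool) -> int:
            # random member of the more (upper) or less (lower) active half
            mid = len(rem) // 2
            if upper:
                k = mid + int(rng.integers(len(rem) - mid))
            else:
                k = int(rng.integers(max(mid, 1)))
            return rem.pop(k)

        while rem_h and rem_l:
            if sel_h and sel_l:
                h_higher = sum_h / len(sel_h) > sum_l / len(sel_l)
            else:
                h_higher = bool(rng.integers(2))
            # the group running higher draws from its less active half
            pick_h = draw(rem_h, upper=not h_higher)
            pick_l = draw(rem_l, upper=h_higher)
            sel_h.append(pick_h)
            sel_l.append(pick_l)
            sum_h += ah[pick_h]
            sum_l += al[pick_l]
    return np.array(sel_h, dtype=int), np.array(sel_l, dtype=int)
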