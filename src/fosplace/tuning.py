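"""Spatial tuning: binned activity, circular smoothing, shuffle null,
place-field calling, spatial information and per-field properties.

The track is divided into 40 bins of 5 cm.  Only running frames
(speed > 5 cm/s) of eligible trials contribute.  Significance of spatial
tuning is assessed against a block-permutation null: on each shuffle the
behaviour stream is circularly shifted by a random number of frames, cut into
six blocks of near-equal duration, and the block order permuted — breaking
the activity-position pairing while preserving the autocorrelation of both
streams.  A place field is a maximal circular run of at least three
consecutive bins whose smoothed activity exceeds the per-bin 99th percentile
of the shuffle distribution.

Spatial information follows the mutual-information form
``H = sum_i p_i a_i log2(a_i / a)`` where ``p_i`` is the occupancy fraction of
bin i, ``a_i`` the mean activity there and ``a`` the overall mean; it is
reported both raw (bits) and normalized by its mean over shuffles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import SessionTimeseries

__all__ = [
    "BinnedActivity",
    "TuningResult",
    "bin_activity",
    "smooth_circular",
    "shuffle_block_permutation",
    "shuffle_null",
    "detect_place_fields",
    "spatial_information",
    "field_properties",
    "analyze_tuning",
]

DEFAULT_N_BINS = 40
DEFAULT_RUN_THRESHOLD = 5.0  # cm/s
DEFAULT_N_BLOCKS = 6
DEFAULT_SIGMA_BINS = 1.0
FIELD_MIN_BINS = 3
NULL_PERCENTILE = 99.0


@dataclass
class BinnedActivity:
    """Spatially binned activity for a population on one session.

    ``per_trial`` is (cells, trials, bins) with NaN where a bin was not
    visited on that trial; ``mean`` is the session mean over all contributing
    frames (NaN at zero-occupancy bins); ``occupancy`` sums to 1 over visited
    bins.  Frame-level vectors (``bin_of_frame`` etc.) index the retained
    (running, eligible) frames and are what the shuffle null permutes.
    """

    per_trial: np.ndarray
    mean: np.ndarray
    occupancy: np.ndarray
    counts: np.ndarray
    trial_ids: np.ndarray
    frame_index: np.ndarray
    bin_of_frame: np.ndarray
    trial_of_frame: np.ndarray
    activity: np.ndarray  # (cells, retained frames)
    bin_width: float

    @property
    def n_bins(self) -> int:
        return self.occupancy.size


def bin_activity(
    activity: np.ndarray,
    session: SessionTimeseries,
    eligible_trials: np.ndarray | None = None,
    run_threshold: float = DEFAULT_RUN_THRESHOLD,
    n_bins: int = DEFAULT_N_BINS,
) -> BinnedActivity:
    """Bin per-frame activity by track position over running frames.

    ``activity`` is (cells, frames) or (frames,) of significant-transient
    dF/F aligned with the session.  Frames contribute when their trial is
    eligible and speed exceeds ``run_threshold``.
    """
    act = np.atleast_2d(np.asarray(activity, dtype=float))
    if act.shape[1] != session.n_frames:
        raise ValueError("activity and session frame counts differ")
    if eligible_trials is None:
        eligible_trials = session.eligible_trials()
    eligible_trials = np.asarray(eligible_trials)
    keep = np.isin(session.trial_id, eligible_trials) & (session.speed > run_threshold)
    if not keep.any():
        raise ValueError("no running frames in any eligible trial")
    frame_index = np.flatnonzero(keep)
    bin_width = session.track_length / n_bins
    bins = np.minimum(
        (session.position[frame_index] // bin_width).astype(int), n_bins - 1
    )
    trials_of = session.trial_id[frame_index]
    sub = act[:, frame_index]

    counts = np.bincount(bins, minlength=n_bins)
    occupancy = counts / counts.sum()
    # session mean over all contributing frames
    sums = np.vstack([np.bincount(bins, weights=row, minlength=n_bins) for row in sub])
    mean = np.full((act.shape[0], n_bins), np.nan)
    vis = counts > 0
    mean[:, vis] = sums[:, vis] / counts[vis]

    # per-trial means
    t_index = {t: i for i, t in enumerate(eligible_trials)}
    flat = np.array([t_index[t] for t in trials_of]) * n_bins + bins
    nt = eligible_trials.size
    cnt_tb = np.bincount(flat, minlength=nt * n_bins).reshape(nt, n_bins)
    per_trial = np.full((act.shape[0], nt, n_bins), np.nan)
    for c in range(act.shape[0]):
        s = np.bincount(flat, weights=sub[c], minlength=nt * n_bins).reshape(nt, n_bins)
        with np.errstate(invalid="ignore"):
            per_trial[c] = np.where(cnt_tb > 0, s / np.maximum(cnt_tb, 1), np.nan)
    return BinnedActivity(
        per_trial=per_trial,
        mean=mean,
        occupancy=occupancy,
        counts=counts,
        trial_ids=eligible_trials,
        frame_index=frame_index,
        bin_of_frame=bins,
        trial_of_frame=trials_of,
        activity=sub,
        bin_width=bin_width,
    )


def _circular_kernel(n_bins: int, sigma_bins: float) -> np.ndarray:
    """Unit-sum circulant Gaussian kernel matrix (n_bins x n_bins)."""
    offs = np.arange(n_bins)
    d = np.minimum(offs, n_bins - offs)
    k = np.exp(-0.5 * (d / sigma_bins) ** 2)
    k /= k.sum()
    idx = (offs[:, None] - offs[None, :]) % n_bins
    return k[idx]


def smooth_circular(
    binned: np.ndarray, sigma_bins: float = DEFAULT_SIGMA_BINS
) -> np.ndarray:
    """Circular Gaussian smoothing of binned tuning curves.

    NaN bins (unvisited) are bridged: the kernel is renormalized over the
    finite bins so present neighbours carry their full weight.  Works on a
    single 40-vector or a stack (..., bins).
    """
    v = np.asarray(binned, dtype=float)
    n = v.shape[-1]
    K = _circular_kernel(n, sigma_bins)
    finite = np.isfinite(v)
    filled = np.where(finite, v, 0.0)
    num = filled @ K.T
    den = finite.astype(float) @ K.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def shuffle_block_permutation(
    n_frames: int,
    rng: np.random.Generator,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> np.ndarray:
    """One behaviour-shuffle index array.

    Circularly shifts ``arange(n_frames)`` by a uniform random offset, cuts
    the result into ``n_blocks`` contiguous blocks whose sizes differ by at
    most one frame (remainder on the leading blocks), and concatenates the
    blocks in a uniformly random order.
    """
    if n_frames < n_blocks:
        raise ValueError("fewer frames than blocks")
    offset = int(rng.integers(n_frames))
    shifted = (np.arange(n_frames) + offset) % n_frames
    base, rem = divmod(n_frames, n_blocks)
    sizes = np.full(n_blocks, base)
    sizes[:rem] += 1
    edges = np.r_[0, np.cumsum(sizes)]
    order = rng.permutation(n_blocks)
    return np.concatenate([shifted[edges[b] : edges[b + 1]] for b in order])


def spatial_information(
    mean_activity: np.ndarray, occupancy: np.ndarray
) -> np.ndarray:
    """Spatial information H = sum_i p_i a_i log2(a_i / a) in bits.

    Bins with zero activity contribute zero (the x log x convention); a
    silent curve (overall mean zero) has H = 0.  Accepts a (bins,) vector or
    a stack (..., bins); NaN bins are treated as unoccupied.
    """
    a = np.atleast_2d(np.asarray(mean_activity, dtype=float))
    p = np.asarray(occupancy, dtype=float)
    a = np.where(np.isfinite(a), a, 0.0)
    # masked transient traces are nonnegative up to merged gap frames; clip
    # the stray small negatives so the log stays defined
    a = np.maximum(a, 0.0)
    abar = a @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / abar[..., None]
        term = p * a * np.log2(ratio)
    term[~np.isfinite(term)] = 0.0
    H = term.sum(axis=-1)
    H[abar == 0] = 0.0
    out = np.maximum(H, 0.0)  # guard tiny negative rounding
    return out if np.asarray(mean_activity).ndim > 1 else float(out[0])


def shuffle_null(
    binned: BinnedActivity,
    n_shuffles: int = 1000,
    n_blocks: int = DEFAULT_N_BLOCKS,
    sigma_bins: float = DEFAULT_SIGMA_BINS,
    seed: int | np.random.Generator | None = None,
    percentile: float = NULL_PERCENTILE,
    observed: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Block-permutation shuffle null for every cell in ``binned``.

    Returns ``(null_curve, shuffle_H)`` where ``null_curve`` is the per-bin
    99th percentile of the smoothed shuffled tuning curves, (cells, bins),
    and ``shuffle_H`` the spatial information of each (unsmoothed) shuffled
    curve, (cells, n_shuffles).  One shuffle stream is shared by all cells of
    the session: the same behaviour permutation is applied against every
    cell's activity, mirroring a shuffle of the behaviour itself.

    If ``observed`` (the true smoothed curves, (cells, bins)) is given it is
    included in the distribution the percentile is taken over — the usual
    permutation-test convention (the identity pairing is one member of the
    permutation group), keeping the per-bin test level at or below its
    nominal rate.  ``shuffle_H`` never includes the observed curve.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    act_t = np.ascontiguousarray(binned.activity.T)  # (frames, cells): row gathers
    n_cells = act_t.shape[1]
    bins = binned.bin_of_frame
    n_bins = binned.n_bins
    counts = binned.counts
    vis = counts > 0
    p = binned.occupancy
    # bin counts are shuffle-invariant (same position multiset), so the
    # segment boundaries for the groupby-sum are fixed
    boundaries = np.r_[0, np.cumsum(counts[vis])[:-1]]
    # float64 throughout: a shuffle can reproduce the true pairing bin-wise,
    # and the strict > test must then see an exact tie, not a rounding gap
    K = _circular_kernel(n_bins, sigma_bins)
    den = vis.astype(float) @ K.T

    extra = 1 if observed is not None else 0
    curves = np.empty((n_shuffles + extra, n_cells, n_bins))
    if observed is not None:
        curves[n_shuffles] = np.where(np.isfinite(observed), observed, 0.0)
    shuffle_H = np.empty((n_cells, n_shuffles))
    for s in range(n_shuffles):
        # slot j pairs activity frame j with behaviour frame perm[j]; group
        # activity columns by the shuffled bin labels
        perm = shuffle_block_permutation(bins.size, rng, n_blocks)
        order = np.argsort(bins[perm], kind="stable")
        sums = np.add.reduceat(act_t[order], boundaries, axis=0)
        a_s = np.zeros((n_cells, n_bins))
        a_s[:, vis] = (sums / counts[vis][:, None]).T
        shuffle_H[:, s] = spatial_information(a_s, p)
        curves[s] = (np.where(vis, a_s, 0.0) @ K.T) / den
    null_curve = np.percentile(curves, percentile, axis=0)
    null_curve[:, den == 0] = np.nan
    return null_curve, shuffle_H


def detect_place_fields(
    smoothed: np.ndarray, null_curve: np.ndarray, min_bins: int = FIELD_MIN_BINS
) -> list[tuple[int, int]]:
    """Place fields of one cell: maximal circular runs of at least
    ``min_bins`` consecutive bins where the smoothed tuning strictly exceeds
    the shuffle null.  Returns ``(start_bin, length)`` pairs; bin 39 is
    adjacent to bin 0."""
    sm = np.asarray(smoothed, dtype=float)
    nc = np.asarray(null_curve, dtype=float)
    if sm.shape != nc.shape:
        raise ValueError("curve length mismatch")
    n = sm.size
    with np.errstate(invalid="ignore"):
        sig = (sm > nc) & np.isfinite(sm) & np.isfinite(nc)
    if sig.all():
        return [(0, n)]
    if not sig.any():
        return []
    # rotate so the sequence starts at a non-significant bin, find linear runs
    start0 = int(np.flatnonzero(~sig)[0])
    rolled = np.roll(sig, -start0)
    fields = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            if j - i >= min_bins:
                fields.append(((i + start0) % n, j - i))
            i = j
        else:
            i += 1
    return sorted(fields)


def field_bins(fields: list[tuple[int, int]], n_bins: int) -> np.ndarray:
    """Sorted array of all bins belonging to any field."""
    out: set[int] = set()
    for start, length in fields:
        out.update((start + k) % n_bins for k in range(length))
    return np.array(sorted(out), dtype=int)


def field_properties(
    cell_index: int,
    binned: BinnedActivity,
    fields: list[tuple[int, int]],
    sig_mask: np.ndarray,
) -> dict:
    """Per-cell place-field properties.

    ``trial_to_trial_corr`` is the mean off-diagonal entry of the trial x
    trial Pearson correlation matrix of the cell's trial-wise binned
    activity; entries for pairs where either trial lacks activity (or the
    correlation is undefined) are set to zero.  ``fraction_active`` is the
    fraction of eligible trials with at least one significant-transient frame
    inside the cell's fields.  ``selectivity`` contrasts mean in-field with
    mean out-of-field binned activity.  ``sig_mask`` is the cell's full-
    session significant-frame mask.
    """
    if not fields:
        raise ValueError("cell has no place field")
    pt = binned.per_trial[cell_index]
    nt = pt.shape[0]
    if nt < 2:
        raise ValueError("need at least 2 eligible trials")
    n_bins = binned.n_bins
    fb = field_bins(fields, n_bins)

    # trial-to-trial correlation; complete trials in one corrcoef call,
    # trials with unvisited bins pairwise-complete in a fallback loop
    has_act = np.nansum(np.abs(pt), axis=1) > 0
    complete = np.isfinite(pt).all(axis=1) & has_act & (np.nanstd(pt, axis=1) > 0)
    R = np.zeros((nt, nt))
    ci = np.flatnonzero(complete)
    if ci.size >= 2:
        R[np.ix_(ci, ci)] = np.corrcoef(pt[ci])
    rest = [
        (i, j)
        for i in range(nt)
        for j in range(i + 1, nt)
        if not (complete[i] and complete[j])
    ]
    for i, j in rest:
        r = 0.0
        if has_act[i] and has_act[j]:
            shared = np.isfinite(pt[i]) & np.isfinite(pt[j])
            if shared.sum() >= 2:
                xi, xj = pt[i, shared], pt[j, shared]
                if xi.std() > 0 and xj.std() > 0:
                    r = float(np.corrcoef(xi, xj)[0, 1])
        R[i, j] = R[j, i] = r
    iu = np.triu_indices(nt, 1)
    trial_corr = float(R[iu].mean())

    # fraction of trials with a significant transient inside the field
    infield_frame = np.isin(binned.bin_of_frame, fb)
    sig_sub = np.asarray(sig_mask, dtype=bool)[binned.frame_index]
    active = 0
    for t in binned.trial_ids:
        sel = binned.trial_of_frame == t
        if np.any(sig_sub[sel] & infield_frame[sel]):
            active += 1
    fraction_active = active / binned.trial_ids.size

    mean = binned.mean[cell_index]
    out_bins = np.setdiff1d(np.arange(n_bins), fb)
    in_act = float(np.nanmean(mean[fb]))
    out_act = float(np.nanmean(mean[out_bins])) if out_bins.size else 0.0
    denom = in_act + out_act
    selectivity = (in_act - out_act) / denom if denom > 0 else float("nan")

    widths = [length * binned.bin_width for _, length in fields]
    sm = smooth_circular(mean)
    peak_bin = int(fb[np.argmax(sm[fb])])
    return dict(
        trial_to_trial_corr=trial_corr,
        fraction_active=fraction_active,
        selectivity=selectivity,
        field_widths_cm=widths,
        total_field_width_cm=float(sum(widths)),
        peak_bin=peak_bin,
    )


@dataclass
class TuningResult:
    """Population tuning for one session: curves, null, fields, information."""

    binned: BinnedActivity
    smoothed: np.ndarray
    null_curve: np.ndarray
    shuffle_H: np.ndarray
    H: np.ndarray
    H_norm: np.ndarray
    fields: list[list[tuple[int, int]]]
    is_place_cell: np.ndarray


def analyze_tuning(
    activity: np.ndarray,
    session: SessionTimeseries,
    eligible_trials: np.ndarray | None = None,
    n_shuffles: int = 1000,
    run_threshold: float = DEFAULT_RUN_THRESHOLD,
    n_bins: int = DEFAULT_N_BINS,
    sigma_bins: float = DEFAULT_SIGMA_BINS,
    n_blocks: int = DEFAULT_N_BLOCKS,
    seed: int | np.random.Generator | None = None,
) -> TuningResult:
    """Full tuning analysis for a population: bin, smooth, shuffle, call
    fields and compute (normalized) spatial information.

    Spatial information uses the unsmoothed binned means; the field test uses
    the smoothed curves against the smoothed-shuffle 99th percentile.
    """
    binned = bin_activity(activity, session, eligible_trials, run_threshold, n_bins)
    smoothed = smooth_circular(binned.mean, sigma_bins)
    null_curve, shuffle_H = shuffle_null(
        binned, n_shuffles=n_shuffles, n_blocks=n_blocks, sigma_bins=sigma_bins,
        seed=seed, observed=smoothed,
    )
    H = spatial_information(binned.mean, binned.occupancy)
    mean_shuffle = shuffle_H.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        H_norm = np.where(mean_shuffle > 0, H / mean_shuffle, np.nan)
    fields = [
        detect_place_fields(smoothed[c], null_curve[c])
        for c in range(smoothed.shape[0])
    ]
    is_pc = np.array([len(f) > 0 for f in fields])
    return TuningResult(
        binned=binned,
        smoothed=smoothed,
        null_curve=null_curve,
        shuffle_H=shuffle_H,
        H=np.atleast_1d(H),
        H_norm=np.atleast_1d(H_norm),
        fields=fields,
        is_place_cell=is_pc,
    )
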