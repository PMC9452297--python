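"""Fluorescence-trace preprocessing: dF/F baselining and significant-transient detection.

Raw fluorescence is converted to dF/F against a rolling-percentile baseline.
Significant calcium transients are then identified by an empirical
false-positive-rate (FPR) criterion: at each threshold ``t`` (in units of the
trace standard deviation), the rate of negative-going excursions below ``-t``
of a given duration estimates how often noise alone produces positive
excursions of that size, because baseline noise is symmetric while real
transients are strictly positive.  A positive excursion is accepted when that
empirical rate falls below 0.1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransientTrace",
    "compute_dff",
    "detect_significant_transients",
    "transient_stats",
    "find_runs",
]

#: threshold grid in units of sigma: 1.0, 1.2, ..., 4.0
DEFAULT_THRESHOLDS = np.round(np.arange(1.0, 4.0 + 1e-9, 0.2), 10)
DEFAULT_FPR = 0.001


@dataclass
class TransientTrace:
    """Significance-masked, zero-baseline dF/F trace for one cell.

    ``dff`` keeps the original dF/F value on significant frames and is exactly
    zero elsewhere.  ``transients`` records each retained transient;
    ``acceptances`` records, per retained transient, the (threshold, run
    length, FPR) combinations at which its constituent runs were accepted
    before merging, so the FPR bound can be re-audited post hoc.
    """

    dff: np.ndarray
    mask: np.ndarray
    transients: pd.DataFrame
    acceptances: list = field(default_factory=list)
    standardized: np.ndarray | None = None

    @property
    def n_transients(self) -> int:
        return len(self.transients)

    def alpha(self, frame_rate: float) -> float:
        """Integrated significant dF/F (sum over frames times frame period, s)."""
        return float(self.dff[self.mask].sum()) / frame_rate


def compute_dff(
    raw: np.ndarray,
    frame_rate: float,
    window_s: float = 60.0,
    percentile: float = 30.0,
) -> np.ndarray:
    """dF/F from raw fluorescence using a moving-percentile baseline.

    The baseline at frame ``i`` is the 30th percentile of the raw trace in a
    60-s window centred on ``i`` (truncated at the trace edges); dF/F is
    ``(raw - baseline) / baseline``.

    Parameters
    ----------
    raw
        Raw fluorescence, shape ``(frames,)`` or ``(cells, frames)``.
    frame_rate
        Acquisition rate in Hz.
    window_s
        Width of the moving window in seconds.
    percentile
        Percentile used as the baseline estimate.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw trace contains non-finite values")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if raw.ndim == 2:
        return np.vstack(
            [compute_dff(r, frame_rate, window_s, percentile) for r in raw]
        )
    n = raw.size
    w = int(round(window_s * frame_rate))
    if n <= w // 2:
        raise ValueError("trace shorter than half the baseline window")
    half = w // 2
    baseline = np.empty(n)
    # interior frames: vectorized sliding windows, chunked to bound memory
    full = n - 2 * half
    if full > 0:
        win = np.lib.stride_tricks.sliding_window_view(raw, 2 * half + 1)
        step = max(1, int(2e7) // (2 * half + 1))
        for s in range(0, full, step):
            e = min(full, s + step)
            baseline[half + s : half + e] = np.percentile(win[s:e], percentile, axis=1)
    # truncated edge windows
    for i in range(min(half, n)):
        baseline[i] = np.percentile(raw[: i + half + 1], percentile)
    for i in range(max(n - half, 0), n):
        baseline[i] = np.percentile(raw[i - half :], percentile)
    if np.any(baseline <= 0):
        raise ValueError("non-positive baseline; raw trace looks corrupt")
    return (raw - baseline) / baseline


def find_runs(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True in a boolean vector as an ``(n, 2)`` array of
    half-open ``[start, end)`` frame intervals."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return np.empty((0, 2), dtype=int)
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return np.column_stack([starts, ends])


def detect_significant_transients(
    dff: np.ndarray,
    fpr_threshold: float = DEFAULT_FPR,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> TransientTrace:
    """Identify significant transients in a single-cell dF/F trace.

    The trace is standardized by subtracting its median and dividing by its
    standard deviation.  For each threshold ``t`` in the grid, maximal runs of
    frames strictly above ``+t`` are candidate transients; for a candidate of
    length ``n``, ``FPR(t, n)`` is the number of runs strictly below ``-t``
    lasting at least ``n`` frames divided by the number of runs above ``+t``
    lasting at least ``n`` frames (the candidate itself counts, so the
    denominator is never zero).  Candidates with ``FPR < fpr_threshold`` are
    significant at that level; the final mask is the union across thresholds.
    Runs separated by a gap of fewer than two frames are then merged (the gap
    frames recover their original dF/F) and runs shorter than two frames are
    dropped.
    """
    x = np.asarray(dff, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-cell 1-D trace")
    if x.size < 10:
        raise ValueError("trace too short")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite dF/F")
    sd = x.std()
    if sd == 0:
        raise ValueError("zero-variance trace cannot be standardized")
    z = (x - np.median(x)) / sd

    mask = np.zeros(x.size, dtype=bool)
    accepted: list[tuple[int, int, float, int, float]] = []  # start, end, t, n, fpr
    for t in thresholds:
        pos = find_runs(z > t)
        if len(pos) == 0:
            continue
        neg = find_runs(z < -t)
        pos_len = pos[:, 1] - pos[:, 0]
        neg_len = np.sort(neg[:, 1] - neg[:, 0]) if len(neg) else np.empty(0, int)
        pos_sorted = np.sort(pos_len)
        for (s, e), n in zip(pos, pos_len):
            n_neg = neg_len.size - np.searchsorted(neg_len, n, side="left")
            n_pos = pos_sorted.size - np.searchsorted(pos_sorted, n, side="left")
            fpr = n_neg / n_pos
            if fpr < fpr_threshold:
                mask[s:e] = True
                accepted.append((int(s), int(e), float(t), int(n), float(fpr)))

    # merge runs separated by < 2 frames (i.e. a single-frame gap)
    runs = find_runs(mask)
    for i in range(len(runs) - 1):
        if runs[i + 1, 0] - runs[i, 1] < 2:
            mask[runs[i, 1] : runs[i + 1, 0]] = True
    # drop transients shorter than 2 frames
    runs = find_runs(mask)
    for s, e in runs:
        if e - s < 2:
            mask[s:e] = False
    runs = find_runs(mask)

    out = np.where(mask, x, 0.0)
    records = []
    acceptances: list[list[tuple[float, int, float]]] = []
    for s, e in runs:
        seg = x[s:e]
        records.append(
            dict(
                start_frame=int(s),
                end_frame=int(e),
                duration_frames=int(e - s),
                peak_dff=float(seg.max()),
                sum_dff=float(seg.sum()),
            )
        )
        acceptances.append(
            [(t, n, fpr) for (as_, ae, t, n, fpr) in accepted if as_ >= s and ae <= e]
        )
    cols = ["start_frame", "end_frame", "duration_frames", "peak_dff", "sum_dff"]
    transients = pd.DataFrame(records, columns=cols)
    return TransientTrace(
        dff=out, mask=mask, transients=transients, acceptances=acceptances,
        standardized=z,
    )


def transient_stats(tr: TransientTrace, frame_rate: float) -> dict:
    """Per-cell summary statistics of retained transients.

    Durations are in seconds, integrals in dF/F * s; ``alpha`` is the
    integrated significant dF/F over the whole trace.  With no transients all
    means are reported as 0 with ``empty=True``.
    """
    n = tr.n_transients
    total_s = tr.dff.size / frame_rate
    if n == 0:
        return dict(
            n_transients=0,
            transients_per_second=0.0,
            mean_duration_s=0.0,
            mean_peak=0.0,
            mean_integral=0.0,
            alpha=0.0,
            empty=True,
        )
    dur = tr.transients["duration_frames"].to_numpy() / frame_rate
    integ = tr.transients["sum_dff"].to_numpy() / frame_rate
    return dict(
        n_transients=int(n),
        transients_per_second=n / total_s,
        mean_duration_s=float(dur.mean()),
        mean_peak=float(tr.transients["peak_dff"].mean()),
        mean_integral=float(integ.mean()),
        alpha=tr.alpha(frame_rate),
        empty=False,
    )
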