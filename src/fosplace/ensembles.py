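"""Trial-wise ensemble analysis of place-cell co-activation.

The activation matrix holds each place cell's mean in-field activity on each
eligible trial; correlating its columns quantifies shared trial-by-trial
fluctuations between cells regardless of where their fields sit on the
track.  Cells are clustered on this correlation structure with affinity
propagation, and the tendency of a labelled group (e.g. Fos-high) to share
clusters is scored against a label-permutation chance level.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .tuning import BinnedActivity, field_bins

__all__ = [
    "activation_matrix",
    "within_group_correlation",
    "cluster_cells",
    "same_cluster_vs_chance",
    "crossday_within_group",
]

MIN_SHARED_TRIALS = 3


def activation_matrix(
    binned: BinnedActivity, fields: list[list[tuple[int, int]]],
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """(trials, place cells) matrix of mean in-field activity per trial.

    ``fields`` lists each cell's place fields as (start_bin, length) runs;
    only cells with at least one field may be included.  Entry (t, c) is the
    mean of cell c's trial-t binned activity over its field bins; NaN when no
    field bin was visited on that trial.
    """
    if cells is None:
        cells = np.flatnonzero([len(f) > 0 for f in fields])
    cells = np.asarray(cells)
    if any(len(fields[c]) == 0 for c in cells):
        raise ValueError("activation matrix includes a cell without a field")
    nt = binned.per_trial.shape[1]
    if nt < 2 or cells.size < 2:
        raise ValueError("need at least 2 trials and 2 place cells")
    out = np.full((nt, cells.size), np.nan)
    for j, c in enumerate(cells):
        fb = field_bins(fields[c], binned.n_bins)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[:, j] = np.nanmean(binned.per_trial[c][:, fb], axis=1)
    return out


def _pairwise_corr(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation over shared finite trials; None when undefined."""
    shared = np.isfinite(x) & np.isfinite(y)
    if shared.sum() < MIN_SHARED_TRIALS:
        return None
    xs, ys = x[shared], y[shared]
    if xs.std() == 0 or ys.std() == 0:
        return None
    return float(np.corrcoef(xs, ys)[0, 1])


def within_group_correlation(
    matrix: np.ndarray, group_cols: np.ndarray
) -> float:
    """Mean pairwise trial-wise activation correlation within one group.

    Averages the Pearson correlation over all distinct pairs of the group's
    columns, each computed over their shared non-missing trials; pairs with
    fewer than 3 shared trials or zero variance are skipped.  NaN when no
    valid pair remains.
    """
    cols = np.asarray(group_cols)
    if cols.size < 2:
        raise ValueError("group needs at least 2 cells")
    vals = []
    for i in range(cols.size):
        for j in range(i + 1, cols.size):
            r = _pairwise_corr(matrix[:, cols[i]], matrix[:, cols[j]])
            if r is not None:
                vals.append(r)
    return float(np.mean(vals)) if vals else float("nan")


def correlation_matrix(matrix: np.ndarray) -> np.ndarray:
    """Cell x cell correlation of activation columns for clustering.

    Missing activation entries are imputed as zero first (the clustering
    similarity needs a complete matrix); undefined correlations (zero
    variance) become 0 and the diagonal is 1.
    """
    m = np.where(np.isfinite(matrix), matrix, 0.0)
    sd = m.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(m, rowvar=False)
    c = np.where(np.isfinite(c), c, 0.0)
    np.fill_diagonal(c, 1.0)
    c[sd == 0, :] = 0.0
    c[:, sd == 0] = 0.0
    np.fill_diagonal(c, 1.0)
    return c


def cluster_cells(
    corr: np.ndarray,
    preference: float = -1.0,
    max_iter: int = 5000,
    damping: float = 0.9,
    seed: int | None = 0,
) -> tuple[np.ndarray, bool]:
    """Affinity-propagation clustering on a pairwise-correlation similarity.

    Returns (labels, converged).  The preference (self-similarity) is -1 and
    the iteration cap 5000; damping 0.9.  On non-convergence each cell is
    left in its own cluster and ``converged`` is False.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("similarity matrix must be square")
    if np.isnan(corr).any():
        raise ValueError("similarity matrix has missing entries; impute first")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    ap = AffinityPropagation(
        affinity="precomputed",
        preference=preference,
        max_iter=max_iter,
        damping=damping,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = ap.fit_predict(corr)
    converged = labels.min() >= 0 and ap.cluster_centers_indices_ is not None
    if not converged:
        labels = np.arange(corr.shape[0])
    return labels, bool(converged)


def _same_cluster_prob(labels: np.ndarray, members: np.ndarray) -> float:
    sub = labels[members]
    n = sub.size
    same = sum(
        1 for i in range(n) for j in range(i + 1, n) if sub[i] == sub[j]
    )
    return same / (n * (n - 1) / 2)


def same_cluster_vs_chance(
    labels: np.ndarray,
    group_members: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Probability that group members share a cluster, relative to chance.

    Chance is the mean same-cluster pair probability over ``n_perm`` random
    draws of equally sized cell sets (equivalent to permuting the group
    labels over the fixed clustering).  A single-cluster partition gives
    ratio 1 by construction.
    """
    labels = np.asarray(labels)
    members = np.asarray(group_members)
    if members.size < 2:
        raise ValueError("group needs at least 2 cells")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = _same_cluster_prob(labels, members)
    if np.unique(labels).size == 1:
        return 1.0
    chance = np.mean(
        [
            _same_cluster_prob(
                labels, rng.choice(labels.size, members.size, replace=False)
            )
            for _ in range(n_perm)
        ]
    )
    return float(obs / chance) if chance > 0 else float("inf")


def crossday_within_group(
    target_matrix: np.ndarray,
    target_cells: np.ndarray,
    reference_group_cells: np.ndarray,
) -> float:
    """Within-group correlation on a target session, groups fixed by the
    reference session's induction.

    ``target_matrix`` is the target session's activation matrix over
    ``target_cells`` (global cell ids, place cells on the target);
    ``reference_group_cells`` are the global ids of the group defined on the
    reference session.  Only group members present and fielded on the target
    contribute.
    """
    target_cells = np.asarray(target_cells)
    cols = np.flatnonzero(np.isin(target_cells, np.asarray(reference_group_cells)))
    if cols.size < 2:
        raise ValueError("fewer than 2 group members present on target session")
    return within_group_correlation(target_matrix, cols)
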