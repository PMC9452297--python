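"""Fos fold-induction quantification from pre/post GFP images.

Fold induction at a cell is the ratio of post-behaviour to pre-behaviour
reporter fluorescence, normalized by a background image obtained by 2-D
median filtering the ratio image with a ~50 x 50 um window.  The median
filter absorbs slowly varying brightness changes (imaging conditions) while
leaving the sparse nuclear GFP signal intact.  Per-cell values are means over
a 10-um-diameter circular ROI; cells are ranked into deciles per session,
with the top 20% labelled high and the bottom 20% low.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "fold_induction_map",
    "cell_fold_induction",
    "assign_induction_groups",
    "standardize_timecourse",
]

DEFAULT_WINDOW_UM = 50.0
DEFAULT_ROI_DIAMETER_UM = 10.0


def _odd_window_px(window_um: float, um_per_px: float) -> int:
    w = int(round(window_um / um_per_px))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


def fold_induction_map(
    pre: np.ndarray,
    post: np.ndarray,
    um_per_px: float,
    exclusion_mask: np.ndarray | None = None,
    window_um: float = DEFAULT_WINDOW_UM,
) -> np.ndarray:
    """Background-normalized fold-induction image.

    ``post / pre`` is divided by its own 2-D median filter (square window of
    edge ~``window_um``, rounded to an odd pixel count, reflective padding).
    Pixels in ``exclusion_mask`` (registration artefacts etc.) propagate NaN;
    for the purpose of the median filter they are replaced by the global
    median of the included ratio pixels so they do not drag the background.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("pre and post must be registered 2-D images of equal shape")
    if exclusion_mask is None:
        exclusion_mask = np.zeros(pre.shape, dtype=bool)
    exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
    ok = ~exclusion_mask
    if np.any(pre[ok] <= 0):
        raise ValueError("non-positive pre-image pixels outside the exclusion mask")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = post / pre
    filler = np.median(ratio[ok])
    filled = np.where(ok, ratio, filler)
    w = _odd_window_px(window_um, um_per_px)
    background = ndimage.median_filter(filled, size=w, mode="reflect")
    if np.any(background[ok] <= 0):
        raise ValueError("non-positive background estimate")
    out = np.where(ok, ratio / background, np.nan)
    return out


def _disc_offsets(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = yy**2 + xx**2 <= radius_px**2
    return np.column_stack([yy[inside], xx[inside]])


def cell_fold_induction(
    fold_map: np.ndarray,
    centroids: np.ndarray,
    um_per_px: float,
    roi_diameter_um: float = DEFAULT_ROI_DIAMETER_UM,
) -> pd.DataFrame:
    """Per-cell fold induction: mean of the fold map over a circular ROI.

    ``centroids`` is (cells, 2) as (row, col) pixel coordinates.  The ROI
    radius is 5 um (at least 1 px).  Discs are clipped at the image border;
    cells with more than half of their in-bounds disc pixels excluded (NaN)
    are flagged ``excluded``.
    """
    fold_map = np.asarray(fold_map, dtype=float)
    centroids = np.asarray(centroids, dtype=float)
    radius_px = max(roi_diameter_um / 2.0 / um_per_px, 1.0)
    offs = _disc_offsets(radius_px)
    h, wid = fold_map.shape
    rows = []
    for cid, (r, c) in enumerate(centroids):
        if not (0 <= r < h and 0 <= c < wid):
            raise ValueError(f"centroid {cid} outside the image")
        pix = offs + np.array([round(r), round(c)])
        inb = (
            (pix[:, 0] >= 0) & (pix[:, 0] < h) & (pix[:, 1] >= 0) & (pix[:, 1] < wid)
        )
        vals = fold_map[pix[inb, 0], pix[inb, 1]]
        n_nan = int(np.isnan(vals).sum())
        excluded = n_nan > vals.size / 2
        value = float(np.nanmean(vals)) if n_nan < vals.size else float("nan")
        rows.append(dict(cell_id=cid, fold_induction=value, excluded=excluded))
    return pd.DataFrame(rows)


def assign_induction_groups(
    values: np.ndarray,
    cell_ids: np.ndarray | None = None,
    excluded: np.ndarray | None = None,
) -> pd.DataFrame:
    """Decile ranks and high/low/mid group labels for per-cell fold induction.

    Deciles are assigned from the rank order among non-excluded cells (decile
    sizes as equal as possible); ties are broken by cell id so the assignment
    is deterministic.  High = deciles 9-10 (top 20%), low = deciles 1-2
    (bottom 20%), mid otherwise.  Excluded or NaN cells get decile 0 and
    group "excluded".
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids = np.asarray(cell_ids)
    if excluded is None:
        excluded = np.zeros(n, dtype=bool)
    excluded = np.asarray(excluded, dtype=bool) | ~np.isfinite(v)

    ok = np.flatnonzero(~excluded)
    if ok.size < 10:
        raise ValueError("need at least 10 non-excluded cells for deciles")
    if np.all(v[ok] == v[ok[0]]):
        raise ValueError("all fold-induction values identical; deciles degenerate")
    order = ok[np.lexsort((cell_ids[ok], v[ok]))]
    decile = np.zeros(n, dtype=int)
    m = ok.size
    for rank, idx in enumerate(order):
        decile[idx] = rank * 10 // m + 1
    group = np.where(
        excluded, "excluded",
        np.where(decile >= 9, "high", np.where((decile >= 1) & (decile <= 2), "low", "mid")),
    )
    return pd.DataFrame(
        dict(
            cell_id=cell_ids,
            fold_induction=v,
            decile=decile,
            group=group,
            excluded=excluded,
        )
    )


def standardize_timecourse(
    images: list[np.ndarray],
    timestamps_h: np.ndarray,
    um_per_px: float,
    centroids: np.ndarray | None = None,
    window_um: float = DEFAULT_WINDOW_UM,
    bin_width_h: float = 1.0,
) -> dict:
    """Standardize an image time series and extract fold-induction kinetics.

    Each image is centred on its median and scaled by its median absolute
    deviation (MAD), then rescaled by a shared multiplicative factor ``A``
    (the MAD of pixel values pooled across the whole series) and additive
    offset ``B`` (the pooled median), so all images share one robust
    intensity scale.  Fold maps are computed against the first image; if
    ``centroids`` are given, per-cell fold values are averaged within
    ``bin_width_h``-hour bins from the first timestamp.
    """
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    images = [np.asarray(im, dtype=float) for im in images]
    timestamps_h = np.asarray(timestamps_h, dtype=float)
    pooled = np.concatenate([im.ravel() for im in images])
    B = float(np.median(pooled))
    A = float(np.median(np.abs(pooled - B)))
    if A <= 0:
        raise ValueError("zero pooled MAD")
    standardized = []
    for im in images:
        med = np.median(im)
        mad = np.median(np.abs(im - med))
        if mad == 0:
            raise ValueError("image with zero MAD")
        standardized.append((im - med) / mad * A + B)
    ref = standardized[0]
    fold_maps = [
        fold_induction_map(ref, im, um_per_px, window_um=window_um)
        for im in standardized[1:]
    ]
    out = dict(standardized=standardized, fold_maps=fold_maps, A=A, B=B)
    if centroids is not None:
        t0 = timestamps_h[0]
        recs = []
        for im_idx, fm in enumerate(fold_maps):
            t = timestamps_h[im_idx + 1]
            cells = cell_fold_induction(fm, centroids, um_per_px)
            for _, row in cells.iterrows():
                recs.append(
                    dict(
                        cell_id=int(row.cell_id),
                        time_h=t - t0,
                        time_bin=int((t - t0) // bin_width_h),
                        fold_induction=row.fold_induction,
                    )
                )
        df = pd.DataFrame(recs)
        out["timecourse"] = (
            df.groupby(["cell_id", "time_bin"])["fold_induction"].mean().reset_index()
        )
    return out
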