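"""Cross-day place-field stability maps and group contrasts.

For a pair of sessions (reference before target), each shared place cell
contributes a Pearson correlation ``x`` between its spatially binned
activity on the two sessions.  Stability at track bin ``i`` is the weighted
mean of ``x`` with weights ``w`` proportional to each cell's reference
activity in that bin; each cell's reference tuning is first normalized to
sum to one so every place field contributes equally regardless of activity
level.  Maps require at least 20 cells per group.  Group differences are
tested per bin and per zone with a paired sign-flip permutation test across
session-to-session comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StabilityMap",
    "placefield_correlation",
    "stability_map",
    "zone_bins",
    "zone_summary",
    "stability_difference_test",
    "remap_contingency",
]

MIN_CELLS = 20


@dataclass
class StabilityMap:
    stability: np.ndarray  # (bins,), NaN where no weight
    x: np.ndarray  # per-cell cross-session tuning correlation
    n_cells: int
    group: str = ""
    delta_sessions: int = 0


def placefield_correlation(
    ref_curves: np.ndarray, target_curves: np.ndarray
) -> np.ndarray:
    """Per-cell Pearson correlation of binned tuning between two sessions.

    Rows are cells (present on both sessions, fields on the reference).
    Cells with zero variance on either session get NaN and are skipped
    downstream.
    """
    a = np.atleast_2d(np.asarray(ref_curves, dtype=float))
    b = np.atleast_2d(np.asarray(target_curves, dtype=float))
    if a.shape != b.shape:
        raise ValueError("curve shapes differ")
    out = np.full(a.shape[0], np.nan)
    for c in range(a.shape[0]):
        shared = np.isfinite(a[c]) & np.isfinite(b[c])
        if shared.sum() < 2:
            continue
        x, y = a[c, shared], b[c, shared]
        if x.std() == 0 or y.std() == 0:
            continue
        out[c] = np.corrcoef(x, y)[0, 1]
    return out


def stability_map(
    x: np.ndarray,
    ref_activity: np.ndarray,
    min_cells: int = MIN_CELLS,
    group: str = "",
    delta_sessions: int = 0,
) -> StabilityMap:
    """Activity-weighted stability map over track bins.

    ``x`` is the per-cell cross-session correlation vector; ``ref_activity``
    the cells' reference-session binned tuning (cells, bins), nonnegative.
    Cells with NaN ``x`` are dropped; fewer than ``min_cells`` remaining
    cells raises (the session pair is excluded).
    """
    x = np.asarray(x, dtype=float)
    act = np.atleast_2d(np.asarray(ref_activity, dtype=float))
    if act.shape[0] != x.size:
        raise ValueError("x and ref_activity cell counts differ")
    keep = np.isfinite(x)
    x = x[keep]
    act = np.where(np.isfinite(act[keep]), act[keep], 0.0)
    if np.any(act < 0):
        raise ValueError("reference activity must be nonnegative")
    if x.size < min_cells:
        raise ValueError(
            f"only {x.size} cells with defined stability (< {min_cells}); pair excluded"
        )
    row_sums = act.sum(axis=1)
    ok = row_sums > 0
    w = np.zeros_like(act)
    w[ok] = act[ok] / row_sums[ok, None]
    tot = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stab = (w * x[:, None]).sum(axis=0) / tot
    stab[tot == 0] = np.nan
    return StabilityMap(
        stability=stab, x=x, n_cells=int(x.size), group=group,
        delta_sessions=delta_sessions,
    )


def zone_bins(
    reward_zone: tuple[float, float],
    track_length: float,
    n_bins: int,
    margin_cm: float = 20.0,
) -> dict[str, np.ndarray]:
    """Peri-reward and no-reward bin sets.

    Peri-reward covers the reward zone extended by ``margin_cm`` on each
    side (circularly); no-reward is the remaining bins.
    """
    bw = track_length / n_bins
    centres = (np.arange(n_bins) + 0.5) * bw
    zs, ze = reward_zone
    lo, hi = zs - margin_cm, ze + margin_cm
    pos = np.mod(centres - lo, track_length)
    peri = pos < np.mod(hi - lo, track_length) if (hi - lo) < track_length else np.ones(n_bins, bool)
    return {
        "peri_reward": np.flatnonzero(peri),
        "no_reward": np.flatnonzero(~peri),
    }


def zone_summary(map_: StabilityMap | np.ndarray, zones: dict[str, np.ndarray]) -> dict[str, float]:
    """Unweighted mean of non-missing per-bin stability within each zone."""
    stab = map_.stability if isinstance(map_, StabilityMap) else np.asarray(map_, float)
    out = {}
    for name, bins in zones.items():
        if len(bins) == 0:
            raise ValueError(f"zone {name!r} is empty")
        out[name] = float(np.nanmean(stab[bins]))
    return out


def stability_difference_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    zones: dict[str, np.ndarray],
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Paired sign-flip permutation test of per-bin group stability differences.

    ``maps_a`` and ``maps_b`` are (comparisons, bins) stacks of paired group
    maps (one row per session-to-session comparison).  The statistic is the
    mean over comparisons of the per-bin difference A - B; the null flips
    each comparison's group assignment at random.  Also tests the zone
    contrast: the A - B difference averaged over peri-reward bins minus over
    no-reward bins.  P-values are two-sided with add-one smoothing.
    """
    a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("map stacks differ in shape")
    k = a.shape[0]
    if k < 2:
        raise ValueError("need at least 2 comparisons")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = a - b  # (k, bins)
    peri, nore = zones["peri_reward"], zones["no_reward"]

    def zone_contrast(dd: np.ndarray) -> float:
        return float(
            np.nanmean(np.nanmean(dd[:, peri], axis=1) - np.nanmean(dd[:, nore], axis=1))
        )

    obs_bin = np.nanmean(d, axis=0)
    obs_zone = zone_contrast(d)
    count_bin = np.zeros(d.shape[1])
    count_zone = 0
    for _ in range(n_shuffles):
        signs = rng.choice([-1.0, 1.0], size=k)[:, None]
        dn = d * signs
        count_bin += np.abs(np.nanmean(dn, axis=0)) >= np.abs(obs_bin) - 1e-12
        if abs(zone_contrast(dn)) >= abs(obs_zone) - 1e-12:
            count_zone += 1
    p_bin = (count_bin + 1) / (n_shuffles + 1)
    p_zone = (count_zone + 1) / (n_shuffles + 1)
    return dict(
        mean_difference=obs_bin,
        p_per_bin=p_bin,
        zone_contrast=obs_zone,
        p_zone=float(p_zone),
    )


def remap_contingency(
    has_field_env1: np.ndarray,
    has_field_env2: np.ndarray,
    high_induction_env2: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Field gain/loss across environments versus induction in the second.

    Among cells without a field in environment 1, compares the proportion
    with high induction in environment 2 between those that gained a field
    and those that did not; among cells with a field in environment 1,
    between those that lost it and those that kept it.  Permutation p-values
    shuffle the induction labels within each stratum.
    """
    f1 = np.asarray(has_field_env1, dtype=bool)
    f2 = np.asarray(has_field_env2, dtype=bool)
    hi = np.asarray(high_induction_env2, dtype=bool)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def stratum(mask: np.ndarray, positive: np.ndarray) -> dict:
        pos, neg = mask & positive, mask & ~positive
        if pos.sum() == 0 or neg.sum() == 0:
            raise ValueError("empty contingency cell")
        p_pos = hi[pos].mean()
        p_neg = hi[neg].mean()
        obs = abs(p_pos - p_neg)
        idx = np.flatnonzero(mask)
        lab = hi[idx].copy()
        split = positive[idx]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(lab)
            if abs(perm[split].mean() - perm[~split].mean()) >= obs - 1e-12:
                count += 1
        return dict(
            p_high_positive=float(p_pos),
            p_high_negative=float(p_neg),
            p_value=(count + 1) / (n_perm + 1),
        )

    return dict(
        gained=stratum(~f1, f2),  # gained vs never had a field
        lost=stratum(f1, ~f2),  # lost vs kept the field
    )
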