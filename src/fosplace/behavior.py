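"""Behaviour on the circular virtual track: trials, licks, selectivity.

The track is 200 cm long and circularly continuous.  A session is a sequence
of laps (trials); each trial is one of three types: on *standard* trials a
water reward is delivered at the first lick inside the hidden reward zone, on
*crutch* trials at zone entry regardless of licking, and on *probe* trials
never.  Licks in the reward zone after reward delivery are *consumption*
licks; all others are *test* licks and are the ones that enter behavioural
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SessionTimeseries",
    "segment_and_classify",
    "licking_selectivity",
    "permutation_test_two_sided",
    "stable_session_filter",
]

TRIAL_TYPES = ("standard", "crutch", "probe")

# trial-eligibility criteria for place-field analyses
MIN_LICKS = 3
MIN_DURATION_S = 4.0
MAX_DURATION_S = 60.0
MAX_CUM_REWARD_ML = 1.2


@dataclass
class SessionTimeseries:
    """Frame-synchronized behaviour for one session.

    ``position`` is in cm on the circular track, ``speed`` in cm/s,
    ``trial_id`` assigns every frame to a lap.  ``licks`` has columns
    (frame, kind) with kind in {"test", "consumption"}; ``rewards`` has
    (frame, volume_ml, manual); ``trials`` carries per-trial metadata
    including the eligibility flag used throughout the place-field analyses.
    """

    frame_rate: float
    track_length: float
    reward_zone: tuple[float, float]
    position: np.ndarray
    speed: np.ndarray
    trial_id: np.ndarray
    licks: pd.DataFrame
    rewards: pd.DataFrame
    trials: pd.DataFrame

    @property
    def n_frames(self) -> int:
        return self.position.size

    def eligible_trials(self) -> np.ndarray:
        t = self.trials
        return t.loc[t["eligible"], "trial"].to_numpy()



def _zone_mask(position: np.ndarray, start: float, end: float, track_length: float) -> np.ndarray:
    """Membership in the half-open circular interval [start, end) cm."""
    p = np.mod(position, track_length)
    s, e = np.mod(start, track_length), np.mod(end, track_length)
    if s <= e:
        return (p >= s) & (p < e)
    return (p >= s) | (p < e)


def segment_and_classify(
    position: np.ndarray,
    frame_rate: float,
    track_length: float,
    reward_zone: tuple[float, float],
    lick_frames: np.ndarray,
    reward_frames: np.ndarray,
    reward_volumes: np.ndarray | None = None,
    manual_flags: np.ndarray | None = None,
    trial_types: list[str] | None = None,
    speed: np.ndarray | None = None,
) -> SessionTimeseries:
    """Build a :class:`SessionTimeseries` from raw frame-indexed streams.

    Trials are cut at position wrap events (large negative position jumps).
    Licks are classified as consumption if they fall inside the reward zone
    after that trial's reward, test otherwise.  Trial eligibility requires at
    least 3 test licks, a duration of 4-60 s, no manual reward, and a start
    before 1.2 ml of cumulative reward has been delivered.
    """
    position = np.asarray(position, dtype=float)
    n = position.size
    if np.any(position < 0) or np.any(position >= track_length):
        raise ValueError("position outside [0, track_length)")
    zs, ze = reward_zone
    if not (0 <= zs < track_length and 0 < ze <= track_length and zs < ze):
        raise ValueError("reward zone outside track")
    if speed is None:
        dpos = np.diff(position)
        dpos = np.where(dpos < -track_length / 2, dpos + track_length, dpos)
        speed = np.r_[0.0, np.abs(dpos)] * frame_rate
    # trial boundaries at wraps
    wraps = np.flatnonzero(np.diff(position) < -track_length / 2) + 1
    starts = np.r_[0, wraps]
    ends = np.r_[wraps, n]
    n_trials = starts.size
    trial_id = np.zeros(n, dtype=int)
    for t, (s, e) in enumerate(zip(starts, ends)):
        trial_id[s:e] = t
    if trial_types is None:
        trial_types = ["standard"] * n_trials
    if len(trial_types) != n_trials:
        raise ValueError(f"expected {n_trials} trial types, got {len(trial_types)}")

    lick_frames = np.asarray(lick_frames, dtype=int)
    reward_frames = np.asarray(reward_frames, dtype=int)
    if reward_volumes is None:
        reward_volumes = np.full(reward_frames.size, 0.004)
    if manual_flags is None:
        manual_flags = np.zeros(reward_frames.size, dtype=bool)
    reward_volumes = np.asarray(reward_volumes, dtype=float)
    manual_flags = np.asarray(manual_flags, dtype=bool)

    # first reward frame per trial (for consumption-lick classification)
    rew_trial = trial_id[reward_frames] if reward_frames.size else np.empty(0, int)
    first_reward = {}
    for f, t in zip(reward_frames, rew_trial):
        first_reward[t] = min(first_reward.get(t, f), f)

    in_zone = _zone_mask(position, zs, ze, track_length)
    kinds = []
    for f in lick_frames:
        t = trial_id[f]
        consum = in_zone[f] and t in first_reward and f >= first_reward[t]
        kinds.append("consumption" if consum else "test")
    licks = pd.DataFrame({"frame": lick_frames, "kind": kinds})
    rewards = pd.DataFrame(
        {"frame": reward_frames, "volume_ml": reward_volumes, "manual": manual_flags}
    )

    records = []
    cum_before = 0.0
    test_frames = licks.loc[licks["kind"] == "test", "frame"].to_numpy()
    for t, (s, e) in enumerate(zip(starts, ends)):
        dur = (e - s) / frame_rate
        if dur < 0:
            raise ValueError("negative trial duration")
        n_test = int(np.sum((test_frames >= s) & (test_frames < e)))
        has_manual = bool(np.any(manual_flags & (rew_trial == t))) if reward_frames.size else False
        eligible = (
            n_test >= MIN_LICKS
            and MIN_DURATION_S <= dur <= MAX_DURATION_S
            and not has_manual
            and cum_before < MAX_CUM_REWARD_ML
        )
        records.append(
            dict(
                trial=t,
                type=trial_types[t],
                start_frame=int(s),
                end_frame=int(e),
                duration_s=dur,
                n_test_licks=n_test,
                cum_reward_before_ml=cum_before,
                has_manual_reward=has_manual,
                eligible=eligible,
            )
        )
        if reward_frames.size:
            cum_before += float(reward_volumes[rew_trial == t].sum())
    trials = pd.DataFrame(records)
    return SessionTimeseries(
        frame_rate=frame_rate,
        track_length=track_length,
        reward_zone=(zs, ze),
        position=position,
        speed=np.asarray(speed, dtype=float),
        trial_id=trial_id,
        licks=licks,
        rewards=rewards,
        trials=trials,
    )


def licking_selectivity(
    session: SessionTimeseries, zone_width: float = 10.0
) -> float:
    """Licking selectivity in [-1, 1].

    Compares test licks in the ``zone_width`` cm immediately before the
    reward-zone start (anticipatory licking) with test licks in the equally
    sized zone on the diametrically opposite side of the circular track:
    ``(pre - opposite) / (pre + opposite)``.  Consumption licks are excluded.
    Returns NaN when both counts are zero.
    """
    L = session.track_length
    zs = session.reward_zone[0]
    pre = (zs - zone_width, zs)
    opp = (pre[0] + L / 2, pre[1] + L / 2)
    if zone_width > L / 2:
        raise ValueError("zones overlap on the circular track")
    test = session.licks.loc[session.licks["kind"] == "test", "frame"].to_numpy()
    pos = session.position[test]
    n_pre = int(_zone_mask(pos, pre[0], pre[1], L).sum())
    n_opp = int(_zone_mask(pos, opp[0], opp[1], L).sum())
    if n_pre + n_opp == 0:
        return float("nan")
    return (n_pre - n_opp) / (n_pre + n_opp)


def permutation_test_two_sided(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Two-sided permutation test on the difference of group means.

    Pools the two samples, relabels ``n_shuffles`` times, and returns the
    add-one-smoothed fraction of shuffled |mean difference| at least as large
    as observed (so p is never below ``1 / (n_shuffles + 1)``).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs = abs(a.mean() - b.mean())
    pooled = np.r_[a, b]
    count = 0
    for _ in range(n_shuffles):
        perm = rng.permutation(pooled)
        d = abs(perm[: a.size].mean() - perm[a.size :].mean())
        if d >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_shuffles + 1)


def stable_session_filter(
    selectivities: np.ndarray, threshold: float = 0.6
) -> np.ndarray:
    """Stable-performance mask: True from the first session whose licking
    selectivity reaches ``threshold`` onward; all-False if none does."""
    s = np.asarray(selectivities, dtype=float)
    mask = np.zeros(s.size, dtype=bool)
    qual = np.flatnonzero(s >= threshold)
    if qual.size:
        mask[qual[0] :] = True
    return mask
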