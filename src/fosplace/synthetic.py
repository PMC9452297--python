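"""Synthetic virtual-track sessions with known ground truth.

Emulates the statistical structure the analysis chain assumes: lap-structured
behaviour at 30 Hz on a 200-cm circular track with standard/crutch/probe
trials, place-tuned calcium transients with per-cell field centre, width,
amplitude and trial-to-trial reliability, Fos fold-induction values coupled
to integrated activity, and multi-day session sets with controlled field
persistence and remapping.  Every generated artefact carries its ground
truth so downstream detectors and estimators can be scored.

Randomness is organised as named substreams derived from one master seed, so
behaviour, traces and induction can be regenerated independently and
bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import behavior as beh
from .behavior import SessionTimeseries

__all__ = [
    "GroupSpec",
    "InductionModel",
    "SimConfig",
    "GroundTruth",
    "SessionData",
    "substream",
    "generate_behavior",
    "make_ground_truth",
    "generate_traces",
    "generate_induction",
    "generate_session",
    "generate_multisession",
]


def substream(seed: int, *keys) -> np.random.Generator:
    """Named RNG substream: one independent stream per generated artefact."""
    ints = [int(seed)] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass
class GroupSpec:
    """Generative parameters for one intended induction group.

    ``reliability_p`` is the probability a tuned cell emits a transient on a
    given traversal of its field; ``shared_trial_gain_sd`` the log-sd of a
    multiplicative per-trial gain shared by all tuned members of the group
    (zero means independent trials); ``stability_rho`` the per-session-step
    probability that a field persists across days.
    """

    fraction: float = 0.5
    reliability_p: float = 0.85
    tuned_fraction: float = 0.9
    shared_trial_gain_sd: float = 0.0
    stability_rho: float | None = None


@dataclass
class InductionModel:
    baseline: float = 1.0
    gain: float = 0.5
    noise_sd: float = 0.15
    floor: float = 0.05


def _default_groups() -> dict[str, GroupSpec]:
    # high-induction cells: reliable, co-fluctuating, stable across days;
    # low-induction cells: unreliable, independent, unstable
    return {
        "high": GroupSpec(0.5, reliability_p=0.85, tuned_fraction=0.9,
                          shared_trial_gain_sd=0.4, stability_rho=0.9),
        "low": GroupSpec(0.5, reliability_p=0.3, tuned_fraction=0.9,
                         shared_trial_gain_sd=0.0, stability_rho=0.4),
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator (defaults are the ones
    the analyses assume: 200-cm track, 40 bins of 5 cm, 30 Hz, 20-cm reward
    zone)."""

    track_length_cm: float = 200.0
    n_bins: int = 40
    frame_rate_hz: float = 30.0
    reward_zone: tuple[float, float] = (100.0, 120.0)
    n_trials: int = 40
    trial_type_fractions: dict = field(
        default_factory=lambda: {"standard": 0.65, "crutch": 0.25, "probe": 0.10}
    )
    n_cells: int = 100
    field_width_cm_mean: float = 20.0  # full width (~4 sigma) of the field
    field_width_cm_sd: float = 5.0
    amplitude_mean: float = 2.0  # peak dF/F of an in-field transient
    amplitude_sd: float = 0.5
    event_decay_s: float = 0.5  # indicator decay time constant
    noise_sd: float = 0.15
    untuned_event_rate_hz: float = 0.02
    lick_policy: str = "expert"  # or "novice"
    licks_per_trial: float = 6.0
    consumption_licks_per_reward: float = 3.0
    reward_volume_ml: float = 0.004
    speed_mean_cm_s: float = 25.0
    speed_log_sd: float = 0.25
    reward_zone_slow_factor: float = 0.5
    induction_model: InductionModel = field(default_factory=InductionModel)
    groups: dict = field(default_factory=_default_groups)
    n_sessions: int = 1
    tuning_stability_rho: float = 0.8
    remap_fraction: float = 0.5
    untuned_gain_prob: float = 0.05
    alignment_dropout: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        zs, ze = self.reward_zone
        if not (0 <= zs < ze <= self.track_length_cm):
            raise ValueError("reward zone outside [0, track_length)")
        if self.n_trials <= 0 or self.n_cells <= 0 or self.n_bins <= 0:
            raise ValueError("counts must be positive")
        if self.frame_rate_hz <= 0 or self.track_length_cm <= 0:
            raise ValueError("rates and lengths must be positive")
        probs = list(self.trial_type_fractions.values()) + [
            self.remap_fraction, self.untuned_gain_prob, self.alignment_dropout,
            self.tuning_stability_rho,
        ] + [g.reliability_p for g in self.groups.values()] + [
            g.tuned_fraction for g in self.groups.values()
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.trial_type_fractions.values()) - 1) > 1e-9:
            raise ValueError("trial_type_fractions must sum to 1")
        if abs(sum(g.fraction for g in self.groups.values()) - 1) > 1e-9:
            raise ValueError("group fractions must sum to 1")

    @property
    def bin_width_cm(self) -> float:
        return self.track_length_cm / self.n_bins


@dataclass
class GroundTruth:
    """Per-cell generative truth for one session."""

    group: np.ndarray  # str per cell
    is_tuned: np.ndarray
    field_center_cm: np.ndarray  # NaN for untuned cells
    field_width_cm: np.ndarray
    amplitude: np.ndarray
    reliability_p: np.ndarray
    event_mask: np.ndarray | None = None  # (cells, frames), set by generate_traces
    active_trials: np.ndarray | None = None  # (cells, trials) bool
    persisted: np.ndarray | None = None  # vs previous session

    @property
    def n_cells(self) -> int:
        return self.group.size

    def field_center_bin(self, bin_width: float) -> np.ndarray:
        return np.floor(self.field_center_cm / bin_width)


@dataclass
class SessionData:
    session: SessionTimeseries
    dff: np.ndarray
    truth: GroundTruth
    induction: np.ndarray | None = None
    present: np.ndarray | None = None


def generate_behavior(config: SimConfig, seed: int | np.random.Generator = 0) -> SessionTimeseries:
    """Simulate one session of lap behaviour.

    Speed is piecewise-constant per trial (lognormal across trials), slowed
    by a configurable factor inside the reward zone.  The expert lick policy
    concentrates test licks in the 10 cm before the reward zone (plus the
    in-zone lick that triggers reward on standard trials); the novice policy
    licks uniformly along the track.  Rewards follow the trial-type rules
    and are followed by consumption licks inside the zone.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "behavior")
    if config.n_trials <= 0:
        raise ValueError("zero trials requested")
    L = config.track_length_cm
    fr = config.frame_rate_hz
    zs, ze = config.reward_zone
    types = list(config.trial_type_fractions)
    probs = np.array([config.trial_type_fractions[t] for t in types])

    pos_all: list[np.ndarray] = []
    lick_frames: list[int] = []
    reward_frames: list[int] = []
    trial_types: list[str] = []
    frame0 = 0
    carry = 0.0
    for _ in range(config.n_trials):
        ttype = types[int(rng.choice(len(types), p=probs))]
        trial_types.append(ttype)
        base = config.speed_mean_cm_s * np.exp(rng.normal(0, config.speed_log_sd))
        base = max(base, 6.0)  # keep laps inside the eligibility window
        pos = []
        p = carry
        while p < L:
            pos.append(p)
            v = base * (config.reward_zone_slow_factor if zs <= p < ze else 1.0)
            p += v / fr
        pos = np.array(pos)
        carry = p - L
        nf = pos.size

        def frame_at(target_cm: float) -> int | None:
            j = int(np.searchsorted(pos, target_cm))
            return frame0 + min(j, nf - 1) if pos[0] <= target_cm else None

        # test licks
        n_licks = max(3, int(rng.poisson(config.licks_per_trial)))
        if config.lick_policy == "expert":
            targets = rng.uniform(zs - 10.0, zs, n_licks)
            targets = np.append(targets, rng.uniform(zs, zs + 5.0, 2))  # zone licks
        elif config.lick_policy == "novice":
            targets = rng.uniform(0, L, n_licks)
        else:
            raise ValueError(f"unknown lick policy {config.lick_policy!r}")
        t_frames = sorted(f for f in (frame_at(t) for t in np.sort(targets)) if f is not None)
        lick_frames.extend(t_frames)

        # reward
        rframe = None
        if ttype == "standard":
            zone_licks = [f for f in t_frames if zs <= pos[f - frame0] < ze]
            if zone_licks:
                rframe = min(zone_licks[0] + 1, frame0 + nf - 1)
        elif ttype == "crutch":
            rframe = frame_at(zs)
        if rframe is not None:
            reward_frames.append(rframe)
            # consumption licks in the zone after delivery
            n_cons = int(rng.poisson(config.consumption_licks_per_reward))
            zone_after = [
                frame0 + j
                for j in range(rframe - frame0 + 1, nf)
                if zs <= pos[j] < ze
            ]
            if zone_after and n_cons:
                lick_frames.extend(
                    int(f) for f in rng.choice(zone_after, min(n_cons, len(zone_after)), replace=False)
                )
        pos_all.append(pos)
        frame0 += nf

    position = np.concatenate(pos_all)
    return beh.segment_and_classify(
        position=np.mod(position, L),
        frame_rate=fr,
        track_length=L,
        reward_zone=config.reward_zone,
        lick_frames=np.array(sorted(lick_frames), dtype=int),
        reward_frames=np.array(reward_frames, dtype=int),
        reward_volumes=np.full(len(reward_frames), config.reward_volume_ml),
        trial_types=trial_types,
    )


def make_ground_truth(config: SimConfig, seed: int | np.random.Generator = 0) -> GroundTruth:
    """Draw per-cell ground truth: group labels, tuning, field parameters."""
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "truth")
    n = config.n_cells
    labels = np.empty(n, dtype=object)
    counts = {g: int(round(s.fraction * n)) for g, s in config.groups.items()}
    # fix rounding drift on the last group
    names = list(config.groups)
    counts[names[-1]] = n - sum(counts[g] for g in names[:-1])
    order = rng.permutation(n)
    i = 0
    for g in names:
        labels[order[i : i + counts[g]]] = g
        i += counts[g]
    is_tuned = np.zeros(n, dtype=bool)
    reliability = np.zeros(n)
    for g, spec in config.groups.items():
        members = labels == g
        is_tuned[members] = rng.random(members.sum()) < spec.tuned_fraction
        reliability[members] = spec.reliability_p
    centers = rng.uniform(0, config.track_length_cm, n)
    centers[~is_tuned] = np.nan
    widths = np.clip(
        rng.normal(config.field_width_cm_mean, config.field_width_cm_sd, n), 8.0, None
    )
    widths[~is_tuned] = np.nan
    amps = np.clip(rng.normal(config.amplitude_mean, config.amplitude_sd, n), 0.5, None)
    reliability[~is_tuned] = 0.0
    return GroundTruth(
        group=labels.astype(str),
        is_tuned=is_tuned,
        field_center_cm=centers,
        field_width_cm=widths,
        amplitude=amps,
        reliability_p=reliability,
    )


def _circdist(a: np.ndarray, b: float, L: float) -> np.ndarray:
    d = np.abs(np.mod(a - b, L))
    return np.minimum(d, L - d)


def generate_traces(
    behavior_ts: SessionTimeseries,
    truth: GroundTruth,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Event-based forward model for the dF/F matrix (cells, frames).

    On each trial a tuned cell fires with probability ``reliability_p``: the
    clean signal is the cell's amplitude times a Gaussian envelope of the
    circular distance to its field centre (scaled by the group's shared
    per-trial gain, if any), smoothed by a unit-area causal exponential with
    the indicator decay constant.  Untuned cells emit Poisson-timed,
    position-independent events.  Additive Gaussian noise of scale
    ``noise_sd`` completes the trace.  The per-frame ground-truth event mask
    (clean signal above half the cell's amplitude) and per-trial activations
    are stored back on ``truth``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "traces")
    n_frames = behavior_ts.n_frames
    n_cells = truth.n_cells
    n_trials = len(behavior_ts.trials)
    if behavior_ts.trial_id.max() + 1 != n_trials:
        raise ValueError("mismatched trial structure")
    L = config.track_length_cm
    fr = config.frame_rate_hz
    pos = behavior_ts.position
    trial_of_frame = behavior_ts.trial_id

    # shared per-trial group gains
    gains = {}
    for g, spec in config.groups.items():
        if spec.shared_trial_gain_sd > 0:
            gains[g] = np.exp(rng.normal(0, spec.shared_trial_gain_sd, n_trials))
        else:
            gains[g] = np.ones(n_trials)

    clean = np.zeros((n_cells, n_frames))
    active_trials = np.zeros((n_cells, n_trials), dtype=bool)
    for c in range(n_cells):
        if truth.is_tuned[c]:
            sigma = truth.field_width_cm[c] / 4.0
            env = truth.amplitude[c] * np.exp(
                -0.5 * (_circdist(pos, truth.field_center_cm[c], L) / sigma) ** 2
            )
            active = rng.random(n_trials) < truth.reliability_p[c]
            active_trials[c] = active
            tg = gains[truth.group[c]] * active
            clean[c] = env * tg[trial_of_frame]
        else:
            n_ev = rng.poisson(config.untuned_event_rate_hz * n_frames / fr)
            if n_ev:
                frames = rng.integers(0, n_frames, n_ev)
                drive = np.zeros(n_frames)
                np.add.at(drive, frames, truth.amplitude[c])
                g = sps.windows.gaussian(int(6 * 0.15 * fr) | 1, 0.15 * fr)
                clean[c] = np.convolve(drive, g, mode="same")

    # causal exponential smoothing (unit area: preserves plateau amplitude)
    a = np.exp(-1.0 / (fr * config.event_decay_s))
    clean = sps.lfilter([1 - a], [1, -a], clean, axis=1)
    truth.event_mask = clean >= 0.5 * truth.amplitude[:, None]
    truth.active_trials = active_trials
    if config.noise_sd > 0:
        dff = clean + rng.normal(0, config.noise_sd, clean.shape)
    else:
        dff = clean
    return dff


def generate_induction(
    truth: GroundTruth,
    dff: np.ndarray,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
    frame_rate: float | None = None,
) -> np.ndarray:
    """Per-cell fold-induction values coupled to integrated activity.

    ``fold = baseline + gain * z(alpha) + noise`` truncated below at a small
    positive floor, where ``z(alpha)`` is the standardized integrated
    positive dF/F.  With gain 0 induction is independent of activity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "induction")
    fr = frame_rate or config.frame_rate_hz
    m = config.induction_model
    alpha = np.maximum(dff, 0).sum(axis=1) / fr
    sd = alpha.std()
    z = (alpha - alpha.mean()) / sd if sd > 0 else np.zeros_like(alpha)
    fold = m.baseline + m.gain * z + rng.normal(0, m.noise_sd, alpha.size)
    return np.maximum(fold, m.floor)


def generate_session(config: SimConfig, seed: int | None = None) -> SessionData:
    """One complete synthetic session (behaviour, traces, induction)."""
    seed = config.seed if seed is None else seed
    session = generate_behavior(config, substream(seed, "behavior"))
    truth = make_ground_truth(config, substream(seed, "truth"))
    dff = generate_traces(session, truth, config, substream(seed, "traces"))
    induction = generate_induction(truth, dff, config, substream(seed, "induction"))
    return SessionData(session=session, dff=dff, truth=truth, induction=induction)


def _evolve_truth(
    truth: GroundTruth, config: SimConfig, rng: np.random.Generator
) -> GroundTruth:
    """Advance ground truth by one session step.

    A tuned cell keeps its field with its group's stability probability;
    otherwise it relocates the field (probability ``remap_fraction`` of the
    non-persisting outcomes) or loses it.  Untuned cells gain a field with a
    small probability.
    """
    n = truth.n_cells
    new = replace(
        truth,
        is_tuned=truth.is_tuned.copy(),
        field_center_cm=truth.field_center_cm.copy(),
        field_width_cm=truth.field_width_cm.copy(),
        reliability_p=truth.reliability_p.copy(),
        event_mask=None,
        active_trials=None,
    )
    persisted = np.zeros(n, dtype=bool)
    for c in range(n):
        spec = config.groups[truth.group[c]]
        rho = spec.stability_rho if spec.stability_rho is not None else config.tuning_stability_rho
        if truth.is_tuned[c]:
            if rng.random() < rho:
                persisted[c] = True
            elif rng.random() < config.remap_fraction:
                new.field_center_cm[c] = rng.uniform(0, config.track_length_cm)
            else:
                new.is_tuned[c] = False
                new.field_center_cm[c] = np.nan
                new.field_width_cm[c] = np.nan
                new.reliability_p[c] = 0.0
        else:
            if rng.random() < config.untuned_gain_prob:
                new.is_tuned[c] = True
                new.field_center_cm[c] = rng.uniform(0, config.track_length_cm)
                new.field_width_cm[c] = max(
                    rng.normal(config.field_width_cm_mean, config.field_width_cm_sd), 8.0
                )
                new.reliability_p[c] = spec.reliability_p
    new.persisted = persisted
    return new


def generate_multisession(
    config: SimConfig, seed: int | None = None
) -> tuple[list[SessionData], pd.DataFrame]:
    """Multi-day session set with a cross-session alignment table.

    Cell identities are shared across sessions; fields persist, relocate or
    disappear according to the per-group stability parameters.  A fraction
    of cells is absent from each session (imperfect cross-day matching); the
    alignment table maps global cell ids to per-session local row indices of
    the cells present in that session's trace matrix.
    """
    if config.n_sessions < 2:
        raise ValueError("n_sessions must be >= 2")
    seed = config.seed if seed is None else seed
    truth = make_ground_truth(config, substream(seed, "truth"))
    sessions: list[SessionData] = []
    rows = []
    for s in range(config.n_sessions):
        if s > 0:
            truth = _evolve_truth(truth, config, substream(seed, "evolve", s))
        session = generate_behavior(config, substream(seed, "behavior", s))
        dff = generate_traces(session, truth, config, substream(seed, "traces", s))
        induction = generate_induction(
            truth, dff, config, substream(seed, "induction", s)
        )
        present = (
            substream(seed, "presence", s).random(config.n_cells)
            >= config.alignment_dropout
        )
        local = -np.ones(config.n_cells, dtype=int)
        local[present] = np.arange(present.sum())
        for gid in np.flatnonzero(present):
            rows.append(dict(global_id=gid, session=s, local_id=int(local[gid])))
        sessions.append(
            SessionData(
                session=session, dff=dff, truth=truth, induction=induction,
                present=present,
            )
        )
    alignment = pd.DataFrame(rows, columns=["global_id", "session", "local_id"])
    return sessions, alignment
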