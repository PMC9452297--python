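"""End-to-end analysis pipeline: signals -> behaviour -> tuning -> induction
-> decoding -> ensembles -> stability.

The pipeline operates on in-memory session data (or bundles read via
:mod:`fosplace.io`) and produces per-session and cross-session summaries
with every design parameter recorded.  All randomness flows from one seed
through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import decoding, ensembles, induction as ind, signals, stability, tuning
from .behavior import SessionTimeseries, licking_selectivity
from .synthetic import SessionData, substream

__all__ = ["AnalysisConfig", "SessionAnalysis", "analyze_session", "analyze_multisession"]

log = logging.getLogger("fosplace")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("fosplace %(levelname)s: %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class AnalysisConfig:
    """Every tunable analysis parameter, with the defaults used throughout."""

    n_shuffles: int = 1000
    run_threshold_cm_s: float = 5.0
    n_bins: int = 40
    sigma_bins: float = 1.0
    n_blocks: int = 6
    fpr_threshold: float = 0.001
    template_floor_frac: float = 0.01
    decode_reps: int = 100
    min_group_cells: int = 10
    max_group_cells: int = 100
    min_stability_cells: int = 20
    peri_reward_margin_cm: float = 20.0
    ap_preference: float = -1.0
    ap_max_iter: int = 5000
    ap_damping: float = 0.9
    n_perm: int = 1000
    smooth_stability_weights: bool = True
    traces_are_dff: bool = True

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SessionAnalysis:
    session: SessionTimeseries
    global_ids: np.ndarray
    sig: np.ndarray  # significance-masked dF/F (cells, frames)
    cell_stats: pd.DataFrame  # per-cell transient stats + alpha
    selectivity: float
    tuning: tuning.TuningResult
    groups: pd.DataFrame | None = None
    decode_errors: dict | None = None
    ensemble: dict | None = None
    properties: pd.DataFrame | None = None

    def group_cells(self, label: str) -> np.ndarray:
        """Row indices of cells in an induction group."""
        if self.groups is None:
            raise ValueError("no induction data for this session")
        return np.flatnonzero((self.groups["group"] == label).to_numpy())


#: optional stages that can be switched off; the core chain
#: (signals -> behaviour -> tuning) always runs
OPTIONAL_STAGES = ("induction", "decoding", "ensembles", "stability")


def analyze_session(
    data: SessionData,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
    global_ids: np.ndarray | None = None,
    stages: set[str] | None = None,
) -> SessionAnalysis:
    """Run the within-session stages on one session.

    ``stages`` optionally restricts the induction-dependent stages; the core
    signals/behaviour/tuning chain always runs (everything depends on it).
    """
    cfg = cfg or AnalysisConfig()
    stages = set(OPTIONAL_STAGES) if stages is None else stages
    present = data.present if data.present is not None else np.ones(data.dff.shape[0], bool)
    dff = data.dff[present]
    if global_ids is None:
        global_ids = np.flatnonzero(present)
    session = data.session
    fr = session.frame_rate

    if not cfg.traces_are_dff:
        dff = signals.compute_dff(dff, fr)
    sig = np.zeros_like(dff)
    stats_rows = []
    for c in range(dff.shape[0]):
        tr = signals.detect_significant_transients(dff[c], cfg.fpr_threshold)
        sig[c] = tr.dff
        stats_rows.append(signals.transient_stats(tr, fr))
    cell_stats = pd.DataFrame(stats_rows)
    cell_stats.insert(0, "global_id", global_ids)

    sel = licking_selectivity(session)
    tun = tuning.analyze_tuning(
        sig,
        session,
        n_shuffles=cfg.n_shuffles,
        run_threshold=cfg.run_threshold_cm_s,
        n_bins=cfg.n_bins,
        sigma_bins=cfg.sigma_bins,
        n_blocks=cfg.n_blocks,
        seed=substream(seed, "shuffle"),
    )

    props_rows = []
    for c in np.flatnonzero(tun.is_place_cell):
        p = tuning.field_properties(c, tun.binned, tun.fields[c], sig[c] > 0)
        p["cell"] = int(c)
        p["global_id"] = int(global_ids[c])
        props_rows.append(p)
    properties = pd.DataFrame(props_rows) if props_rows else None

    groups = None
    decode_errors = None
    ensemble = None
    if data.induction is not None and "induction" in stages:
        vals = np.asarray(data.induction)[present]
        groups = ind.assign_induction_groups(vals, cell_ids=global_ids)
        hi = np.flatnonzero((groups["group"] == "high").to_numpy())
        lo = np.flatnonzero((groups["group"] == "low").to_numpy())
        if "decoding" in stages:
            try:
                decode_errors = decoding.compare_groups(
                    tun.binned,
                    {"high": hi, "low": lo},
                    fr,
                    n_reps=cfg.decode_reps,
                    seed=substream(seed, "decode"),
                    floor_frac=cfg.template_floor_frac,
                    min_cells=cfg.min_group_cells,
                    max_cells=cfg.max_group_cells,
                )
            except ValueError as e:
                log.warning("decoding skipped: %s", e)
        if "ensembles" in stages:
            ensemble = _ensemble_stage(tun, hi, lo, cfg, seed)
    elif data.induction is None:
        log.info("no induction data; induction-dependent stages skipped")
    return SessionAnalysis(
        session=session,
        global_ids=global_ids,
        sig=sig,
        cell_stats=cell_stats,
        selectivity=sel,
        tuning=tun,
        groups=groups,
        decode_errors=decode_errors,
        ensemble=ensemble,
        properties=properties,
    )


def _ensemble_stage(
    tun: tuning.TuningResult, hi: np.ndarray, lo: np.ndarray,
    cfg: AnalysisConfig, seed: int,
) -> dict | None:
    pc = np.flatnonzero(tun.is_place_cell)
    if pc.size < 2:
        log.warning("ensemble stage skipped: fewer than 2 place cells")
        return None
    try:
        mat = ensembles.activation_matrix(tun.binned, tun.fields, cells=pc)
    except ValueError as e:
        log.warning("ensemble stage skipped: %s", e)
        return None
    out: dict = {"place_cells": pc, "activation": mat}
    for name, grp in (("high", hi), ("low", lo)):
        cols = np.flatnonzero(np.isin(pc, grp))
        out[f"within_{name}"] = (
            ensembles.within_group_correlation(mat, cols) if cols.size >= 2 else np.nan
        )
    corr = ensembles.correlation_matrix(mat)
    labels, converged = ensembles.cluster_cells(
        corr, preference=cfg.ap_preference, max_iter=cfg.ap_max_iter,
        damping=cfg.ap_damping,
    )
    out["labels"], out["converged"] = labels, converged
    for name, grp in (("high", hi), ("low", lo)):
        cols = np.flatnonzero(np.isin(pc, grp))
        out[f"same_cluster_ratio_{name}"] = (
            ensembles.same_cluster_vs_chance(
                labels, cols, n_perm=cfg.n_perm, seed=substream(seed, "cluster", name)
            )
            if cols.size >= 2
            else np.nan
        )
    return out


def _group_ids(analysis: SessionAnalysis, label: str) -> np.ndarray:
    return analysis.groups.loc[
        (analysis.groups["group"] == label).to_numpy(), "cell_id"
    ].to_numpy()


def analyze_multisession(
    sessions: list[SessionData],
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
    global_ids_list: list[np.ndarray] | None = None,
    stages: set[str] | None = None,
) -> dict:
    """Full pipeline over an aligned multi-day session set.

    Runs the within-session stages on every session, then cross-day
    stability maps and within-group correlations for every session pair with
    positive delta, with induction groups fixed on the reference session.
    """
    cfg = cfg or AnalysisConfig()
    stages = set(OPTIONAL_STAGES) if stages is None else stages
    analyses = [
        analyze_session(
            d, cfg, seed=int(substream(seed, "session", i).integers(2**31)),
            global_ids=None if global_ids_list is None else global_ids_list[i],
            stages=stages,
        )
        for i, d in enumerate(sessions)
    ]
    zones = stability.zone_bins(
        sessions[0].session.reward_zone,
        sessions[0].session.track_length,
        cfg.n_bins,
        cfg.peri_reward_margin_cm,
    )
    maps: list[dict] = []
    crossday: list[dict] = []
    for r in range(len(analyses) if "stability" in stages else 0):
        ref = analyses[r]
        if ref.groups is None:
            continue
        for t in range(r + 1, len(analyses)):
            tgt = analyses[t]
            shared = np.intersect1d(ref.global_ids, tgt.global_ids)
            for label in ("high", "low"):
                gids = np.intersect1d(_group_ids(ref, label), shared)
                ref_pc = ref.global_ids[ref.tuning.is_place_cell]
                gids = np.intersect1d(gids, ref_pc)
                ridx = np.searchsorted(ref.global_ids, gids)
                tidx = np.searchsorted(tgt.global_ids, gids)
                if gids.size == 0:
                    continue
                x = stability.placefield_correlation(
                    ref.tuning.binned.mean[ridx], tgt.tuning.binned.mean[tidx]
                )
                weights_src = (
                    ref.tuning.smoothed if cfg.smooth_stability_weights
                    else ref.tuning.binned.mean
                )
                try:
                    m = stability.stability_map(
                        x, weights_src[ridx], min_cells=cfg.min_stability_cells,
                        group=label, delta_sessions=t - r,
                    )
                except ValueError as e:
                    log.warning("stability pair (%d,%d,%s) skipped: %s", r, t, label, e)
                    continue
                maps.append(
                    dict(
                        reference=r, target=t, group=label, delta=t - r,
                        map=m, zones=stability.zone_summary(m, zones),
                    )
                )
                # cross-day within-group correlation on the target session
                if tgt.ensemble is not None:
                    tgt_pc_ids = tgt.global_ids[tgt.ensemble["place_cells"]]
                    try:
                        c = ensembles.crossday_within_group(
                            tgt.ensemble["activation"], tgt_pc_ids, _group_ids(ref, label)
                        )
                    except ValueError:
                        c = float("nan")
                    crossday.append(
                        dict(reference=r, target=t, group=label, delta=t - r, correlation=c)
                    )
    test = None
    paired_high = [m for m in maps if m["group"] == "high"]
    paired_low = [m for m in maps if m["group"] == "low"]
    pairs = {(m["reference"], m["target"]) for m in paired_high} & {
        (m["reference"], m["target"]) for m in paired_low
    }
    if len(pairs) >= 2:
        hk = {(m["reference"], m["target"]): m["map"].stability for m in paired_high}
        lk = {(m["reference"], m["target"]): m["map"].stability for m in paired_low}
        keys = sorted(pairs)
        test = stability.stability_difference_test(
            np.vstack([hk[k] for k in keys]),
            np.vstack([lk[k] for k in keys]),
            zones,
            n_shuffles=cfg.n_shuffles,
            seed=substream(seed, "stability-test"),
        )
    return dict(
        sessions=analyses,
        stability_maps=maps,
        stability_test=test,
        crossday_correlations=crossday,
        zones=zones,
        config_hash=cfg.hash(),
    )
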