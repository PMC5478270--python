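"""Safe/threat block schedules for both acquisition modes.

MEG mode: per run, 4 habituation probes, then 2 safe + 2 threat blocks of 8
probes each, inter-probe intervals uniform on [6, 14] s; each interprobe
interval inside a threat block has a 1/12 chance of a shock (2-4 s after the
preceding probe) up to 2 shocks per run.

fMRI mode: 4 alternating ~2-min blocks of TR-spaced frames, no probes, 0-3
shocks per run at random threat frames.
"""

from __future__ import annotations

import numpy as np

from .types import BlockSchedule

__all__ = ["build_block_schedule"]

INTERPROBE_RANGE_S = (6.0, 14.0)
PROBES_PER_BLOCK = 8
HABITUATION_PROBES = 4
SHOCK_PROB_PER_INTERVAL = 1.0 / 12.0
SHOCK_DELAY_RANGE_S = (2.0, 4.0)
MAX_SHOCKS = {"meg": 2, "fmri": 3}


def build_block_schedule(mode, cfg, rng) -> list[BlockSchedule]:
    """One BlockSchedule per run for the given simulation config.

    ``cfg`` supplies ``n_runs`` plus, in fMRI mode, ``tr_s``/``run_length_s``.
    ``rng`` is a seeded ``numpy.random.Generator`` (shared across runs by
    default, i.e. per-session randomization).
    """
    if mode not in ("fmri", "meg"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    start = getattr(cfg, "start_condition", "safe")
    order = [start, _other(start)] * 2
    builder = _fmri_run if mode == "fmri" else _meg_run
    return [builder(cfg, run, order, rng) for run in range(cfg.n_runs)]


def _other(cond: str) -> str:
    return "threat" if cond == "safe" else "safe"


def _fmri_run(cfg, run: int, order, rng) -> BlockSchedule:
    n_frames = int(round(cfg.run_length_s / cfg.tr_s))
    if n_frames < 4:
        raise ValueError(
            f"run length {cfg.run_length_s} s fits only {n_frames} frames at "
            f"TR {cfg.tr_s} s; need at least 1 frame per block"
        )
    frame_times = np.arange(n_frames) * cfg.tr_s
    labels = np.empty(n_frames, object)
    blocks = []
    for cond, chunk in zip(order, np.array_split(np.arange(n_frames), 4)):
        labels[chunk] = cond
        blocks.append(
            (cond, float(frame_times[chunk[0]]),
             float(frame_times[chunk[-1]] + cfg.tr_s))
        )
    prob = getattr(cfg, "shock_prob", SHOCK_PROB_PER_INTERVAL)
    n_shocks = int(rng.integers(0, MAX_SHOCKS["fmri"] + 1)) if prob > 0 else 0
    threat_frames = np.flatnonzero(labels == "threat")
    picks = rng.choice(threat_frames, size=n_shocks, replace=False) if n_shocks else []
    shock_times = np.sort(frame_times[np.asarray(picks, int)]) if n_shocks else np.array([])
    return BlockSchedule(
        run_index=run,
        frame_times=frame_times,
        condition_per_frame=labels.astype(str),
        probe_times=np.array([]),
        probe_conditions=np.array([], dtype=str),
        habituation=np.array([], bool),
        shock_times=np.asarray(shock_times, float),
        blocks=blocks,
    )


def _meg_run(cfg, run: int, order, rng) -> BlockSchedule:
    lo, hi = INTERPROBE_RANGE_S
    n_probes = HABITUATION_PROBES + 4 * PROBES_PER_BLOCK
    intervals = rng.uniform(lo, hi, size=n_probes)
    probe_times = np.cumsum(intervals)
    probe_conditions = np.empty(n_probes, object)
    habituation = np.zeros(n_probes, bool)
    habituation[:HABITUATION_PROBES] = True
    probe_conditions[:HABITUATION_PROBES] = "pre"
    blocks = []
    prev_end = float(probe_times[HABITUATION_PROBES - 1]) + 1.0
    shock_times = []
    for b, cond in enumerate(order):
        sel = slice(
            HABITUATION_PROBES + b * PROBES_PER_BLOCK,
            HABITUATION_PROBES + (b + 1) * PROBES_PER_BLOCK,
        )
        probe_conditions[sel] = cond
        block_probes = probe_times[sel]
        block_end = float(block_probes[-1]) + 1.0
        blocks.append((cond, prev_end, block_end))
        if cond == "threat":
            for i in range(PROBES_PER_BLOCK - 1):
                if len(shock_times) >= MAX_SHOCKS["meg"]:
                    break
                if rng.random() < getattr(cfg, "shock_prob", SHOCK_PROB_PER_INTERVAL):
                    shock_times.append(
                        float(block_probes[i] + rng.uniform(*SHOCK_DELAY_RANGE_S))
                    )
        prev_end = block_end

    run_end = prev_end
    frame_times = np.arange(0.0, run_end, 1.0)
    labels = np.full(frame_times.size, "pre", object)
    for cond, t0, t1 in blocks:
        labels[(frame_times >= t0) & (frame_times < t1)] = cond
    return BlockSchedule(
        run_index=run,
        frame_times=frame_times,
        condition_per_frame=labels.astype(str),
        probe_times=probe_times,
        probe_conditions=probe_conditions.astype(str),
        habituation=habituation,
        shock_times=np.sort(np.asarray(shock_times, float)),
        blocks=blocks,
    )
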