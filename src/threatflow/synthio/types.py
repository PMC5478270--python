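"""Shared simulation types: block schedules and injected ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BlockSchedule", "GroundTruth"]


@dataclass
class BlockSchedule:
    """Timing of one run: frame labels, probes, and shocks.

    ``blocks`` lists (condition, t_start, t_end) for the 2 safe + 2 threat
    blocks; the pre-block habituation window (MEG mode) is labelled 'pre'.
    """

    run_index: int
    frame_times: np.ndarray  # seconds
    condition_per_frame: np.ndarray  # 'safe' / 'threat' / 'pre'
    probe_times: np.ndarray  # seconds, empty in fMRI mode
    probe_conditions: np.ndarray
    habituation: np.ndarray  # bool per probe
    shock_times: np.ndarray  # seconds
    blocks: list = field(default_factory=list)

    def validate(
        self,
        interprobe_range_s: tuple[float, float] = (6.0, 14.0),
        max_shocks: int = 2,
    ) -> None:
        """Raise if the schedule violates its structural invariants."""
        conds = [c for c, _, _ in self.blocks]
        if len(conds) != 4 or sorted(conds) != ["safe", "safe", "threat", "threat"]:
            raise ValueError("each run needs 2 safe + 2 threat blocks")
        if any(a == b for a, b in zip(conds, conds[1:])):
            raise ValueError("block conditions must alternate")
        labels = self.condition_per_frame
        change = np.flatnonzero(labels[1:] != labels[:-1])
        if change.size > len(self.blocks):  # at most one boundary per block edge
            raise ValueError("frame conditions are not contiguous blocks")
        if self.probe_times.size:
            gaps = np.diff(self.probe_times)
            lo, hi = interprobe_range_s
            if gaps.min() < lo - 1e-9 or gaps.max() > hi + 1e-9:
                raise ValueError("inter-probe interval outside the allowed range")
        if self.shock_times.size > max_shocks:
            raise ValueError(f"more than {max_shocks} shocks in one run")
        for t in self.shock_times:
            inside = any(
                c == "threat" and t0 - 1e-9 <= t <= t1 + 1e-9
                for c, t0, t1 in self.blocks
            )
            if not inside:
                raise ValueError(f"shock at {t:.1f} s outside any threat block")


@dataclass
class GroundTruth:
    """Injected effects of a simulated cohort, for recovery testing."""

    # fMRI arm
    hub_voxels: np.ndarray | None = None  # indices into in-mask ordering
    delta_rho: float | None = None
    base_rho: float | None = None
    hub_corr_safe: float | None = None
    hub_corr_threat: float | None = None
    # MEG arm
    iaf_hz: np.ndarray | None = None  # per subject
    alpha_mod: float | None = None
    active_sources: np.ndarray | None = None
    artifact_flags: list | None = None  # per subject: bool per trial
    # physiology arm
    threat_multiplier: float | None = None
    rating_effect: float | None = None
    probe_amplitudes: list | None = None
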