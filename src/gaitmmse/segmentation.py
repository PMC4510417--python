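"""Gait-cycle segmentation from accelerometer heel-strike peaks.

The gravity-axis accelerometer on each shank shows a sharp peak at every
heel strike.  A gait cycle of one leg runs from an ipsilateral heel strike
to the next ipsilateral strike; the stance phase runs to the intervening
contralateral strike, the swing phase covers the remainder.  All spans are
0-based half-open sample intervals at the EMG rate; accelerometer indices
are mapped to EMG indices by nearest-integer rate-ratio scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .signal import MultichannelSignal

__all__ = [
    "HeelStrikeSeries",
    "GaitCycle",
    "detect_acc_peaks",
    "build_gait_cycles",
    "extract_segment",
    "reject_artifact_cycles",
]

log = logging.getLogger(__name__)

#: default minimum spacing between heel strikes, seconds
DEFAULT_MIN_INTERVAL_S = 0.4
#: default peak height threshold as a multiple of the trace SD
DEFAULT_PROMINENCE_FACTOR = 2.0
#: physiologic bounds on cycle duration, seconds
DEFAULT_CYCLE_BOUNDS_S = (0.5, 4.0)
#: default artifact threshold: peak amplitude as a multiple of channel SD.
#: Clean burst-modulated gait EMG has a crest factor of roughly 9-13 against
#: its global SD (bursts over a quiet baseline), so the screen sits well
#: above that while still catching large motion-artifact spikes.
DEFAULT_ARTIFACT_Z = 20.0


@dataclass
class HeelStrikeSeries:
    """Heel-strike sample indices of one leg at the accelerometer rate."""

    side: str                # "left" | "right"
    acc_indices: np.ndarray  # strictly increasing
    acc_rate: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.acc_indices = np.asarray(self.acc_indices, dtype=int)
        if len(self.acc_indices) > 1 and not np.all(np.diff(self.acc_indices) > 0):
            raise ValueError("heel-strike indices must be strictly increasing")

    @property
    def times_s(self) -> np.ndarray:
        return self.acc_indices / self.acc_rate


@dataclass
class GaitCycle:
    """One gait cycle as half-open EMG-rate sample spans.

    ``[start, stance_end)`` is the stance phase, ``[stance_end, end)`` the
    swing phase; together they tile the cycle exactly.
    """

    side: str
    start_emg_index: int
    stance_end_emg_index: int
    end_emg_index: int

    def __post_init__(self) -> None:
        if not (self.start_emg_index < self.stance_end_emg_index < self.end_emg_index):
            raise ValueError(
                f"need start < stance_end < end, got "
                f"({self.start_emg_index}, {self.stance_end_emg_index}, {self.end_emg_index})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_emg_index - self.start_emg_index

    def span(self, segment: str) -> tuple[int, int]:
        """Half-open EMG span of ``'full'``, ``'stance'`` or ``'swing'``."""
        if segment == "full":
            return self.start_emg_index, self.end_emg_index
        if segment == "stance":
            return self.start_emg_index, self.stance_end_emg_index
        if segment == "swing":
            return self.stance_end_emg_index, self.end_emg_index
        raise ValueError(f"segment must be full|stance|swing, got {segment!r}")


def detect_acc_peaks(
    acc: np.ndarray,
    acc_rate: float,
    side: str = "left",
    min_interval_s: float = DEFAULT_MIN_INTERVAL_S,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
) -> HeelStrikeSeries:
    """Detect heel-strike peaks in a gravity-axis accelerometer trace.

    Local maxima exceeding ``prominence_factor * SD(acc)`` and separated by
    at least ``min_interval_s`` are kept (the larger of two close peaks
    wins).  An empty or flat trace yields an empty series.
    """
    acc = np.asarray(acc, dtype=float).ravel()
    if acc.size == 0 or np.ptp(acc) == 0.0:
        return HeelStrikeSeries(side=side, acc_indices=np.array([], dtype=int), acc_rate=acc_rate)
    if not np.isfinite(acc).all():
        raise ValueError("non-finite samples in accelerometer trace")
    height = prominence_factor * float(np.std(acc))
    distance = max(1, int(round(min_interval_s * acc_rate)))
    peaks, _ = find_peaks(acc, height=height, distance=distance)
    return HeelStrikeSeries(side=side, acc_indices=peaks, acc_rate=acc_rate)


def build_gait_cycles(
    ipsi: HeelStrikeSeries,
    contra: HeelStrikeSeries,
    emg_rate: float,
    cycle_bounds_s: tuple[float, float] = DEFAULT_CYCLE_BOUNDS_S,
) -> list[GaitCycle]:
    """Pair consecutive ipsilateral strikes into cycles split by the contralateral strike.

    For each consecutive ipsilateral peak pair containing exactly one
    contralateral peak, the cycle spans the pair and the stance/swing
    boundary sits at the contralateral peak.  Pairs with zero or multiple
    intervening contralateral peaks, and cycles outside the physiologic
    duration bounds, are dropped (logged).
    """
    ratio = emg_rate / ipsi.acc_rate
    if not ratio > 0:
        raise ValueError("rate ratio must be positive")
    lo_s, hi_s = cycle_bounds_s
    cycles: list[GaitCycle] = []
    dropped_contra = 0
    dropped_duration = 0
    contra_idx = np.asarray(contra.acc_indices)
    for p0, p1 in zip(ipsi.acc_indices[:-1], ipsi.acc_indices[1:]):
        between = contra_idx[(contra_idx > p0) & (contra_idx < p1)]
        if len(between) != 1:
            dropped_contra += 1
            continue
        duration_s = (p1 - p0) / ipsi.acc_rate
        if not (lo_s <= duration_s <= hi_s):
            dropped_duration += 1
            continue
        q = int(between[0])
        cycles.append(
            GaitCycle(
                side=ipsi.side,
                start_emg_index=int(round(p0 * ratio)),
                stance_end_emg_index=int(round(q * ratio)),
                end_emg_index=int(round(p1 * ratio)),
            )
        )
    if dropped_contra or dropped_duration:
        log.info(
            "dropped %d cycle(s) without exactly one contralateral strike, "
            "%d outside duration bounds %s",
            dropped_contra, dropped_duration, cycle_bounds_s,
        )
    return cycles


def extract_segment(
    emg: MultichannelSignal,
    cycle: GaitCycle,
    segment: str = "full",
    channels: list[str] | None = None,
) -> np.ndarray:
    """Slice the EMG rows of one cycle phase and the requested channels."""
    start, stop = cycle.span(segment)
    if start < 0 or stop > emg.n_samples:
        raise IndexError(
            f"cycle span [{start}, {stop}) outside signal of length {emg.n_samples}"
        )
    if channels is None:
        cols = slice(None)
    else:
        cols = [emg.channel_index(lb) for lb in channels]
    return emg.values[start:stop, cols]


def reject_artifact_cycles(
    emg: MultichannelSignal,
    cycles: list[GaitCycle],
    z_threshold: float = DEFAULT_ARTIFACT_Z,
) -> list[GaitCycle]:
    """Drop cycles whose peak amplitude betrays a motion artifact.

    A cycle is rejected when the absolute amplitude on any channel exceeds
    ``z_threshold`` times that channel's global standard deviation.  This is
    an automated stand-in for visual artifact screening.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    sd = np.std(emg.values, axis=0)
    sd[sd == 0.0] = np.inf  # constant channels can never trip the rule
    kept: list[GaitCycle] = []
    for cyc in cycles:
        seg = emg.values[cyc.start_emg_index: cyc.end_emg_index]
        if np.all(np.max(np.abs(seg), axis=0) <= z_threshold * sd):
            kept.append(cyc)
    if len(kept) < len(cycles):
        log.info("rejected %d artifact cycle(s) of %d", len(cycles) - len(kept), len(cycles))
    return kept
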