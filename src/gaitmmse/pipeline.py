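"""End-to-end coactivation analysis: decompose, slice, score, aggregate.

The pipeline decomposes the (noise-augmented) multichannel EMG once, builds
cumulative-IMF scales, then for every gait cycle and every analysis scheme
slices the raw data and each scale to the scheme's channels and phase span
and computes an MMSE curve.  Cycle curves average into one curve per
subject and scheme; subject curves average into group mean/SD curves.

Decomposition precedes slicing: in ``concat`` mode all subjects' cycle
blocks are concatenated and decomposed in a single MEMD run, which
guarantees scale alignment across cycles, channels and subjects; in
``per-subject`` mode each subject's block is decomposed separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .entropy import EmbeddingParams, MMSECurve, mmse_curve, tolerance_from_raw
from .memd import (DEFAULT_MAX_MODES, DEFAULT_MAX_SIFT, DEFAULT_N_DIRECTIONS,
                   DEFAULT_N_NOISE, DEFAULT_SD_THRESHOLD, add_noise_channels,
                   cumulative_scales, memd, strip_noise_channels)
from .schemes import SchemeSpec, enumerate_schemes
from .segmentation import GaitCycle
from .signal import MultichannelSignal

__all__ = [
    "SubjectData",
    "GroupSummary",
    "AnalysisConfig",
    "AnalysisResult",
    "subject_curve",
    "group_summary",
    "run_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class SubjectData:
    """One subject's EMG recording, detected gait cycles and group label."""

    subject_id: str
    emg: MultichannelSignal
    cycles: list[GaitCycle]
    group: str


@dataclass
class AnalysisConfig:
    """Tunables of one pipeline run (decomposition, entropy, orchestration)."""

    n_directions: int = DEFAULT_N_DIRECTIONS
    max_modes: int = DEFAULT_MAX_MODES
    n_noise: int = DEFAULT_N_NOISE
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    max_sift: int = DEFAULT_MAX_SIFT
    r_factor: float = 0.2
    m: int = 2
    tau: int = 1
    mode: str = "concat"  # concat | per-subject
    seed: int = 0

    @property
    def n_scales(self) -> int:
        return self.max_modes + 1

    def __post_init__(self) -> None:
        if self.mode not in ("concat", "per-subject"):
            raise ValueError(f"mode must be concat|per-subject, got {self.mode!r}")


@dataclass
class GroupSummary:
    """Mean and SD MMSE curve over the subjects of one group."""

    group: str
    mean: np.ndarray
    sd: np.ndarray
    n_subjects: int
    subject_curves: list[MMSECurve] = field(default_factory=list)


@dataclass
class AnalysisResult:
    """All curves and summaries of one pipeline run."""

    cycle_curves: list[MMSECurve]
    subject_curves: list[MMSECurve]
    summaries: dict[tuple[int, str], GroupSummary]  # (scheme id, group) -> summary
    schemes: list[SchemeSpec]
    config: AnalysisConfig

    def cycle_table(self) -> pd.DataFrame:
        return _curves_to_table(self.cycle_curves)

    def subject_table(self) -> pd.DataFrame:
        return _curves_to_table(self.subject_curves)

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for (scheme_id, group), gs in sorted(self.summaries.items()):
            for i, (mu, sd) in enumerate(zip(gs.mean, gs.sd)):
                rows.append(
                    dict(scheme=scheme_id, group=group, scale=i + 1,
                         mean=mu, sd=sd, n_subjects=gs.n_subjects)
                )
        return pd.DataFrame(rows)


def _curves_to_table(curves: list[MMSECurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for sf, val, ok in zip(c.scale_factors, c.values, c.defined):
            rows.append({**c.provenance, "scale": int(sf), "value": val, "defined": bool(ok)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def subject_curve(cycle_curves: list[MMSECurve]) -> MMSECurve:
    """Per-scale mean over a subject's cycle curves, skipping undefined values.

    A scale where every cycle is undefined stays flagged in the output; the
    number of contributing cycles per scale is recorded in the provenance.
    """
    if not cycle_curves:
        raise ValueError("need at least one cycle curve")
    n_scales = cycle_curves[0].n_scales
    for c in cycle_curves:
        if c.n_scales != n_scales:
            raise ValueError("cycle curves disagree on scale count")
    vals = np.array([c.values for c in cycle_curves])       # (n_cycles, S)
    ok = np.array([c.defined for c in cycle_curves])
    contributed = ok.sum(axis=0)
    mean = np.full(n_scales, np.nan)
    any_ok = contributed > 0
    with np.errstate(invalid="ignore"):
        masked = np.where(ok, vals, np.nan)
        mean[any_ok] = np.nanmean(masked[:, any_ok], axis=0)
    prov = dict(cycle_curves[0].provenance)
    prov.pop("cycle", None)
    prov["n_cycles"] = len(cycle_curves)
    prov["contributed"] = contributed.tolist()
    return MMSECurve(
        scale_factors=cycle_curves[0].scale_factors.copy(),
        values=mean,
        defined=any_ok,
        params=cycle_curves[0].params,
        provenance=prov,
    )


def group_summary(
    subject_curves: list[MMSECurve], group_labels: list[str]
) -> dict[str, GroupSummary]:
    """Per-scale mean and sample SD over subjects, per group label.

    Pooling (e.g. merging two healthy cohorts into one control group) is
    done by passing the pooled label for those subjects.  A singleton group
    gets NaN SDs (flagged undefined rather than zero).
    """
    if len(subject_curves) != len(group_labels):
        raise ValueError("one group label per subject curve")
    out: dict[str, GroupSummary] = {}
    for grp in sorted(set(group_labels)):
        curves = [c for c, g in zip(subject_curves, group_labels) if g == grp]
        vals = np.array([c.values for c in curves])
        mean = np.nanmean(vals, axis=0)
        if len(curves) >= 2:
            sd = np.nanstd(vals, axis=0, ddof=1)
        else:
            sd = np.full(vals.shape[1], np.nan)
            log.warning("group %r has a single subject: SD undefined", grp)
        out[grp] = GroupSummary(
            group=grp, mean=mean, sd=sd, n_subjects=len(curves), subject_curves=curves
        )
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _subject_block(sub: SubjectData) -> tuple[int, int]:
    """Contiguous span covering all of a subject's cycles."""
    if not sub.cycles:
        raise ValueError(f"subject {sub.subject_id} has no cycles")
    start = min(c.start_emg_index for c in sub.cycles)
    end = max(c.end_emg_index for c in sub.cycles)
    return start, end


def _shift_cycle(cyc: GaitCycle, offset: int) -> GaitCycle:
    return GaitCycle(
        side=cyc.side,
        start_emg_index=cyc.start_emg_index + offset,
        stance_end_emg_index=cyc.stance_end_emg_index + offset,
        end_emg_index=cyc.end_emg_index + offset,
    )


def _decompose_block(
    block: MultichannelSignal, config: AnalysisConfig
) -> list[np.ndarray]:
    """Noise-assisted MEMD of one block; returns the scale matrices (EMG channels only)."""
    augmented = add_noise_channels(block, n_noise=config.n_noise, seed=config.seed)
    dec = memd(
        augmented,
        n_directions=config.n_directions,
        max_modes=config.max_modes,
        sd_threshold=config.sd_threshold,
        max_sift=config.max_sift,
    )
    dec = strip_noise_channels(dec, config.n_noise)
    scales = cumulative_scales(dec, config.n_scales)
    return [s.values for s in scales]


def run_analysis(
    dataset: list[SubjectData],
    schemes: list[SchemeSpec] | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisResult:
    """Run the full coactivation analysis over a dataset.

    For every subject, cycle and scheme: slice the raw EMG and every
    cumulative scale to the scheme's channels and phase span, compute the
    tolerance from the raw slice, and evaluate the MMSE curve.  Cycle curves
    are averaged into subject curves per scheme, and subject curves into
    group summaries.  Fully deterministic for a fixed config and dataset.
    """
    if not dataset:
        raise ValueError("empty dataset")
    schemes = schemes if schemes is not None else enumerate_schemes()
    config = config if config is not None else AnalysisConfig()

    labels = dataset[0].emg.labels
    rate = dataset[0].emg.rate
    for sub in dataset:
        if sub.emg.labels != labels or sub.emg.rate != rate:
            raise ValueError("all subjects must share channel labels and rate")

    # per-subject blocks, shifted cycles, and (possibly concatenated) scales
    blocks: list[np.ndarray] = []
    shifted: list[tuple[SubjectData, list[GaitCycle]]] = []
    offset = 0
    for sub in dataset:
        b0, b1 = _subject_block(sub)
        blocks.append(sub.emg.values[b0:b1])
        shifted.append((sub, [_shift_cycle(c, offset - b0) for c in sub.cycles]))
        offset += b1 - b0

    if config.mode == "concat":
        concat = MultichannelSignal(np.concatenate(blocks, axis=0), rate, list(labels))
        log.info("concat mode: one MEMD over %d samples x %d channels",
                 concat.n_samples, concat.n_channels)
        scale_mats = _decompose_block(concat, config)
        raw_all = concat.values
        per_subject_scales = [(scale_mats, raw_all)] * len(dataset)
    else:
        per_subject_scales = []
        sub_offset = 0
        for blk, sub in zip(blocks, dataset):
            sig = MultichannelSignal(blk, rate, list(labels))
            log.info("per-subject mode: MEMD for %s (%d samples)",
                     sub.subject_id, sig.n_samples)
            mats = _decompose_block(sig, config)
            per_subject_scales.append((mats, blk))
            sub_offset += blk.shape[0]
        # re-shift cycles to per-subject coordinates
        shifted2 = []
        offset = 0
        for (sub, cycs), blk in zip(shifted, blocks):
            shifted2.append((sub, [_shift_cycle(c, -offset) for c in cycs]))
            offset += blk.shape[0]
        shifted = shifted2

    col_index = {lb: j for j, lb in enumerate(labels)}
    cycle_curves: list[MMSECurve] = []
    subject_curves: list[MMSECurve] = []
    subject_groups: dict[int, tuple[list[MMSECurve], list[str]]] = {}

    for (sub, cycs), (scale_mats, raw) in zip(shifted, per_subject_scales):
        for scheme in schemes:
            cols = [col_index[lb] for lb in scheme.channels]
            per_cycle: list[MMSECurve] = []
            for i_cyc, cyc in enumerate(c for c in cycs if c.side == scheme.side):
                a, b = cyc.span(scheme.segment)
                raw_seg = raw[a:b, cols]
                scales = [m[a:b, cols] for m in scale_mats]
                r = tolerance_from_raw(raw_seg, factor=config.r_factor)
                params = EmbeddingParams(
                    M=[config.m] * len(cols), tau=[config.tau] * len(cols), r=r
                )
                curve = mmse_curve(
                    raw_seg, scales, params=params,
                    provenance=dict(
                        subject=sub.subject_id, group=sub.group,
                        scheme=scheme.id, strategy=scheme.strategy,
                        side=scheme.side, segment=scheme.segment, cycle=i_cyc,
                    ),
                )
                per_cycle.append(curve)
            if not per_cycle:
                log.warning("subject %s has no %s-side cycles for scheme %d",
                            sub.subject_id, scheme.side, scheme.id)
                continue
            cycle_curves.extend(per_cycle)
            sc = subject_curve(per_cycle)
            subject_curves.append(sc)
            curves, groups = subject_groups.setdefault(scheme.id, ([], []))
            curves.append(sc)
            groups.append(sub.group)

    summaries: dict[tuple[int, str], GroupSummary] = {}
    for scheme_id, (curves, groups) in subject_groups.items():
        for grp, gs in group_summary(curves, groups).items():
            summaries[(scheme_id, grp)] = gs

    return AnalysisResult(
        cycle_curves=cycle_curves,
        subject_curves=subject_curves,
        summaries=summaries,
        schemes=schemes,
        config=config,
    )


def load_dataset(dataset_dir, run_config=None) -> list[SubjectData]:
    """Load a cohort directory (as written by ``make_cohort``) into memory.

    Reads each subject's EMG and accelerometer traces, detects heel-strike
    peaks, builds both legs' gait cycles and drops artifact cycles.
    """
    from pathlib import Path

    from .io import RunConfig, read_signal
    from .segmentation import (build_gait_cycles, detect_acc_peaks,
                               reject_artifact_cycles)

    rc = run_config if run_config is not None else RunConfig()
    dataset_dir = Path(dataset_dir)
    groups_file = dataset_dir / "groups.tsv"
    if not groups_file.exists():
        raise FileNotFoundError(f"no groups.tsv in {dataset_dir}")
    dataset: list[SubjectData] = []
    for line in groups_file.read_text().splitlines()[1:]:
        sid, grp = line.split("\t")
        sdir = dataset_dir / sid
        emg = read_signal(sdir / "emg.tsv")
        strikes = {}
        for side, fname in (("left", "acc_left.tsv"), ("right", "acc_right.tsv")):
            acc = read_signal(sdir / fname)
            strikes[side] = detect_acc_peaks(
                acc.values[:, 0], acc.rate, side=side,
                min_interval_s=rc.min_interval_s,
                prominence_factor=rc.prominence_factor,
            )
        cycles = []
        for side, other in (("left", "right"), ("right", "left")):
            cycles.extend(
                build_gait_cycles(strikes[side], strikes[other], emg.rate,
                                  cycle_bounds_s=tuple(rc.cycle_bounds_s))
            )
        if cycles:
            cycles = reject_artifact_cycles(emg, cycles, z_threshold=rc.artifact_z)
        dataset.append(SubjectData(subject_id=sid, emg=emg, cycles=cycles, group=grp))
    return dataset
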