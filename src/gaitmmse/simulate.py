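"""Synthetic gait EMG and accelerometry with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: 16 surface EMG channels (8 muscles per leg) at 1 kHz whose
activity is phase-locked to the gait cycle, plus one gravity-axis
accelerometer trace per shank at 100 Hz with a sharp peak at every heel
strike.  Each muscle's EMG is a smooth activation envelope (a raised-cosine
burst inside the muscle's activation window, expressed as phase fractions
of the cycle) multiplied by a band-limited 20-450 Hz Gaussian carrier.
Cross-muscle coupling is controlled by mixing each carrier with a shared
band-limited drive at weight rho: pairwise carrier correlation grows
monotonically with rho and vanishes at rho = 0.  Legs alternate half a
cycle out of phase.

Impairment profiles mirror two mechanisms discussed for cerebral palsy
gait: a "spastic" profile raises the coupling and widens/strengthens the
thigh-muscle bursts during stance (over-activation and abnormal
synchronization), while a "paretic" profile attenuates the lower-leg
burst amplitudes and removes their shared drive (insufficient motor
output, loss of couplings).  These profiles are simulation fixtures, not
claims about any clinical cohort.

All randomness flows from one seed through named ``numpy`` seed-sequence
spawns, so every output is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal import MultichannelSignal
from .schemes import MUSCLES

__all__ = [
    "SubjectProfile",
    "GroundTruth",
    "control_profile",
    "spastic_profile",
    "paretic_profile",
    "generate_subject",
    "make_cohort",
]

#: textbook activation windows as (start, end) phase fractions of the gait
#: cycle (heel strike = 0); windows may wrap around 1.  Quadriceps and TF
#: fire around heel strike / early stance, hamstrings in late swing through
#: contact, TA during swing and heel strike, plantar flexors in late stance.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "VL": (0.90, 0.25),
    "RF": (0.92, 0.22),
    "SE": (0.75, 0.05),
    "BF": (0.78, 0.08),
    "TF": (0.90, 0.30),
    "TA": (0.55, 0.10),
    "SO": (0.10, 0.55),
    "LG": (0.15, 0.55),
}

THIGH = ["VL", "RF", "SE", "BF", "TF"]
LOWER = ["TA", "SO", "LG"]

EMG_RATE = 1000.0
ACC_RATE = 100.0
EMG_BAND = (20.0, 450.0)

_ACC_PULSE_AMPLITUDE = 2.0
_ACC_PULSE_WIDTH_S = 0.03
_ACC_NOISE_SD = 0.1
_EMG_BASELINE = 0.05
_EMG_SENSOR_NOISE_SD = 0.02
_LEAD_IN_S = 0.5
_TAIL_S = 0.5


@dataclass
class SubjectProfile:
    """Everything needed to synthesize one subject's walk."""

    group: str = "control"                       # control | spastic | paretic
    n_cycles: int = 12
    cadence_mean_s: float = 0.9                  # gait-cycle duration (child-like)
    cadence_jitter_s: float = 0.05               # SD of cycle-to-cycle duration
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {m: 1.0 for m in MUSCLES}
    )
    rho: float = 0.3                             # shared-drive mixing weight
    coupled_muscles: list[str] = field(default_factory=lambda: list(MUSCLES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        for m, (a, b) in self.windows.items():
            if not (0.0 <= a < 1.0 and 0.0 <= b < 1.0):
                raise ValueError(f"activation window of {m} must lie in [0, 1): {(a, b)}")
        if any(v < 0 for v in self.amplitudes.values()):
            raise ValueError("burst amplitudes must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("need at least one gait cycle")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    strike_times_left: np.ndarray    # seconds; n_cycles + 1 entries
    strike_times_right: np.ndarray   # seconds; n_cycles + 1 entries
    stance_swing_left: list[tuple[float, float, float]]   # (start, stance end, end) s
    stance_swing_right: list[tuple[float, float, float]]
    envelopes: np.ndarray            # (T, 16) at EMG rate
    carriers: np.ndarray             # (T, 16) at EMG rate, pre-envelope
    rho: float
    coupled_muscles: list[str]

    def __post_init__(self) -> None:
        for name, t in (("left", self.strike_times_left), ("right", self.strike_times_right)):
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} strike times must be strictly increasing")


def control_profile(seed: int = 0, n_cycles: int = 12) -> SubjectProfile:
    """Typical gait: moderate shared drive across all muscles of a leg."""
    return SubjectProfile(group="control", n_cycles=n_cycles, seed=seed)


def spastic_profile(seed: int = 0, n_cycles: int = 12) -> SubjectProfile:
    """Raised coupling plus widened, stronger thigh bursts through stance."""
    windows = dict(DEFAULT_WINDOWS)
    for m in THIGH:
        a, _ = windows[m]
        windows[m] = (a, 0.55)  # thigh bursts persist through most of stance
    amplitudes = {m: (1.3 if m in THIGH else 1.0) for m in MUSCLES}
    return SubjectProfile(
        group="spastic", n_cycles=n_cycles, windows=windows,
        amplitudes=amplitudes, rho=0.8, seed=seed,
    )


def paretic_profile(seed: int = 0, n_cycles: int = 12) -> SubjectProfile:
    """Attenuated lower-leg output with its shared drive removed."""
    amplitudes = {m: (0.3 if m in LOWER else 1.0) for m in MUSCLES}
    return SubjectProfile(
        group="paretic", n_cycles=n_cycles, amplitudes=amplitudes,
        rho=0.3, coupled_muscles=list(THIGH), seed=seed,
    )


# ---------------------------------------------------------------------------
# pieces
# ---------------------------------------------------------------------------

def _strike_times(profile: SubjectProfile, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    durations = rng.normal(profile.cadence_mean_s, profile.cadence_jitter_s, profile.n_cycles)
    durations = np.clip(durations, 0.6 * profile.cadence_mean_s, 1.4 * profile.cadence_mean_s)
    left = _LEAD_IN_S + np.concatenate([[0.0], np.cumsum(durations)])
    # contralateral strikes near mid-cycle, slightly jittered
    frac = np.clip(rng.normal(0.5, 0.02, profile.n_cycles + 1), 0.4, 0.6)
    right = np.empty(profile.n_cycles + 1)
    right[:-1] = left[:-1] + frac[:-1] * durations
    right[-1] = left[-1] + frac[-1] * durations[-1]
    return left, right


def _phase(t: np.ndarray, strikes: np.ndarray) -> np.ndarray:
    """Piecewise-linear gait phase in [0, 1) relative to a strike series."""
    mean_dur = float(np.mean(np.diff(strikes)))
    knots = np.concatenate([[strikes[0] - mean_dur], strikes, [strikes[-1] + mean_dur]])
    cycle = np.searchsorted(knots, t, side="right") - 1
    cycle = np.clip(cycle, 0, len(knots) - 2)
    left = knots[cycle]
    width = knots[cycle + 1] - knots[cycle]
    return (t - left) / width


def _burst(phase: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Raised-cosine burst inside an activation window (phase fractions, wraps)."""
    a, b = window
    width = (b - a) % 1.0
    if width == 0.0:
        width = 1.0
    u = ((phase - a) % 1.0) / width
    out = np.zeros_like(phase)
    inside = u <= 1.0
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * u[inside]))
    return out


def _bandlimited_noise(n: int, rng: np.random.Generator, sos: np.ndarray) -> np.ndarray:
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / np.std(x)


def _acc_trace(strikes_s: np.ndarray, n_acc: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n_acc) / ACC_RATE
    acc = np.zeros(n_acc)
    for ts in strikes_s:
        acc += _ACC_PULSE_AMPLITUDE * np.exp(-0.5 * ((t - ts) / _ACC_PULSE_WIDTH_S) ** 2)
    return acc + _ACC_NOISE_SD * rng.standard_normal(n_acc)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_subject(
    profile: SubjectProfile,
) -> tuple[MultichannelSignal, MultichannelSignal, MultichannelSignal, GroundTruth]:
    """Synthesize one subject: 16-channel EMG, two ACC traces, ground truth.

    Returns ``(emg, acc_left, acc_right, truth)`` with EMG at 1 kHz and the
    accelerometer traces at 100 Hz.
    """
    streams = np.random.SeedSequence(profile.seed).spawn(4)
    rng_gait = np.random.default_rng(streams[0])
    rng_carrier = np.random.default_rng(streams[1])
    rng_acc = np.random.default_rng(streams[2])
    rng_sensor = np.random.default_rng(streams[3])

    left_strikes, right_strikes = _strike_times(profile, rng_gait)
    t_end = max(left_strikes[-1], right_strikes[-1]) + _TAIL_S
    n_emg = int(round(t_end * EMG_RATE))
    n_acc = int(round(t_end * ACC_RATE))
    t_emg = np.arange(n_emg) / EMG_RATE

    phase = {
        "L": _phase(t_emg, left_strikes),
        "R": _phase(t_emg, right_strikes),
    }

    nyq = EMG_RATE / 2.0
    sos = butter(4, [EMG_BAND[0] / nyq, EMG_BAND[1] / nyq], btype="band", output="sos")
    rho = profile.rho
    shared = {p: _bandlimited_noise(n_emg, rng_carrier, sos) for p in ("L", "R")}

    labels, env_cols, carrier_cols, emg_cols = [], [], [], []
    for prefix in ("L", "R"):
        for muscle in MUSCLES:
            labels.append(f"{prefix}_{muscle}")
            env = _EMG_BASELINE + profile.amplitudes[muscle] * _burst(
                phase[prefix], profile.windows[muscle]
            )
            own = _bandlimited_noise(n_emg, rng_carrier, sos)
            if muscle in profile.coupled_muscles and rho > 0.0:
                carrier = np.sqrt(1.0 - rho**2) * own + rho * shared[prefix]
            else:
                carrier = own
            emg = env * carrier + _EMG_SENSOR_NOISE_SD * rng_sensor.standard_normal(n_emg)
            env_cols.append(env)
            carrier_cols.append(carrier)
            emg_cols.append(emg)

    emg_sig = MultichannelSignal(np.column_stack(emg_cols), EMG_RATE, labels)
    acc_left = MultichannelSignal(
        _acc_trace(left_strikes, n_acc, rng_acc)[:, None], ACC_RATE, ["L_ACC"]
    )
    acc_right = MultichannelSignal(
        _acc_trace(right_strikes, n_acc, rng_acc)[:, None], ACC_RATE, ["R_ACC"]
    )

    def _phases(ipsi: np.ndarray, contra: np.ndarray) -> list[tuple[float, float, float]]:
        out = []
        for p0, p1 in zip(ipsi[:-1], ipsi[1:]):
            mid = contra[(contra > p0) & (contra < p1)]
            if len(mid) == 1:
                out.append((float(p0), float(mid[0]), float(p1)))
        return out

    truth = GroundTruth(
        strike_times_left=left_strikes,
        strike_times_right=right_strikes,
        stance_swing_left=_phases(left_strikes, right_strikes),
        stance_swing_right=_phases(right_strikes, left_strikes),
        envelopes=np.column_stack(env_cols),
        carriers=np.column_stack(carrier_cols),
        rho=rho,
        coupled_muscles=list(profile.coupled_muscles),
    )
    return emg_sig, acc_left, acc_right, truth


def make_cohort(
    n_per_group: dict[str, int],
    out_dir: str | Path,
    master_seed: int = 0,
    n_cycles: int = 12,
    profiles: dict[str, SubjectProfile] | None = None,
) -> Path:
    """Write a cohort of synthetic subjects to a dataset directory.

    One subdirectory per subject (``emg.tsv``, ``acc_left.tsv``,
    ``acc_right.tsv``, ``truth.json``) plus a ``groups.tsv`` map.  Fully
    deterministic from ``master_seed``.
    """
    from .io import write_signal  # deferred: io imports nothing from here

    base = {
        "control": control_profile(n_cycles=n_cycles),
        "spastic": spastic_profile(n_cycles=n_cycles),
        "paretic": paretic_profile(n_cycles=n_cycles),
    }
    if profiles:
        base.update(profiles)
    for grp in n_per_group:
        if grp not in base:
            raise ValueError(f"no profile for group {grp!r}")
    if any(n < 1 for n in n_per_group.values()):
        raise ValueError("n_per_group entries must be >= 1")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(master_seed).generate_state(
        sum(n_per_group.values())
    ) % (2**31)
    rows = []
    i = 0
    for grp in sorted(n_per_group):
        for j in range(n_per_group[grp]):
            sid = f"{grp}{j + 1:02d}"
            profile = replace(base[grp], seed=int(seeds[i]))
            emg, acc_l, acc_r, truth = generate_subject(profile)
            sdir = out_dir / sid
            sdir.mkdir(exist_ok=True)
            write_signal(emg, sdir / "emg.tsv")
            write_signal(acc_l, sdir / "acc_left.tsv")
            write_signal(acc_r, sdir / "acc_right.tsv")
            (sdir / "truth.json").write_text(json.dumps({
                "strike_times_left": truth.strike_times_left.tolist(),
                "strike_times_right": truth.strike_times_right.tolist(),
                "stance_swing_left": truth.stance_swing_left,
                "stance_swing_right": truth.stance_swing_right,
                "rho": truth.rho,
                "coupled_muscles": truth.coupled_muscles,
                "seed": int(seeds[i]),
            }, indent=1))
            rows.append(f"{sid}\t{grp}")
            i += 1
    (out_dir / "groups.tsv").write_text("subject\tgroup\n" + "\n".join(rows) + "\n")
    return out_dir
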