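"""Multivariate empirical mode decomposition (MEMD).

Standard EMD extracts intrinsic mode functions (IMFs) from a single time
series by repeatedly subtracting the mean of its extremum envelopes
("sifting").  Applied channel-by-channel to multichannel data it tends to
produce different mode counts and misaligned scales across channels.  MEMD
instead projects the multivariate signal along many directions on the unit
hypersphere, builds one envelope per direction from the projection maxima,
and sifts against the average of those envelopes.  Because every channel is
decomposed jointly, each extracted mode has the same index and a comparable
scale on every channel (mode alignment), which is what makes per-scale
multichannel entropy analysis meaningful.

Noise-assisted operation appends a few independent white-noise channels to
the input before decomposition; their broadband content populates every
mode and counteracts mode mixing.  The noise channels are stripped again
after decomposition.

Scales for multiscale analysis are *cumulative* IMFs: scale n is the sum of
modes n..N plus the residual, i.e. the signal with its finest n-1 modes
removed.  Scale 1 is the full signal; the last scale is the coarsest
remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks
from scipy.stats import beta as beta_dist

from .signal import MultichannelSignal, SignalValidationError

__all__ = [
    "DirectionSet",
    "IMFDecomposition",
    "CumulativeScale",
    "InsufficientExtremaError",
    "generate_directions",
    "project",
    "local_mean",
    "sift_mode",
    "memd",
    "add_noise_channels",
    "strip_noise_channels",
    "cumulative_scales",
]

#: default number of projection directions
DEFAULT_N_DIRECTIONS = 64
#: sift-difference stoppage threshold
DEFAULT_SD_THRESHOLD = 0.2
#: hard cap on sifting iterations per mode
DEFAULT_MAX_SIFT = 15
#: default number of modes extracted before the residual
DEFAULT_MAX_MODES = 6
#: default number of white-noise helper channels
DEFAULT_N_NOISE = 6


class InsufficientExtremaError(RuntimeError):
    """Signalled when no projection of the signal has enough maxima to sift."""


@dataclass
class DirectionSet:
    """Unit direction vectors sampled quasi-uniformly on the hypersphere."""

    vectors: np.ndarray  # (K, n_dim), rows unit norm
    angles: np.ndarray   # (K, n_dim - 1) generating angle tuples

    @property
    def count(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class IMFDecomposition:
    """Scale-aligned IMFs for every channel, plus the residual.

    ``imfs[k]`` is the (T, n) matrix of the k-th mode across all channels,
    ordered fine (high frequency) to coarse.  The sum of all modes and the
    residual reconstructs the input to numerical precision.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_rate: float
    source_labels: list[str] = field(default_factory=list)

    @property
    def n_modes(self) -> int:
        return len(self.imfs)

    @property
    def n_channels(self) -> int:
        return self.residual.shape[1]

    @property
    def n_samples(self) -> int:
        return self.residual.shape[0]

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for m in self.imfs:
            out += m
        return out


@dataclass
class CumulativeScale:
    """Signal with its finest ``scale_factor - 1`` modes removed."""

    scale_factor: int
    values: np.ndarray  # (T, n)


# ---------------------------------------------------------------------------
# direction sampling
# ---------------------------------------------------------------------------

_PRIMES = [2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59,
           61, 67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113]


def _radical_inverse(i: int, base: int) -> float:
    inv = 0.0
    f = 1.0 / base
    while i > 0:
        inv += f * (i % base)
        i //= base
        f /= base
    return inv


def _hammersley(count: int, dim: int) -> np.ndarray:
    """Hammersley low-discrepancy point set on the unit cube [0, 1)^dim."""
    pts = np.empty((count, dim))
    pts[:, 0] = (np.arange(count) + 0.5) / count
    for d in range(1, dim):
        base = _PRIMES[(d - 1) % len(_PRIMES)]
        pts[:, d] = [_radical_inverse(i + 1, base) for i in range(count)]
    return pts


def generate_directions(n_dim: int, count: int) -> DirectionSet:
    """Sample ``count`` unit vectors quasi-uniformly on the (n_dim-1)-sphere.

    Hammersley points on the unit cube are pushed through the angular
    (hyperspherical) parameterization with the equal-area inverse-CDF
    transform per angle, so that the resulting vectors are low-discrepancy
    on the sphere itself rather than clustered at the poles.  Deterministic
    for fixed ``(n_dim, count)``.
    """
    if n_dim < 2:
        raise ValueError(
            "direction sampling needs >= 2 dimensions; univariate input "
            "routes to plain EMD"
        )
    if count < 1:
        raise ValueError("count must be >= 1")
    u = _hammersley(count, n_dim - 1)
    angles = np.empty_like(u)
    # angle j (0-based) of the hyperspherical parameterization has density
    # proportional to sin^k with k = n_dim - 2 - j; the last angle is uniform
    # on [0, 2*pi).
    for j in range(n_dim - 2):
        k = n_dim - 2 - j
        a = (k + 1) / 2.0
        x = 2.0 * beta_dist.ppf(u[:, j], a, a) - 1.0  # cos(theta_j), area-uniform
        angles[:, j] = np.arccos(np.clip(x, -1.0, 1.0))
    angles[:, n_dim - 2] = 2.0 * np.pi * u[:, n_dim - 2]

    vectors = np.empty((count, n_dim))
    sin_prod = np.ones(count)
    for j in range(n_dim - 1):
        vectors[:, j] = sin_prod * np.cos(angles[:, j])
        sin_prod = sin_prod * np.sin(angles[:, j])
    vectors[:, n_dim - 1] = sin_prod
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return DirectionSet(vectors=vectors, angles=angles)


# ---------------------------------------------------------------------------
# envelopes and sifting
# ---------------------------------------------------------------------------

def project(values: np.ndarray | MultichannelSignal, direction: np.ndarray) -> np.ndarray:
    """Project the multichannel samples onto a direction vector."""
    if isinstance(values, MultichannelSignal):
        values = values.values
    direction = np.asarray(direction, dtype=float)
    if values.shape[1] != direction.shape[0]:
        raise ValueError(
            f"direction dimension {direction.shape[0]} != channel count {values.shape[1]}"
        )
    return values @ direction


def _maxima_indices(p: np.ndarray) -> np.ndarray:
    """Strict local maxima; plateaus contribute their midpoint sample."""
    peaks, _ = find_peaks(p)
    return peaks


def _mirror_extend(idx: np.ndarray, t_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to 2 extrema across each boundary; returns (times, source idx)."""
    left_t, left_src = [], []
    for i in (min(1, len(idx) - 1), 0):
        t = -int(idx[i])
        if t < idx[0] and (not left_t or t > left_t[-1]):
            left_t.append(t)
            left_src.append(int(idx[i]))
    right_t, right_src = [], []
    for i in (-1, max(-2, -len(idx))):
        t = 2 * t_max - int(idx[i])
        if t > idx[-1] and (not right_t or t > right_t[-1]):
            right_t.append(t)
            right_src.append(int(idx[i]))
    times = np.array(left_t + list(idx) + right_t)
    src = np.array(left_src + list(idx) + right_src)
    return times, src


def _envelope(values: np.ndarray, idx: np.ndarray, t_eval: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through the samples at ``idx``, all channels at once."""
    times, src = _mirror_extend(idx, t_max=values.shape[0] - 1)
    knots = values[src]
    bc = "not-a-knot" if len(times) >= 4 else "natural"
    return CubicSpline(times, knots, axis=0, bc_type=bc)(t_eval)


def local_mean(values: np.ndarray, directions: DirectionSet) -> np.ndarray:
    """Mean of the direction-wise envelope curves (the multivariate local mean).

    For each direction the signal is projected, the projection maxima are
    located, and the multivariate samples at those times are interpolated
    with a cubic spline (per channel) to form one envelope; the local mean
    is the average of the envelopes over all usable directions.

    Raises
    ------
    InsufficientExtremaError
        If no projection has at least 3 local maxima.
    """
    t, n = values.shape
    t_eval = np.arange(t)
    proj = values @ directions.vectors.T  # (T, K)
    acc = np.zeros_like(values)
    used = 0
    for k in range(directions.count):
        idx = _maxima_indices(proj[:, k])
        if len(idx) < 3:
            continue
        acc += _envelope(values, idx, t_eval)
        used += 1
    if used == 0:
        raise InsufficientExtremaError(
            "no projection has >= 3 local maxima; remainder is monotonic "
            "at every sampled direction"
        )
    return acc / used


def sift_mode(
    values: np.ndarray,
    directions: DirectionSet,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_sift: int = DEFAULT_MAX_SIFT,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract one IMF by iterative sifting; returns ``(mode, remainder)``.

    Iterates ``d <- d - local_mean(d)`` until the sift difference
    ``SD = sum ||d_prev - d_cur||^2 / sum ||d_prev||^2`` drops below
    ``sd_threshold``, capped at ``max_sift`` iterations.
    """
    cur = values
    for _ in range(max_sift):
        m = local_mean(cur, directions)
        new = cur - m
        denom = float(np.sum(cur * cur))
        sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
        cur = new
        if sd < sd_threshold:
            break
    return cur, values - cur


def _is_terminal(values: np.ndarray, directions: DirectionSet) -> bool:
    proj = values @ directions.vectors.T
    for k in range(directions.count):
        if len(_maxima_indices(proj[:, k])) >= 3:
            return False
    return True


# ---------------------------------------------------------------------------
# univariate special case (classic EMD)
# ---------------------------------------------------------------------------

def _emd_local_mean_1d(x: np.ndarray) -> np.ndarray | None:
    """Classic EMD local mean: average of maxima and minima spline envelopes."""
    t_eval = np.arange(len(x))
    imax = _maxima_indices(x)
    imin = _maxima_indices(-x)
    if len(imax) < 3 or len(imin) < 3:
        return None
    col = x[:, None]
    upper = _envelope(col, imax, t_eval)
    lower = _envelope(col, imin, t_eval)
    return ((upper + lower) / 2.0)[:, 0]


def _emd_univariate(
    x: np.ndarray, max_modes: int, sd_threshold: float, max_sift: int
) -> tuple[list[np.ndarray], np.ndarray]:
    imfs: list[np.ndarray] = []
    res = x.copy()
    for _ in range(max_modes):
        if _emd_local_mean_1d(res) is None:
            break
        cur = res.copy()
        for _ in range(max_sift):
            m = _emd_local_mean_1d(cur)
            if m is None:
                break
            new = cur - m
            denom = float(np.sum(cur * cur))
            sd = float(np.sum(m * m)) / denom if denom > 0 else 0.0
            cur = new
            if sd < sd_threshold:
                break
        imfs.append(cur)
        res = res - cur
    return imfs, res


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def memd(
    signal: MultichannelSignal,
    n_directions: int = DEFAULT_N_DIRECTIONS,
    max_modes: int = DEFAULT_MAX_MODES,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_sift: int = DEFAULT_MAX_SIFT,
) -> IMFDecomposition:
    """Decompose a multichannel signal into scale-aligned IMFs plus residual.

    At most ``max_modes`` modes are extracted fine-to-coarse; whatever is
    left (including all coarser oscillations) is kept as the residual, which
    downstream multiscale analysis treats as the final scale.  A univariate
    input routes to classic (extremum-envelope) EMD with the same stoppage
    rule; the output structure is identical.
    """
    if not np.isfinite(signal.values).all():
        raise SignalValidationError("non-finite samples in decomposition input")
    if signal.n_channels == 1:
        imfs1d, res1d = _emd_univariate(
            signal.values[:, 0], max_modes, sd_threshold, max_sift
        )
        return IMFDecomposition(
            imfs=[m[:, None] for m in imfs1d],
            residual=res1d[:, None],
            source_rate=signal.rate,
            source_labels=list(signal.labels),
        )

    directions = generate_directions(signal.n_channels, n_directions)
    imfs: list[np.ndarray] = []
    res = signal.values.copy()
    for _ in range(max_modes):
        if _is_terminal(res, directions):
            break
        mode, res = sift_mode(res, directions, sd_threshold, max_sift)
        imfs.append(mode)
    return IMFDecomposition(
        imfs=imfs,
        residual=res,
        source_rate=signal.rate,
        source_labels=list(signal.labels),
    )


def add_noise_channels(
    signal: MultichannelSignal,
    n_noise: int = DEFAULT_N_NOISE,
    seed: int | np.random.Generator = 0,
) -> MultichannelSignal:
    """Append independent Gaussian white-noise channels for noise assistance.

    Each noise channel is scaled to the mean standard deviation of the
    existing channels so it carries comparable energy and can populate every
    mode.  With the default 6 noise channels a 16-channel EMG recording
    becomes the 22-channel composite used for decomposition.
    """
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    if n_noise == 0:
        return signal
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scale = float(np.mean(np.std(signal.values, axis=0)))
    if scale == 0.0:
        scale = 1.0
    noise = rng.standard_normal((signal.n_samples, n_noise)) * scale
    values = np.concatenate([signal.values, noise], axis=1)
    labels = list(signal.labels) + [f"WN{j + 1}" for j in range(n_noise)]
    return MultichannelSignal(values, signal.rate, labels)


def strip_noise_channels(dec: IMFDecomposition, n_noise: int) -> IMFDecomposition:
    """Drop the trailing noise channels from a decomposition."""
    if n_noise < 0:
        raise ValueError("n_noise must be >= 0")
    if n_noise == 0:
        return dec
    keep = dec.n_channels - n_noise
    if keep < 1:
        raise ValueError(
            f"cannot strip {n_noise} channels from a {dec.n_channels}-channel decomposition"
        )
    return IMFDecomposition(
        imfs=[m[:, :keep].copy() for m in dec.imfs],
        residual=dec.residual[:, :keep].copy(),
        source_rate=dec.source_rate,
        source_labels=dec.source_labels[:keep],
    )


def cumulative_scales(dec: IMFDecomposition, n_scales: int) -> list[CumulativeScale]:
    """Build cumulative-IMF scales, fine to coarse.

    Scale ``n`` is ``sum(imfs[n-1:]) + residual``: scale 1 reconstructs the
    input, the last scale is the residual-inclusive coarsest remainder, and
    ``scale_n - scale_{n+1} == imf_n`` exactly.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    if n_scales > dec.n_modes + 1:
        raise ValueError(
            f"n_scales={n_scales} exceeds mode count + 1 = {dec.n_modes + 1}"
        )
    scales: list[CumulativeScale] = []
    acc = dec.residual.copy()
    for i in range(dec.n_modes - 1, n_scales - 2, -1):
        acc = acc + dec.imfs[i]
    # acc now holds scale n_scales ... build upward by exact telescoping
    partial = [None] * n_scales
    partial[n_scales - 1] = acc
    for n in range(n_scales - 1, 0, -1):
        partial[n - 1] = partial[n] + dec.imfs[n - 1]
    for n in range(1, n_scales + 1):
        scales.append(CumulativeScale(scale_factor=n, values=partial[n - 1]))
    return scales
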