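"""Multivariate sample entropy (MSampEn) and MMSE curves.

Sample entropy is the negative log of the conditional probability that two
segments of a series that match within tolerance ``r`` for ``m`` points
still match when extended by one point, with self-matches excluded.  The
multivariate form embeds all channels jointly in a composite delay vector

    X_m(i) = [x_{1,i}, x_{1,i+tau_1}, ..., x_{1,i+(m_1-1)tau_1},
              x_{2,i}, ...,
              x_{n,i}, ..., x_{n,i+(m_n-1)tau_n}]

and, for the (m+1)-point stage, extends the embedding by one sample in each
of the n channels in turn, pooling the n*(N-delta) extended vectors.
Distances are Chebyshev (max-norm); a pair matches when d <= r.

The tolerance follows the raw-signal convention: r = factor * sum of the
per-channel standard deviations of the *raw* segment involved, computed
once and then applied unchanged to every decomposition scale, so that MMSE
values across scales are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .memd import CumulativeScale

__all__ = [
    "EmbeddingParams",
    "DelayVectorSet",
    "MatchStatistics",
    "MSampEnResult",
    "MMSECurve",
    "SegmentTooShortError",
    "embed",
    "msampen",
    "tolerance_from_raw",
    "mmse_curve",
]


class SegmentTooShortError(ValueError):
    """Raised when a segment has too few samples for the requested embedding."""


@dataclass
class EmbeddingParams:
    """Embedding dimensions, lags and tolerance for MSampEn.

    ``M[k]`` and ``tau[k]`` are the embedding dimension and time lag of
    channel k; ``r`` is the similarity tolerance in amplitude units.  The
    composite dimension is ``m = sum(M)`` and the warm-up span is
    ``delta = max(M) * max(tau)``.
    """

    M: list[int]
    tau: list[int]
    r: float

    def __post_init__(self) -> None:
        if len(self.M) != len(self.tau):
            raise ValueError("M and tau must have one entry per channel")
        if any(int(m) < 1 for m in self.M) or any(int(t) < 1 for t in self.tau):
            raise ValueError("embedding dimensions and lags must be >= 1")
        if self.r < 0:
            raise ValueError("tolerance r must be >= 0")
        self.M = [int(m) for m in self.M]
        self.tau = [int(t) for t in self.tau]

    @classmethod
    def default(cls, n_channels: int, r: float) -> "EmbeddingParams":
        """m_k = 2, tau_k = 1 on every channel — the standard choice."""
        return cls(M=[2] * n_channels, tau=[1] * n_channels, r=r)

    @property
    def n_channels(self) -> int:
        return len(self.M)

    @property
    def m(self) -> int:
        return int(sum(self.M))

    @property
    def delta(self) -> int:
        return int(max(self.M) * max(self.tau))


@dataclass
class DelayVectorSet:
    """Composite delay vectors and the sample index each one starts at."""

    vectors: np.ndarray  # (N - delta, m)
    origins: np.ndarray  # (N - delta,)


@dataclass
class MatchStatistics:
    """Match frequencies underlying one MSampEn estimate."""

    b_m: float
    b_m1: float
    counts_m: np.ndarray = field(repr=False, default=None)
    counts_m1: np.ndarray = field(repr=False, default=None)


@dataclass
class MSampEnResult:
    """MSampEn value with a defined-ness flag and its match statistics.

    ``defined`` is False when either match frequency is zero, in which case
    ``value`` is NaN and must not enter averages silently.
    """

    value: float
    defined: bool
    stats: MatchStatistics


@dataclass
class MMSECurve:
    """MSampEn per cumulative-IMF scale factor, fine to coarse."""

    scale_factors: np.ndarray
    values: np.ndarray          # NaN where undefined
    defined: np.ndarray         # bool per scale
    params: EmbeddingParams
    provenance: dict = field(default_factory=dict)

    @property
    def n_scales(self) -> int:
        return len(self.scale_factors)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def _embed_matrix(segment: np.ndarray, M: list[int], tau: list[int]) -> np.ndarray:
    """Stack composite delay vectors row-wise; channel blocks in channel order."""
    n_samp = segment.shape[0]
    delta = max(M) * max(tau)
    n_vec = n_samp - delta
    cols = []
    for k, (mk, tk) in enumerate(zip(M, tau)):
        for j in range(mk):
            cols.append(segment[j * tk: j * tk + n_vec, k])
    return np.column_stack(cols)


def embed(segment: np.ndarray, params: EmbeddingParams) -> DelayVectorSet:
    """Multivariate delay embedding of an (N, n) segment.

    Produces exactly ``N - delta`` composite vectors of dimension
    ``m = sum(M)``, ordered channel-by-channel within each vector.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] == 1 and params.n_channels == 1:
        segment = segment.T
    if segment.shape[1] != params.n_channels:
        raise ValueError(
            f"segment has {segment.shape[1]} channels, params expect {params.n_channels}"
        )
    n_samp = segment.shape[0]
    if n_samp <= params.delta:
        raise SegmentTooShortError(
            f"segment of length {n_samp} too short for delta={params.delta}; "
            f"need at least {params.delta + 1} samples"
        )
    vectors = _embed_matrix(segment, params.M, params.tau)
    return DelayVectorSet(vectors=vectors, origins=np.arange(vectors.shape[0]))


# ---------------------------------------------------------------------------
# match counting (numba kernel; exact Chebyshev with early exit)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _count_matches(x: np.ndarray, r: float) -> np.ndarray:  # pragma: no cover
    n_vec, m = x.shape
    counts = np.zeros(n_vec, dtype=np.int64)
    for i in range(n_vec - 1):
        for j in range(i + 1, n_vec):
            match = True
            for c in range(m):
                if abs(x[i, c] - x[j, c]) > r:
                    match = False
                    break
            if match:
                counts[i] += 1
                counts[j] += 1
    return counts


def _extended_matrix(segment: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """All n*(N-delta) vectors of dimension m+1 (each channel extended in turn).

    Because delta = max(M) * max(tau) >= m_k * tau_k for every channel, the
    extension index i + m_k * tau_k never runs past the segment, so every
    origin stays valid for every channel extension.
    """
    blocks = []
    for k in range(params.n_channels):
        M_ext = list(params.M)
        M_ext[k] += 1
        n_vec = segment.shape[0] - params.delta
        cols = []
        for kk, (mk, tk) in enumerate(zip(M_ext, params.tau)):
            for j in range(mk):
                cols.append(segment[j * tk: j * tk + n_vec, kk])
        blocks.append(np.column_stack(cols))
    return np.concatenate(blocks, axis=0)


def msampen(segment: np.ndarray, params: EmbeddingParams) -> MSampEnResult:
    """Multivariate sample entropy of an (N, n) segment.

    Computes the average match frequency B^m over the N-delta composite
    delay vectors, extends the embedding by one point per channel to pool
    n*(N-delta) vectors for B^{m+1}, and returns -ln(B^{m+1} / B^m).
    Chebyshev distance, inclusive tolerance (d <= r), self-matches excluded.
    A zero match frequency at either stage yields an undefined (flagged)
    result rather than an infinity.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    if segment.shape[0] == 1 and params.n_channels == 1:
        segment = segment.T
    if segment.shape[1] != params.n_channels:
        raise ValueError(
            f"segment has {segment.shape[1]} channels, params expect {params.n_channels}"
        )
    if segment.shape[0] <= params.delta + 1:
        raise SegmentTooShortError(
            f"segment of length {segment.shape[0]} too short; need more than "
            f"delta + 1 = {params.delta + 1} samples"
        )
    xm = _embed_matrix(segment, params.M, params.tau)
    counts_m = _count_matches(np.ascontiguousarray(xm), params.r)
    n_m = xm.shape[0]
    b_m = float(np.mean(counts_m / (n_m - 1)))

    xm1 = _extended_matrix(segment, params)
    counts_m1 = _count_matches(np.ascontiguousarray(xm1), params.r)
    n_m1 = xm1.shape[0]
    b_m1 = float(np.mean(counts_m1 / (n_m1 - 1)))

    stats = MatchStatistics(b_m=b_m, b_m1=b_m1, counts_m=counts_m, counts_m1=counts_m1)
    if b_m <= 0.0 or b_m1 <= 0.0:
        return MSampEnResult(value=math.nan, defined=False, stats=stats)
    return MSampEnResult(value=-math.log(b_m1 / b_m), defined=True, stats=stats)


def tolerance_from_raw(raw_channels: np.ndarray, factor: float = 0.2) -> float:
    """Similarity tolerance r = factor * sum of raw per-channel SDs.

    The SDs are taken on the raw (pre-decomposition) segment so that one r
    serves every scale of the same segment.
    """
    raw_channels = np.atleast_2d(np.asarray(raw_channels, dtype=float))
    if raw_channels.shape[0] == 1 and raw_channels.shape[1] > 1:
        raw_channels = raw_channels.T
    if raw_channels.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute standard deviations")
    r = float(factor * np.sum(np.std(raw_channels, axis=0)))
    if r == 0.0:
        import warnings

        warnings.warn(
            "all channels constant: r = 0 makes matches exact-equality only",
            stacklevel=2,
        )
    return r


def mmse_curve(
    raw_segment: np.ndarray,
    scales: list[CumulativeScale] | list[np.ndarray],
    params: EmbeddingParams | None = None,
    r_factor: float = 0.2,
    provenance: dict | None = None,
) -> MMSECurve:
    """MSampEn across cumulative-IMF scales of one segment.

    The tolerance is computed once from the raw segment and applied to the
    MSampEn of every scale, fine to coarse.  Undefined scales (zero match
    frequency) are flagged, not zero-filled.
    """
    raw_segment = np.atleast_2d(np.asarray(raw_segment, dtype=float))
    scale_mats = [s.values if isinstance(s, CumulativeScale) else np.asarray(s) for s in scales]
    factors = [
        s.scale_factor if isinstance(s, CumulativeScale) else i + 1
        for i, s in enumerate(scales)
    ]
    for mat in scale_mats:
        if mat.shape != raw_segment.shape:
            raise ValueError(
                f"scale shape {mat.shape} does not cover raw segment shape {raw_segment.shape}"
            )
    if params is None:
        r = tolerance_from_raw(raw_segment, factor=r_factor)
        params = EmbeddingParams.default(raw_segment.shape[1], r=r)
    values = np.full(len(scale_mats), np.nan)
    defined = np.zeros(len(scale_mats), dtype=bool)
    for i, mat in enumerate(scale_mats):
        res = msampen(mat, params)
        values[i] = res.value
        defined[i] = res.defined
    return MMSECurve(
        scale_factors=np.asarray(factors),
        values=values,
        defined=defined,
        params=params,
        provenance=provenance or {},
    )
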