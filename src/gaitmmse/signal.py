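"""Multichannel signal container shared by every stage of the pipeline.

A :class:`MultichannelSignal` is a plain samples-by-channels matrix plus the
sampling rate and per-channel labels.  Surface EMG is carried at 1 kHz on
labelled channels such as ``L_VL`` (left vastus lateralis); accelerometer
traces are carried at 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SignalValidationError(ValueError):
    """Raised when a signal violates its structural invariants."""


@dataclass
class MultichannelSignal:
    """T x n matrix of amplitudes with sampling rate and channel labels.

    Parameters
    ----------
    values
        Array of shape ``(T, n)``; ``T >= 2`` samples, ``n >= 1`` channels,
        all values finite.
    rate
        Sampling frequency in Hz, strictly positive.
    labels
        One identifier per channel, e.g. ``["L_VL", "L_RF", ...]``.
    """

    values: np.ndarray
    rate: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise SignalValidationError(
                f"values must be 2-D (samples x channels), got ndim={self.values.ndim}"
            )
        t, n = self.values.shape
        if t < 2:
            raise SignalValidationError(f"need at least 2 samples, got {t}")
        if n < 1:
            raise SignalValidationError("need at least 1 channel")
        if not self.rate > 0:
            raise SignalValidationError(f"rate must be > 0, got {self.rate}")
        if not self.labels:
            self.labels = [f"ch{j}" for j in range(n)]
        if len(self.labels) != n:
            raise SignalValidationError(
                f"{len(self.labels)} labels for {n} channels"
            )
        if not np.isfinite(self.values).all():
            raise SignalValidationError("non-finite values in signal")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown channel {label!r}; valid labels: {', '.join(self.labels)}"
            ) from None

    def select(self, labels: list[str]) -> "MultichannelSignal":
        """Return a new signal restricted to the given channels, in order."""
        idx = [self.channel_index(lb) for lb in labels]
        return MultichannelSignal(self.values[:, idx].copy(), self.rate, list(labels))

    def slice(self, start: int, stop: int) -> "MultichannelSignal":
        """Return the half-open sample span ``[start, stop)``."""
        if not (0 <= start < stop <= self.n_samples):
            raise IndexError(
                f"span [{start}, {stop}) outside signal of length {self.n_samples}"
            )
        return MultichannelSignal(self.values[start:stop].copy(), self.rate, list(self.labels))
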