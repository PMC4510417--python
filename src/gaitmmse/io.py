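"""Text-based file formats and run configuration.

Canonical interchange is tab-separated text: greppable, diffable, and
stable across platforms.  A signal file has a single header line --
``rate=<Hz>`` followed by the tab-separated channel labels -- and one row
of amplitudes per sample.  Cycles and curve tables are TSV with a comment
line stating the index convention (0-based, half-open).  An optional
``.npz`` container mirrors the signal format for speed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .memd import IMFDecomposition
from .segmentation import GaitCycle
from .signal import MultichannelSignal

__all__ = [
    "SignalParseError",
    "RunConfig",
    "read_signal",
    "write_signal",
    "read_cycles",
    "write_cycles",
    "save_decomposition",
    "load_decomposition",
]

log = logging.getLogger(__name__)


class SignalParseError(ValueError):
    """Malformed signal file; the message names the offending line."""


@dataclass
class RunConfig:
    """Resolved tunables of a pipeline run, serialized beside every output."""

    n_directions: int = 64
    max_modes: int = 6
    n_noise: int = 6
    sd_threshold: float = 0.2
    max_sift: int = 15
    r_factor: float = 0.2
    m: int = 2
    tau: int = 1
    min_interval_s: float = 0.4
    prominence_factor: float = 2.0
    cycle_bounds_s: tuple[float, float] = (0.5, 4.0)
    artifact_z: float = 20.0
    mode: str = "concat"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cycle_bounds_s" in data:
            data["cycle_bounds_s"] = tuple(data["cycle_bounds_s"])
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def write_signal(signal: MultichannelSignal, path: str | Path, fmt: str = "%.9g") -> None:
    """Write a signal as header + one tab-separated row per sample.

    ``.npz`` paths are written as a binary container instead (same content).
    """
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, values=signal.values, rate=signal.rate,
            labels=np.array(signal.labels),
        )
        return
    header = f"rate={signal.rate:g}\t" + "\t".join(signal.labels)
    np.savetxt(path, signal.values, fmt=fmt, delimiter="\t",
               header=header, comments="")


def read_signal(path: str | Path) -> MultichannelSignal:
    """Read a signal file; raises :class:`SignalParseError` on malformed input."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            return MultichannelSignal(
                z["values"], float(z["rate"]), [str(x) for x in z["labels"]]
            )
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    parts = header.split("\t")
    if not parts or not parts[0].startswith("rate="):
        raise SignalParseError(
            f"{path}:1: header must start with 'rate=<Hz>'; got {header[:50]!r}"
        )
    try:
        rate = float(parts[0][len("rate="):])
    except ValueError:
        raise SignalParseError(f"{path}:1: cannot parse rate from {parts[0]!r}") from None
    labels = parts[1:]
    if not labels:
        raise SignalParseError(f"{path}:1: header lists no channel labels")
    try:
        values = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise SignalParseError(f"{path}: malformed data row ({exc})") from None
    if values.shape[1] != len(labels):
        raise SignalParseError(
            f"{path}: {values.shape[1]} columns but {len(labels)} labels in header"
        )
    bad = ~np.isfinite(values)
    if bad.any():
        row = int(np.argwhere(bad)[0][0]) + 2  # 1-based, after header
        raise SignalParseError(f"{path}:{row}: non-finite value")
    return MultichannelSignal(values, rate, labels)


# ---------------------------------------------------------------------------
# cycles
# ---------------------------------------------------------------------------

_CYCLES_COMMENT = "# 0-based half-open EMG sample indices; stance=[start,stance_end), swing=[stance_end,end)"


def write_cycles(cycles: list[GaitCycle], path: str | Path) -> None:
    lines = [_CYCLES_COMMENT, "side\tstart\tstance_end\tend"]
    for c in cycles:
        lines.append(f"{c.side}\t{c.start_emg_index}\t{c.stance_end_emg_index}\t{c.end_emg_index}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_cycles(path: str | Path) -> list[GaitCycle]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GaitCycle(side=row.side, start_emg_index=int(row.start),
                  stance_end_emg_index=int(row.stance_end),
                  end_emg_index=int(row.end))
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# decompositions
# ---------------------------------------------------------------------------

def save_decomposition(dec: IMFDecomposition, out_dir: str | Path) -> Path:
    """Write one TSV per mode plus the residual and a JSON manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sig = lambda v: MultichannelSignal(v, dec.source_rate, list(dec.source_labels))
    for i, mode in enumerate(dec.imfs):
        write_signal(sig(mode), out_dir / f"imf{i + 1:02d}.tsv")
    write_signal(sig(dec.residual), out_dir / "residual.tsv")
    manifest = dict(
        n_modes=dec.n_modes, n_channels=dec.n_channels, n_samples=dec.n_samples,
        rate=dec.source_rate, labels=list(dec.source_labels),
        files=[f"imf{i + 1:02d}.tsv" for i in range(dec.n_modes)] + ["residual.tsv"],
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return out_dir


def load_decomposition(in_dir: str | Path) -> IMFDecomposition:
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    imfs = [read_signal(in_dir / f).values for f in manifest["files"][:-1]]
    residual = read_signal(in_dir / manifest["files"][-1]).values
    return IMFDecomposition(
        imfs=imfs, residual=residual,
        source_rate=float(manifest["rate"]), source_labels=list(manifest["labels"]),
    )
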