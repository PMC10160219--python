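"""Reading and writing temporal signals and scale-space matrices.

Signals: one-column (value) or two-column (time, value) delimited text
with an optional header line, uniform sampling required; or WAV audio
(first channel, normalized to [-1, 1]).  Matrices: delimited text with a
'#'-prefixed header comment carrying the layout as JSON for provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .cascade import ScaleSpaceArray
from .layout import ScaleLayout

__all__ = ["read_signal", "write_signal", "write_matrix", "read_matrix"]


def _detect_delimiter(line: str) -> str | None:
    return "," if ("," in line and "\t" not in line) else None


def read_signal(path) -> tuple[np.ndarray, float]:
    """Load a 1-D signal; returns (values, sample_rate).

    sample_rate is samples per unit of the time column (1.0 for
    one-column files), or the WAV frame rate.
    """
    path = Path(path)
    if path.suffix.lower() == ".wav":
        from scipy.io import wavfile

        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data[:, 0]
        if np.issubdtype(data.dtype, np.integer):
            data = data.astype(float) / float(np.iinfo(data.dtype).max)
        return data.astype(float), float(rate)

    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty signal file")
    delim = _detect_delimiter(lines[0])
    first = lines[0].split(delim)
    try:
        [float(x) for x in first]
        start = 0
    except ValueError:
        start = 1  # header row
    rows = [ln.split(delim) for ln in lines[start:]]
    arr = np.asarray([[float(x) for x in r] for r in rows])
    if arr.ndim != 2 or arr.shape[1] not in (1, 2):
        raise ValueError(f"{path}: expected one or two columns")
    if arr.shape[1] == 1:
        return arr[:, 0], 1.0
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    rate = 1.0 / dt[0] if dt.size else 1.0
    return v, float(rate)


def write_signal(path, values, times=None) -> None:
    values = np.asarray(values, float)
    if times is None:
        np.savetxt(path, values, fmt="%.17g")
    else:
        np.savetxt(path, np.column_stack([times, values]), fmt="%.17g", delimiter="\t")


def write_matrix(path, ss: ScaleSpaceArray) -> None:
    """Write a time x scale matrix: '#' layout JSON, tau header row, then
    one row per sample (first column the sample index)."""
    header = "layout " + ss.layout.to_json()
    cols = "\t".join(["t"] + [f"tau={t:.17g}" for t in ss.layout.tau_levels])
    data = np.column_stack([np.arange(ss.n_samples), ss.values])
    np.savetxt(
        path, data, fmt="%.17g", delimiter="\t", header=header + "\n" + cols, comments="# "
    )


def read_matrix(path) -> ScaleSpaceArray:
    layout = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "layout" in line:
                layout = ScaleLayout.from_json(line.split("layout", 1)[1].strip())
                break
    if layout is None:
        raise ValueError(f"{path}: missing layout header")
    data = np.loadtxt(path, delimiter="\t")
    return ScaleSpaceArray(values=data[:, 1:], layout=layout)
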