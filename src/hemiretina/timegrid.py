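"""Canonical epoch time grid.

Epochs run from -100 ms (pre-stimulus baseline) to 600 ms post-stimulus at
512 Hz; every latency in the package lives on this sample grid. Window
endpoints given in (possibly fractional) milliseconds are rounded to the
nearest sample, and window means use inclusive endpoints.
"""

from __future__ import annotations

import numpy as np

SRATE_HZ = 512
T0_MS = -100.0
TMAX_MS = 600.0

#: Samples per epoch: round((600 - (-100))/1000 * 512) + 1.
N_SAMPLES = int(round((TMAX_MS - T0_MS) / 1000.0 * SRATE_HZ)) + 1

DT_MS = 1000.0 / SRATE_HZ


def times_ms(n_samples: int = N_SAMPLES, t0_ms: float = T0_MS, srate_hz: float = SRATE_HZ) -> np.ndarray:
    """Strictly increasing time axis in ms."""
    return t0_ms + np.arange(n_samples) * (1000.0 / srate_hz)


def sample_index(t_ms: float, t0_ms: float = T0_MS, srate_hz: float = SRATE_HZ) -> int:
    """Nearest-sample index for a time in ms."""
    return int(round((t_ms - t0_ms) * srate_hz / 1000.0))


def window_slice(
    t_start_ms: float,
    t_end_ms: float,
    n_samples: int = N_SAMPLES,
    t0_ms: float = T0_MS,
    srate_hz: float = SRATE_HZ,
) -> slice:
    """Inclusive sample slice covering [t_start, t_end] ms on the grid."""
    if t_end_ms < t_start_ms:
        raise ValueError("window end precedes window start")
    i0 = sample_index(t_start_ms, t0_ms, srate_hz)
    i1 = sample_index(t_end_ms, t0_ms, srate_hz)
    if i0 < 0 or i1 >= n_samples:
        raise ValueError(
            f"window [{t_start_ms}, {t_end_ms}] ms outside epoch support "
            f"[{t0_ms}, {t0_ms + (n_samples - 1) * 1000.0 / srate_hz}] ms"
        )
    return slice(i0, i1 + 1)


def window_mean_values(
    values: np.ndarray,
    t_start_ms: float,
    t_end_ms: float,
    t0_ms: float = T0_MS,
    srate_hz: float = SRATE_HZ,
    axis: int = -1,
) -> np.ndarray | float:
    """Arithmetic mean of samples whose times fall in [t_start, t_end] ms."""
    values = np.asarray(values, dtype=float)
    sl = window_slice(t_start_ms, t_end_ms, values.shape[axis], t0_ms, srate_hz)
    idx = [slice(None)] * values.ndim
    idx[axis] = sl
    out = values[tuple(idx)].mean(axis=axis)
    return float(out) if np.ndim(out) == 0 else out
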