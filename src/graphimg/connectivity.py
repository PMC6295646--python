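"""Phase-lag-index (PLI) functional connectivity.

Builds a weighted, undirected brain network from a multichannel
recording: each channel (sensor) is a node and the edge weight between
two nodes is the PLI of their instantaneous phases,

    PLI = | < sign(dphi(t_k)) >_k |

where dphi is the phase difference wrapped to (-pi, pi], sign is the
mathematical signum (sign(0) = 0), < > is the time average and | | the
absolute value.  PLI is 0 when there is no consistent nonzero phase
lead/lag (including identical signals and pure zero-lag coupling) and 1
when one signal consistently leads the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

__all__ = [
    "Recording",
    "PhaseMatrix",
    "ConnectivityGraph",
    "band_filter",
    "instantaneous_phase",
    "pli_pair",
    "connectivity_matrix",
    "wrap_phase",
]


@dataclass
class Recording:
    """Multichannel time series: ``samples`` is channels x time points."""

    channel_ids: list[str]
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) matrix")
        n_ch, n_t = self.samples.shape
        if len(self.channel_ids) != n_ch:
            raise ValueError("channel_ids length must match the number of rows")
        if n_ch < 2:
            raise ValueError("a recording needs at least 2 channels")
        if n_t < 2:
            raise ValueError("a recording needs at least 2 time points")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class PhaseMatrix:
    """Instantaneous phases (radians in (-pi, pi]), channels x time."""

    channel_ids: list[str]
    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2 or len(self.channel_ids) != self.phases.shape[0]:
            raise ValueError("phases must be channels x time with matching ids")
        if not np.all(np.isfinite(self.phases)):
            raise ValueError("phases contain non-finite values")


@dataclass
class ConnectivityGraph:
    """Symmetric weighted adjacency over named nodes; weights in [0, 1]."""

    node_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.node_ids)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be a square |V| x |V| matrix")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights contain non-finite values")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diagonal(self.weights) != 0):
            raise ValueError("diagonal must be exactly 0")
        off = self.weights[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def wrap_phase(delta: np.ndarray) -> np.ndarray:
    """Map angles to the interval (-pi, pi]."""
    wrapped = np.mod(np.asarray(delta, dtype=float) + np.pi, 2 * np.pi) - np.pi
    # np.mod puts exact -pi at the open end; fold it onto +pi
    if np.ndim(wrapped) == 0:
        return np.pi if wrapped == -np.pi else wrapped
    wrapped[wrapped == -np.pi] = np.pi
    return wrapped


def band_filter(rec: Recording, low_hz: float, high_hz: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    ``low_hz == 0`` degrades to a low-pass filter.
    """
    nyq = rec.sampling_rate / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for sampling rate "
            f"{rec.sampling_rate} Hz (need 0 <= low < high < {nyq})"
        )
    if low_hz == 0:
        sos = butter(order, high_hz, btype="lowpass", fs=rec.sampling_rate, output="sos")
    else:
        sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, rec.samples, axis=1)
    return Recording(list(rec.channel_ids), filtered, rec.sampling_rate)


def instantaneous_phase(rec: Recording) -> PhaseMatrix:
    """Analytic-signal (Hilbert-transform) phase of each channel.

    Constant channels have no meaningful phase; they are kept (phase of
    the numerical analytic signal) but flagged with a warning.
    """
    flat = np.where(np.ptp(rec.samples, axis=1) == 0)[0]
    if flat.size:
        ids = [rec.channel_ids[i] for i in flat]
        warnings.warn(f"constant (zero-variance) channels, phases ill-defined: {ids}")
    analytic = hilbert(rec.samples, axis=1)
    phases = wrap_phase(np.angle(analytic))
    return PhaseMatrix(list(rec.channel_ids), phases)


def pli_pair(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """PLI of two phase time series: |mean_k sign(wrap(a_k - b_k))|."""
    a = np.asarray(phase_a, dtype=float).ravel()
    b = np.asarray(phase_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"phase rows differ in length ({a.size} vs {b.size})")
    if a.size < 1:
        raise ValueError("phase rows must contain at least one sample")
    return float(abs(np.mean(np.sign(wrap_phase(a - b)))))


def _pli_block(phases: np.ndarray) -> np.ndarray:
    """Dense PLI matrix for one segment of phases (channels x time)."""
    n = phases.shape[0]
    w = np.zeros((n, n))
    for i in range(n - 1):
        delta = wrap_phase(phases[i][None, :] - phases[i + 1 :])
        w[i, i + 1 :] = np.abs(np.mean(np.sign(delta), axis=1))
    return w + w.T


def connectivity_matrix(ph: PhaseMatrix, epoch_samples: int | None = None) -> ConnectivityGraph:
    """PLI connectivity graph from a phase matrix.

    By default one PLI value is computed over the whole recording (one
    network per subject).  With ``epoch_samples`` set, PLI is computed on
    consecutive non-overlapping epochs of that length and averaged.
    """
    phases = ph.phases
    if phases.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if epoch_samples is None:
        weights = _pli_block(phases)
    else:
        if epoch_samples < 1:
            raise ValueError("epoch_samples must be positive")
        n_epochs = phases.shape[1] // epoch_samples
        if n_epochs < 1:
            raise ValueError("recording shorter than one epoch")
        blocks = [
            _pli_block(phases[:, e * epoch_samples : (e + 1) * epoch_samples])
            for e in range(n_epochs)
        ]
        weights = np.mean(blocks, axis=0)
    np.fill_diagonal(weights, 0.0)
    return ConnectivityGraph(list(ph.channel_ids), np.clip(weights, 0.0, 1.0))
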