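"""Synthetic signals, graphs and cohorts with controllable class structure.

The generator emulates the two things the pipeline consumes:

* multichannel oscillatory recordings in which channels are organised in
  coupled blocks — each block shares a common sinusoidal oscillator (with
  its own random initial phase and a small random frequency offset) and
  each channel mixes that oscillator, shifted by a per-channel phase
  lag, with independent Gaussian noise;
* weighted, symmetric, dense connectivity graphs with planted community
  (block) structure.

Class differences are encoded in the coupling topology (number of
blocks, coupling strength), never in amplitude, because the phase lag
index is amplitude-insensitive: a discriminative signal can only reach
the classifier through phase relationships.  Two details matter for a
faithful PLI signal: channels within a block must have distinct phase
lags (PLI of exactly zero-lag coupling is 0 by construction), and
different blocks must have slightly different frequencies (two blocks
locked to one common frequency would show a constant phase difference,
i.e. spuriously perfect PLI between blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import derive_rng
from .connectivity import ConnectivityGraph, Recording

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "simulate_coupled_signals",
    "simulate_modular_graph",
    "simulate_two_class_cohort",
    "block_coupling_spec",
    "default_cohort_spec",
]


@dataclass
class CouplingSpec:
    """How one class's recordings are generated.

    groups
        Partition of channel indices into coupled blocks (covers every
        channel exactly once).
    coupling_strength
        Share of each channel's signal drawn from its block's common
        oscillator, in [0, 1]; the rest is independent noise.
    phase_lags
        Per-channel phase shift (radians) applied to the block
        oscillator; within-block lag differences are what PLI detects.
    freq_jitter_hz
        Half-width of the band of per-block frequency offsets around
        ``base_freq_hz``.  Blocks are spread evenly across the band
        (with a small random component) so that every pair of blocks
        differs in frequency and their phase difference drifts instead
        of locking; a shared frequency would make two nominally
        independent blocks show spuriously perfect PLI.
    """

    n_channels: int
    groups: list[list[int]]
    coupling_strength: float
    phase_lags: np.ndarray
    noise_sd: float = 1.0
    base_freq_hz: float = 10.0
    freq_jitter_hz: float = 1.0
    sampling_rate_hz: float = 250.0

    def __post_init__(self) -> None:
        self.phase_lags = np.asarray(self.phase_lags, dtype=float)
        flat = sorted(i for g in self.groups for i in g)
        if flat != list(range(self.n_channels)):
            raise ValueError("groups must partition channels 0..n_channels-1 exactly once")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must be in [0, 1]")
        if self.phase_lags.shape != (self.n_channels,):
            raise ValueError("phase_lags must have one entry per channel")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class CohortSpec:
    """Two-class cohort: n_per_class recordings from each CouplingSpec."""

    n_per_class: int
    class_a: CouplingSpec
    class_b: CouplingSpec
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be positive")
        if self.class_a.n_channels != self.class_b.n_channels:
            raise ValueError("both classes must share n_channels")


def simulate_coupled_signals(spec: CouplingSpec, n_samples: int,
                             rng: np.random.Generator) -> Recording:
    """One recording: block oscillators mixed with independent noise."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    t = np.arange(n_samples) / spec.sampling_rate_hz
    samples = np.empty((spec.n_channels, n_samples))
    cs = spec.coupling_strength
    n_blocks = len(spec.groups)
    # evenly spaced block frequencies (plus a small random component)
    # guarantee pairwise frequency separation, hence phase drift,
    # between blocks
    offsets = (np.linspace(-spec.freq_jitter_hz, spec.freq_jitter_hz, n_blocks)
               if n_blocks > 1 else np.zeros(1))
    spacing = (offsets[1] - offsets[0]) if n_blocks > 1 else spec.freq_jitter_hz
    for b, group in enumerate(spec.groups):
        f = (spec.base_freq_hz + offsets[b]
             + rng.uniform(-0.1, 0.1) * spacing)
        phi0 = rng.uniform(0, 2 * np.pi)
        carrier_phase = 2 * np.pi * f * t + phi0
        for ch in group:
            osc = np.cos(carrier_phase + spec.phase_lags[ch])
            noise = rng.normal(0.0, spec.noise_sd, size=n_samples)
            samples[ch] = cs * osc + (1 - cs) * noise
    ids = [f"ch{i:03d}" for i in range(spec.n_channels)]
    return Recording(ids, samples, spec.sampling_rate_hz)


def simulate_modular_graph(n_nodes: int, n_blocks: int, w_in: float, w_out: float,
                           jitter: float, rng: np.random.Generator) -> ConnectivityGraph:
    """Planted-block weighted graph: ~w_in within blocks, ~w_out between.

    Symmetric, zero diagonal, weights clipped to [0, 1]; ``jitter`` is
    the half-width of uniform noise added to every edge weight.
    """
    if not (0 <= w_in <= 1 and 0 <= w_out <= 1):
        raise ValueError("w_in and w_out must be in [0, 1]")
    if n_blocks > n_nodes or n_blocks < 1:
        raise ValueError("need 1 <= n_blocks <= n_nodes")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    block = np.array_split(np.arange(n_nodes), n_blocks)
    membership = np.empty(n_nodes, dtype=int)
    for b, idx in enumerate(block):
        membership[idx] = b
    same = membership[:, None] == membership[None, :]
    w = np.where(same, w_in, w_out).astype(float)
    if jitter > 0:
        noise = rng.uniform(-jitter, jitter, size=(n_nodes, n_nodes))
        w = w + np.triu(noise, 1) + np.triu(noise, 1).T
    w = np.clip(w, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    return ConnectivityGraph(ids, w)


def simulate_two_class_cohort(spec: CohortSpec, n_samples: int
                              ) -> tuple[list[Recording], np.ndarray, list[str]]:
    """n_per_class recordings per class; labels 0 (class_a) and 1 (class_b)."""
    recordings: list[Recording] = []
    labels: list[int] = []
    subject_ids: list[str] = []
    for label, cls in ((0, spec.class_a), (1, spec.class_b)):
        for j in range(spec.n_per_class):
            rng = derive_rng(spec.seed, f"subject-{label}-{j}")
            recordings.append(simulate_coupled_signals(cls, n_samples, rng))
            labels.append(label)
            subject_ids.append(f"s{label}{j:02d}")
    return recordings, np.asarray(labels), subject_ids


def block_coupling_spec(n_channels: int, n_blocks: int, coupling_strength: float = 0.85,
                        seed: int = 0, base_freq_hz: float = 10.0,
                        sampling_rate_hz: float = 250.0) -> CouplingSpec:
    """Convenience builder: equal blocks, per-channel lags spread over (0, pi/2]."""
    groups = [list(g) for g in np.array_split(np.arange(n_channels), n_blocks)]
    rng = derive_rng(seed, "phase-lags")
    lags = np.empty(n_channels)
    for g in groups:
        # distinct, ordered lags within each block so every pair has a
        # consistent nonzero lead/lag that PLI can detect
        lags[g] = np.sort(rng.uniform(0.05, np.pi / 2, size=len(g)))
    return CouplingSpec(
        n_channels=n_channels,
        groups=groups,
        coupling_strength=coupling_strength,
        phase_lags=lags,
        base_freq_hz=base_freq_hz,
        sampling_rate_hz=sampling_rate_hz,
    )


def default_cohort_spec(n_channels: int = 40, n_per_class: int = 20,
                        seed: int = 0) -> CohortSpec:
    """Strongly separated two-class cohort: 2-block vs 4-block coupling."""
    return CohortSpec(
        n_per_class=n_per_class,
        class_a=block_coupling_spec(n_channels, 2, coupling_strength=0.85, seed=seed),
        class_b=block_coupling_spec(n_channels, 4, coupling_strength=0.85, seed=seed + 1),
        seed=seed,
    )
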