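"""Phase-locking value connectivity per event, band and time segment.

Instantaneous phase comes from the analytic signal of the full 7-s
band-limited epoch (never per 250-sample segment, to avoid Hilbert edge
distortion inside the short windows); the PLV between two channels over a
segment is the modulus of the time-averaged unit phasor of their phase
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .ingest import (
    SEGMENT_LENGTH,
    BandDefinition,
    Epoch,
    SegmentWindow,
    segment_windows,
)

__all__ = ["PLVTensor", "instantaneous_phase", "plv", "plv_tensor", "EDGE_SAMPLES"]

#: Samples at each end of an epoch whose analytic-signal phase is
#: edge-affected; carried as metadata, segments are not trimmed.
EDGE_SAMPLES = 125


@dataclass
class PLVTensor:
    """Synchrony values of shape (events, segments, pairs), all in [0, 1].

    ``pair_index`` lists (i, j) with i < j, lexicographic in the channel
    order of the source recording, and is persisted with every output.
    """

    band: BandDefinition
    values: np.ndarray
    pair_index: list[tuple[int, int]]
    channels: list[str]
    event_ids: list[str]
    subjects: list[str]
    edge_samples: int = EDGE_SAMPLES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_pairs = len(self.pair_index)
        if self.values.ndim != 3 or self.values.shape[2] != n_pairs:
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n_pairs} pairs"
            )
        if ((self.values < 0) | (self.values > 1.0 + 1e-12)).any():
            raise ValueError("PLV values must lie in [0, 1]")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]


def instantaneous_phase(x: np.ndarray) -> np.ndarray:
    """Analytic-signal phase in (-pi, pi] along the last axis."""
    x = np.asarray(x, dtype=float)
    if not x.any():
        raise ValueError("instantaneous phase of an all-zero signal is undefined")
    return np.angle(hilbert(x, axis=-1))


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """|mean exp(i (phi_a - phi_b))|; 1 = perfect locking, 0 = none."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError(
            f"phase series lengths differ: {phase_a.shape} vs {phase_b.shape}"
        )
    return float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))


def pair_list(n_channels: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j), i < j — the pair order used everywhere."""
    return list(combinations(range(n_channels), 2))


def _segment_plv(phases: np.ndarray, windows: Sequence[SegmentWindow],
                 pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """(segments, pairs) PLV matrix from a (channels, samples) phase array."""
    phasor = np.exp(1j * phases)
    ii = np.fromiter((p[0] for p in pairs), int)
    jj = np.fromiter((p[1] for p in pairs), int)
    out = np.empty((len(windows), len(pairs)))
    for s, w in enumerate(windows):
        seg = phasor[:, w.start : w.end]
        cross = seg[ii] * np.conj(seg[jj])
        out[s] = np.abs(cross.mean(axis=1))
    return out


def plv_tensor(epochs: Sequence[Epoch]) -> PLVTensor:
    """PLV for every (event, segment, channel pair) of one band.

    All epochs must share channel set and band; phases are computed on the
    full epoch and only then cut into the nine 250-sample segments.
    """
    if not epochs:
        raise ValueError("no epochs given")
    ref = epochs[0]
    bad = [
        k for k, ep in enumerate(epochs)
        if ep.channels != ref.channels or ep.band != ref.band
    ]
    if bad:
        raise ValueError(
            f"epochs {bad} differ in channels or band from epoch 0"
        )
    pairs = pair_list(len(ref.channels))
    windows = segment_windows(ref.data.shape[1])
    values = np.empty((len(epochs), len(windows), len(pairs)))
    event_ids, subjects = [], []
    for k, ep in enumerate(epochs):
        phases = instantaneous_phase(ep.data)
        values[k] = _segment_plv(phases, windows, pairs)
        subjects.append(ep.subject)
        if ep.event is not None:
            event_ids.append(f"{ep.subject}-t{ep.event.click_time:.3f}")
        elif ep.baseline_start is not None:
            event_ids.append(f"{ep.subject}-baseline-{ep.baseline_start:.3f}")
        else:
            event_ids.append(f"{ep.subject}-epoch{k}")
    return PLVTensor(
        band=ref.band,
        values=np.clip(values, 0.0, 1.0),
        pair_index=pairs,
        channels=list(ref.channels),
        event_ids=event_ids,
        subjects=subjects,
    )
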