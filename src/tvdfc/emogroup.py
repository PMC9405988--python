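"""Pooling of self-reported emotion labels into balanced groups.

Labels are clustered by the proximity of their mean positions in
valence-arousal space (complete-linkage agglomeration to k clusters),
then a greedy pass moves boundary labels from oversized to the nearest
undersized cluster until every group's instance count is within the
balance tolerance of the even share, or no improving move remains. The
procedure is deterministic for a fixed input ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .ingest import EventRecord

__all__ = ["EmotionGroup", "label_va_means", "group_labels", "assign_groups"]


@dataclass
class EmotionGroup:
    """One pooled emotion group with its V-A centroid and instance count."""

    group_id: int
    labels: list[str]
    n_instances: int
    mean_valence: float
    mean_arousal: float


def label_va_means(
    events: Sequence[EventRecord],
) -> dict[str, tuple[float, float]]:
    """Per-label arithmetic mean of (valence, arousal) over its events."""
    if not events:
        raise ValueError("no events given")
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for ev in events:
        acc = sums.setdefault(ev.emotion, np.zeros(2))
        acc += (ev.valence, ev.arousal)
        counts[ev.emotion] = counts.get(ev.emotion, 0) + 1
    return {
        lab: (float(s[0] / counts[lab]), float(s[1] / counts[lab]))
        for lab, s in sums.items()
    }


def label_counts(events: Sequence[EventRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ev in events:
        counts[ev.emotion] = counts.get(ev.emotion, 0) + 1
    return counts


def _rebalance(
    assignment: np.ndarray,
    positions: np.ndarray,
    counts: np.ndarray,
    k: int,
    tolerance: float,
) -> np.ndarray:
    """Greedy moves of boundary labels from oversized to undersized groups."""
    assignment = assignment.copy()
    target = counts.sum() / k
    hi = (1 + tolerance) * target

    def group_sizes() -> np.ndarray:
        return np.array(
            [counts[assignment == g].sum() for g in range(k)], dtype=float
        )

    def centroid(g: int) -> np.ndarray:
        members = assignment == g
        w = counts[members]
        return (positions[members] * w[:, None]).sum(axis=0) / w.sum()

    while True:
        sizes = group_sizes()
        over = [g for g in range(k) if sizes[g] > hi]
        # receivers: anything below the even share (not only below lo)
        under = [g for g in range(k) if sizes[g] < target]
        if not over or not under:
            return assignment
        best: tuple[float, int, int] | None = None
        for g in over:
            members = np.flatnonzero(assignment == g)
            if members.size <= 1:
                continue  # never empty a group
            for u in under:
                c = centroid(u)
                for m in members:
                    d = float(np.linalg.norm(positions[m] - c))
                    cand = (d, int(m), u)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            return assignment
        d, m, u = best
        g = assignment[m]
        new_sizes = sizes.copy()
        new_sizes[g] -= counts[m]
        new_sizes[u] += counts[m]
        # accept only moves that reduce total imbalance
        imbalance = lambda s: np.abs(s - target).sum()
        if imbalance(new_sizes) >= imbalance(sizes):
            return assignment
        assignment[m] = u


def group_labels(
    label_means: Mapping[str, tuple[float, float]],
    counts: Mapping[str, int],
    k: int = 8,
    balance_tolerance: float = 0.25,
) -> list[EmotionGroup]:
    """Cluster labels on V-A means into k groups under a size-balance pass.

    Group ids are assigned 1..k by ascending mean valence of the group
    centroid (ties broken by mean arousal).
    """
    labels = list(label_means)
    if len(labels) < k:
        raise ValueError(f"{len(labels)} labels cannot form {k} groups")
    missing = [lab for lab in labels if lab not in counts]
    if missing:
        raise ValueError(f"labels without instance counts: {missing}")
    positions = np.array([label_means[lab] for lab in labels], dtype=float)
    n = np.array([counts[lab] for lab in labels], dtype=float)

    if len(labels) == k:
        assignment = np.arange(k)
    else:
        d = pdist(positions)
        if np.all(d == 0):
            # degenerate geometry: any partition is as good; balancing alone
            # decides, starting from a round-robin split
            assignment = np.arange(len(labels)) % k
        else:
            z = linkage(d, method="complete")
            assignment = fcluster(z, t=k, criterion="maxclust") - 1
        assignment = _rebalance(assignment, positions, n, k, balance_tolerance)

    order = sorted(
        range(k),
        key=lambda g: (
            float(np.mean(positions[assignment == g, 0])),
            float(np.mean(positions[assignment == g, 1])),
        ),
    )
    groups = []
    for new_id, g in enumerate(order, start=1):
        members = [labels[i] for i in np.flatnonzero(assignment == g)]
        w = np.array([counts[m] for m in members], dtype=float)
        pos = np.array([label_means[m] for m in members], dtype=float)
        cent = (pos * w[:, None]).sum(axis=0) / w.sum()
        groups.append(
            EmotionGroup(
                group_id=new_id,
                labels=members,
                n_instances=int(w.sum()),
                mean_valence=float(cent[0]),
                mean_arousal=float(cent[1]),
            )
        )
    return groups


def assign_groups(
    events: Sequence[EventRecord],
    k: int = 8,
    balance_tolerance: float = 0.25,
) -> tuple[list[EmotionGroup], dict[str, int]]:
    """Group the labels of an event set; returns groups and label->id map."""
    means = label_va_means(events)
    groups = group_labels(means, label_counts(events), k, balance_tolerance)
    mapping = {lab: g.group_id for g in groups for lab in g.labels}
    return groups, mapping


def write_group_table(
    groups: Sequence[EmotionGroup], path: str | Path
) -> pd.DataFrame:
    rows = [
        {"label": lab, "group_id": g.group_id, "n_instances": g.n_instances}
        for g in groups
        for lab in g.labels
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
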