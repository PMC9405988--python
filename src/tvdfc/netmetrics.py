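"""Network-level statistics: connectivity vectors, inter-group distances,
band selection against the global threshold Gcst, temporal variability of
dynamic functional connectivity (tvDFC), and eigenvector-centrality hubs
with an Erdős–Rényi random-graph null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ConnectivityVector",
    "BandTestResult",
    "HubResult",
    "connectivity_vector",
    "group_pair_distances",
    "band_average_distances",
    "global_threshold",
    "band_selection_test",
    "paired_band_comparison",
    "temporal_variability",
    "eigenvector_centrality",
    "hub_significance",
]


@dataclass
class ConnectivityVector:
    """Weighted multi-hot vector over channel pairs for one network.

    Entries hold the group-mean PLV of significant pairs and exactly zero
    elsewhere.
    """

    band: str
    segment: int
    group: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if ((self.weights < 0) | (self.weights > 1.0 + 1e-12)).any():
            raise ValueError("connectivity weights must lie in [0, 1]")


@dataclass
class BandTestResult:
    """One-sample t of a band's 28 pooled distances against Gcst."""

    band: str
    t: float
    df: int
    p: float  # Bonferroni-corrected over bands
    cohens_d: float
    selected: bool


@dataclass
class HubResult:
    """Eigenvector-centrality hub decision for one channel."""

    channel: str
    centrality: float
    null_percentile: float
    is_hub: bool
    n_random: int
    seed: int


def connectivity_vector(
    mask: np.ndarray,
    group_mean_plv: np.ndarray,
    band: str = "",
    segment: int = -1,
    group: int = -1,
) -> ConnectivityVector:
    """Group-mean PLV where significant, zero elsewhere."""
    mask = np.asarray(mask, dtype=bool)
    w = np.asarray(group_mean_plv, dtype=float)
    if mask.shape != w.shape:
        raise ValueError(
            f"mask ({mask.shape}) and mean PLV ({w.shape}) pair indices differ"
        )
    return ConnectivityVector(band, segment, group, np.where(mask, w, 0.0))


def group_pair_distances(
    vectors: Mapping[int, ConnectivityVector] | Mapping[int, np.ndarray],
) -> dict[tuple[int, int], float]:
    """Euclidean distance for every unordered pair of group vectors."""
    arrays = {
        g: (v.weights if isinstance(v, ConnectivityVector) else np.asarray(v))
        for g, v in vectors.items()
    }
    lengths = {a.shape for a in arrays.values()}
    if len(lengths) > 1:
        raise ValueError(f"connectivity vectors differ in length: {lengths}")
    return {
        (a, b): float(np.linalg.norm(arrays[a] - arrays[b]))
        for a, b in combinations(sorted(arrays), 2)
    }


def band_average_distances(
    per_segment: Mapping[int, Mapping[tuple[int, int], float]],
    n_segments: int = 9,
) -> dict[tuple[int, int], float]:
    """Segment-pooled mean distance per group pair (28 values for 8 groups)."""
    missing = set(range(n_segments)) - set(per_segment)
    if missing:
        raise ValueError(f"missing segments: {sorted(missing)}")
    pairs = set().union(*(d.keys() for d in per_segment.values()))
    return {
        p: float(np.mean([per_segment[s][p] for s in range(n_segments)]))
        for p in sorted(pairs)
    }


def global_threshold(
    band_averages: Mapping[str, Mapping[tuple[int, int], float]],
) -> float:
    """Gcst: grand mean of the pooled distances over all bands and pairs."""
    values = [v for d in band_averages.values() for v in d.values()]
    return float(np.mean(values))


def band_selection_test(
    averages: Sequence[float],
    gcst: float,
    band: str = "",
    n_bands: int = 6,
    alpha: float = 0.05,
) -> BandTestResult:
    """One-sample t-test (mean > Gcst) with Bonferroni correction over bands.

    Cohen's d is (mean - Gcst) / sd.
    """
    x = np.asarray(list(averages), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 pooled distances")
    sd = x.std(ddof=1)
    if sd == 0:
        if x.mean() == gcst:
            # exactly at the threshold with no spread: null case, t = d = 0
            return BandTestResult(band, 0.0, x.size - 1, 1.0, 0.0, False)
        raise ValueError("zero variance among pooled distances")
    res = stats.ttest_1samp(x, popmean=gcst, alternative="greater")
    p = min(1.0, float(res.pvalue) * n_bands)
    d = float((x.mean() - gcst) / sd)
    return BandTestResult(
        band=band,
        t=float(res.statistic),
        df=x.size - 1,
        p=p,
        cohens_d=d,
        selected=p < alpha,
    )


def paired_band_comparison(
    averages_a: Sequence[float], averages_b: Sequence[float]
) -> dict:
    """Paired t-test of two bands' pooled distances, matched by group pair."""
    a = np.asarray(list(averages_a), dtype=float)
    b = np.asarray(list(averages_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("band distance vectors differ in length")
    diff = a - b
    n = a.size
    if not diff.any():
        return {"t": 0.0, "df": n - 1, "p": 1.0, "ci95": (0.0, 0.0),
                "cohens_d": 0.0}
    res = stats.ttest_rel(a, b)
    se = diff.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, df=n - 1)
    return {
        "t": float(res.statistic),
        "df": n - 1,
        "p": float(res.pvalue),
        "ci95": (
            float(diff.mean() - tcrit * se),
            float(diff.mean() + tcrit * se),
        ),
        "cohens_d": float(diff.mean() / diff.std(ddof=1)),
    }


def temporal_variability(segment_vectors: np.ndarray) -> float:
    """Mean Euclidean distance between consecutive segment vectors.

    For the nine-segment epochs of the pipeline this averages exactly
    eight consecutive-segment dissimilarities.
    """
    x = np.asarray(segment_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 segment vectors")
    return float(np.mean(np.linalg.norm(np.diff(x, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# Hubs


def _principal_scores(adj: np.ndarray) -> np.ndarray:
    """Perron eigenvector of a connected non-negative adjacency by shifted
    power iteration (the shift handles bipartite spectra)."""
    n = adj.shape[0]
    if n == 1:
        return np.ones(1)
    shift = adj.sum(axis=1).max()
    m = adj + shift * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(10_000):
        w = m @ v
        w /= np.linalg.norm(w)
        if np.linalg.norm(w - v) < 1e-13:
            return w
        v = w
    return v


def eigenvector_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Principal-eigenvector node scores, unit Euclidean norm.

    Computed on the largest connected component (by node count, ties to
    the component containing the lowest-indexed node); other nodes score
    zero. Isolated-only graphs are rejected.
    """
    adj = np.asarray(adjacency, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if (adj < 0).any():
        raise ValueError("adjacency must be non-negative")
    if not np.allclose(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if not (adj - np.diag(np.diag(adj))).any():
        raise ValueError("graph has no edges")
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    comp = int(np.argmax(sizes))
    members = np.flatnonzero(labels == comp)
    scores = np.zeros(adj.shape[0])
    sub = adj[np.ix_(members, members)]
    scores[members] = np.abs(_principal_scores(sub))
    return scores / np.linalg.norm(scores)


def _random_graph_adjacency(
    rng: np.random.Generator, n: int, p: float
) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    edges = rng.random(iu[0].size) < p
    adj = np.zeros((n, n))
    adj[iu[0][edges], iu[1][edges]] = 1.0
    return adj + adj.T


def hub_significance(
    adjacency: np.ndarray,
    channels: Sequence[str] | None = None,
    n_random: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[HubResult]:
    """Hubs: channels whose centrality exceeds the (1-alpha) quantile of the
    pooled centrality distribution of Erdős–Rényi graphs with the observed
    connection probability.

    The null pools node centralities across all random graphs, reading
    "less than a 5% chance of being randomly selected" as exceedance of
    that pooled distribution. (An alternative, stricter reading would
    compare against the null distribution of each graph's maximum
    centrality; it is not used here.)
    """
    adj = np.asarray(adjacency, dtype=float)
    n = adj.shape[0]
    if channels is None:
        channels = [f"ch{i}" for i in range(n)]
    observed = eigenvector_centrality(adj)
    off = adj - np.diag(np.diag(adj))
    density = float((off > 0).sum() / (n * (n - 1)))
    if density <= 0.0 or density >= 1.0:
        raise ValueError(
            f"degenerate connection probability {density:g}: the random-graph "
            "null is undefined"
        )
    rng = np.random.default_rng(seed)
    null = np.empty((n_random, n))
    for r in range(n_random):
        g = _random_graph_adjacency(rng, n, density)
        while not (g.any()):
            g = _random_graph_adjacency(rng, n, density)
        null[r] = eigenvector_centrality(g)
    pooled = null.ravel()
    threshold = float(np.quantile(pooled, 1.0 - alpha))
    results = []
    for i, ch in enumerate(channels):
        pct = float(np.mean(pooled < observed[i]))
        results.append(
            HubResult(
                channel=ch,
                centrality=float(observed[i]),
                null_percentile=pct,
                is_hub=bool(observed[i] > threshold),
                n_random=n_random,
                seed=seed,
            )
        )
    return results


def hub_adjacency(
    masks: Sequence[np.ndarray],
    mean_plvs: Sequence[np.ndarray],
    pair_index: Sequence[tuple[int, int]],
    n_channels: int,
) -> np.ndarray:
    """Pool significant connections into one weighted channel adjacency.

    The union over the given (group, segment) networks keeps a pair if it
    is significant anywhere; its weight is the mean of the group-mean PLV
    over the networks in which it is significant.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    weights = [np.asarray(w, dtype=float) for w in mean_plvs]
    if len(masks) != len(weights) or not masks:
        raise ValueError("need matching, non-empty mask and weight lists")
    acc = np.zeros(len(pair_index))
    cnt = np.zeros(len(pair_index))
    for m, w in zip(masks, weights):
        acc += np.where(m, w, 0.0)
        cnt += m
    pooled = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    adj = np.zeros((n_channels, n_channels))
    for k, (i, j) in enumerate(pair_index):
        adj[i, j] = adj[j, i] = pooled[k]
    return adj
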