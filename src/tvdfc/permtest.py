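"""Max-statistic permutation test for significant connectivity changes.

Channel-pair PLV values of an emotion group's events are contrasted with
baseline epochs using a two-sample pooled-variance t statistic per pair.
Family-wise error over all pairs is controlled with the single-threshold
method: each permutation exchanges condition labels within subject (both
conditions come from the same subjects, with unequal counts) and records
the maximum |t| over pairs; a pair is significant when its adjusted
p-value — the add-one tail proportion of permutation maxima at or above
its observed |t| — falls below alpha. The critical value is the (c+1)th
largest permutation maximum with c = floor(alpha * N).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignificanceResult",
    "pair_tstat",
    "critical_index",
    "max_stat_test",
    "write_edge_list",
]


@dataclass
class SignificanceResult:
    """Per-pair statistics and FWER-adjusted decisions for one contrast."""

    t_obs: np.ndarray
    null_max: np.ndarray
    critical_value: float
    p_adj: np.ndarray
    mask: np.ndarray
    alpha: float
    n_perm: int
    seed: int
    band: str | None = None
    segment: int | None = None
    group: int | None = None

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


def pair_tstat(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sample pooled-variance t statistic of A versus B."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance: degenerate samples")
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def critical_index(alpha: float, n_perm: int) -> int:
    """Rank (1-based, from the top) of the critical permutation maximum."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_perm < 1:
        raise ValueError("need at least one permutation")
    return int(np.floor(alpha * n_perm)) + 1


def _tstat_matrix(x: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance t over pairs for many labelings.

    x: (n_obs, P) data; in_a: (n_perm, n_obs) boolean condition-A masks.
    Returns (n_perm, P).
    """
    in_a = in_a.astype(float)
    na = in_a.sum(axis=1, keepdims=True)
    nb = in_a.shape[1] - na
    sa = in_a @ x
    sb = x.sum(axis=0) - sa
    ssa = in_a @ (x * x)
    ssb = (x * x).sum(axis=0) - ssa
    ma, mb = sa / na, sb / nb
    var_a = (ssa - na * ma**2) / (na - 1)
    var_b = (ssb - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    sp2 = np.maximum(sp2, 1e-300)
    return (ma - mb) / np.sqrt(sp2 * (1 / na + 1 / nb))


def _within_subject_permutations(
    rng: np.random.Generator,
    subjects: np.ndarray,
    base_in_a: np.ndarray,
    n_perm: int,
) -> np.ndarray:
    """Condition-A masks for permutations exchanging labels within subject,
    preserving each subject's per-condition counts."""
    n_obs = subjects.size
    out = np.zeros((n_perm, n_obs), dtype=bool)
    rows = np.arange(n_perm)[:, None]
    for subj in np.unique(subjects):
        idx = np.flatnonzero(subjects == subj)
        k = int(base_in_a[idx].sum())
        # random k-subset per permutation via argsort of uniform keys
        keys = rng.random((n_perm, idx.size))
        chosen = idx[np.argsort(keys, axis=1)[:, :k]]
        out[rows, chosen] = True
    return out


def max_stat_test(
    plv_group: np.ndarray,
    plv_baseline: np.ndarray,
    subjects_group: Sequence[str],
    subjects_baseline: Sequence[str],
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
    band: str | None = None,
    segment: int | None = None,
    group: int | None = None,
) -> SignificanceResult:
    """Single-threshold max-|t| permutation test over all channel pairs.

    ``plv_group`` is (events, P), ``plv_baseline`` is (epochs, P); each
    observation carries a subject label and every subject must appear in
    both conditions (the relabeling is within-subject).
    """
    a = np.atleast_2d(np.asarray(plv_group, dtype=float))
    b = np.atleast_2d(np.asarray(plv_baseline, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("condition matrices disagree on the pair dimension")
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both conditions must be non-empty")
    sub_a = np.asarray(list(subjects_group))
    sub_b = np.asarray(list(subjects_baseline))
    if sub_a.size != a.shape[0] or sub_b.size != b.shape[0]:
        raise ValueError("subject labels do not match observation counts")
    only = set(sub_a) ^ set(sub_b)
    if only:
        raise ValueError(
            f"subjects present in only one condition: {sorted(only)}"
        )

    x = np.vstack([a, b])
    subjects = np.concatenate([sub_a, sub_b])
    base_in_a = np.zeros(x.shape[0], dtype=bool)
    base_in_a[: a.shape[0]] = True

    t_obs = np.abs(_tstat_matrix(x, base_in_a[None, :])[0])

    rng = np.random.default_rng(seed)
    perms = _within_subject_permutations(rng, subjects, base_in_a, n_perm)
    null_max = np.abs(_tstat_matrix(x, perms)).max(axis=1)

    p_adj = (1 + (null_max[:, None] >= t_obs[None, :]).sum(axis=0)) / (
        n_perm + 1
    )
    c = critical_index(alpha, n_perm)
    critical_value = float(np.sort(null_max)[::-1][c - 1])
    return SignificanceResult(
        t_obs=t_obs,
        null_max=null_max,
        critical_value=critical_value,
        p_adj=p_adj,
        mask=p_adj < alpha,
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
        band=band,
        segment=segment,
        group=group,
    )


def write_edge_list(
    result: SignificanceResult,
    pair_index: Sequence[tuple[int, int]],
    channels: Sequence[str],
    path: str | Path,
) -> pd.DataFrame:
    """Persist a contrast as a TSV edge list (one row per channel pair)."""
    df = pd.DataFrame(
        {
            "channel_a": [channels[i] for i, _ in pair_index],
            "channel_b": [channels[j] for _, j in pair_index],
            "t": result.t_obs,
            "p_adj": result.p_adj,
            "significant": result.mask,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
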