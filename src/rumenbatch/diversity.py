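"""OTU-table analytics: alpha diversity, Venn partitions, Bray-Curtis, PERMANOVA.

The alpha indices follow the Mothur definitions used throughout the rumen
16S literature:

* Shannon  ``H = -sum p_i ln p_i``
* Simpson dominance ``D = sum n_i (n_i - 1) / (N (N - 1))`` (small = diverse)
* Chao1    ``S_obs + F1^2 / (2 F2)`` with the bias-corrected form
  ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` when no doubletons exist
* ACE      abundance-based coverage estimator with rare cutoff 10
* Good's coverage ``1 - F1 / N``

Between-sample structure uses the Bray-Curtis dissimilarity
``d(x, y) = sum |x_i - y_i| / sum (x_i + y_i)`` and a permutation PERMANOVA
(Anderson's pseudo-F on the distance matrix, label permutations, p-value with
the +1 convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import InvalidInputError, UndefinedValueError

__all__ = [
    "AlphaDiversity", "PermanovaResult",
    "alpha_indices", "alpha_table", "otu_venn",
    "bray_curtis", "permanova", "rarefy",
]

ACE_RARE_CUTOFF = 10


@dataclass(frozen=True)
class AlphaDiversity:
    """Per-sample alpha-diversity summary."""

    observed_otus: int
    shannon: float
    simpson: float
    chao1: float
    ace: float
    goods_coverage: float


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _counts_array(counts: Sequence[int] | np.ndarray) -> np.ndarray:
    c = np.asarray(counts)
    if np.any(c < 0):
        raise InvalidInputError("counts must be non-negative")
    return c[c > 0].astype(float)


def _ace(c: np.ndarray, cutoff: int = ACE_RARE_CUTOFF) -> float:
    rare = c[c <= cutoff]
    s_abund = int((c > cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = float((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        # all rare species are singletons; fall back to the Chao1 estimate
        return _chao1(c)
    top = sum((rare == i).sum() * i * (i - 1) for i in range(1, cutoff + 1))
    gamma = max(s_rare / c_ace * top / (n_rare * (n_rare - 1.0)) - 1.0, 0.0) \
        if n_rare > 1 else 0.0
    return s_abund + s_rare / c_ace + f1 / c_ace * gamma


def _chao1(c: np.ndarray) -> float:
    s_obs = c.size
    f1 = float((c == 1).sum())
    f2 = float((c == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1.0) / 2.0


def alpha_indices(counts: Sequence[int] | np.ndarray) -> AlphaDiversity:
    """All six alpha indices for one sample's OTU counts."""
    c = _counts_array(counts)
    if c.size == 0:
        raise UndefinedValueError("alpha diversity undefined for an empty sample")
    n = c.sum()
    p = c / n
    shannon = float(-(p * np.log(p)).sum())
    simpson = float((c * (c - 1.0)).sum() / (n * (n - 1.0))) if n > 1 else 1.0
    f1 = float((c == 1).sum())
    return AlphaDiversity(
        observed_otus=int(c.size),
        shannon=shannon,
        simpson=simpson,
        chao1=_chao1(c),
        ace=_ace(c),
        goods_coverage=1.0 - f1 / n,
    )


def alpha_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Alpha indices for every row (sample) of a counts matrix."""
    records = []
    for sid, row in counts.iterrows():
        a = alpha_indices(row.to_numpy())
        records.append({
            "sample_id": sid, "observed_otus": a.observed_otus,
            "shannon": a.shannon, "simpson": a.simpson,
            "chao1": a.chao1, "ace": a.ace,
            "goods_coverage": a.goods_coverage,
        })
    return pd.DataFrame(records).set_index("sample_id")


def otu_venn(counts: pd.DataFrame, groups: Sequence[str] | pd.Series,
             min_count: int = 1) -> dict[tuple[str, ...], int]:
    """Presence/absence Venn partition of OTUs across treatment groups.

    An OTU is present in a group when the group's summed count is at least
    *min_count*.  Returns ``{sorted group combination: number of OTUs found
    in exactly those groups}``; OTUs absent everywhere are not reported.
    """
    groups = pd.Series(list(groups), index=counts.index)
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise InvalidInputError("need at least two groups for a Venn partition")
    presence = {g: (counts[groups == g].sum(axis=0) >= min_count)
                for g in labels}
    partition: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = np.logical_and.reduce([presence[g].to_numpy() for g in combo])
            outside = np.logical_or.reduce(
                [presence[g].to_numpy() for g in labels if g not in combo]
            ) if len(combo) < len(labels) else np.zeros(counts.shape[1], bool)
            partition[tuple(combo)] = int((inside & ~outside).sum())
    return partition


def bray_curtis(counts: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix over samples (rows)."""
    if counts.shape[0] < 2:
        raise InvalidInputError("need at least two samples")
    x = counts.to_numpy(dtype=float)
    zero_rows = (x.sum(axis=1) == 0).sum()
    if zero_rows >= 2:
        raise UndefinedValueError(
            "Bray-Curtis is undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in counts.index])


def _permanova_stats(d2: np.ndarray, labels: np.ndarray,
                     uniq: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    a = uniq.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    f = (ss_among / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else (
        np.inf if ss_among > 0 else 0.0)
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dist: DistanceMatrix | np.ndarray | pd.DataFrame,
    grouping: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    The pseudo-F compares among-group to within-group sums of squared
    distances; the p-value counts permuted statistics at least as large as
    the observed one, with the +1 convention, so the smallest attainable p is
    ``1 / (n_permutations + 1)``.  Deterministic for a fixed seed.
    """
    if n_permutations < 1:
        raise InvalidInputError("n_permutations must be >= 1")
    if isinstance(dist, DistanceMatrix):
        d = dist.data
    else:
        d = np.asarray(dist, dtype=float)
    labels = np.asarray(list(grouping))
    if labels.size != d.shape[0]:
        raise InvalidInputError("grouping length must match the matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise InvalidInputError("need at least two groups")
    if np.any(counts < 2):
        warnings.warn("groups of size 1 make the within-group term fragile",
                      stacklevel=2)
    d2 = d * d
    f_obs, r2 = _permanova_stats(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        f_perm, _ = _permanova_stats(d2, perm, uniq)
        if f_perm >= f_obs:
            count_ge += 1
    p = (count_ge + 1) / (n_permutations + 1)
    return PermanovaResult(pseudo_f=float(f_obs), r_squared=float(r2),
                           p_value=float(p), n_permutations=n_permutations)


def rarefy(counts: Sequence[int] | np.ndarray, depth: int,
           seed: int | None = None) -> np.ndarray:
    """Subsample one sample's counts to a fixed depth without replacement."""
    c = np.asarray(counts, dtype=int)
    total = int(c.sum())
    if depth > total:
        raise InvalidInputError(
            f"cannot rarefy to {depth} reads from {total}")
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(c.size), c)
    picked = rng.choice(pool, size=depth, replace=False)
    return np.bincount(picked, minlength=c.size)
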