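"""One-way PERMANOVA on an arbitrary distance matrix.

The pseudo-F statistic partitions the total sum of squared pairwise
distances into within- and between-group components,

    SS_total  = (1/n)  sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    F = ((SS_total - SS_within)/(k - 1)) / (SS_within/(n - k)),

and significance comes from permuting group labels: with B permutations,
``p = (1 + #{F_perm >= F_obs}) / (1 + B)``, which is a valid (never
anti-conservative) p-value.  An exhaustive-enumeration variant serves as an
oracle on small designs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .composition import DistanceMatrix


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    method: str  # "permutation" | "exact"
    n_samples: int = 0
    n_groups: int = 0


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    return groups


def pseudo_f(dm: DistanceMatrix | np.ndarray, labels) -> float:
    """PERMANOVA pseudo-F for one grouping; +inf when SS_within is zero."""
    d = np.asarray(dm.data if isinstance(dm, DistanceMatrix) else dm, float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length does not match distance matrix")
    groups = _group_indices(labels)
    d2 = d ** 2
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for idx in groups:
        sub = d2[np.ix_(idx, idx)]
        ss_within += np.triu(sub, 1).sum() / len(idx)
    k = len(groups)
    if ss_within == 0:
        warnings.warn("SS_within is zero; pseudo-F is infinite")
        return math.inf
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def permanova(dm: DistanceMatrix, labels, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """Permutation PERMANOVA with uniformly random relabellings that
    preserve the group sizes."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    f_obs = pseudo_f(dm, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if pseudo_f(dm, perm) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(pseudo_f=f_obs, p_value=p, n_permutations=n_perm,
                           method="permutation", n_samples=len(labels),
                           n_groups=len(np.unique(labels)))


def _distinct_assignments(labels):
    """Yield every distinct assignment of the multiset of labels."""
    labels = list(labels)
    uniq = sorted(set(labels), key=str)
    counts = {u: labels.count(u) for u in uniq}
    n = len(labels)
    out = [None] * n

    def rec(pos, remaining):
        if pos == n:
            yield tuple(out)
            return
        for u in uniq:
            if remaining[u] > 0:
                remaining[u] -= 1
                out[pos] = u
                yield from rec(pos + 1, remaining)
                remaining[u] += 1

    yield from rec(0, counts)


def n_distinct_assignments(labels) -> int:
    labels = list(labels)
    total = math.factorial(len(labels))
    for u in set(labels):
        total //= math.factorial(labels.count(u))
    return total


def permanova_exact(dm: DistanceMatrix, labels,
                    max_assignments: int = 100_000) -> PermanovaResult:
    """Exact PERMANOVA p-value by enumerating every distinct relabelling.

    ``p`` is the fraction of assignments (the observed one included) whose
    pseudo-F is at least the observed value.
    """
    labels = np.asarray(labels)
    total = n_distinct_assignments(labels)
    if total > max_assignments:
        raise ValueError(
            f"{total} distinct relabellings exceed the enumeration budget "
            f"({max_assignments}); use the permutation test")
    f_obs = pseudo_f(dm, labels)
    count = 0
    for assign in _distinct_assignments(labels):
        if pseudo_f(dm, np.asarray(assign)) >= f_obs:
            count += 1
    return PermanovaResult(pseudo_f=f_obs, p_value=count / total,
                           n_permutations=total, method="exact",
                           n_samples=len(labels),
                           n_groups=len(np.unique(labels)))
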