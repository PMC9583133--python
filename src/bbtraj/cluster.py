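"""Hierarchical community typing: Ward.D2 linkage, silhouette-guided choice
of the number of clusters, anchor-based label alignment across timepoints,
and CLR-PCA driver identification.

The linkage follows the ``ward.D2`` convention: the Lance-Williams update is
applied to *squared* dissimilarities and reported merge heights are square
roots of the updated values, so that for Euclidean inputs the heights live
on the original distance scale.  Ties in the merge criterion are broken by
the smallest (i, j) cluster-index pair, making the dendrogram deterministic
for a given sample order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import DistanceMatrix, clr_transform
from .tables import AbundanceTable

logger = logging.getLogger(__name__)

#: letters used for aligned cluster labels, anchor-richest first
_ALIGN_LETTERS = "ABCDEFGH"


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage layout.

    ``merges`` is an (n-1, 4) array; row t merges cluster ids ``merges[t,0]``
    and ``merges[t,1]`` (original samples are 0..n-1, merged clusters n+t) at
    height ``merges[t,2]`` producing a cluster of size ``merges[t,3]``.
    """

    merges: np.ndarray
    ids: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.ids)


@dataclass
class ClusterSolution:
    """A dendrogram cut with silhouette diagnostics for one timepoint."""

    timepoint: str
    k: int
    sample_ids: list[str]
    labels: np.ndarray                   # integers 1..k
    silhouette_widths: np.ndarray
    mean_silhouette: float
    silhouette_profile: dict[int, float] = field(default_factory=dict)
    aligned_labels: list[str] | None = None  # "A", "B", ... after anchoring


# ---------------------------------------------------------------------------
# linkage
# ---------------------------------------------------------------------------

def ward_d2_linkage(dm: DistanceMatrix, variant: str = "ward.D2") -> Dendrogram:
    """Agglomerative Ward clustering of a precomputed distance matrix.

    ``variant="ward.D2"`` (default) squares the dissimilarities before the
    Lance-Williams recurrence and reports square-rooted heights;
    ``"ward.D"`` runs the same recurrence on the raw dissimilarities
    (heights reported as updated), exposed for sensitivity checks.
    """
    d = np.asarray(dm.data, float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two samples to cluster")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if variant not in ("ward.D2", "ward.D"):
        raise ValueError(f"unknown ward variant {variant!r}")
    work = d ** 2 if variant == "ward.D2" else d.copy()

    # active-cluster bookkeeping: matrix rows keep their slot, clusters own ids
    size = {i: 1 for i in range(n)}
    cluster_id = {i: i for i in range(n)}  # slot -> current cluster id
    active = list(range(n))
    merges = np.zeros((n - 1, 4))
    cur = work.copy()
    next_id = n
    for step in range(n - 1):
        best = None
        for a_pos in range(len(active)):
            for b_pos in range(a_pos + 1, len(active)):
                i, j = active[a_pos], active[b_pos]
                val = cur[i, j]
                ci, cj = sorted((cluster_id[i], cluster_id[j]))
                key = (val, ci, cj)
                if best is None or key < best[0]:
                    best = (key, i, j)
        (_, _, _), i, j = best
        ni, nj = size[i], size[j]
        # Lance-Williams Ward update against every other active cluster
        for m in active:
            if m in (i, j):
                continue
            nm = size[m]
            tot = ni + nj + nm
            cur[i, m] = cur[m, i] = ((ni + nm) * cur[i, m]
                                     + (nj + nm) * cur[j, m]
                                     - nm * cur[i, j]) / tot
        height = cur[i, j] ** 0.5 if variant == "ward.D2" else cur[i, j]
        lo, hi = sorted((cluster_id[i], cluster_id[j]))
        merges[step] = [lo, hi, height, ni + nj]
        size[i] = ni + nj
        cluster_id[i] = next_id
        next_id += 1
        active.remove(j)
    return Dendrogram(merges, ids=list(dm.ids))


def cut_tree(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Labels 1..k from undoing the last ``k - 1`` merges.

    Labels are renumbered by first-sample appearance so the assignment is
    invariant to internal cluster ids.
    """
    n = dendrogram.n_samples
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        a, b = int(dendrogram.merges[t, 0]), int(dendrogram.merges[t, 1])
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new
    raw = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    out = np.zeros(n, dtype=int)
    for i, r in enumerate(raw):
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        out[i] = relabel[r]
    return out


def dendrogram_to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths from merge heights."""
    n = dendrogram.n_samples
    height = {i: 0.0 for i in range(n)}
    node = {i: dendrogram.ids[i] for i in range(n)}
    for t in range(n - 1):
        a, b, h = (int(dendrogram.merges[t, 0]), int(dendrogram.merges[t, 1]),
                   float(dendrogram.merges[t, 2]))
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[n + t] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + t] = h
    return node[2 * n - 2] + ";"


# ---------------------------------------------------------------------------
# silhouette and k selection
# ---------------------------------------------------------------------------

def silhouette(dm: DistanceMatrix, labels) -> tuple[np.ndarray, float]:
    """Per-sample silhouette widths ``(b - a)/max(a, b)`` and their mean.

    Singleton clusters get width 0; samples where both ``a`` and ``b`` are 0
    (coincident points) also get 0.
    """
    d = np.asarray(dm.data, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    n = d.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            widths[i] = 0.0
            continue
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, labels == g].mean() for g in uniq if g != labels[i])
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths, float(widths.mean())


def select_k(dm: DistanceMatrix, k_min: int = 2, k_max: int | None = None,
             timepoint: str = "", variant: str = "ward.D2") -> ClusterSolution:
    """Cut the Ward.D2 tree at every k in the search range and keep the cut
    with the highest mean silhouette (ties go to the smallest k)."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("k selection needs at least three samples")
    if k_max is None:
        k_max = min(8, n - 1)
    k_max = min(k_max, n - 1)
    if k_min < 2 or k_min > k_max:
        raise ValueError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    dendro = ward_d2_linkage(dm, variant=variant)
    profile: dict[int, float] = {}
    best = None
    for k in range(k_min, k_max + 1):
        labels = cut_tree(dendro, k)
        widths, mean_s = silhouette(dm, labels)
        profile[k] = mean_s
        if best is None or mean_s > best[0] + 1e-12:
            best = (mean_s, k, labels, widths)
    mean_s, k, labels, widths = best
    return ClusterSolution(timepoint=timepoint, k=k, sample_ids=list(dm.ids),
                           labels=labels, silhouette_widths=widths,
                           mean_silhouette=mean_s, silhouette_profile=profile)


# ---------------------------------------------------------------------------
# label alignment across timepoints
# ---------------------------------------------------------------------------

def align_labels(solutions, table: AbundanceTable,
                 anchor_taxon: str = "Bacteroidaceae") -> list[ClusterSolution]:
    """Assign letters to clusters by mean relative abundance of an anchor
    taxon, per timepoint: the anchor-richest cluster becomes "A".

    Accepts the anchor with or without its rank prefix (``f__``).  Exact
    ties give the lower original label the earlier letter, with a warning.
    """
    anchor = anchor_taxon.split("__", 1)[-1]
    if anchor not in table.feature_ids:
        raise KeyError(
            f"anchor taxon {anchor!r} not in table; available: "
            f"{sorted(table.feature_ids)}")
    rel = table.data / table.data.sum(axis=0)
    out = []
    for sol in solutions:
        anchor_rel = rel.loc[anchor, sol.sample_ids].to_numpy(float)
        means = {}
        for g in sorted(set(sol.labels.tolist())):
            means[g] = float(anchor_rel[sol.labels == g].mean())
        if len(set(means.values())) < len(means):
            logger.warning("align_labels: exact anchor-mean tie at %s; "
                           "lower label wins", sol.timepoint or "<timepoint>")
        order = sorted(means, key=lambda g: (-means[g], g))
        letter = {g: _ALIGN_LETTERS[i] for i, g in enumerate(order)}
        sol.aligned_labels = [letter[g] for g in sol.labels]
        out.append(sol)
    return out


# ---------------------------------------------------------------------------
# CLR-PCA drivers
# ---------------------------------------------------------------------------

def clr_pca(table: AbundanceTable, zero_replacement: float = 1.0,
            n_components: int | None = None):
    """PCA of the feature-centred CLR matrix (samples as observations).

    Returns ``(scores, loadings, variance_explained)``: scores are samples x
    components, loadings features x components, and variance_explained the
    per-component fraction of total variance (sums to <= 1).
    """
    clr = clr_transform(table, zero_replacement)
    X = clr.to_numpy().T  # samples x features
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("clr_pca needs at least 2 samples and 2 features")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components is None:
        n_components = min(Xc.shape)
    u, s, vt = u[:, :n_components], s[:n_components], vt[:n_components]
    total_var = (Xc ** 2).sum()
    var_exp = (s ** 2) / total_var if total_var > 0 else np.zeros_like(s)
    scores = pd.DataFrame(u * s, index=clr.columns,
                          columns=[f"PC{i+1}" for i in range(n_components)])
    loadings = pd.DataFrame(vt.T, index=clr.index,
                            columns=[f"PC{i+1}" for i in range(n_components)])
    return scores, loadings, var_exp


def driving_taxa(loadings: pd.DataFrame, top_n: int = 5,
                 component: str = "PC1") -> list[str]:
    """Features ranked by absolute loading on a principal component."""
    mag = loadings[component].abs().sort_values(ascending=False)
    return list(mag.index[:top_n])
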