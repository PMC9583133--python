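"""Compositional transforms, beta-diversity distances and alpha-diversity
indices.

The centred log-ratio (CLR) transform maps each sample's composition to
unconstrained coordinates, ``clr_i = ln x_i - mean_j ln x_j``; Euclidean
distance between CLR vectors is the Aitchison distance.  Zeros are replaced
by a pseudo-count of 1 on the count scale before the transform (one read is
the natural detection unit), which keeps the transform defined while
perturbing observed features negligibly at metagenomic depths.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import skbio.stats.distance as _skbd
from scipy.spatial.distance import pdist, squareform

from .tables import AbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)


class DistanceMatrix(_skbd.DistanceMatrix):
    """A symmetric, hollow sample-by-sample distance matrix with a metric label."""

    def __init__(self, data, ids=None, metric: str = "unknown"):
        super().__init__(data, ids)
        self.metric = metric


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def clr_transform(table: AbundanceTable | pd.DataFrame,
                  zero_replacement: float = 1.0) -> pd.DataFrame:
    """Centred log-ratio transform of a counts table (features x samples).

    Zeros are replaced by ``zero_replacement`` (default one count) before
    taking logs.  Each sample's (column's) CLR values sum to zero.
    """
    if zero_replacement <= 0:
        raise ValueError("zero_replacement must be > 0")
    df = table.data if isinstance(table, AbundanceTable) else table
    vals = df.to_numpy(float).copy()
    if vals.size and vals.min() < 0:
        raise ValueError("counts must be non-negative")
    vals[vals == 0] = zero_replacement
    logs = np.log(vals)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=df.index, columns=df.columns)


def aitchison_distance(table: AbundanceTable | pd.DataFrame,
                       zero_replacement: float = 1.0) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples."""
    clr = clr_transform(table, zero_replacement)
    d = squareform(pdist(clr.to_numpy().T, metric="euclidean"))
    return DistanceMatrix(d, ids=[str(c) for c in clr.columns], metric="aitchison")


# ---------------------------------------------------------------------------
# distances on raw / relative abundances
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity, ``sum|x-y| / sum(x+y)``, bounded in [0, 1]."""
    df = table.data if isinstance(table, AbundanceTable) else table
    vals = df.to_numpy(float)
    if vals.size and vals.min() < 0:
        raise ValueError("Bray-Curtis requires non-negative abundances")
    d = squareform(pdist(vals.T, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # two all-zero samples: no evidence of difference
    return DistanceMatrix(d, ids=[str(c) for c in df.columns], metric="braycurtis")


def jaccard_pa(table: AbundanceTable | pd.DataFrame,
               detect_threshold: float = 0.0) -> DistanceMatrix:
    """Presence-absence Jaccard dissimilarity, ``1 - |A&B| / |A|B|``.

    Membership is abundance strictly greater than ``detect_threshold``.
    Two empty communities are defined as distance 0.
    """
    df = table.data if isinstance(table, AbundanceTable) else table
    present = (df.to_numpy(float) > detect_threshold).astype(bool).T
    n = present.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = np.logical_or(present[i], present[j]).sum()
            inter = np.logical_and(present[i], present[j]).sum()
            d[i, j] = d[j, i] = 0.0 if union == 0 else 1.0 - inter / union
    return DistanceMatrix(d, ids=[str(c) for c in df.columns], metric="jaccard")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(abundances) -> float:
    """Shannon index, natural log: ``H = -sum p ln p`` over positive parts."""
    x = np.asarray(abundances, float)
    if x.size == 0 or x.sum() == 0:
        return 0.0
    if x.min() < 0:
        raise ValueError("abundances must be non-negative")
    p = x[x > 0] / x.sum()
    return float(-(p * np.log(p)).sum())


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness, ``S_obs + f1 (f1 - 1) / (2 (f2 + 1))``.

    Requires integer counts: singleton/doubleton frequencies are undefined
    on normalized data.
    """
    x = np.asarray(counts, float)
    if x.size and not np.allclose(x, np.round(x)):
        raise ValueError("Chao1 requires integer counts")
    if x.size and x.min() < 0:
        raise ValueError("counts must be non-negative")
    x = np.round(x).astype(np.int64)
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon (any kind) and Chao1 (counts only) indices."""
    rows = {}
    for sid in table.sample_ids:
        col = table.data[sid].to_numpy(float)
        row = {"shannon": shannon(col)}
        if table.value_kind == "counts":
            row["chao1"] = chao1(col)
        rows[sid] = row
    return pd.DataFrame(rows).T.rename_axis("sample_id")


def rarefy(table: AbundanceTable, depth: int, seed: int = 0) -> AbundanceTable:
    """Subsample each sample's counts to a common depth without replacement.

    Samples shallower than ``depth`` are dropped with a logged notice.
    Optional pre-step for alpha diversity; not applied by default.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for sid in table.sample_ids:
        counts = np.round(table.data[sid].to_numpy(float)).astype(np.int64)
        total = counts.sum()
        if total < depth:
            logger.info("rarefy: dropping %s (depth %d < %d)", sid, total, depth)
            continue
        cols[sid] = rng.multivariate_hypergeometric(counts, depth)
    if not cols:
        raise ValueError("no sample reaches the rarefaction depth")
    df = pd.DataFrame(cols, index=table.data.index)
    return AbundanceTable(df.astype(float), rank=table.rank, value_kind="counts",
                          lineages=dict(table.lineages))


# ---------------------------------------------------------------------------
# longitudinal stability
# ---------------------------------------------------------------------------

def successive_jaccard_stability(table: AbundanceTable,
                                 metadata: SampleMetadata,
                                 detect_threshold: float = 0.0) -> pd.DataFrame:
    """Presence-absence Jaccard dissimilarity between each subject's
    consecutive available timepoints.

    Membership is relative abundance strictly above ``detect_threshold``
    (columns are total-sum scaled first, so the threshold is on the
    relative scale whatever the table's value kind).  Returns a long
    DataFrame (subject_id, t_from, t_to, dissimilarity); subjects with
    fewer than two infant samples are omitted with a logged notice.
    Higher values mean a less stable community over time.
    """
    sums = table.data.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("zero-sum sample(s) in stability input")
    rel = table.data / sums
    order = metadata.timepoint_order
    rank_of = {t: i for i, t in enumerate(order)}
    rows = []
    meta = metadata.data
    infants = meta[meta["timepoint"].isin(order)]
    for subject, grp in infants.groupby("subject_id"):
        grp = grp.assign(_ord=[rank_of[t] for t in grp["timepoint"]]).sort_values("_ord")
        if len(grp) < 2:
            logger.info("stability: subject %s has <2 timepoints, skipped", subject)
            continue
        sids = list(grp.index)
        tps = list(grp["timepoint"])
        for (s1, t1), (s2, t2) in zip(zip(sids, tps), zip(sids[1:], tps[1:])):
            a = rel[s1].to_numpy(float) > detect_threshold
            b = rel[s2].to_numpy(float) > detect_threshold
            union = np.logical_or(a, b).sum()
            inter = np.logical_and(a, b).sum()
            dis = 0.0 if union == 0 else 1.0 - inter / union
            rows.append({"subject_id": subject, "t_from": t1, "t_to": t2,
                         "dissimilarity": dis})
    return pd.DataFrame(rows, columns=["subject_id", "t_from", "t_to",
                                       "dissimilarity"])


# ---------------------------------------------------------------------------
# distance matrix round-trip
# ---------------------------------------------------------------------------

def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path, metric: str = "unknown") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(float), ids=[str(i) for i in df.index],
                          metric=metric)
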