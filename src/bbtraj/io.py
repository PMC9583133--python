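"""Reading, writing, aggregating, normalizing and filtering abundance tables.

File conventions: feature tables are TSV with features as rows and samples
as columns (an ``orientation`` flag accepts transposed input); an optional
``lineage`` column holds semicolon-delimited rank-prefixed lineages.
Bracken per-sample report files are merged on (taxon name, taxonomy id)
using their re-estimated read counts.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .tables import (AbundanceTable, SampleMetadata, TableValidationError,
                     RANKS, parse_lineage, format_lineage)

BRACKEN_COLUMNS = ["name", "taxonomy_id", "taxonomy_lvl", "kraken_assigned_reads",
                   "added_reads", "new_est_reads", "fraction_total_reads"]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_feature_table(path, orientation: str = "features_as_rows",
                       rank: str = "species",
                       value_kind: str = "counts") -> AbundanceTable:
    """Read a TSV feature table (first column feature id, optional
    ``lineage`` column) into an :class:`AbundanceTable`."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    lineages: dict[str, dict[str, str]] = {}
    if "lineage" in df.columns:
        for fid, lin in df["lineage"].items():
            if isinstance(lin, str) and lin:
                lineages[str(fid)] = parse_lineage(lin)
        df = df.drop(columns=["lineage"])
    if orientation == "samples_as_rows":
        df = df.T
    elif orientation != "features_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return AbundanceTable(df, rank=rank, value_kind=value_kind, lineages=lineages)


def write_feature_table(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    if table.lineages:
        df.insert(0, "lineage",
                  [format_lineage(table.lineages.get(f, {})) for f in df.index])
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_metadata(path, timepoint_order=None) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    kwargs = {}
    if timepoint_order is not None:
        kwargs["timepoint_order"] = list(timepoint_order)
    return SampleMetadata(df, **kwargs)


def write_metadata(metadata: SampleMetadata, path) -> None:
    df = metadata.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_bracken_reports(paths, sample_ids=None) -> AbundanceTable:
    """Merge per-sample Bracken report files into one counts table.

    Values are taken from ``new_est_reads`` (the Bayesian re-estimated
    counts), never ``kraken_assigned_reads``; taxa absent from a sample get 0.
    """
    paths = list(paths)
    if sample_ids is None:
        sample_ids = [os.path.splitext(os.path.basename(p))[0] for p in paths]
    sample_ids = [str(s) for s in sample_ids]
    if len(sample_ids) != len(paths):
        raise ValueError("sample_ids length does not match paths")
    if len(set(sample_ids)) != len(sample_ids):
        raise TableValidationError("duplicated sample_ids for Bracken merge")

    columns = {}
    ranks = {}
    for path, sid in zip(paths, sample_ids):
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in BRACKEN_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(
                f"Bracken report {path} missing columns {missing}")
        key = df["name"].astype(str) + "|" + df["taxonomy_id"].astype(str)
        columns[sid] = pd.Series(df["new_est_reads"].to_numpy(float), index=key)
        for k, lvl in zip(key, df["taxonomy_lvl"]):
            ranks[k] = str(lvl)
    merged = pd.DataFrame(columns).fillna(0.0)
    merged = merged.loc[sorted(merged.index)]
    lineages = {}
    lvl_to_rank = {"S": "species", "G": "genus", "F": "family", "O": "order",
                   "C": "class", "P": "phylum", "D": "domain", "K": "domain"}
    for key in merged.index:
        name = key.split("|", 1)[0]
        rank = lvl_to_rank.get(ranks.get(key, ""), None)
        if rank:
            lineages[key] = {rank: name}
    return AbundanceTable(merged, rank="species", value_kind="counts",
                          lineages=lineages)


# ---------------------------------------------------------------------------
# aggregation / normalization / filtering
# ---------------------------------------------------------------------------

def aggregate_rank(table: AbundanceTable, rank: str,
                   drop_unclassified: bool = False) -> AbundanceTable:
    """Sum features sharing the same name at ``rank``.

    Features with no lineage entry at the requested rank are pooled into an
    ``"unclassified"`` bucket (kept by default so that column sums — and
    hence compositional closure — are preserved exactly).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    names = []
    any_known = False
    for fid in table.feature_ids:
        name = table.lineages.get(fid, {}).get(rank)
        if name is None and table.rank == rank:
            name = fid  # already at this rank; feature id is the rank name
        if name is not None:
            any_known = True
        names.append(name if name is not None else "unclassified")
    if not any_known:
        raise ValueError(f"no feature carries a lineage at rank {rank!r}")
    grouped = table.data.groupby(pd.Index(names, name=rank), sort=True).sum()
    if drop_unclassified and "unclassified" in grouped.index:
        grouped = grouped.drop(index="unclassified")
    # retain the coarser part of the lineage for each aggregated feature
    rank_idx = RANKS.index(rank)
    lineages: dict[str, dict[str, str]] = {}
    for fid in table.feature_ids:
        lin = table.lineages.get(fid, {})
        name = lin.get(rank)
        if name is not None and name in grouped.index and name not in lineages:
            lineages[name] = {r: lin[r] for r in RANKS[:rank_idx + 1] if r in lin}
    return AbundanceTable(grouped, rank=rank, value_kind=table.value_kind,
                          lineages=lineages)


def _column_sums_checked(table: AbundanceTable) -> np.ndarray:
    sums = table.data.sum(axis=0)
    zero = sums.index[sums.to_numpy() == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample(s), cannot normalize: {zero}")
    return sums.to_numpy(float)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Total-sum scaling: each column divided by its sum (columns sum to 1)."""
    sums = _column_sums_checked(table)
    return AbundanceTable(table.data / sums, rank=table.rank,
                          value_kind="relative", lineages=dict(table.lineages))


def cpm_normalize(table: AbundanceTable) -> AbundanceTable:
    """Counts-per-million scaling (columns sum to 1e6)."""
    sums = _column_sums_checked(table)
    return AbundanceTable(table.data * (1e6 / sums), rank=table.rank,
                          value_kind="cpm", lineages=dict(table.lineages))


def filter_features(table: AbundanceTable, detection: float,
                    prevalence: float) -> AbundanceTable:
    """Prevalence-of-detection feature filter.

    A feature is kept iff its relative abundance reaches ``detection`` in at
    least a ``prevalence`` fraction of samples.  Values of retained features
    are left untouched (removed mass is not redistributed).
    """
    if not (0 <= detection <= 1 and 0 <= prevalence <= 1):
        raise ValueError("detection and prevalence must lie in [0, 1]")
    rel = table if table.value_kind == "relative" else to_relative(table)
    detected = rel.data.to_numpy() >= detection
    frac = detected.mean(axis=1) if detected.shape[1] else np.ones(len(table.feature_ids))
    keep = frac >= prevalence
    if not keep.any():
        raise ValueError(
            "filter removed every feature; relax detection/prevalence thresholds")
    kept = table.data.loc[keep]
    lineages = {f: table.lineages[f] for f in kept.index if f in table.lineages}
    return AbundanceTable(kept.copy(), rank=table.rank,
                          value_kind=table.value_kind, lineages=lineages)
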