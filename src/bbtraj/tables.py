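"""Core in-memory containers for abundance profiles and sample metadata.

An :class:`AbundanceTable` is a features-by-samples matrix (taxa or
pathways) carrying optional taxonomic lineages and a label for the
aggregation rank currently represented.  A :class:`SampleMetadata` wraps a
per-sample record of subject, timepoint and exposures, enabling the
longitudinal joins used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Taxonomic ranks from coarsest to finest, with their lineage-string prefixes.
RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]
RANK_PREFIXES = {
    "k__": "domain",
    "d__": "domain",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}

#: Default infant sampling schedule; "mother" is a pseudo-timepoint.
DEFAULT_TIMEPOINTS = ["3w", "3m", "6m", "12m"]
MOTHER_TIMEPOINT = "mother"

VALUE_KINDS = {"counts", "relative", "cpm", "abundance"}


class TableValidationError(ValueError):
    """Raised when a table or metadata object violates its invariants."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse a semicolon-delimited, rank-prefixed lineage string.

    ``"k__Bacteria;f__Bacteroidaceae;g__Bacteroides"`` maps to
    ``{"domain": "Bacteria", "family": "Bacteroidaceae", ...}``.  Fields with
    an empty name after the prefix are skipped.
    """
    out: dict[str, str] = {}
    for piece in str(lineage).split(";"):
        piece = piece.strip()
        if len(piece) >= 3 and piece[:3] in RANK_PREFIXES:
            name = piece[3:].strip()
            if name:
                out[RANK_PREFIXES[piece[:3]]] = name
    return out


def format_lineage(lineage: dict[str, str]) -> str:
    """Inverse of :func:`parse_lineage` (canonical prefixes, known ranks only)."""
    prefix_for = {"domain": "k__", "phylum": "p__", "class": "c__",
                  "order": "o__", "family": "f__", "genus": "g__",
                  "species": "s__"}
    return ";".join(prefix_for[r] + lineage[r] for r in RANKS if r in lineage)


@dataclass
class AbundanceTable:
    """Features-by-samples abundance matrix with lineage annotations.

    Parameters
    ----------
    data:
        DataFrame with feature ids as index and sample ids as columns.
        All entries must be non-negative.
    rank:
        Aggregation level of the features (one of :data:`RANKS`, or a free
        label such as ``"pathway"``).
    value_kind:
        ``"counts"`` for raw counts, ``"relative"`` for columns summing to 1,
        ``"cpm"`` for columns summing to 1e6, ``"abundance"`` for
        unconstrained non-negative values (e.g. mixed pathway profiles).
    lineages:
        Optional map of feature id to a rank-to-name dictionary.
    """

    data: pd.DataFrame
    rank: str = "species"
    value_kind: str = "counts"
    lineages: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise TableValidationError(f"unknown value_kind {self.value_kind!r}")
        if not self.data.index.is_unique:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate feature ids: {dupes}")
        if not self.data.columns.is_unique:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise TableValidationError(f"duplicate sample ids: {dupes}")
        vals = self.data.to_numpy()
        if vals.size and not np.issubdtype(vals.dtype, np.number):
            raise TableValidationError("non-numeric values in table")
        if vals.size and np.nanmin(vals) < 0:
            raise TableValidationError("negative values in abundance table")
        if self.value_kind == "relative" and vals.size:
            sums = vals.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = self.data.columns[np.abs(sums - 1.0) > 1e-9].tolist()
                raise TableValidationError(
                    f"relative table columns do not sum to 1: {bad}")

    # -- convenience accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), self.rank, self.value_kind,
                              {k: dict(v) for k, v in self.lineages.items()})

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[:, list(sample_ids)].copy(),
                              self.rank, self.value_kind, dict(self.lineages))


@dataclass
class SampleMetadata:
    """Per-sample subject / timepoint / exposure records.

    The underlying DataFrame is indexed by sample id and must contain
    ``subject_id`` and ``timepoint`` columns; ``birth_mode`` and ``iap``
    default to ``"NA"``.  Any further columns are free-form covariates.
    """

    data: pd.DataFrame
    timepoint_order: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "timepoint"):
            if col not in df.columns:
                raise TableValidationError(f"metadata missing column {col!r}")
        for col, default in (("birth_mode", "NA"), ("iap", "NA")):
            if col not in df.columns:
                df[col] = default
        if not df.index.is_unique:
            raise TableValidationError("duplicate sample ids in metadata")
        allowed = set(self.timepoint_order) | {MOTHER_TIMEPOINT}
        bad = set(df["timepoint"]) - allowed
        if bad:
            raise TableValidationError(f"unknown timepoints: {sorted(bad)}")
        pairs = df[["subject_id", "timepoint"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise TableValidationError("(subject_id, timepoint) pairs not unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def infant_timepoints(self) -> list[str]:
        """Ordered infant timepoints actually present (mothers excluded)."""
        present = set(self.data["timepoint"])
        return [t for t in self.timepoint_order if t in present]

    def samples_at(self, timepoint: str) -> list[str]:
        return list(self.data.index[self.data["timepoint"] == timepoint])

    def subject_of(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "subject_id"])
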