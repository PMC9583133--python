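"""Longitudinal trajectory classification and *Bacteroides*-group
definition.

A subject's trajectory is the sequence of anchor-aligned cluster letters
across timepoints: all-"A" is ``stable_A`` (the high-*Bacteroidaceae*
trajectory), all-"B" is ``stable_B``, any switching makes the subject
``intermediary``, and subjects sampled at fewer timepoints than the policy
requires are ``insufficient_data``.  The *Bacteroides* group splits
subjects by the genus's relative abundance at the first sampled timepoint:
strictly below the cutoff (default 1%) is ``depleted``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import to_relative
from .tables import AbundanceTable, SampleMetadata

logger = logging.getLogger(__name__)

TRAJECTORY_CLASSES = ["stable_A", "stable_B", "intermediary", "insufficient_data"]
_ALIGNED = set("ABCDEFGH")


@dataclass
class TrajectoryAssignment:
    subject_id: str
    trajectory: str
    labels_by_timepoint: dict[str, str]
    n_timepoints_used: int


@dataclass
class BacteroidesGroup:
    subject_id: str
    group: str  # "present" | "depleted" | "no_sample"
    first_timepoint_rel_abundance: float | None
    timepoint: str | None


def aligned_label_frame(solutions, metadata: SampleMetadata) -> pd.DataFrame:
    """Subject x timepoint frame of aligned cluster letters from a list of
    per-timepoint :class:`~bbtraj.cluster.ClusterSolution` objects."""
    records = {}
    for sol in solutions:
        if sol.aligned_labels is None:
            raise ValueError("solutions must be aligned (run align_labels first)")
        for sid, lab in zip(sol.sample_ids, sol.aligned_labels):
            subject = metadata.subject_of(sid)
            records.setdefault(subject, {})[sol.timepoint] = lab
    order = [t for t in metadata.timepoint_order
             if any(t in r for r in records.values())]
    return pd.DataFrame.from_dict(records, orient="index").reindex(columns=order)


def assign_trajectories(aligned_labels: pd.DataFrame,
                        required_timepoints: int | str = "all",
                        ) -> list[TrajectoryAssignment]:
    """Classify each subject's aligned label sequence.

    ``required_timepoints="all"`` mirrors restricting the longitudinal
    analysis to subjects with a complete sampling series; an integer relaxes
    the policy to that minimum number of timepoints.
    """
    n_tp = aligned_labels.shape[1]
    required = n_tp if required_timepoints == "all" else int(required_timepoints)
    out = []
    for subject, row in aligned_labels.iterrows():
        labels = {t: v for t, v in row.items() if isinstance(v, str)}
        bad = [v for v in labels.values() if v not in _ALIGNED]
        if bad:
            raise ValueError(
                f"unaligned labels {bad!r} for subject {subject}; "
                "pass anchor-aligned letters")
        used = len(labels)
        if used < required or used == 0:
            traj = "insufficient_data"
        else:
            uniq = set(labels.values())
            if uniq == {"A"}:
                traj = "stable_A"
            elif uniq == {"B"}:
                traj = "stable_B"
            else:
                traj = "intermediary"
        out.append(TrajectoryAssignment(subject_id=str(subject), trajectory=traj,
                                        labels_by_timepoint=labels,
                                        n_timepoints_used=used))
    return out


def define_bacteroides_groups(genus_table: AbundanceTable,
                              metadata: SampleMetadata,
                              cutoff: float = 0.01,
                              timepoint: str = "first",
                              genus: str = "Bacteroides",
                              ) -> list[BacteroidesGroup]:
    """Split subjects into *Bacteroides*-present / -depleted groups.

    ``timepoint="first"`` uses each subject's earliest infant sample; a
    concrete label (e.g. ``"3w"``) enforces that exact timepoint, flagging
    subjects without it as ``no_sample`` rather than dropping them.  The
    depletion rule is a strict ``< cutoff`` on relative abundance.
    """
    if genus not in genus_table.feature_ids:
        raise KeyError(f"genus {genus!r} absent from table at rank "
                       f"{genus_table.rank!r}")
    rel = (genus_table if genus_table.value_kind == "relative"
           else to_relative(genus_table))
    order = metadata.timepoint_order
    rank_of = {t: i for i, t in enumerate(order)}
    meta = metadata.data
    infants = meta[meta["timepoint"].isin(order)]
    out = []
    for subject, grp in infants.groupby("subject_id"):
        if timepoint == "first":
            grp = grp.assign(_ord=[rank_of[t] for t in grp["timepoint"]])
            row = grp.sort_values("_ord").iloc[0]
            sid, tp = row.name, row["timepoint"]
        else:
            hit = grp[grp["timepoint"] == timepoint]
            if hit.empty:
                logger.info("bacteroides group: subject %s lacks %s sample",
                            subject, timepoint)
                out.append(BacteroidesGroup(str(subject), "no_sample", None, None))
                continue
            sid, tp = hit.index[0], timepoint
        ra = float(rel.data.loc[genus, sid])
        group = "depleted" if ra < cutoff else "present"
        out.append(BacteroidesGroup(str(subject), group, ra, tp))
    return out


def transition_counts(aligned_labels: pd.DataFrame,
                      ) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Per-interval k x k transition count matrices between consecutive
    timepoints, plus a long-format table.

    Row/column marginals of each interval matrix count the subjects sampled
    at both endpoints (subjects missing either endpoint are excluded from
    that interval).
    """
    tps = list(aligned_labels.columns)
    letters = sorted({v for v in aligned_labels.to_numpy().ravel()
                      if isinstance(v, str)})
    matrices: dict[tuple[str, str], pd.DataFrame] = {}
    long_rows = []
    for t1, t2 in zip(tps, tps[1:]):
        mat = pd.DataFrame(0, index=letters, columns=letters)
        for _, row in aligned_labels.iterrows():
            a, b = row[t1], row[t2]
            if isinstance(a, str) and isinstance(b, str):
                mat.loc[a, b] += 1
        matrices[(t1, t2)] = mat
        for a in letters:
            for b in letters:
                long_rows.append({"t_from": t1, "t_to": t2, "label_from": a,
                                  "label_to": b, "count": int(mat.loc[a, b])})
    long = pd.DataFrame(long_rows,
                        columns=["t_from", "t_to", "label_from", "label_to",
                                 "count"])
    return matrices, long


def trajectory_table(assignments: list[TrajectoryAssignment],
                     groups: list[BacteroidesGroup] | None = None) -> pd.DataFrame:
    """Flat per-subject TSV-ready summary of trajectories (and groups)."""
    rows = {}
    for a in assignments:
        rows[a.subject_id] = {"trajectory": a.trajectory,
                              "n_timepoints_used": a.n_timepoints_used,
                              **{f"label_{t}": v
                                 for t, v in a.labels_by_timepoint.items()}}
    if groups is not None:
        for g in groups:
            rows.setdefault(g.subject_id, {})
            rows[g.subject_id]["bacteroides_group"] = g.group
            rows[g.subject_id]["bacteroides_first_rel"] = (
                g.first_timepoint_rel_abundance)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject_id")
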