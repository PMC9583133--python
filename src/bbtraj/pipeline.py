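"""End-to-end orchestration: family-level clustering per timepoint,
PERMANOVA confirmation, trajectory and *Bacteroides*-group assignment,
diversity trends, exposure associations and pathway differential abundance,
from a single config, with a machine-readable JSON report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .association import (bh_fdr, feature_lm, fisher_exact,
                          pairwise_wilcoxon_fdr, stratified_categorical_test)
from .cluster import align_labels, select_k
from .composition import aitchison_distance, alpha_diversity_table
from .permanova import permanova
from .synthetic import CohortConfig, generate_cohort
from .tables import AbundanceTable, SampleMetadata
from .trajectories import (aligned_label_frame, assign_trajectories,
                           define_bacteroides_groups, trajectory_table,
                           transition_counts)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Inputs and knobs for :func:`run_full`.

    Exactly one of (``taxa_table_path``, ``cohort``) must be provided; the
    former loads a genus-level TSV counts table plus metadata TSV, the
    latter simulates a cohort.
    """

    taxa_table_path: str | None = None
    metadata_path: str | None = None
    pathway_table_path: str | None = None
    cohort: CohortConfig | None = None
    family_detection: float = 0.01
    family_prevalence: float = 0.005
    anchor_taxon: str = "Bacteroidaceae"
    k_min: int = 2
    k_max: int = 8
    permutations: int = 999
    seed: int = 0
    bacteroides_cutoff: float = 0.01
    exposures: list[dict] = field(default_factory=list)
    # each: {"variable": ..., "type": "categorical"|"numeric",
    #        "controlled_for": "birth_mode" | None}
    output_dir: str | None = None

    def validate(self) -> None:
        has_paths = self.taxa_table_path is not None
        if has_paths == (self.cohort is not None):
            raise ValueError("set exactly one of taxa_table_path or cohort")
        if has_paths and self.metadata_path is None:
            raise ValueError("metadata_path required with taxa_table_path")
        for thr in (self.family_detection, self.family_prevalence):
            if not (0 <= thr <= 1):
                raise ValueError("filter thresholds must lie in [0, 1]")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_full(config: AnalysisConfig) -> dict:
    """Execute the whole analysis; returns (and optionally writes) the
    report dictionary.  Deterministic for a fixed config."""
    config.validate()
    report: dict = {"parameters": {
        "family_detection": config.family_detection,
        "family_prevalence": config.family_prevalence,
        "anchor_taxon": config.anchor_taxon,
        "k_range": [config.k_min, config.k_max],
        "permutations": config.permutations,
        "seed": config.seed,
        "bacteroides_cutoff": config.bacteroides_cutoff,
    }}
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- load or simulate ------------------------------------------------
    if config.cohort is not None:
        genus_table, metadata, truth = generate_cohort(config.cohort)
        report["input"] = {"source": "synthetic",
                           "n_subjects": config.cohort.n_subjects}
    else:
        genus_table = pio.read_feature_table(config.taxa_table_path, rank="genus")
        metadata = pio.read_metadata(config.metadata_path)
        truth = None
        report["input"] = {"source": config.taxa_table_path}
    report["input"]["n_samples"] = len(genus_table.sample_ids)

    # ---- family aggregation + filter ------------------------------------
    family_table = _stage("aggregate_family")(pio.aggregate_rank)(
        genus_table, "family")
    infant_samples = [s for s in family_table.sample_ids
                      if metadata.data.loc[s, "timepoint"]
                      in metadata.timepoint_order]
    family_inf = family_table.subset_samples(infant_samples)
    family_filt = _stage("filter_families")(pio.filter_features)(
        family_inf, config.family_detection, config.family_prevalence)
    report["families_kept"] = family_filt.feature_ids

    # ---- per-timepoint clustering + PERMANOVA ----------------------------
    solutions = []
    report["clusters"] = {}
    rng = np.random.default_rng(config.seed)
    for tp in metadata.infant_timepoints():
        sids = [s for s in metadata.samples_at(tp) if s in infant_samples]
        if len(sids) < 3:
            logger.info("skipping timepoint %s with %d samples", tp, len(sids))
            continue
        sub = family_filt.subset_samples(sids)
        dm = aitchison_distance(sub)
        sol = select_k(dm, k_min=config.k_min, k_max=config.k_max, timepoint=tp)
        perm = permanova(dm, sol.labels, n_perm=config.permutations,
                         seed=int(rng.integers(2 ** 31)))
        solutions.append(sol)
        report["clusters"][tp] = {
            "n_samples": len(sids), "k": sol.k,
            "mean_silhouette": round(sol.mean_silhouette, 6),
            "silhouette_profile": {str(k): round(v, 6)
                                   for k, v in sol.silhouette_profile.items()},
            "permanova_pseudo_f": round(perm.pseudo_f, 6),
            "permanova_p": perm.p_value,
        }
    if not solutions:
        raise RuntimeError("pipeline stage 'clustering' failed: no timepoint "
                           "had enough samples")

    # ---- alignment, trajectories, Bacteroides groups ---------------------
    align_labels(solutions, family_filt, anchor_taxon=config.anchor_taxon)
    labels_frame = aligned_label_frame(solutions, metadata)
    assignments = assign_trajectories(labels_frame)
    counts = pd.Series([a.trajectory for a in assignments]).value_counts()
    report["trajectories"] = {k: int(v) for k, v in counts.items()}
    groups = _stage("bacteroides_groups")(define_bacteroides_groups)(
        genus_table.subset_samples(infant_samples), metadata,
        cutoff=config.bacteroides_cutoff)
    gcounts = pd.Series([g.group for g in groups]).value_counts()
    report["bacteroides_groups"] = {k: int(v) for k, v in gcounts.items()}
    matrices, long = transition_counts(labels_frame)
    report["transitions"] = {f"{a}->{b}": m.to_dict()
                             for (a, b), m in matrices.items()}

    # ---- diversity trends ------------------------------------------------
    alpha = alpha_diversity_table(genus_table.subset_samples(infant_samples))
    alpha["timepoint"] = [metadata.data.loc[s, "timepoint"] for s in alpha.index]
    shannon_groups = {tp: g["shannon"].to_numpy()
                      for tp, g in alpha.groupby("timepoint")}
    report["alpha_diversity"] = {
        "mean_shannon": {tp: float(np.mean(v)) for tp, v in shannon_groups.items()}}
    if len(shannon_groups) > 1:
        q = pairwise_wilcoxon_fdr(shannon_groups)
        report["alpha_diversity"]["pairwise_q"] = {
            f"{a}|{b}": float(q.loc[a, b])
            for a in q.index for b in q.columns if a < b}

    # ---- exposure associations ------------------------------------------
    traj_by_subject = {a.subject_id: a.trajectory for a in assignments
                       if a.trajectory in ("stable_A", "stable_B", "intermediary")}
    report["exposures"] = {}
    exposure_ps = []
    for spec_ in config.exposures:
        var = spec_["variable"]
        subjects = [s for s in traj_by_subject
                    if s in set(metadata.data["subject_id"])]
        sub_meta = (metadata.data.drop_duplicates("subject_id")
                    .set_index("subject_id").loc[subjects])
        outcome = np.array([traj_by_subject[s] == "stable_A" for s in subjects])
        values = sub_meta[var]
        entry = {"variable": var}
        if spec_.get("controlled_for") == "birth_mode":
            strata = sub_meta["birth_mode"].to_numpy()
            if spec_.get("type") == "numeric":
                res = stratified_categorical_test(
                    values.astype(float).to_numpy(),
                    outcome.astype(str), strata)
            else:
                res = stratified_categorical_test(
                    outcome.astype(str), values.astype(str).to_numpy(), strata)
            entry.update(model=res.model, p=res.p_value)
        else:
            if spec_.get("type") == "numeric":
                from .association import wilcoxon_rank_sum
                x = values[outcome].astype(float).to_numpy()
                y = values[~outcome].astype(float).to_numpy()
                _, p = wilcoxon_rank_sum(x, y)
                entry.update(model="wilcoxon", p=p)
            else:
                lv = sorted(values.astype(str).unique())[:2]
                t = np.array([[np.sum(outcome & (values.astype(str) == l))
                               for l in lv],
                              [np.sum(~outcome & (values.astype(str) == l))
                               for l in lv]])
                _, p = fisher_exact(t)
                entry.update(model="fisher", p=p)
        exposure_ps.append(entry)
        report["exposures"][var] = entry
    if exposure_ps:
        qs = bh_fdr([e["p"] for e in exposure_ps])
        for e, q in zip(exposure_ps, qs):
            e["q"] = float(q)

    # ---- pathway differential abundance ----------------------------------
    if config.pathway_table_path:
        pathways = pio.read_feature_table(config.pathway_table_path,
                                          rank="pathway")
        report["pathways"] = {}
        for sol in solutions:
            letters = np.asarray(sol.aligned_labels)
            if len(set(letters)) < 2:
                continue
            sub = pathways.subset_samples(sol.sample_ids)
            meta = pd.DataFrame({"cluster": letters}, index=sol.sample_ids)
            res = feature_lm(sub, meta, "cluster", detection=1e-6,
                             prevalence=0.10)
            report["pathways"][sol.timepoint] = {
                "n_tested": int(len(res)),
                "n_significant": int(res["significant"].sum()),
                "significant": res.loc[res["significant"],
                                       "feature_id"].tolist()}

    # ---- optional recovery metrics vs planted truth ----------------------
    if truth is not None:
        from sklearn.metrics import adjusted_rand_score
        common = [a.subject_id for a in assignments
                  if a.trajectory != "insufficient_data"
                  and a.subject_id in truth.trajectory]
        rec = {a.subject_id: a.trajectory for a in assignments}
        if common:
            report["truth_recovery"] = {
                "trajectory_ari": float(adjusted_rand_score(
                    [truth.trajectory[s] for s in common],
                    [rec[s] for s in common])),
                "n_compared": len(common)}

    # ---- emit -----------------------------------------------------------
    if outdir:
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        trajectory_table(assignments, groups).to_csv(
            outdir / "trajectories.tsv", sep="\t")
        long.to_csv(outdir / "transitions.tsv", sep="\t", index=False)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    return report
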