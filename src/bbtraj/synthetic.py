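"""Synthetic longitudinal infant-cohort generator with planted structure.

The generator emulates the statistical shape of a birth cohort sampled at
four infant timepoints (3 weeks, 3 and 6 and 12 months) plus mothers in
late pregnancy: two family-level community types (type A rich in
*Bacteroidaceae* / *Tannerellaceae* / *Rikenellaceae*; type B nearly devoid
of *Bacteroidaceae* and carrying *Clostridiaceae*), three longitudinal
trajectory classes (stable_A, stable_B, and a temporally unstable
intermediary class), birth-mode confounding (caesarean-born subjects never
follow the stable_A trajectory and always start in type B), an age drift
that raises *Lachnospiraceae* and *Oscillospiraceae* toward 12 months,
log-normally distributed sequencing depths, and taxa-linked pathway
profiles.  Counts are Dirichlet-multinomial: a family-level composition is
drawn per sample from the type's concentration vector, split into genera by
fixed within-family proportions, and read counts are multinomial at the
drawn depth — so every sample's column sum equals its depth exactly.

Each subject consumes an independent, hierarchically derived random
stream, so subject ``i`` is reproducible regardless of cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMetadata, DEFAULT_TIMEPOINTS, MOTHER_TIMEPOINT

FAMILIES = ["Bacteroidaceae", "Tannerellaceae", "Rikenellaceae",
            "Clostridiaceae", "Enterobacteriaceae", "Bifidobacteriaceae",
            "Lachnospiraceae", "Veillonellaceae", "Oscillospiraceae",
            "Streptococcaceae"]

#: total Dirichlet concentration mass; lower = more sample-to-sample
#: overdispersion around the type's mean composition
_CONC_TOTAL = 60.0

# mean family compositions for the two infant community types; driver
# families (Bacteroidaceae, Clostridiaceae) differ by far more than the
# 10-fold concentration-mass ratio the downstream recovery assumes
_TYPE_A_REL = {"Bacteroidaceae": 0.32, "Tannerellaceae": 0.05,
               "Rikenellaceae": 0.03, "Clostridiaceae": 0.004,
               "Enterobacteriaceae": 0.22, "Bifidobacteriaceae": 0.22,
               "Lachnospiraceae": 0.06, "Veillonellaceae": 0.04,
               "Oscillospiraceae": 0.03, "Streptococcaceae": 0.026}
_TYPE_B_REL = {"Bacteroidaceae": 0.0005, "Tannerellaceae": 0.001,
               "Rikenellaceae": 0.001, "Clostridiaceae": 0.12,
               "Enterobacteriaceae": 0.33, "Bifidobacteriaceae": 0.30,
               "Lachnospiraceae": 0.09, "Veillonellaceae": 0.07,
               "Oscillospiraceae": 0.05, "Streptococcaceae": 0.0375}
_MOTHER_REL = {"Bacteroidaceae": 0.18, "Tannerellaceae": 0.04,
               "Rikenellaceae": 0.04, "Clostridiaceae": 0.02,
               "Enterobacteriaceae": 0.03, "Bifidobacteriaceae": 0.04,
               "Lachnospiraceae": 0.32, "Veillonellaceae": 0.03,
               "Oscillospiraceae": 0.25, "Streptococcaceae": 0.05}

DEFAULT_GENUS_SPLIT = {
    "Bacteroidaceae": {"Bacteroides": 0.85, "Phocaeicola": 0.15},
    "Tannerellaceae": {"Parabacteroides": 1.0},
    "Rikenellaceae": {"Alistipes": 1.0},
    "Clostridiaceae": {"Clostridium": 1.0},
    "Enterobacteriaceae": {"Escherichia": 1.0},
    "Bifidobacteriaceae": {"Bifidobacterium": 1.0},
    "Lachnospiraceae": {"Blautia": 0.6, "Anaerostipes": 0.4},
    "Veillonellaceae": {"Veillonella": 1.0},
    "Oscillospiraceae": {"Faecalibacterium": 1.0},
    "Streptococcaceae": {"Streptococcus": 1.0},
}

# additive log-scale concentration shifts per timepoint: the weaning-age
# rise of adult-associated fibre degraders
DEFAULT_AGE_DRIFT = {
    "3w": {},
    "3m": {"Lachnospiraceae": 0.3, "Oscillospiraceae": 0.3},
    "6m": {"Lachnospiraceae": 0.6, "Oscillospiraceae": 0.6},
    "12m": {"Lachnospiraceae": 1.0, "Oscillospiraceae": 1.0},
}

# P(trajectory | birth mode); stable_A never occurs after caesarean birth
DEFAULT_BIRTH_MODE_RULE = {
    "VD": {"stable_A": 0.576, "stable_B": 0.091, "intermediary": 0.333},
    "CS": {"stable_A": 0.0, "stable_B": 0.231, "intermediary": 0.769},
}

TRAJECTORIES = ["stable_A", "stable_B", "intermediary"]


def _as_conc(rel: dict[str, float]) -> pd.Series:
    s = pd.Series(rel, dtype=float).reindex(FAMILIES)
    return s * _CONC_TOTAL


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort; defaults are the study-shaped
    conditions described in the module docstring."""

    n_subjects: int = 80
    timepoints: list[str] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    include_mothers: bool = False
    trajectory_probs: tuple[float, float, float] = (0.41, 0.13, 0.46)
    birth_mode_rule: dict[str, dict[str, float]] | None = field(
        default_factory=lambda: {m: dict(d) for m, d in DEFAULT_BIRTH_MODE_RULE.items()})
    p_cs: float = 0.30
    p_iap_vd: float = 0.42
    base_composition_A: pd.Series = field(default_factory=lambda: _as_conc(_TYPE_A_REL))
    base_composition_B: pd.Series = field(default_factory=lambda: _as_conc(_TYPE_B_REL))
    mother_composition: pd.Series = field(default_factory=lambda: _as_conc(_MOTHER_REL))
    age_drift: dict[str, dict[str, float]] = field(
        default_factory=lambda: {t: dict(d) for t, d in DEFAULT_AGE_DRIFT.items()})
    depth_log_mean: float = math.log(5e6)
    depth_log_sd: float = 0.4
    intermediary_switch_prob: float = 0.5
    genus_split: dict[str, dict[str, float]] = field(
        default_factory=lambda: {f: dict(g) for f, g in DEFAULT_GENUS_SPLIT.items()})
    transmission_bias: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.trajectory_probs) - 1) > 1e-9 or min(self.trajectory_probs) < 0:
            raise ValueError("trajectory_probs must be a probability triple")
        if self.birth_mode_rule is not None:
            for mode, probs in self.birth_mode_rule.items():
                vals = [probs.get(t, 0.0) for t in TRAJECTORIES]
                if abs(sum(vals) - 1) > 1e-9 or min(vals) < 0:
                    raise ValueError(
                        f"birth_mode_rule[{mode!r}] is not a probability triple")
        for name in ("base_composition_A", "base_composition_B",
                     "mother_composition"):
            conc = getattr(self, name)
            if conc.isna().any() or (conc <= 0).any():
                raise ValueError(f"{name} must be strictly positive over {FAMILIES}")
        if list(self.base_composition_A.index) != list(self.base_composition_B.index):
            raise ValueError("type A and B concentration vectors must share a panel")
        for fam, split in self.genus_split.items():
            if abs(sum(split.values()) - 1) > 1e-9 or min(split.values()) < 0:
                raise ValueError(f"genus_split[{fam!r}] proportions must sum to 1")
        if not (0 <= self.intermediary_switch_prob <= 1):
            raise ValueError("intermediary_switch_prob must lie in [0, 1]")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be non-negative")


@dataclass
class PlantedTruth:
    """Ground truth planted by :func:`generate_cohort`."""

    trajectory: dict[str, str] = field(default_factory=dict)           # subject -> class
    community_type: dict[str, str] = field(default_factory=dict)       # sample -> A/B
    birth_mode: dict[str, str] = field(default_factory=dict)           # subject -> VD/CS
    bacteroides_group: dict[str, str] = field(default_factory=dict)    # subject -> present/depleted
    differential_pathways: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {"trajectory": self.trajectory,
                "community_type": self.community_type,
                "birth_mode": self.birth_mode,
                "bacteroides_group": self.bacteroides_group,
                "differential_pathways": self.differential_pathways}


def _subject_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def _type_sequence(trajectory: str, birth_mode: str, n_tp: int,
                   switch_prob: float, rng: np.random.Generator) -> list[str]:
    """Community-type letters over timepoints, consistent with the class.

    Intermediary subjects flip type between intervals with ``switch_prob``;
    the draw is conditioned on at least one flip so the planted class is
    observable in the realized sequence (a forced flip at a random interval
    when none occurred).  Caesarean-born subjects always start in type B.
    """
    if trajectory == "stable_A":
        return ["A"] * n_tp
    if trajectory == "stable_B":
        return ["B"] * n_tp
    start = "B" if birth_mode == "CS" else ("A" if rng.random() < 0.5 else "B")
    if n_tp == 1:
        return [start]
    flips = rng.random(n_tp - 1) < switch_prob
    if not flips.any():
        flips[rng.integers(0, n_tp - 1)] = True
    seq = [start]
    for f in flips:
        cur = seq[-1]
        seq.append(({"A": "B", "B": "A"}[cur]) if f else cur)
    return seq


def generate_cohort(config: CohortConfig,
                    ) -> tuple[AbundanceTable, SampleMetadata, PlantedTruth]:
    """Draw a full synthetic cohort: genus-level counts, metadata, truth."""
    config.validate()
    if config.n_subjects <= 0 and not config.include_mothers:
        if not config.timepoints:
            raise ValueError("nothing to generate: no subjects, mothers or "
                             "timepoints configured")

    genera: list[str] = []
    genus_family: dict[str, str] = {}
    for fam in config.base_composition_A.index:
        for gen in config.genus_split.get(fam, {fam: 1.0}):
            genera.append(gen)
            genus_family[gen] = fam
    split_vec = {fam: np.array(list(config.genus_split.get(fam, {fam: 1.0}).values()))
                 for fam in config.base_composition_A.index}

    families = list(config.base_composition_A.index)
    conc_by_type = {"A": config.base_composition_A.to_numpy(float),
                    "B": config.base_composition_B.to_numpy(float)}
    drift_vecs = {}
    for tp in config.timepoints:
        shift = config.age_drift.get(tp, {})
        drift_vecs[tp] = np.exp([shift.get(f, 0.0) for f in families])

    columns: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    truth = PlantedTruth()
    n_tp = len(config.timepoints)

    def draw_sample(rng, conc_fam):
        rel_fam = rng.dirichlet(conc_fam)
        probs = []
        for fi, fam in enumerate(families):
            probs.append(rel_fam[fi] * split_vec[fam])
        p = np.concatenate(probs)
        p = p / p.sum()
        depth = max(1, int(round(rng.lognormal(config.depth_log_mean,
                                               config.depth_log_sd))))
        return rng.multinomial(depth, p).astype(float)

    for i in range(max(config.n_subjects, 0)):
        subject = f"S{i:03d}"
        rng = _subject_rng(config.seed, i)
        birth_mode = "CS" if rng.random() < config.p_cs else "VD"
        iap = "yes" if birth_mode == "CS" else (
            "yes" if rng.random() < config.p_iap_vd else "no")
        if config.birth_mode_rule is not None:
            probs = [config.birth_mode_rule[birth_mode].get(t, 0.0)
                     for t in TRAJECTORIES]
        else:
            probs = list(config.trajectory_probs)
        trajectory = TRAJECTORIES[rng.choice(3, p=probs)]
        types = _type_sequence(trajectory, birth_mode, n_tp,
                               config.intermediary_switch_prob, rng)
        truth.trajectory[subject] = trajectory
        truth.birth_mode[subject] = birth_mode
        if types:
            truth.bacteroides_group[subject] = (
                "depleted" if types[0] == "B" else "present")
        breastfeeding = float(np.round(rng.uniform(4, 12), 1))
        solids_age = int(rng.integers(18, 32))
        abx = int(rng.poisson(0.4))
        for tp, ctype in zip(config.timepoints, types):
            sid = f"{subject}_{tp}"
            conc = conc_by_type[ctype] * drift_vecs[tp]
            columns[sid] = draw_sample(rng, conc)
            truth.community_type[sid] = ctype
            meta_rows[sid] = {"subject_id": subject, "timepoint": tp,
                              "birth_mode": birth_mode, "iap": iap,
                              "breastfeeding_months": breastfeeding,
                              "solids_age_weeks": solids_age,
                              "abx_courses_year1": abx}
        if config.include_mothers:
            mrng = _subject_rng(config.seed, i, 1)
            conc = config.mother_composition.to_numpy(float).copy()
            if config.transmission_bias and types and types[0] == "A":
                bi = families.index("Bacteroidaceae")
                conc[bi] *= math.exp(config.transmission_bias)
            sid = f"{subject}_mother"
            columns[sid] = draw_sample(mrng, conc)
            meta_rows[sid] = {"subject_id": subject,
                              "timepoint": MOTHER_TIMEPOINT,
                              "birth_mode": "NA", "iap": "NA",
                              "breastfeeding_months": np.nan,
                              "solids_age_weeks": np.nan,
                              "abx_courses_year1": np.nan}

    data = pd.DataFrame(columns, index=pd.Index(genera, name="genus"))
    if not columns:
        data = pd.DataFrame(index=pd.Index(genera, name="genus"))
    lineages = {g: {"family": genus_family[g], "genus": g} for g in genera}
    table = AbundanceTable(data.astype(float), rank="genus",
                           value_kind="counts", lineages=lineages)
    meta_df = pd.DataFrame.from_dict(meta_rows, orient="index")
    if meta_df.empty:
        meta_df = pd.DataFrame(columns=["subject_id", "timepoint",
                                        "birth_mode", "iap"])
    metadata = SampleMetadata(meta_df, timepoint_order=list(config.timepoints))
    return table, metadata, truth


# ---------------------------------------------------------------------------
# pathway profiles
# ---------------------------------------------------------------------------

BACTEROIDES_CLADE = ["Bacteroides", "Phocaeicola", "Parabacteroides", "Alistipes"]
_BACTEROIDES_PATHWAYS = ["beta-mannan degradation",
                         "chondroitin sulfate degradation",
                         "starch degradation I",
                         "sphingolipid biosynthesis",
                         "succinate fermentation"]
_CLOSTRIDIUM_PATHWAYS = ["butanoate fermentation",
                         "spore coat biosynthesis",
                         "glycine reductase pathway"]
_HOUSEKEEPING_PATHWAYS = ["glycolysis I", "TCA cycle",
                          "pyruvate fermentation to acetate",
                          "amino acid biosynthesis", "nucleotide biosynthesis",
                          "fatty acid biosynthesis", "cofactor biosynthesis",
                          "peptidoglycan biosynthesis", "purine salvage",
                          "queuosine biosynthesis"]


def default_pathway_mixing(genera: list[str]) -> pd.DataFrame:
    """Taxa x pathway loading matrix: clade-specific degradation /
    fermentation pathways plus housekeeping pathways carried by everyone."""
    pathways = (_BACTEROIDES_PATHWAYS + _CLOSTRIDIUM_PATHWAYS
                + _HOUSEKEEPING_PATHWAYS)
    mix = pd.DataFrame(0.0, index=genera, columns=pathways)
    for p in _BACTEROIDES_PATHWAYS:
        for g in BACTEROIDES_CLADE:
            if g in mix.index:
                mix.loc[g, p] = 1.0
    for p in _CLOSTRIDIUM_PATHWAYS:
        if "Clostridium" in mix.index:
            mix.loc["Clostridium", p] = 1.0
    for p in _HOUSEKEEPING_PATHWAYS:
        mix[p] = 0.5
    return mix


def planted_differential_pathways() -> list[str]:
    """Pathways whose abundance is structurally tied to one community type."""
    return list(_BACTEROIDES_PATHWAYS + _CLOSTRIDIUM_PATHWAYS)


def generate_pathway_profiles(taxa_rel: AbundanceTable, mixing: pd.DataFrame,
                              noise_sd: float = 0.2,
                              seed: int = 0) -> AbundanceTable:
    """Pathway abundances as taxa relative abundances times the loading
    matrix, with multiplicative log-normal noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    missing = [t for t in taxa_rel.feature_ids if t not in mixing.index]
    if missing:
        raise ValueError(f"mixing matrix lacks rows for taxa: {missing}")
    mix = mixing.loc[taxa_rel.feature_ids]
    vals = mix.to_numpy(float).T @ taxa_rel.data.to_numpy(float)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        vals = vals * np.exp(rng.normal(0.0, noise_sd, size=vals.shape))
    df = pd.DataFrame(vals, index=mix.columns, columns=taxa_rel.sample_ids)
    sums = df.sum(axis=0).to_numpy()
    kind = ("relative" if sums.size and np.allclose(sums, 1.0, atol=1e-9)
            else "abundance")
    return AbundanceTable(df, rank="pathway", value_kind=kind)


# ---------------------------------------------------------------------------
# planted differential feature matrix (model-calibration fixture generator)
# ---------------------------------------------------------------------------

def simulate_differential_features(n_per_group: int = 40, n_features: int = 400,
                                   n_differential: int = 20,
                                   fold_change: float = 4.0,
                                   dispersion: float = 0.5,
                                   depth: int = 100_000,
                                   depth_cv: float = 0.2,
                                   differential_mass: float = 0.002,
                                   direction: str = "both",
                                   seed: int = 0,
                                   ) -> tuple[AbundanceTable, pd.DataFrame, list[str]]:
    """Two-group count matrix with a planted fold change on a feature subset.

    Features are independent negative-binomial counts around lognormal
    baseline means scaled by a per-sample depth factor; the first
    ``n_differential`` features carry a ``fold_change`` perturbation in
    group B — half up and half down for ``direction="both"`` (real cluster
    comparisons enrich pathways in both groups, and a balanced set also
    respects TMM's mostly-non-differential, symmetric-change assumption),
    or all up for ``direction="up"``.  The differential features jointly
    carry only ``differential_mass`` of the expected library so that the
    perturbation barely moves library totals and the remaining features
    stay effectively null after total-sum scaling.  The default panel size
    matches the scale of a prokaryotic MetaCyc pathway table (~400
    pathways).  Returns (counts table, per-sample metadata with a ``group``
    column, list of truly differential feature ids).  Useful both for power
    checks (fold_change > 1) and null calibration (``n_differential=0``).
    """
    if direction not in ("both", "up"):
        raise ValueError("direction must be 'both' or 'up'")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_features)
    if n_differential:
        base[:n_differential] *= (differential_mass / base[:n_differential].sum())
        base[n_differential:] *= ((1 - differential_mass)
                                  / base[n_differential:].sum())
    else:
        base /= base.sum()
    groups = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    depths = depth * np.exp(rng.normal(0, depth_cv, size=n))
    fids = [f"F{j:04d}" for j in range(n_features)]
    diff = fids[:n_differential]
    effect = np.ones(n_features)
    effect[:n_differential] = fold_change
    if direction == "both":
        effect[:n_differential // 2] = 1.0 / fold_change
    mat = np.zeros((n_features, n))
    for s in range(n):
        mean = base.copy()
        if groups[s] == "B" and n_differential:
            mean *= effect
        mean = mean * depths[s]
        if dispersion > 0:
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, mean / shape)
        else:
            lam = mean
        mat[:, s] = rng.poisson(lam)
    sids = [f"{g}{i:03d}" for i, g in enumerate(groups)]
    table = AbundanceTable(pd.DataFrame(mat, index=fids, columns=sids),
                           rank="pathway", value_kind="counts")
    meta = pd.DataFrame({"group": groups}, index=sids)
    return table, meta, diff
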