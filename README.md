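# bbtraj

Community typing and longitudinal trajectory analysis for infant gut
microbiota, centred on the birth-mode-linked depletion of *Bacteroides*.

## The problem

Shotgun-metagenomic birth cohorts sample infants repeatedly over the first
year of life (here: 3 weeks, 3, 6 and 12 months, plus mothers in late
pregnancy) and ask how the community assembles: do samples fall into
recurring community types, do individual infants stay on one developmental
trajectory, and which perinatal exposures (birth mode, intrapartum
antibiotics, breastfeeding) explain the differences?  A recurring
observation is a *Bacteroides*-depleted community — universal after
caesarean section but also present in a substantial minority of vaginally
delivered infants.

`bbtraj` implements the statistical machinery for this analysis as a
tested, reusable Python library:

- **Compositional analysis** — centred log-ratio transform
  (`clr_i = ln x_i − mean_j ln x_j`, zeros replaced by one count) and the
  Aitchison distance (Euclidean on CLR coordinates); Bray-Curtis and
  presence-absence Jaccard dissimilarities; Shannon and bias-corrected
  Chao1 (`S_obs + f1(f1−1)/(2(f2+1))`) indices.
- **Community typing** — Ward.D2 agglomerative clustering on the Aitchison
  distance matrix (Lance-Williams recurrence on squared dissimilarities,
  heights on the original scale), with the number of clusters chosen by
  maximising the mean silhouette width `(b − a)/max(a, b)`, and cluster
  labels aligned across timepoints by the mean relative abundance of an
  anchor family (*Bacteroidaceae*).
- **PERMANOVA** — a from-scratch one-way permutational MANOVA,
  `F = ((SS_total − SS_within)/(k−1)) / (SS_within/(n−k))` with
  `p = (1 + #{F_perm ≥ F_obs})/(1 + B)`, plus an exact-enumeration variant
  for small designs.
- **Trajectories** — per-subject classification of aligned label sequences
  into stable-A (high *Bacteroidaceae*), stable-B and intermediary
  (switching) trajectories; *Bacteroides*-present vs -depleted groups by a
  strict 1 % relative-abundance cutoff at the first timepoint; interval
  transition tables.
- **Association statistics** — Fisher exact (2×2 and enumerated r×c),
  exact/asymptotic Wilcoxon rank-sum, pairwise Wilcoxon with joint BH-FDR,
  Cochran–Mantel–Haenszel and van Elteren stratified tests for
  birth-mode-confounded exposures, MaAsLin2-style per-feature linear
  models (TSS → log2 with half-minimum pseudo-count → OLS) and
  negative-binomial models with TMM (trimmed mean of M-values) offsets,
  and the A.R.E. minimum-detectable-effect calculation for the Wilcoxon
  test.
- **k-mer distances** — annotation-free sample comparison via canonical
  k-mer counting (abundance-min filter, reservoir read equalization) and
  abundance-weighted Bray-Curtis.
- **Synthetic cohorts** — a Dirichlet-multinomial generator that plants
  community types, trajectory classes, birth-mode confounding, age drift,
  sequencing-depth variation and taxa-linked pathway profiles, with full
  ground truth, so that every stage of the pipeline is testable end to end
  without access to cohort data.

## Worked example

```python
from bbtraj import (CohortConfig, generate_cohort, aitchison_distance,
                    select_k, align_labels, permanova,
                    assign_trajectories, mdes_wilcoxon)
from bbtraj.io import aggregate_rank, filter_features
from bbtraj.trajectories import aligned_label_frame

table, metadata, truth = generate_cohort(CohortConfig(n_subjects=80, seed=1))
family = filter_features(aggregate_rank(table, "family"),
                         detection=0.01, prevalence=0.005)

solutions = []
for tp in metadata.infant_timepoints():
    dm = aitchison_distance(family.subset_samples(metadata.samples_at(tp)))
    sol = select_k(dm, timepoint=tp)
    res = permanova(dm, sol.labels, n_perm=999, seed=7)
    print(tp, "k =", sol.k, "silhouette = %.3f" % sol.mean_silhouette,
          "PERMANOVA p =", res.p_value)
    solutions.append(sol)

align_labels(solutions, family, anchor_taxon="Bacteroidaceae")
assignments = assign_trajectories(aligned_label_frame(solutions, metadata))
from collections import Counter
print(Counter(a.trajectory for a in assignments))
print("MDES d =", round(mdes_wilcoxon(21, 32), 3))
```

prints

```
3w k = 2 silhouette = 0.680 PERMANOVA p = 0.001
3m k = 2 silhouette = 0.686 PERMANOVA p = 0.001
6m k = 2 silhouette = 0.681 PERMANOVA p = 0.001
12m k = 2 silhouette = 0.671 PERMANOVA p = 0.001
Counter({'stable_A': 36, 'intermediary': 33, 'stable_B': 11})
MDES d = 0.821
```

Each timepoint's samples split into two community types (k = 2 with a
clear silhouette), the split is confirmed at the permutation floor
p = 0.001 (999 permutations), subjects fall into the two stable and one
switching trajectory, and at group sizes 21 vs 32 a Wilcoxon comparison at
α = 0.05 can reliably detect only effects of about d ≥ 0.82 at 80 % power.

The same analysis is available from the shell:

```bash
bbtraj run --n-subjects 80 --seed 1 --out-dir out/
bbtraj power --n1 21 --n2 32
```

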