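import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from bbtraj.composition import DistanceMatrix
from bbtraj.io import aggregate_rank, filter_features
from bbtraj.synthetic import CohortConfig, generate_cohort
from bbtraj.tables import AbundanceTable, SampleMetadata


def euclidean_dm(points, ids=None) -> DistanceMatrix:
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] == 1:
        pts = pts.T
    if ids is None:
        ids = [f"s{i}" for i in range(pts.shape[0])]
    return DistanceMatrix(squareform(pdist(pts)), ids=ids, metric="euclidean")


def run_timepoint_clustering(table, metadata, timepoints=None):
    """Family-filter + per-timepoint Ward/silhouette clustering, aligned."""
    from bbtraj.cluster import align_labels, select_k
    from bbtraj.composition import aitchison_distance

    fam = filter_features(aggregate_rank(table, "family"), 0.01, 0.005)
    sols = []
    for tp in (timepoints or metadata.infant_timepoints()):
        sids = metadata.samples_at(tp)
        sols.append(select_k(aitchison_distance(fam.subset_samples(sids)),
                             timepoint=tp))
    align_labels(sols, fam)
    return fam, sols


@pytest.fixture(scope="session")
def default_cohort():
    """One 80-subject cohort with planted truth, shared across tests."""
    return generate_cohort(CohortConfig(n_subjects=80, seed=1))


@pytest.fixture
def small_counts_table():
    data = pd.DataFrame(
        {"s1": [10.0, 5.0, 0.0], "s2": [2.0, 2.0, 6.0], "s3": [1.0, 0.0, 9.0]},
        index=["Bacteroides", "Phocaeicola", "Clostridium"])
    lineages = {
        "Bacteroides": {"family": "Bacteroidaceae", "genus": "Bacteroides"},
        "Phocaeicola": {"family": "Bacteroidaceae", "genus": "Phocaeicola"},
        "Clostridium": {"family": "Clostridiaceae", "genus": "Clostridium"},
    }
    return AbundanceTable(data, rank="genus", value_kind="counts",
                          lineages=lineages)


@pytest.fixture
def small_metadata():
    df = pd.DataFrame(
        {"subject_id": ["a", "a", "b"], "timepoint": ["3w", "3m", "3w"],
         "birth_mode": ["VD", "VD", "CS"], "iap": ["no", "no", "yes"]},
        index=["s1", "s2", "s3"])
    return SampleMetadata(df)
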