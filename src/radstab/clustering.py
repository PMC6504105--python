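"""Stable/Unstable feature split, patient clustering, clinical associations.

Features are partitioned at a population 4D COV of 5% (Stable <= 5% <
Unstable; an undefined COV counts as Unstable).  Patients are clustered
on the Stable block only (average linkage, Euclidean distance, features
z-scored), the dendrogram cut into k = 3 clusters; the Unstable block is
re-ordered by its own feature dendrogram but keeps the Stable patient
order.  Cluster-clinical associations use Kruskal-Wallis for the
continuous pack-years and plain chi-square independence tests (no
continuity correction) for the categorical parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

STABLE_CUTOFF = 5.0  # percent


def split_features(mean_cov: pd.Series, cutoff: float = STABLE_CUTOFF) -> tuple[list[str], list[str]]:
    """Partition features into Stable (COV <= cutoff) and Unstable.

    NaN (undefined COV) goes to Unstable.
    """
    stable = [f for f, c in mean_cov.items() if np.isfinite(c) and c <= cutoff]
    unstable = [f for f in mean_cov.index if f not in stable]
    return stable, unstable


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    return (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)


def _feature_order(X: np.ndarray, names: list[str]) -> list[str]:
    if len(names) < 2:
        return list(names)
    Z = linkage(_zscore(X).T, method="average", metric="euclidean")
    return [names[i] for i in leaves_list(Z)]


@dataclass
class ClusterAssignment:
    """Patient cluster labels plus display orderings for the heatmap."""

    labels: pd.Series  # per patient, 1..k
    patient_order: list[str]
    stable_feature_order: list[str]
    unstable_feature_order: list[str]

    @property
    def k(self) -> int:
        return int(self.labels.nunique())


def cluster_patients(
    features: pd.DataFrame,
    mean_cov: pd.Series,
    k: int = 3,
    standardize: bool = True,
) -> ClusterAssignment:
    """Unsupervised patient clustering on the Stable feature block.

    Average-linkage hierarchical clustering on Euclidean distances of the
    (z-scored) Stable features, cut into ``k`` clusters; the patient
    display order is the dendrogram leaf order.  Feature dendrograms are
    computed separately for the Stable and Unstable blocks; the Unstable
    block reuses the patient order.
    """
    if k > len(features):
        raise ValueError("k cannot exceed the number of patients")
    stable, unstable = split_features(mean_cov.reindex(features.columns))
    if not stable:
        raise ValueError("no Stable features to cluster on")
    Xs = features[stable].to_numpy(dtype=float)
    if standardize:
        Xs = _zscore(Xs)
    patients = list(features.index)
    if len(patients) > 1:
        Z = linkage(Xs, method="average", metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
        patient_order = [patients[i] for i in leaves_list(Z)]
    else:
        labels = np.ones(1, dtype=int)
        patient_order = patients
    return ClusterAssignment(
        labels=pd.Series(labels, index=patients, name="cluster"),
        patient_order=patient_order,
        stable_feature_order=_feature_order(features[stable].to_numpy(float), stable),
        unstable_feature_order=_feature_order(features[unstable].to_numpy(float), unstable) if unstable else [],
    )


CONTINUOUS_PARAMS = ("pack_years",)


def association_tests(assignment: ClusterAssignment, clinical: pd.DataFrame) -> pd.DataFrame:
    """Cluster-clinical association P-values.

    Kruskal-Wallis across clusters for continuous parameters
    (pack-years); chi-square independence on the cluster x category
    contingency table for the rest.  A parameter with a single level is
    flagged undefined; a warning is emitted when any expected cell count
    is below 5.
    """
    labels = assignment.labels.reindex(clinical.index)
    if labels.nunique() < 2:
        raise ValueError("need at least 2 clusters")
    rows = []
    for col in clinical.columns:
        vals = clinical[col]
        if col in CONTINUOUS_PARAMS:
            groups = [vals[labels == g].to_numpy(float) for g in sorted(labels.unique())]
            if len(np.unique(np.concatenate(groups))) < 2:
                rows.append({"parameter": col, "test": "kruskal_wallis", "statistic": np.nan, "p": np.nan, "flag": "single_level"})
                continue
            stat, p = stats.kruskal(*groups)
            rows.append({"parameter": col, "test": "kruskal_wallis", "statistic": stat, "p": p, "flag": ""})
        else:
            table = pd.crosstab(labels, vals)
            if table.shape[1] < 2:
                rows.append({"parameter": col, "test": "chi2", "statistic": np.nan, "p": np.nan, "flag": "single_level"})
                continue
            res = stats.chi2_contingency(table.to_numpy(), correction=False)
            flag = ""
            if (res.expected_freq < 5).any():
                flag = "expected<5"
                warnings.warn(f"{col}: expected cell count < 5; chi-square approximation is rough")
            rows.append({"parameter": col, "test": "chi2", "statistic": res.statistic, "p": res.pvalue, "flag": flag})
    return pd.DataFrame(rows).set_index("parameter")
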