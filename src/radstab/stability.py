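"""Inter-phase stability of radiomic features on 4D respiratory CT.

For every (patient, feature) the variability across the breathing phases
is summarized by the coefficient of variation

    COV = |SD / mean| * 100  (percent),

with the sample standard deviation (n-1 denominator) over the phases.
Per feature, the population mean COV (average over patients) drives a
four-tier stability categorization (Very Small <= 5% < Small <= 10% <
Intermediate <= 20% < Large) and a five-bin histogram that splits the
Intermediate tier at 15%.  Tumor motion is summarized per patient as the
maximum pairwise 3D distance between the phase centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

CATEGORIES = ("VerySmall", "Small", "Intermediate", "Large")
CATEGORY_EDGES = (5.0, 10.0, 20.0)  # right-closed upper bounds of the first 3 tiers
HISTOGRAM_BINS = ("<=5", "5-10", "10-15", "15-20", ">20")
HISTOGRAM_EDGES = (5.0, 10.0, 15.0, 20.0)
HEATMAP_CAP = 20.0  # display/clustering cap: colors saturate at >=20%


@dataclass
class PhaseFeatureTensor:
    """Per-patient, per-phase feature values plus phase centroids.

    ``values`` has shape (n_patients, n_phases, n_features); ``centroids``
    has shape (n_patients, n_phases, 3) in mm.
    """

    values: np.ndarray
    feature_names: list[str]
    patient_ids: list[str]
    centroids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (patients, phases, features)")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 phases")
        if self.values.shape[2] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")
        if self.values.shape[0] != len(self.patient_ids):
            raise ValueError("patient_ids length mismatch")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_phases(self) -> int:
        return self.values.shape[1]

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy long format: patient_id, phase, feature, value."""
        p, ph, f = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.patient_ids, range(ph), self.feature_names],
            names=["patient_id", "phase", "feature"],
        )
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame, centroids: pd.DataFrame | None = None) -> "PhaseFeatureTensor":
        wide = df.pivot_table(index=["patient_id", "phase"], columns="feature", values="value", sort=False, dropna=False)
        patients = list(dict.fromkeys(df["patient_id"]))
        features = list(wide.columns)
        n_phases = df["phase"].nunique()
        values = np.empty((len(patients), n_phases, len(features)))
        for i, pid in enumerate(patients):
            values[i] = wide.loc[pid].to_numpy()
        cents = None
        if centroids is not None:
            cents = np.empty((len(patients), n_phases, 3))
            for i, pid in enumerate(patients):
                sub = centroids[centroids["patient_id"] == pid].sort_values("phase")
                cents[i] = sub[["x_mm", "y_mm", "z_mm"]].to_numpy()
        return cls(values, features, patients, cents)


def compute_cov(values) -> float:
    """Coefficient of variation, percent: 100 * |sample SD / mean|.

    Returns NaN (the undefined sentinel) when the mean is exactly zero;
    callers must treat NaN as "undefined", never as 0 or infinity.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("COV needs at least 2 finite values")
    if v.max() == v.min():  # exactly constant: SD = 0 by definition
        return float("nan") if v[0] == 0.0 else 0.0
    m = v.mean()
    if m == 0.0:
        return float("nan")
    return float(100.0 * abs(v.std(ddof=1) / m))


def compute_cov_matrix(values: np.ndarray) -> np.ndarray:
    """Vectorized COV over axis 1 of a (patients, phases, features) array."""
    v = np.asarray(values, dtype=float)
    m = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = 100.0 * np.abs(sd / m)
    constant = np.ptp(v, axis=1) == 0  # exactly constant: SD = 0 by definition
    cov[constant & (m != 0)] = 0.0
    cov[m == 0.0] = np.nan
    return cov


def population_mean_cov(individual_covs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean of individual COVs over patients with a defined COV.

    Parameters
    ----------
    individual_covs : (patients, features) array, NaN = undefined.

    Returns
    -------
    mean_cov : (features,) array; NaN when no patient had a defined COV.
    n_excluded : (features,) int array of undefined patients per feature.
    """
    c = np.asarray(individual_covs, dtype=float)
    n_excluded = np.isnan(c).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean_cov = np.nanmean(np.where(np.isnan(c), np.nan, c), axis=0)
    return mean_cov, n_excluded


def categorize_cov(cov: float) -> tuple[str, str]:
    """Map a population COV (percent) to (category, histogram bin).

    Boundaries are right-closed as printed: 5.0 -> VerySmall, 10.0 ->
    Small, 20.0 -> Intermediate.  An undefined COV (NaN) is assigned
    Large / ">20", the conservative choice.
    """
    if np.isnan(cov):
        return "Large", ">20"
    if cov < 0:
        raise ValueError("COV cannot be negative")
    if cov <= 5.0:
        return "VerySmall", "<=5"
    if cov <= 10.0:
        return "Small", "5-10"
    if cov <= 15.0:
        return "Intermediate", "10-15"
    if cov <= 20.0:
        return "Intermediate", "15-20"
    return "Large", ">20"


def motion_magnitude(centroids) -> float:
    """Maximum pairwise 3D excursion (mm) among phase centroids."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 centroids")
    return float(pdist(pts).max())


@dataclass
class StabilityTable:
    """Per-feature stability summary plus the per-patient COV matrix."""

    individual_cov: pd.DataFrame  # patients x features, NaN = undefined
    summary: pd.DataFrame  # per feature: mean_cov, n_excluded, category, bin
    motion: pd.Series | None = None  # per patient motion magnitude (mm)

    @property
    def mean_cov(self) -> pd.Series:
        return self.summary["mean_cov"]

    def to_csv(self, path) -> None:
        self.summary.to_csv(path)


def stability_table(tensor: PhaseFeatureTensor) -> StabilityTable:
    """Full stability analysis of a phase-feature tensor."""
    covs = compute_cov_matrix(tensor.values)
    individual = pd.DataFrame(covs, index=tensor.patient_ids, columns=tensor.feature_names)
    mean_cov, n_excl = population_mean_cov(covs)
    cats, bins = zip(*(categorize_cov(c) for c in mean_cov))
    summary = pd.DataFrame(
        {
            "mean_cov": mean_cov,
            "n_excluded": n_excl,
            "category": cats,
            "bin": bins,
        },
        index=pd.Index(tensor.feature_names, name="feature"),
    )
    motion = None
    if tensor.centroids is not None:
        motion = pd.Series(
            [motion_magnitude(tensor.centroids[i]) for i in range(tensor.n_patients)],
            index=tensor.patient_ids,
            name="motion_mm",
        )
    return StabilityTable(individual, summary, motion)


def cov_heatmap_order(table: StabilityTable) -> tuple[list[str], list[str]]:
    """Row/column orders for the individual-COV heatmap.

    Features are ordered by the leaf order of a complete-linkage
    hierarchical clustering (Euclidean distance) of their per-patient COV
    profiles; COVs are capped at 20% (undefined imputed at the cap) so the
    clustering matches the saturated display scale.  Patients are ordered
    by ascending motion magnitude (ties by patient id); without motion
    data the input order is kept.
    """
    data = table.individual_cov.to_numpy(copy=True)
    data = np.where(np.isnan(data), HEATMAP_CAP, np.minimum(data, HEATMAP_CAP))
    features = list(table.individual_cov.columns)
    if len(features) > 1:
        Z = linkage(data.T, method="complete", metric="euclidean")
        feature_order = [features[i] for i in leaves_list(Z)]
    else:
        feature_order = features
    patients = list(table.individual_cov.index)
    if table.motion is not None:
        patients = sorted(patients, key=lambda p: (table.motion[p], str(p)))
    return feature_order, patients


def summarize_groups(table: StabilityTable, catalog=None) -> pd.DataFrame:
    """Category counts and fractions, overall and split by filter/class.

    When a :class:`~radstab.catalog.FeatureCatalog` is given, features are
    matched to it by full name and the summary is additionally broken down
    by filter label and feature class.
    """
    rows = []
    cats = table.summary["category"]

    def _block(label: str, sub: pd.Series) -> None:
        n = len(sub)
        counts = sub.value_counts()
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            rows.append({"group": label, "category": cat, "count": c, "fraction": c / n if n else np.nan})

    _block("all", cats)
    if catalog is not None:
        frame = catalog.to_frame()
        frame["full_name"] = [e.full_name for e in catalog]
        frame = frame.set_index("full_name")
        matched = frame.reindex(cats.index).dropna(subset=["filter"])
        for filt, sub in matched.groupby("filter", sort=False):
            _block(f"filter:{filt}", cats.loc[sub.index])
        wavelet_idx = matched.index[matched["filter"] != "original"]
        if len(wavelet_idx):
            _block("filter:wavelet(all)", cats.loc[wavelet_idx])
        for cls, sub in matched.groupby("class", sort=False):
            _block(f"class:{cls}", cats.loc[sub.index])
    return pd.DataFrame(rows)
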