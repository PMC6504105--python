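"""The 841-feature radiomic panel taxonomy.

The panel follows the IBSI feature families as implemented by common
radiomics extractors: 105 "original" features (7 classes) plus the same
intensity/texture classes recomputed on the 8 single-level 3D wavelet
subbands (Shape is geometry-only and is never recomputed on filtered
images), giving 8 x 92 = 736 wavelet features and 841 in total.

Only Shape, FirstOrder and GLCM are computable by this package's
extractor; the remaining classes are cataloged for bookkeeping (counts,
category summaries) and raise if their values are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")
#: subband labels in lexicographic {L,H}^3 order with L < H
FILTER_LABELS = ("original",) + tuple(f"wavelet-{s}" for s in WAVELET_SUBBANDS)

COMPUTABLE_CLASSES = frozenset({"Shape", "FirstOrder", "GLCM"})

SHAPE_FEATURES = (
    "MeshVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRSTORDER_FEATURES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

GLCM_FEATURES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLDM_FEATURES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGTDM_FEATURES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

CLASS_FEATURES: dict[str, tuple[str, ...]] = {
    "Shape": SHAPE_FEATURES,
    "FirstOrder": FIRSTORDER_FEATURES,
    "GLCM": GLCM_FEATURES,
    "GLDM": GLDM_FEATURES,
    "GLRLM": GLRLM_FEATURES,
    "GLSZM": GLSZM_FEATURES,
    "NGTDM": NGTDM_FEATURES,
}


@dataclass(frozen=True)
class CatalogEntry:
    """One feature of the panel: (filter, class, name)."""

    filter_label: str
    class_label: str
    feature_name: str

    @property
    def computable(self) -> bool:
        return self.class_label in COMPUTABLE_CLASSES

    @property
    def full_name(self) -> str:
        return f"{self.filter_label}_{self.class_label}_{self.feature_name}"


@dataclass
class FeatureCatalog:
    """The full feature taxonomy; iteration order is deterministic."""

    entries: list[CatalogEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subset(self, *, filter_label: str | None = None, class_label: str | None = None) -> "FeatureCatalog":
        sel = [
            e
            for e in self.entries
            if (filter_label is None or e.filter_label == filter_label)
            and (class_label is None or e.class_label == class_label)
        ]
        return FeatureCatalog(sel)

    @property
    def full_names(self) -> list[str]:
        return [e.full_name for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "filter": [e.filter_label for e in self.entries],
                "class": [e.class_label for e in self.entries],
                "feature": [e.feature_name for e in self.entries],
                "computable": [e.computable for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_catalog() -> FeatureCatalog:
    """Enumerate the full 841-entry panel.

    Original: all 7 classes (13+18+23+14+16+16+5 = 105).  Each of the 8
    wavelet subbands repeats every class except Shape (92 per subband).
    """
    entries: list[CatalogEntry] = []
    for cls, names in CLASS_FEATURES.items():
        for name in names:
            entries.append(CatalogEntry("original", cls, name))
    for sub in WAVELET_SUBBANDS:
        for cls, names in CLASS_FEATURES.items():
            if cls == "Shape":
                continue
            for name in names:
                entries.append(CatalogEntry(f"wavelet-{sub}", cls, name))
    return FeatureCatalog(entries)
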