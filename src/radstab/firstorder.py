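"""First-order (intensity histogram) features of a prepared ROI."""

from __future__ import annotations

import numpy as np

from .roi import PreparedROI

FIRSTORDER_NAMES = (
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


def extract_first_order(roi: PreparedROI) -> dict[str, float]:
    """The 18 first-order features.

    Entropy (base 2) and Uniformity are computed on the fixed-bin-width
    discretized histogram; moments are population moments; Kurtosis is
    uncorrected (a Gaussian scores 3); Skewness/Kurtosis of a constant
    ROI are defined as 0.
    """
    v = roi.intensities.astype(float)
    n = v.size
    mean = v.mean()
    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    var = v.var(ddof=0)
    m2 = var
    m3 = np.mean((v - mean) ** 3)
    m4 = np.mean((v - mean) ** 4)
    robust = v[(v >= p10) & (v <= p90)]

    counts = np.bincount(roi.mask_levels)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    return {
        "Energy": float((v**2).sum()),
        "TotalEnergy": float(roi.voxel_volume * (v**2).sum()),
        "Entropy": entropy,
        "Minimum": float(v.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(v.max()),
        "Mean": float(mean),
        "Median": float(np.median(v)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(v.max() - v.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(v - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0,
        "RootMeanSquared": float(np.sqrt(np.mean(v**2))),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": float(var),
        "Uniformity": uniformity,
    }
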