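"""Gray Level Co-occurrence Matrix features (3D, 13 directions).

Symmetric co-occurrence matrices are accumulated at distance 1 over the
13 unique 3D direction offsets, restricted to voxel pairs inside the
mask, normalized per direction; each of the 23 features is computed per
direction and averaged over directions that contain at least one pair.
Level-dependent normalizers use Ng = the number of discretized gray
levels of the ROI (the highest occupied level).
"""

from __future__ import annotations

import warnings

import numpy as np

from .roi import PreparedROI

GLCM_NAMES = (
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

# 13 unique direction offsets: first nonzero component positive
DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)


def cooccurrence_matrix(levels: np.ndarray, mask: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one direction offset."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, levels.shape):
        start = max(0, -o)
        stop = n - max(0, o)
        sl_a.append(slice(start, stop))
        sl_b.append(slice(start + o, stop + o))
    sl_a, sl_b = tuple(sl_a), tuple(sl_b)
    valid = mask[sl_a] & mask[sl_b]
    la = levels[sl_a][valid] - 1
    lb = levels[sl_b][valid] - 1
    counts = np.zeros((n_levels, n_levels))
    np.add.at(counts, (la, lb), 1.0)
    np.add.at(counts, (lb, la), 1.0)
    return counts


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _direction_features(P: np.ndarray, n_levels: int) -> dict[str, float]:
    ng = n_levels
    i = np.arange(1, ng + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    ux = float((i * px).sum())
    sx2 = float(((i - ux) ** 2 * px).sum())

    diff = np.abs(I - J).astype(int)
    p_diff = np.bincount(diff.ravel(), weights=P.ravel(), minlength=ng)
    k_diff = np.arange(ng, dtype=float)
    da = float((k_diff * p_diff).sum())
    ssum = (I + J).astype(int)
    p_sum = np.bincount(ssum.ravel(), weights=P.ravel(), minlength=2 * ng + 1)[2:]
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)

    contrast = float((((I - J) ** 2) * P).sum())
    autocorr = float((I * J * P).sum())
    cluster = I + J - 2 * ux

    hxy = _entropy2(P.ravel())
    hx = _entropy2(px)
    outer = px[:, None] * px[None, :]
    nz = (P > 0) & (outer > 0)
    hxy1 = float(-(P[nz] * np.log2(outer[nz])).sum())
    nzo = outer > 0
    hxy2 = float(-(outer[nzo] * np.log2(outer[nzo])).sum())

    if sx2 > 0:
        correlation = (autocorr - ux * ux) / sx2
    else:
        correlation = float("nan")
    if hx > 0:
        imc1 = (hxy - hxy1) / hx
        imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    else:
        imc1 = float("nan")
        imc2 = float("nan")

    off_diag = diff > 0
    with np.errstate(divide="ignore"):
        inv_var = float((P[off_diag] / (I - J)[off_diag] ** 2).sum()) if off_diag.any() else 0.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": ux,
        "ClusterProminence": float((cluster**4 * P).sum()),
        "ClusterShade": float((cluster**3 * P).sum()),
        "ClusterTendency": float((cluster**2 * P).sum()),
        "Contrast": contrast,
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float((((k_diff - da) ** 2) * p_diff).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((P / (1.0 + (I - J) ** 2 / ng**2)).sum()),
        "Id": float((P / (1.0 + np.abs(I - J))).sum()),
        "Idn": float((P / (1.0 + np.abs(I - J) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float((((I - ux) ** 2) * P).sum()),
    }


def extract_glcm(roi: PreparedROI) -> dict[str, float]:
    """The 23 GLCM features, averaged over the 13 3D directions.

    With a single gray level, Correlation and the information measures
    are undefined: they are returned as NaN with a warning.
    """
    ng = roi.n_levels
    per_dir: list[dict[str, float]] = []
    for off in DIRECTIONS:
        counts = cooccurrence_matrix(roi.levels, roi.mask, off, ng)
        total = counts.sum()
        if total == 0:
            continue
        per_dir.append(_direction_features(counts / total, ng))
    if not per_dir:
        raise ValueError("no in-mask voxel pairs in any direction")
    if ng < 2:
        warnings.warn("single gray level: Correlation/Imc1/Imc2 undefined (NaN)")
    out = {}
    for name in GLCM_NAMES:
        vals = np.array([d[name] for d in per_dir])
        out[name] = float(vals.mean()) if not np.isnan(vals).all() else float("nan")
    return out
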