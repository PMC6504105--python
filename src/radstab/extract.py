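"""Feature-extraction facade: images in, tidy feature tables out.

The computable subset of the panel is Shape + FirstOrder + GLCM on the
original image (54 features) and, optionally, FirstOrder + GLCM on each
of the 8 wavelet subbands.  The remaining catalog classes (GLDM, GLRLM,
GLSZM, NGTDM) are bookkeeping-only and raise if extraction is requested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import COMPUTABLE_CLASSES
from .firstorder import extract_first_order
from .glcm import extract_glcm
from .roi import DEFAULT_BIN_WIDTH, DEFAULT_SPACING, PreparedROI, discretize, prepare_roi
from .shape import extract_shape
from .wavelet import wavelet_subbands

DEFAULT_CLASSES = ("Shape", "FirstOrder", "GLCM")


class NotComputableError(NotImplementedError):
    """Raised when extraction of a catalog-only feature class is requested."""


def extract_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing,
    classes=DEFAULT_CLASSES,
    wavelet: str | None = None,
    new_spacing=DEFAULT_SPACING,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, float]:
    """Extract features from one image/mask pair.

    Returns a flat dict keyed by ``<filter>_<class>_<name>``.  With
    ``wavelet`` set (e.g. ``"haar"``) the intensity/texture classes are
    additionally computed on the 8 undecimated subbands.
    """
    for cls in classes:
        if cls not in COMPUTABLE_CLASSES:
            raise NotComputableError(f"feature class {cls!r} is catalog-only, not computable")
    roi = prepare_roi(image, mask, spacing, new_spacing=new_spacing, bin_width=bin_width)
    out: dict[str, float] = {}
    if "Shape" in classes:
        for k, v in extract_shape(roi.mask, roi.spacing).items():
            out[f"original_Shape_{k}"] = v
    if "FirstOrder" in classes:
        for k, v in extract_first_order(roi).items():
            out[f"original_FirstOrder_{k}"] = v
    if "GLCM" in classes:
        for k, v in extract_glcm(roi).items():
            out[f"original_GLCM_{k}"] = v
    if wavelet is not None:
        sub_classes = [c for c in classes if c != "Shape"]
        for label, sub in wavelet_subbands(roi.image, wavelet).items():
            sub_roi = PreparedROI(sub, roi.mask, roi.spacing, bin_width, discretize(sub, roi.mask, bin_width))
            if "FirstOrder" in sub_classes:
                for k, v in extract_first_order(sub_roi).items():
                    out[f"wavelet-{label}_FirstOrder_{k}"] = v
            if "GLCM" in sub_classes:
                for k, v in extract_glcm(sub_roi).items():
                    out[f"wavelet-{label}_GLCM_{k}"] = v
    return out


def extract_phase_set(phase_set, patient_id: str = "P000", **kwargs) -> pd.DataFrame:
    """Extract features from every phase of a 4D image set.

    Returns a tidy frame: patient_id, phase, feature, value.
    """
    rows = []
    for k in range(phase_set.n_phases):
        feats = extract_features(phase_set.images[k], phase_set.masks[k], phase_set.spacing, **kwargs)
        for name, value in feats.items():
            rows.append({"patient_id": patient_id, "phase": k, "feature": name, "value": value})
    return pd.DataFrame(rows)
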