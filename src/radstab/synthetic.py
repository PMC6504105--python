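"""Synthetic study-data generators with known ground truth.

Every input the real study measured on patients can be emulated here:

* phase-resolved feature tensors with a controlled per-feature
  intra-patient COV (percent),
* per-patient sinusoidal superior-inferior tumor trajectories whose
  maximum pairwise 3D excursion is exact,
* 4D image sets (textured ellipsoid translated per phase, plus noise),
* right-censored survival cohorts whose hazard follows a Weibull
  proportional-hazards model on a planted subset of (stable) features,
  with clinical covariates drawn to match the published cohort mix.

Generators are deterministic under a fixed seed, and each returns the
realized ground truth so downstream recovery can be tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .stability import PhaseFeatureTensor
from .survival import SurvivalCohort

PHASE_LABELS_8 = (
    "0%in", "25%in", "50%in", "75%in", "100%in", "75%ex", "50%ex", "25%ex",
)

#: observation-noise sd (in latent-sd units) contributed per COV percent;
#: an unstable feature (COV 30%) carries noise of 1.5 sd vs. a unit signal
NOISE_SD_PER_COV = 0.05

# Published cohort mix used as generator defaults (categorical proportions)
ECOG_PROBS = (0.29, 0.48, 0.20, 0.04)  # normalized below (rounding)
GENDER_PROBS = {"female": 0.51, "male": 0.49}
ETHNICITY_PROBS = {"caucasian": 0.89, "african_american": 0.11, "other": 0.01}
HISTOLOGY_PROBS = {"adeno": 0.44, "squamous": 0.33, "nos": 0.24}
LOCATION_PROBS = {"RUL": 0.32, "RML": 0.04, "RLL": 0.22, "LUL": 0.26, "LLL": 0.15, "chestwall": 0.01}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``planted_cov`` (percent) controls both the intra-patient phase
    variability of the feature tensor and, in the survival cohort, the
    motion-noise contaminating the observed feature value.
    ``hazard_betas`` are log-hazard coefficients applied to the clean
    (noise-free) feature signals.  ``censor_rate`` is the target fraction
    of censored patients.
    """

    n_patients: int = 20
    n_phases: int = 8
    feature_names: list[str] = field(default_factory=list)
    planted_cov: dict[str, float] = field(default_factory=dict)
    motion_magnitudes: np.ndarray | None = None  # per patient, mm
    hazard_betas: dict[str, float] = field(default_factory=dict)
    baseline_scale: float = 30.0  # Weibull scale, months
    baseline_shape: float = 1.2
    censor_rate: float = 0.59  # fraction censored (41% deceased in the study cohort)
    latent_of: dict[str, int] | None = None  # shared signal structure; default: own latent
    n_patient_groups: int = 1
    group_shift: float = 0.0  # latent-mean separation between planted patient groups
    ecog_group_assoc: float = 0.0  # >0 tilts ECOG by planted group
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("n_phases must be >= 2")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if any(c < 0 for c in self.planted_cov.values()):
            raise ValueError("planted_cov must be >= 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0,1)")
        unknown = set(self.hazard_betas) - set(self.feature_names)
        if unknown:
            raise ValueError(f"hazard_betas reference unknown features: {sorted(unknown)}")

    def cov_of(self, feature: str) -> float:
        return float(self.planted_cov.get(feature, 0.0))

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=[int(self.seed), int(stream)]))


@dataclass
class GroundTruth:
    """Realized truth stored alongside every generated dataset."""

    planted_cov: dict[str, float] = field(default_factory=dict)
    motion_magnitudes: np.ndarray | None = None
    hazard_betas: dict[str, float] = field(default_factory=dict)
    censor_fraction: float | None = None
    patient_groups: np.ndarray | None = None
    clean_signals: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {
            "planted_cov": self.planted_cov,
            "motion_magnitudes": None if self.motion_magnitudes is None else list(map(float, self.motion_magnitudes)),
            "hazard_betas": self.hazard_betas,
            "censor_fraction": self.censor_fraction,
            "patient_groups": None if self.patient_groups is None else list(map(int, self.patient_groups)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Gaussian draws redrawn (not clipped) until positive where mean > 0."""
    out = rng.normal(mean, sd)
    bad = (out <= 0) & (mean > 0) & (sd > 0)
    for _ in range(100):
        if not bad.any():
            break
        out[bad] = rng.normal(mean[bad], sd[bad])
        bad = (out <= 0) & (mean > 0) & (sd > 0)
    return out


def gen_phase_feature_tensor(spec: SyntheticSpec) -> tuple[PhaseFeatureTensor, GroundTruth]:
    """Phase-resolved feature values with a planted intra-patient COV.

    Per patient p and feature f a patient-level mean mu_pf is drawn
    log-normally across patients (inter-patient variability); the
    n_phases values are Gaussian around mu_pf with standard deviation
    mu_pf * planted_cov_f / 100, redrawn to stay positive.
    """
    if not spec.feature_names:
        raise ValueError("spec.feature_names is empty")
    rng = spec.rng(stream=1)
    n_p, n_ph, n_f = spec.n_patients, spec.n_phases, len(spec.feature_names)
    covs = np.array([spec.cov_of(f) for f in spec.feature_names])
    mu = np.exp(rng.normal(np.log(100.0), 0.4, size=(n_p, n_f)))
    sd = mu * covs[None, :] / 100.0
    vals = _truncated_normal(rng, np.repeat(mu[:, None, :], n_ph, axis=1), np.repeat(sd[:, None, :], n_ph, axis=1))

    centroids = None
    if spec.motion_magnitudes is not None:
        trajs = gen_motion_trajectories(spec)
        centroids = np.stack(trajs)
    patient_ids = [f"P{i:03d}" for i in range(n_p)]
    tensor = PhaseFeatureTensor(vals, list(spec.feature_names), patient_ids, centroids)
    truth = GroundTruth(
        planted_cov={f: spec.cov_of(f) for f in spec.feature_names},
        motion_magnitudes=None if spec.motion_magnitudes is None else np.asarray(spec.motion_magnitudes, float),
    )
    return tensor, truth


def gen_motion_trajectories(spec: SyntheticSpec) -> list[np.ndarray]:
    """Per-patient superior-inferior sinusoidal centroid trajectories.

    The 8 breathing-phase labels map to a full sine period sampled at
    fractions k/n; the trajectory is rescaled so the maximum pairwise 3D
    excursion equals the requested magnitude exactly.
    """
    if spec.motion_magnitudes is None:
        raise ValueError("spec.motion_magnitudes not set")
    mags = np.asarray(spec.motion_magnitudes, dtype=float)
    if (mags < 0).any():
        raise ValueError("motion magnitudes must be >= 0")
    t = np.arange(spec.n_phases) / spec.n_phases
    wave = -np.cos(2 * np.pi * t)  # peak-to-peak 2 when sampled at phase fractions
    span = wave.max() - wave.min()
    out = []
    for m in mags:
        z = wave * (m / span) if m > 0 else np.zeros_like(wave)
        traj = np.zeros((spec.n_phases, 3))
        traj[:, 2] = z
        out.append(traj)
    return out


@dataclass
class PhaseImageSet:
    """One synthetic 4D image study: image + mask per phase."""

    images: list[np.ndarray]
    masks: list[np.ndarray]
    spacing: tuple[float, float, float]

    @property
    def n_phases(self) -> int:
        return len(self.images)

    def centroid(self, phase: int) -> np.ndarray:
        """Physical (mm) centroid of the phase mask."""
        idx = np.argwhere(self.masks[phase])
        return idx.mean(axis=0) * np.asarray(self.spacing)

    def centroids(self) -> np.ndarray:
        return np.stack([self.centroid(k) for k in range(self.n_phases)])

    def write(self, directory, prefix: str = "phase", fmt: str = "nrrd") -> list[tuple[str, str]]:
        """Write image/mask pairs (NRRD or NIfTI) via SimpleITK."""
        import os

        from .roi import write_image

        ext = {"nrrd": ".nrrd", "nifti": ".nii.gz"}[fmt]
        paths = []
        os.makedirs(directory, exist_ok=True)
        for k in range(self.n_phases):
            ip = os.path.join(directory, f"{prefix}{k}_image{ext}")
            mp = os.path.join(directory, f"{prefix}{k}_mask{ext}")
            write_image(ip, self.images[k], self.spacing)
            write_image(mp, self.masks[k].astype(np.uint8), self.spacing)
            paths.append((ip, mp))
        return paths


def gen_4d_image(
    spec: SyntheticSpec,
    radii_mm: tuple[float, float, float] = (15.0, 12.0, 9.0),
    grid_shape: tuple[int, int, int] = (40, 40, 40),
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    base_intensity: float = 60.0,
    background: float = -800.0,
    texture_scale: float = 300.0,
    texture_smooth_vox: float = 1.0,
    noise_sd: float = 0.0,
    patient: int = 0,
) -> PhaseImageSet:
    """A textured ellipsoid translated rigidly along the breathing cycle.

    The intensity field is a smoothed Gaussian random field; inside the
    ellipsoid it is offset to a tumor-like level.  Per phase, image and
    mask are rolled together by the trajectory offset snapped to whole
    voxels, so with zero noise every phase is an exact translation of the
    base (all intensity/texture/shape features are then phase-invariant).
    Independent Gaussian noise (sd ``noise_sd``) is added per phase.
    """
    radii = np.asarray(radii_mm, dtype=float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    spacing_arr = np.asarray(spacing, dtype=float)
    shape = tuple(grid_shape)
    rng = spec.rng(stream=100 + patient)

    center = (np.asarray(shape) - 1) / 2.0 * spacing_arr
    coords = np.meshgrid(*[np.arange(s) * sp for s, sp in zip(shape, spacing_arr)], indexing="ij")
    dist2 = sum(((c - mu) / r) ** 2 for c, mu, r in zip(coords, center, radii))
    mask = dist2 <= 1.0  # voxel in mask iff its center is inside the ellipsoid
    if not mask.any():
        raise ValueError("ellipsoid contains no voxel centers")

    texture = gaussian_filter(rng.normal(0.0, 1.0, size=shape), texture_smooth_vox) * texture_scale
    image = np.where(mask, base_intensity + texture, background + 0.1 * texture)

    if spec.motion_magnitudes is not None:
        traj = gen_motion_trajectories(spec)[patient]
    else:
        traj = np.zeros((spec.n_phases, 3))
    shifts = np.round(traj / spacing_arr[None, :]).astype(int)

    # field-of-view check: the rolled mask must never wrap
    idx = np.argwhere(mask)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    for s in shifts:
        if (lo + s < 0).any() or (hi + s >= np.asarray(shape)).any():
            raise ValueError("tumor exits the field of view; enlarge grid_shape")

    images, masks = [], []
    for k in range(spec.n_phases):
        img_k = np.roll(image, shifts[k], axis=(0, 1, 2))
        msk_k = np.roll(mask, shifts[k], axis=(0, 1, 2))
        if noise_sd > 0:
            img_k = img_k + rng.normal(0.0, noise_sd, size=shape)
        images.append(img_k)
        masks.append(msk_k)
    return PhaseImageSet(images, masks, tuple(spacing_arr))


def _draw_categorical(rng, probs: dict, n: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p /= p.sum()
    return np.array(keys)[rng.choice(len(keys), size=n, p=p)]


def _calibrate_censoring(times: np.ndarray, u: np.ndarray, target: float) -> tuple[np.ndarray, float]:
    """Exponential censoring times with rate bisected to hit the target
    censored fraction on the realized event times."""
    if target <= 0:
        return np.full_like(times, np.inf), 0.0
    base = -np.log(u)  # unit-exponential quantiles, fixed across the search

    def frac_censored(scale: float) -> float:
        return float(np.mean(base * scale < times))

    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac_censored(mid) > target:
            lo = mid  # too many censored -> push censoring times later
        else:
            hi = mid
    scale = np.sqrt(lo * hi)
    return base * scale, frac_censored(scale)


def gen_survival_cohort(spec: SyntheticSpec) -> tuple[SurvivalCohort, GroundTruth]:
    """Right-censored cohort whose hazard depends on clean feature signals.

    Each feature observes a latent standard-normal signal (shared between
    features via ``spec.latent_of``) through additive motion noise whose
    sd is ``NOISE_SD_PER_COV * planted_cov``: stable features are nearly
    clean measurements, unstable ones are attenuated noisy proxies.
    Event times follow a Weibull proportional-hazards model with linear
    predictor sum(beta_f * clean_signal_f); censoring is independent
    exponential, calibrated to the requested censored fraction.  The
    observed feature matrix is z-scored per feature.
    """
    if not spec.feature_names:
        raise ValueError("spec.feature_names is empty")
    if all(b == 0 for b in spec.hazard_betas.values()) and spec.hazard_betas:
        import warnings

        warnings.warn("all hazard betas are zero: cohort carries no survival signal")
    rng = spec.rng(stream=2)
    n = spec.n_patients
    feats = list(spec.feature_names)
    latent_of = spec.latent_of or {f: i for i, f in enumerate(feats)}
    n_latent = max(latent_of.values()) + 1

    latents = rng.normal(0.0, 1.0, size=(n, n_latent))
    groups = None
    if spec.n_patient_groups > 1:
        groups = rng.integers(0, spec.n_patient_groups, size=n)
        offsets = rng.normal(0.0, 1.0, size=(spec.n_patient_groups, n_latent))
        offsets -= offsets.mean(axis=0, keepdims=True)
        norm = np.linalg.norm(offsets, axis=1, keepdims=True)
        offsets = offsets / np.where(norm == 0, 1, norm) * spec.group_shift
        latents = latents + offsets[groups]

    clean = np.column_stack([latents[:, latent_of[f]] for f in feats])
    noise_sd = np.array([NOISE_SD_PER_COV * spec.cov_of(f) for f in feats])
    observed = clean + rng.normal(0.0, 1.0, size=clean.shape) * noise_sd[None, :]
    observed = (observed - observed.mean(axis=0)) / np.where(observed.std(axis=0) == 0, 1, observed.std(axis=0))

    beta = np.array([spec.hazard_betas.get(f, 0.0) for f in feats])
    # betas act on the clean signals: motion noise dilutes observed features,
    # not the underlying biology
    eta = clean @ beta
    u = rng.uniform(size=n)
    times = spec.baseline_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / spec.baseline_shape)
    times = np.maximum(times, 1e-3)

    cens, realized = _calibrate_censoring(times, rng.uniform(size=n), spec.censor_rate)
    event = (times <= cens).astype(int)
    obs_time = np.minimum(times, cens)
    obs_time = np.maximum(obs_time, 1e-3)

    patient_ids = [f"P{i:03d}" for i in range(n)]
    ecog_p = np.array(ECOG_PROBS) / np.sum(ECOG_PROBS)
    if groups is not None and spec.ecog_group_assoc > 0:
        ecog = np.empty(n, dtype=int)
        for g in range(spec.n_patient_groups):
            tilt = np.exp(spec.ecog_group_assoc * (np.arange(4) - 1.5) * (g - (spec.n_patient_groups - 1) / 2))
            p = ecog_p * tilt
            sel = groups == g
            ecog[sel] = rng.choice(4, size=sel.sum(), p=p / p.sum())
    else:
        ecog = rng.choice(4, size=n, p=ecog_p)
    clinical = pd.DataFrame(
        {
            "ecog": ecog,
            "gender": _draw_categorical(rng, GENDER_PROBS, n),
            "ethnicity": _draw_categorical(rng, ETHNICITY_PROBS, n),
            "pack_years": np.round(np.minimum(rng.lognormal(np.log(40.0), 0.8, size=n), 180.0), 1),
            "histology": _draw_categorical(rng, HISTOLOGY_PROBS, n),
            "location": _draw_categorical(rng, LOCATION_PROBS, n),
        },
        index=patient_ids,
    )

    cohort = SurvivalCohort(
        features=pd.DataFrame(observed, index=patient_ids, columns=feats),
        time=pd.Series(obs_time, index=patient_ids, name="time_months"),
        event=pd.Series(event, index=patient_ids, name="event"),
        clinical=clinical,
        feature_cov=pd.Series({f: spec.cov_of(f) for f in feats}),
    )
    truth = GroundTruth(
        planted_cov={f: spec.cov_of(f) for f in feats},
        hazard_betas=dict(spec.hazard_betas),
        censor_fraction=float(1 - event.mean()),
        patient_groups=groups,
        clean_signals=pd.DataFrame(clean, index=patient_ids, columns=feats),
    )
    return cohort, truth


def planted_stability_spec(
    seed: int = 0,
    n_patients: int = 20,
    n_features: int = 56,
    covs: tuple[float, ...] = (3.0, 8.0, 15.0, 30.0),
    motion_range: tuple[float, float] = (1.0, 30.0),
) -> SyntheticSpec:
    """A 4D stability study design: equal blocks of features planted at
    each target COV tier, motion magnitudes spanning the given range."""
    if n_features % len(covs):
        raise ValueError("n_features must split evenly across the COV tiers")
    per = n_features // len(covs)
    names, planted = [], {}
    for b, cov in enumerate(covs):
        for j in range(per):
            f = f"cov{cov:g}_{j}"
            names.append(f)
            planted[f] = float(cov)
    return SyntheticSpec(
        n_patients=n_patients,
        feature_names=names,
        planted_cov=planted,
        motion_magnitudes=np.linspace(motion_range[0], motion_range[1], n_patients),
        seed=seed,
    )


def planted_survival_spec(
    seed: int = 0,
    n_patients: int = 140,
    beta: float = 1.0,
    null_signal: bool = False,
) -> SyntheticSpec:
    """The default planted survival study design.

    Three predictive latent signals are each observed through a clean
    stable feature (COV 3%) and through noisy proxies of increasing
    motion contamination (COV 8/15/22/30%); stable and unstable null
    features are added.  With ``null_signal`` every beta is zero (the
    calibration design).
    """
    cov_tiers = {"s": 3.0, "a": 8.0, "b": 15.0, "c": 22.0, "d": 30.0}
    names: list[str] = []
    planted: dict[str, float] = {}
    latent_of: dict[str, int] = {}
    betas: dict[str, float] = {}
    for lat in range(3):
        for tier, cov in cov_tiers.items():
            f = f"sig{lat}_{tier}"
            names.append(f)
            planted[f] = cov
            latent_of[f] = lat
            if tier == "s" and not null_signal:
                betas[f] = beta
    next_latent = 3
    for j in range(5):
        for tier, cov in (("s", 3.0), ("d", 30.0)):
            f = f"null{j}_{tier}"
            names.append(f)
            planted[f] = cov
            latent_of[f] = next_latent
            next_latent += 1
    return SyntheticSpec(
        n_patients=n_patients,
        feature_names=names,
        planted_cov=planted,
        hazard_betas=betas,
        latent_of=latent_of,
        censor_rate=0.59,
        seed=seed,
    )
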