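"""Bootstrap out-of-bag survival modeling with 4D-stability pre-selection.

The pipeline mirrors a common radiomic prognosis workflow: univariate
Cox screening of every feature (P and Benjamini-Hochberg Q cutoffs),
optional pre-exclusion of features whose 4D respiratory-phase COV
exceeds a cutoff, then a multi-round bootstrap in which each round
re-ranks the candidate pool on the in-bag sample, removes redundant
features (|Pearson r| > R), fits a small multiple Cox model, and scores
the out-of-bag patients.  OOB patients are split into low/high-risk
groups at the median risk score and the two-group logrank chi-square is
the per-round performance currency.  Two configurations are compared by
a one-tailed Welch t-test on the log chi-square values across rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .coxlib import (
    CoxFit,
    cox_fit,
    logrank_chi2,
    logrank_chi2_matrix,
    logrank_p,
    univariate_cox,
    univariate_cox_matrix,
)

__all__ = [
    "SurvivalCohort",
    "ModelConfig",
    "BootstrapEvaluation",
    "univariate_cox",
    "cox_fit",
    "logrank_chi2",
    "logrank_p",
    "screen_univariate",
    "fdr_adjust",
    "draw_bootstrap",
    "risk_dichotomize",
    "rank_features_bootstrap",
    "redundancy_filter",
    "evaluate_model",
    "compare_models",
    "significance_stars",
    "cutoff_grid",
]

DEFAULT_COV_CUTOFFS = (5.0, 10.0, 15.0, 20.0, 25.0)
DEFAULT_PQ_PAIRS = ((0.005, 0.04), (0.007, 0.045), (0.01, 0.05), (0.03, 0.07), (0.05, 0.09))


@dataclass
class SurvivalCohort:
    """Patients x features with right-censored overall survival.

    ``features``: DataFrame indexed by patient id; ``time`` in months
    (> 0); ``event`` 1 = death, 0 = censored.  ``feature_cov`` optionally
    carries each feature's population 4D COV (percent) for stability
    pre-selection; ``clinical`` optionally carries covariates (never used
    by the radiomic models, only by the clustering association tests).
    """

    features: pd.DataFrame
    time: pd.Series
    event: pd.Series
    clinical: pd.DataFrame | None = None
    feature_cov: pd.Series | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("survival times must be finite and > 0")
        if not np.isin(e, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")
        if not np.isfinite(self.features.to_numpy()).all():
            raise ValueError("features must be finite")

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def constant_features(self) -> list[str]:
        x = self.features.to_numpy()
        return [c for c, flat in zip(self.features.columns, np.ptp(x, axis=0) == 0) if flat]

    def to_csv(self, path) -> None:
        df = pd.concat(
            [self.time.rename("time_months"), self.event.rename("event"), self.clinical, self.features],
            axis=1,
        )
        df.to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path, clinical_columns: list[str] | None = None) -> "SurvivalCohort":
        df = pd.read_csv(path, index_col="patient_id")
        for col in ("time_months", "event"):
            if col not in df.columns:
                raise ValueError(f"missing required column: {col}")
        clinical_columns = clinical_columns or []
        feats = df.drop(columns=["time_months", "event", *clinical_columns])
        clin = df[clinical_columns] if clinical_columns else None
        return cls(feats, df["time_months"], df["event"].astype(int), clin)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up Q-values (NaNs passed through)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def screen_univariate(cohort: SurvivalCohort, ties: str = "breslow") -> pd.DataFrame:
    """Univariate Cox screening of every feature on the full cohort.

    Returns a per-feature frame with ``coef``, ``p``, ``q`` (BH FDR).
    Constant features get NaN and are never selected.
    """
    X = cohort.features.to_numpy(dtype=float)
    beta, se, p = univariate_cox_matrix(X, cohort.time.to_numpy(), cohort.event.to_numpy())
    q = fdr_adjust(p)
    return pd.DataFrame({"coef": beta, "se": se, "p": p, "q": q}, index=cohort.features.columns)


def draw_bootstrap(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap round: in-bag indices (with replacement) and OOB set."""
    if n < 2:
        raise ValueError("need n >= 2")
    in_bag = rng.integers(0, n, size=n)
    mask = np.zeros(n, dtype=bool)
    mask[in_bag] = True
    return in_bag, np.flatnonzero(~mask)


def oob_fraction(n: int, n_rounds: int, seed: int) -> float:
    """Mean out-of-bag fraction over ``n_rounds`` simulated rounds."""
    rng = np.random.default_rng(seed)
    total = 0
    for _ in range(n_rounds):
        _, oob = draw_bootstrap(n, rng)
        total += len(oob)
    return total / (n_rounds * n)


def risk_dichotomize(scores, reference_median: float) -> np.ndarray:
    """True = high risk (score > median); ties at the median go low."""
    s = np.asarray(scores, dtype=float)
    return s > reference_median


def redundancy_filter(
    ranked_features: list[str],
    corr: pd.DataFrame,
    r_threshold: float = 0.75,
    max_size: int | None = None,
) -> list[str]:
    """Greedy redundancy exclusion down a ranked feature list.

    A feature is kept iff its absolute Pearson correlation with every
    already-kept feature is <= ``r_threshold``; stops at ``max_size``.
    """
    kept: list[str] = []
    for f in ranked_features:
        if all(abs(corr.loc[f, g]) <= r_threshold for g in kept):
            kept.append(f)
        if max_size is not None and len(kept) >= max_size:
            break
    return kept


@dataclass
class ModelConfig:
    """One model-development configuration of the comparison grid."""

    cov_cutoff: float | None = None  # percent; None = no 4D pre-selection
    p_cutoff: float = 0.01
    q_cutoff: float = 0.05
    redundancy_r: float = 0.75
    n_boot: int = 500
    max_model_size: int = 3
    seed: int = 0
    ties: str = "breslow"
    oob_median: str = "inbag"  # or "cohort"

    def __post_init__(self) -> None:
        if not (0 < self.redundancy_r < 1):
            raise ValueError("redundancy_r must be in (0,1)")
        if self.oob_median not in ("inbag", "cohort"):
            raise ValueError("oob_median must be 'inbag' or 'cohort'")


@dataclass
class BootstrapEvaluation:
    """Per-configuration bootstrap results."""

    config: ModelConfig
    pool: list[str]
    chi2: np.ndarray  # length n_boot; NaN = non-evaluable round
    selections: list[list[str]]
    final_model: list[str]
    final_fit: CoxFit | None = None
    infeasible: bool = False

    @property
    def evaluable_chi2(self) -> np.ndarray:
        return self.chi2[np.isfinite(self.chi2)]

    @property
    def n_evaluable(self) -> int:
        return int(np.isfinite(self.chi2).sum())


def _round_rng(seed: int, round_idx: int) -> np.random.Generator:
    # counter-derived per-round streams: independent of evaluation order
    return np.random.default_rng(np.random.SeedSequence(entropy=[int(seed), int(round_idx)]))


def _rank_pool_inbag(X_in, t_in, e_in, pool: list[str]) -> list[str]:
    """Rank pool features by in-bag univariate logrank chi2, descending."""
    beta, _, _ = univariate_cox_matrix(X_in, t_in, e_in)
    scores = X_in * beta  # per-feature risk scores of in-bag patients
    med = np.nanmedian(scores, axis=0)
    groups = scores > med
    chi2 = logrank_chi2_matrix(groups, t_in, e_in)
    chi2 = np.where(np.isnan(chi2), -1.0, chi2)  # never-evaluable ranks last
    order = np.argsort(-chi2, kind="stable")
    return [pool[i] for i in order]


def select_pool(cohort: SurvivalCohort, config: ModelConfig, screen: pd.DataFrame | None = None) -> list[str]:
    """Apply univariate P/Q screening, then the optional COV cutoff."""
    if screen is None:
        screen = screen_univariate(cohort, ties=config.ties)
    ok = (screen["p"] < config.p_cutoff) & (screen["q"] < config.q_cutoff)
    pool = [f for f in cohort.feature_names if bool(ok.get(f, False))]
    if config.cov_cutoff is not None:
        if cohort.feature_cov is None:
            raise ValueError("cov_cutoff requested but cohort has no feature_cov")
        pool = [f for f in pool if cohort.feature_cov.get(f, np.inf) <= config.cov_cutoff]
    return pool


def evaluate_model(
    cohort: SurvivalCohort,
    config: ModelConfig,
    screen: pd.DataFrame | None = None,
) -> BootstrapEvaluation:
    """Run the full bootstrap model development for one configuration.

    Pre-selection (univariate P/Q on the full cohort, then COV cutoff) is
    applied once; each bootstrap round then re-ranks the pool in-bag,
    filters redundancy, fits a multiple Cox model in-bag and scores the
    out-of-bag patients, whose median-split logrank chi-square is
    recorded.  Clinical covariates never enter the models.
    """
    pool = select_pool(cohort, config, screen=screen)
    if not pool:
        return BootstrapEvaluation(config, [], np.full(config.n_boot, np.nan), [], [], infeasible=True)

    X = cohort.features[pool].to_numpy(dtype=float)
    t = cohort.time.to_numpy(dtype=float)
    e = cohort.event.to_numpy(dtype=int)
    n = len(t)
    corr = cohort.features[pool].corr()

    def _one_pass(idx_in: np.ndarray):
        Xi, ti, ei = X[idx_in], t[idx_in], e[idx_in]
        ranked = _rank_pool_inbag(Xi, ti, ei, pool)
        sel = redundancy_filter(ranked, corr, config.redundancy_r, config.max_model_size)
        cols = [pool.index(f) for f in sel]
        fit = cox_fit(Xi[:, cols], ti, ei, ties=config.ties)
        return sel, cols, fit

    chi2 = np.full(config.n_boot, np.nan)
    selections: list[list[str]] = []
    for r in range(config.n_boot):
        rng = _round_rng(config.seed, r)
        in_bag, oob = draw_bootstrap(n, rng)
        if len(oob) < 2 or e[oob].sum() < 1 or e[in_bag].sum() < 2:
            selections.append([])
            continue
        try:
            sel, cols, fit = _one_pass(in_bag)
        except (ValueError, np.linalg.LinAlgError):
            selections.append([])
            continue
        selections.append(sel)
        scores_oob = X[oob][:, cols] @ fit.beta
        if config.oob_median == "inbag":
            ref = float(np.median(X[in_bag][:, cols] @ fit.beta))
        else:
            ref = float(np.median(X[:, cols] @ fit.beta))
        high = risk_dichotomize(scores_oob, ref)
        if high.all() or not high.any():
            continue
        chi2[r] = logrank_chi2(high, t[oob], e[oob])

    final_sel, final_cols, final_fit = _one_pass(np.arange(n))
    return BootstrapEvaluation(config, pool, chi2, selections, final_sel, final_fit)


def rank_features_bootstrap(
    cohort: SurvivalCohort,
    pool: list[str],
    n_boot: int = 500,
    seed: int = 0,
) -> pd.Series:
    """Univariate predictive value: per-feature median logrank chi2.

    Per round, each pool feature is fit univariately on the in-bag
    sample; all patients are scored and split at the whole-cohort median
    score; the logrank chi-square is recorded.  The per-feature median
    over evaluable rounds is the feature's predictive value.
    """
    if not pool:
        raise ValueError("empty pool")
    X = cohort.features[pool].to_numpy(dtype=float)
    t = cohort.time.to_numpy(dtype=float)
    e = cohort.event.to_numpy(dtype=int)
    n = len(t)
    out = np.full((n_boot, len(pool)), np.nan)
    for r in range(n_boot):
        rng = _round_rng(seed, r)
        in_bag, _ = draw_bootstrap(n, rng)
        if e[in_bag].sum() < 2:
            continue
        beta, _, _ = univariate_cox_matrix(X[in_bag], t[in_bag], e[in_bag])
        scores = X * beta  # all patients scored with in-bag coefficients
        med = np.nanmedian(scores, axis=0)
        out[r] = logrank_chi2_matrix(scores > med, t, e)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(out, axis=0)
    return pd.Series(med, index=pool, name="median_chi2")


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return "na"
    if p < 1e-5:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_models(chi2_a, chi2_b) -> dict:
    """One-tailed Welch t-test on log chi2: alternative = A better than B.

    Non-evaluable (NaN) and exactly-zero rounds are dropped before the
    logarithm; their counts are reported.  Returns NaN P with a flag when
    fewer than 3 rounds survive on either side.
    """
    a = np.asarray(chi2_a, dtype=float)
    b = np.asarray(chi2_b, dtype=float)
    drop_a = int(np.isnan(a).sum() + (a == 0).sum())
    drop_b = int(np.isnan(b).sum() + (b == 0).sum())
    a = a[np.isfinite(a) & (a > 0)]
    b = b[np.isfinite(b) & (b > 0)]
    if len(a) < 3 or len(b) < 3:
        return {"p": float("nan"), "t": float("nan"), "stars": "na", "n_a": len(a), "n_b": len(b), "dropped_a": drop_a, "dropped_b": drop_b}
    res = stats.ttest_ind(np.log(a), np.log(b), equal_var=False, alternative="greater")
    return {
        "p": float(res.pvalue),
        "t": float(res.statistic),
        "stars": significance_stars(float(res.pvalue)),
        "n_a": len(a),
        "n_b": len(b),
        "dropped_a": drop_a,
        "dropped_b": drop_b,
    }


@dataclass
class GridResult:
    """COV-cutoff x P/Q-cutoff comparison matrix plus the raw evaluations."""

    p_matrix: pd.DataFrame  # rows: COV cutoffs; columns: (p,q) labels
    evaluations: dict = field(default_factory=dict)  # key -> BootstrapEvaluation

    def best_cell(self) -> tuple[float, str]:
        """(cov_cutoff, pq_label) of the smallest comparison P-value."""
        m = self.p_matrix
        idx = np.unravel_index(np.nanargmin(m.to_numpy()), m.shape)
        return m.index[idx[0]], m.columns[idx[1]]


def cutoff_grid(
    cohort: SurvivalCohort,
    base_config: ModelConfig | None = None,
    cov_cutoffs=DEFAULT_COV_CUTOFFS,
    pq_pairs=DEFAULT_PQ_PAIRS,
) -> GridResult:
    """Evaluate every (COV cutoff, P/Q cutoff) cell against its no-COV twin.

    All cells share the same master seed, so every configuration sees the
    same bootstrap draws (a paired comparison).  Infeasible cells (empty
    pool) are NaN.
    """
    base = base_config or ModelConfig()
    screen = screen_univariate(cohort, ties=base.ties)
    mat = pd.DataFrame(
        np.nan,
        index=pd.Index(list(cov_cutoffs), name="cov_cutoff"),
        columns=[f"P<{p},Q<{q}" for p, q in pq_pairs],
    )
    evaluations: dict = {}
    for (p_cut, q_cut), col in zip(pq_pairs, mat.columns):
        ref_cfg = replace(base, cov_cutoff=None, p_cutoff=p_cut, q_cutoff=q_cut)
        ref = evaluate_model(cohort, ref_cfg, screen=screen)
        evaluations[("none", col)] = ref
        for cov in cov_cutoffs:
            cfg = replace(base, cov_cutoff=cov, p_cutoff=p_cut, q_cutoff=q_cut)
            ev = evaluate_model(cohort, cfg, screen=screen)
            evaluations[(cov, col)] = ev
            if not ev.infeasible and not ref.infeasible:
                mat.loc[cov, col] = compare_models(ev.chi2, ref.chi2)["p"]
    return GridResult(mat, evaluations)
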