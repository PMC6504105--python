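"""Orchestration: seeded end-to-end runs with file outputs and a manifest.

Stages run in dependency order (simulate -> stability -> cluster ->
grid); every intermediate is a file under the output directory, no stage
mutates another stage's inputs, and a run manifest records the config
snapshot, master seed, output hashes and stage timings so every output
file is traceable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import build_catalog
from .clustering import association_tests, cluster_patients
from .stability import stability_table, summarize_groups
from .survival import ModelConfig, compare_models, cutoff_grid
from .synthetic import gen_phase_feature_tensor, gen_survival_cohort, planted_stability_spec, planted_survival_spec


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-study run."""

    seed: int = 0
    n_patients_4d: int = 20
    n_phases: int = 8
    n_patients_cohort: int = 140
    n_boot: int = 100
    max_model_size: int = 3
    cov_cutoffs: tuple = (5.0, 10.0, 15.0, 20.0, 25.0)
    pq_pairs: tuple = ((0.01, 0.05),)
    redundancy_r: float = 0.75
    k_clusters: int = 3

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        allowed = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.n_phases < 2 or cfg.n_boot < 1 or cfg.k_clusters < 2:
            raise ValueError("invalid config values")
        cfg.cov_cutoffs = tuple(cfg.cov_cutoffs)
        cfg.pq_pairs = tuple(tuple(x) for x in cfg.pq_pairs)
        return cfg


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)  # path -> sha256
    timings: dict = field(default_factory=dict)  # stage -> seconds

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig | str | Path, out_dir, make_figures: bool = True) -> RunManifest:
    """Run the full synthetic study and write all tables and figures."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(asdict(config), config.seed, __version__)
    written: list[Path] = []

    def _stage(name):
        manifest.timings[name] = time.perf_counter()

    def _done(name):
        manifest.timings[name] = round(time.perf_counter() - manifest.timings[name], 3)

    # --- simulate -------------------------------------------------------
    _stage("simulate")
    stab_spec = planted_stability_spec(seed=config.seed, n_patients=config.n_patients_4d)
    stab_spec.n_phases = config.n_phases
    tensor, truth_t = gen_phase_feature_tensor(stab_spec)
    cohort_spec = planted_survival_spec(seed=config.seed, n_patients=config.n_patients_cohort)
    cohort, truth_c = gen_survival_cohort(cohort_spec)
    tensor.to_long_frame().to_csv(out / "phase_features.csv", index=False)
    cohort.to_csv(out / "cohort.csv")
    truth_t.to_json(out / "ground_truth_tensor.json")
    truth_c.to_json(out / "ground_truth_cohort.json")
    written += [out / "phase_features.csv", out / "cohort.csv", out / "ground_truth_tensor.json", out / "ground_truth_cohort.json"]
    _done("simulate")

    # --- stability ------------------------------------------------------
    _stage("stability")
    table = stability_table(tensor)
    table.summary.to_csv(out / "stability_table.csv")
    summary = summarize_groups(table, build_catalog())
    summary.to_csv(out / "category_summary.csv", index=False)
    written += [out / "stability_table.csv", out / "category_summary.csv"]
    _done("stability")

    # --- cluster --------------------------------------------------------
    _stage("cluster")
    assignment = cluster_patients(cohort.features, cohort.feature_cov, k=config.k_clusters)
    assignment.labels.to_csv(out / "patient_clusters.csv")
    assoc = association_tests(assignment, cohort.clinical)
    assoc.to_csv(out / "cluster_associations.csv")
    written += [out / "patient_clusters.csv", out / "cluster_associations.csv"]
    _done("cluster")

    # --- grid -----------------------------------------------------------
    _stage("grid")
    base = ModelConfig(
        n_boot=config.n_boot,
        max_model_size=config.max_model_size,
        redundancy_r=config.redundancy_r,
        seed=config.seed,
    )
    grid = cutoff_grid(cohort, base, cov_cutoffs=config.cov_cutoffs, pq_pairs=config.pq_pairs)
    grid.p_matrix.to_csv(out / "grid_p_values.csv")
    chi2_frame = pd.DataFrame(
        {f"cov={k[0]},{k[1]}": ev.chi2 for k, ev in grid.evaluations.items() if not ev.infeasible}
    )
    chi2_frame.to_csv(out / "grid_chi2.csv", index_label="round")
    written += [out / "grid_p_values.csv", out / "grid_chi2.csv"]
    _done("grid")

    # --- figures --------------------------------------------------------
    if make_figures:
        _stage("figures")
        from . import plots

        plots.category_fractions_bar(summary, out / "fig_category_fractions.png")
        plots.cov_histogram(table.summary, out / "fig_cov_histogram.png")
        plots.cov_heatmap(table, out / "fig_cov_heatmap.png")
        plots.cohort_heatmap(cohort.features, assignment, cohort.clinical, out / "fig_cohort_heatmap.png")
        pq_label = f"P<{config.pq_pairs[0][0]},Q<{config.pq_pairs[0][1]}"
        evals = {}
        comps = {}
        ref = grid.evaluations.get(("none", pq_label))
        for cov in config.cov_cutoffs:
            ev = grid.evaluations.get((cov, pq_label))
            if ev is not None and not ev.infeasible:
                lab = f"COV<={cov:g}"
                evals[lab] = ev.chi2
                if ref is not None and not ref.infeasible:
                    comps[lab] = compare_models(ev.chi2, ref.chi2)["p"]
        if ref is not None and not ref.infeasible:
            evals["all"] = ref.chi2
        if evals:
            plots.chi2_boxplot(evals, comps, out / "fig_chi2_boxplot.png")
        _km_example(grid, cohort, config, out)
        _done("figures")

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[p.name] = _sha256(p)
    manifest.write(out / "manifest.json")
    return manifest


def _km_example(grid, cohort, config, out: Path) -> None:
    """Kaplan-Meier curves for one example bootstrap round (median chi2)."""
    from . import plots
    from .survival import draw_bootstrap, risk_dichotomize
    from .coxlib import cox_fit
    import numpy as np

    pq_label = f"P<{config.pq_pairs[0][0]},Q<{config.pq_pairs[0][1]}"
    ev = grid.evaluations.get((config.cov_cutoffs[0], pq_label))
    if ev is None or ev.infeasible or ev.n_evaluable == 0:
        return
    finite = np.flatnonzero(np.isfinite(ev.chi2))
    r = int(finite[np.argsort(ev.chi2[finite])[len(finite) // 2]])  # the median round
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[int(ev.config.seed), r]))
    in_bag, oob = draw_bootstrap(cohort.n, rng)
    sel = ev.selections[r]
    X = cohort.features[sel].to_numpy(float)
    t = cohort.time.to_numpy(float)
    e = cohort.event.to_numpy(int)
    fit = cox_fit(X[in_bag], t[in_bag], e[in_bag])
    high = risk_dichotomize(X[oob] @ fit.beta, float(np.median(X[in_bag] @ fit.beta)))
    plots.km_curves(t[oob], e[oob], high, out / "fig_km_example.png", title=f"round {r}:")
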