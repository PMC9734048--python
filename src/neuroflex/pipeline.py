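"""End-to-end orchestration: simulate -> connectivity -> communities ->
flexibility -> statistics -> predictive models.

`run_pipeline` drives the on-disk pipeline (every stage writes files a
package reader can load back, plus a manifest with the exact configuration,
seeds and per-file checksums).  `subject_flexibility` and
`cohort_flexibility` are the in-memory workhorses the statistics, modelling
and reproduction code build on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nfio
from .community import MultilayerNetwork, repeated_detection
from .connectivity import RoiTimeSeries, build_layer_stack
from .errors import DegenerateModelError
from .flexibility import FlexibilityProfile, profile_from_assignments
from .models import prepare_cohort_features, top_n_search
from .stats import group_contrast_table, medication_contrasts
from .synthetic import Cohort, SyntheticConfig, generate_cohort
from . import __version__

__all__ = ["PipelineConfig", "subject_flexibility", "cohort_flexibility", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every stage parameter of one full run, serializable to YAML."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    window_width: int = 30
    window_step: int = 1
    alpha: float = 0.05
    negatives: str = "zero"
    gamma: float = 1.0
    omega: float = 1.0
    n_reps: int = 100
    detection_seed: int = 1
    n_folds: int = 10
    n_repeats: int = 10
    model_seed: int = 1
    candidate_stride: int = 1
    exclude_female: bool = True
    exclude_medicated: bool = True
    run_models: bool = True

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["synthetic"]["state_partitions"] = np.asarray(
            self.synthetic.state_partitions
        ).tolist()
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        syn = dict(data.pop("synthetic", {}))
        if syn.get("state_partitions") is not None:
            syn["state_partitions"] = np.asarray(syn["state_partitions"])
        if "covariate_effects" in syn and isinstance(syn["covariate_effects"], dict):
            from .synthetic import CovariateEffects

            syn["covariate_effects"] = CovariateEffects(**syn["covariate_effects"])
        return cls(synthetic=SyntheticConfig(**syn), **data)


def subject_flexibility(
    ts: RoiTimeSeries,
    atlas: pd.DataFrame,
    width: int = 30,
    step: int = 1,
    alpha: float = 0.05,
    negatives: str = "zero",
    gamma: float = 1.0,
    omega: float = 1.0,
    n_reps: int = 100,
    seed: int = 0,
) -> FlexibilityProfile:
    """Full single-subject chain: layers -> communities -> flexibility."""
    stack = build_layer_stack(ts, width=width, step=step, alpha=alpha, negatives=negatives)
    net = MultilayerNetwork(stack, omega=omega, gamma=gamma)
    assignments = repeated_detection(net, n_reps=n_reps, master_seed=seed)
    return profile_from_assignments(assignments, atlas, subject_id=ts.subject_id)


def cohort_flexibility(
    cohort: Cohort, config: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-subject flexibility tables for a whole cohort.

    Returns ``(whole, systems, nodes)`` frames indexed by subject_id:
    ``whole`` has the single whole-brain column, ``systems`` one column per
    functional system and ``nodes`` one column per node.  Per-subject
    detection seeds are derived from ``config.detection_seed``.
    """
    seeds = np.random.SeedSequence(config.detection_seed).generate_state(
        len(cohort.timeseries), np.uint32
    )
    whole, systems, nodes = {}, {}, {}
    for ts, seed in zip(cohort.timeseries, seeds):
        prof = subject_flexibility(
            ts, cohort.atlas,
            width=config.window_width, step=config.window_step,
            alpha=config.alpha, negatives=config.negatives,
            gamma=config.gamma, omega=config.omega,
            n_reps=config.n_reps, seed=int(seed),
        )
        whole[ts.subject_id] = prof.whole_brain
        systems[ts.subject_id] = prof.system_flexibility
        nodes[ts.subject_id] = prof.node_flexibility
    whole_df = pd.DataFrame({"whole_brain": pd.Series(whole)})
    systems_df = pd.DataFrame(systems).T
    nodes_df = pd.DataFrame(nodes).T
    for frame in (whole_df, systems_df, nodes_df):
        frame.index.name = "subject_id"
    return whole_df, systems_df, nodes_df


def _write_flexibility(whole, systems, nodes, path: Path) -> None:
    tidy = []
    for level, frame in (("whole_brain", whole), ("system", systems), ("node", nodes)):
        melted = frame.reset_index().melt(
            id_vars="subject_id", var_name="unit", value_name="value"
        )
        melted.insert(1, "level", level)
        tidy.append(melted)
    pd.concat(tidy, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage, writing outputs and a manifest under ``outdir``.

    Identical configurations produce identical files (and therefore
    identical manifest checksums).  Returns the manifest dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": PipelineConfig.to_dict(config),
        "package_version": __version__,
        "stages": {},
    }

    def record(stage: str, paths: list[Path]) -> None:
        files = {}
        for p in sorted(paths):
            if p.is_dir():
                for f in sorted(p.rglob("*")):
                    if f.is_file():
                        files[str(f.relative_to(outdir))] = nfio.file_checksum(f)
            else:
                files[str(p.relative_to(outdir))] = nfio.file_checksum(p)
        manifest["stages"][stage] = {"files": files}

    # stage 1: simulate
    cohort = generate_cohort(config.synthetic)
    sim_dir = outdir / "timeseries"
    sim_dir.mkdir(exist_ok=True)
    paths = [nfio.write_timeseries(ts, sim_dir / f"{ts.subject_id}.csv") for ts in cohort.timeseries]
    paths.append(nfio.write_subjects(cohort.subjects, outdir / "subjects.csv"))
    paths.append(nfio.write_atlas(cohort.atlas, outdir / "atlas.tsv"))
    paths.append(nfio.write_config(manifest["config"], outdir / "config.yaml"))
    record("simulate", paths)

    # stages 2-4: connectivity, communities, flexibility
    conn_dir = outdir / "connectivity"
    comm_dir = outdir / "communities"
    seeds = np.random.SeedSequence(config.detection_seed).generate_state(
        len(cohort.timeseries), np.uint32
    )
    whole, systems, nodes = {}, {}, {}
    conn_paths, comm_paths = [], []
    for ts, seed in zip(cohort.timeseries, seeds):
        stack = build_layer_stack(
            ts, width=config.window_width, step=config.window_step,
            alpha=config.alpha, negatives=config.negatives,
        )
        conn_paths.append(nfio.write_layer_stack(stack, conn_dir / ts.subject_id))
        net = MultilayerNetwork(stack, omega=config.omega, gamma=config.gamma)
        assignments = repeated_detection(net, n_reps=config.n_reps, master_seed=int(seed))
        comm_paths.append(
            nfio.write_assignments(
                assignments, comm_dir / ts.subject_id, config.gamma, config.omega
            )
        )
        prof = profile_from_assignments(assignments, cohort.atlas, subject_id=ts.subject_id)
        whole[ts.subject_id] = prof.whole_brain
        systems[ts.subject_id] = prof.system_flexibility
        nodes[ts.subject_id] = prof.node_flexibility
    record("connectivity", conn_paths)
    record("communities", comm_paths)

    whole_df = pd.DataFrame({"whole_brain": pd.Series(whole)})
    systems_df = pd.DataFrame(systems).T
    nodes_df = pd.DataFrame(nodes).T
    for frame in (whole_df, systems_df, nodes_df):
        frame.index.name = "subject_id"
    flex_path = outdir / "flexibility.csv"
    _write_flexibility(whole_df, systems_df, nodes_df, flex_path)
    record("flexibility", [flex_path])

    # stage 5: statistics; cohorts too small for the full covariate model
    # fall back per feature to the unadjusted contrast, and constant
    # features (no variance to explain) are skipped rather than fatal
    def contrasts(features, family):
        from .stats import correct_family

        out = []
        for col in features.columns:
            for covs in ((("age", "sex", "mean_fd", "site")), ()):
                try:
                    out += group_contrast_table(
                        features[[col]], cohort.subjects,
                        contrast="ADHD-TDC", covariates=covs,
                    )
                    break
                except DegenerateModelError:
                    continue
        return correct_family(out, family) if out else []

    results = contrasts(whole_df, "whole_brain")
    results += contrasts(systems_df, "systems")
    if (cohort.subjects["medication"] == "medicated").any():
        try:
            results += medication_contrasts(whole_df, cohort.subjects)
        except DegenerateModelError:
            # medication subgroups too small for the covariate model; the
            # primary contrast above is still reported
            pass
    stats_path = outdir / "contrasts.csv"
    pd.DataFrame([r.to_dict() for r in results]).to_csv(
        stats_path, index=False, float_format="%.17g"
    )
    record("stats", [stats_path])

    # stage 6: predictive models
    model_paths = []
    if config.run_models:
        strides = np.arange(1, nodes_df.shape[1] + 1, config.candidate_stride)
        metrics = {}
        for task, target in (("classify", "group"), ("regress", "severity")):
            x, y = prepare_cohort_features(
                nodes_df, cohort.subjects, task=task,
                exclude_female=config.exclude_female,
                exclude_medicated=config.exclude_medicated,
            )
            sel = top_n_search(
                x, y, task=task, n_folds=config.n_folds,
                n_repeats=config.n_repeats, seed=config.model_seed,
                candidate_ns=strides,
            )
            metrics[task] = {
                "best_n": sel.best_n,
                "selected": sel.selected,
                "cv_metrics": sel.cv_metrics,
                "curve": sel.curve.tolist(),
                "candidate_ns": sel.candidate_ns.tolist(),
            }
        models_path = outdir / "models.json"
        models_path.write_text(json.dumps(metrics, indent=1, sort_keys=True))
        model_paths.append(models_path)
    else:
        skip_path = outdir / "models.json"
        skip_path.write_text(json.dumps({"skipped": True}))
        model_paths.append(skip_path)
    record("models", model_paths)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
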