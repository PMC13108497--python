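"""End-to-end orchestration: cohort -> per-subject metrics -> statistics.

:func:`run_subject` turns one subject's raw structural/functional matrix
pair into a flat row of network metrics (single-layer and multiplex
frontoparietal and dorsal-attention centrality, mean eccentricities).
:func:`run_full_pipeline` drives the whole analysis from a
:class:`PipelineConfig`, writing a report bundle of TSV/JSON files.
Per-subject failures are recorded and summarized instead of aborting the
run; a failing mandatory statistics stage raises :class:`PipelineError`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import connectome_io, graph_layers, network_metrics, stats_models
from .connectome_io import ConnectivityMatrix, Parcellation
from .exceptions import ConfigError, MplexcogError

log = logging.getLogger("mplexcog")

METRIC_COLUMNS = (
    "ecfpn_structural",
    "ecfpn_functional",
    "ecfpn_multiplex",
    "ecdan_structural",
    "ecdan_functional",
    "ecdan_multiplex",
    "ecc_structural",
    "ecc_functional",
    "ecc_multiplex",
)


class PipelineError(MplexcogError, RuntimeError):
    """A mandatory pipeline stage failed."""


@dataclasses.dataclass
class PipelineConfig:
    mode: str  # "simulate" | "load"
    out_dir: str
    cohort_dir: str | None = None  # required for mode="load"
    parcellation: str = "schaefer114"  # packaged name or path to a TSV
    cohort: "object | None" = None  # CohortConfig when simulating
    fd_covariate: bool = False
    fd_exclusion_mm: float | None = None
    r2_baseline: str = "test_mean"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("simulate", "load"):
            raise ConfigError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "load" and not self.cohort_dir:
            raise ConfigError("mode='load' requires cohort_dir")


def load_parcellation_ref(ref: str) -> Parcellation:
    """Resolve a packaged parcellation name or a TSV path."""
    if Path(ref).is_file():
        return connectome_io.read_parcellation(ref)
    return connectome_io.packaged_parcellation(ref)


def run_subject(
    structural: ConnectivityMatrix,
    functional: ConnectivityMatrix,
    parcellation: Parcellation,
) -> dict:
    """Compute the full per-subject metric row from raw matrices."""
    sc = connectome_io.preprocess_structural(structural)
    fc = connectome_io.preprocess_functional(functional)
    mst_s = graph_layers.maximum_spanning_tree(sc, "structural")
    mst_f = graph_layers.maximum_spanning_tree(fc, "functional")
    mplex = graph_layers.build_multiplex([mst_s, mst_f])

    ec_s = network_metrics.eigenvector_centrality(mst_s.adjacency)
    ec_f = network_metrics.eigenvector_centrality(mst_f.adjacency)
    ec_m = network_metrics.multilayer_nodal_ec(mplex)
    _, ecc_s = network_metrics.eccentricity(mst_s.adjacency)
    _, ecc_f = network_metrics.eccentricity(mst_f.adjacency)
    _, ecc_m = network_metrics.multiplex_eccentricity(mplex)

    row = {"subject_id": structural.subject_id}
    for net, key in (("frontoparietal", "ecfpn"), ("dorsal_attention", "ecdan")):
        for tag, vec in (("structural", ec_s), ("functional", ec_f), ("multiplex", ec_m)):
            row[f"{key}_{tag}"] = network_metrics.subnetwork_mean(
                vec, parcellation, net
            ).mean
    row["ecc_structural"] = ecc_s
    row["ecc_functional"] = ecc_f
    row["ecc_multiplex"] = ecc_m
    return row


def load_cohort(cohort_dir: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a manifest plus per-subject matrix TSV pairs from a directory."""
    cohort_dir = Path(cohort_dir)
    manifest = connectome_io.read_manifest(cohort_dir / "manifest.tsv")
    matrices = {}
    for sid in manifest["subject_id"]:
        matrices[sid] = {
            modality: connectome_io.read_matrix(
                cohort_dir / f"{sid}_{modality}.tsv", sid, modality
            )
            for modality in ("structural", "functional")
        }
    return manifest, matrices


def compute_metric_table(
    manifest: pd.DataFrame, matrices: dict, parcellation: Parcellation
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-subject metric rows; failures collected, not raised."""
    rows, failures = [], []
    for sid in manifest["subject_id"]:
        try:
            pair = matrices[sid]
            rows.append(run_subject(pair["structural"], pair["functional"], parcellation))
            log.info("stage=metrics subject_id=%s status=ok", sid)
        except MplexcogError as exc:
            failures.append({"subject_id": sid, "error": str(exc)})
            log.warning("stage=metrics subject_id=%s status=failed error=%s", sid, exc)
    return pd.DataFrame(rows), failures


def _blockspec(metric_prefix: str, covariates: list[str]) -> stats_models.BlockSpec:
    return stats_models.BlockSpec(
        outcome="sdmt_z",
        blocks=(
            tuple(covariates),
            (f"{metric_prefix}_structural", f"{metric_prefix}_functional"),
            (f"{metric_prefix}_multiplex",),
        ),
    )


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Returns a summary dict with the in-memory results; see the written
    files for the Table-style reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    parcellation = load_parcellation_ref(config.parcellation)

    if config.mode == "simulate":
        from . import synthetic_cohort

        cohort_cfg = config.cohort or synthetic_cohort.CohortConfig(
            n_subjects=120, n_regions=parcellation.n_regions, seed=config.seed
        )
        cohort = synthetic_cohort.generate_cohort(
            cohort_cfg, parcellation, out_dir=out / "cohort"
        )
        manifest, matrices = cohort.manifest, cohort.matrices
    else:
        manifest, matrices = load_cohort(config.cohort_dir)

    if config.fd_exclusion_mm is not None and "mean_fd" in manifest.columns:
        thr = float(config.fd_exclusion_mm)
        manifest = connectome_io.filter_subjects(
            manifest, lambda row: row.mean_fd <= thr
        )

    metric_table, failures = compute_metric_table(manifest, matrices, parcellation)
    if metric_table.empty:
        raise PipelineError("no subject produced metrics")
    design = manifest.merge(metric_table, on="subject_id", how="inner")
    design.to_csv(out / "metrics.tsv", sep="\t", index=False)

    covariates = ["age", "gender"]
    if config.fd_covariate and "mean_fd" in design.columns:
        covariates.append("mean_fd")

    reports: dict = {"n_subjects": len(design), "n_failures": len(failures)}
    errors: list[str] = []

    def stage(name, fn):
        try:
            reports[name] = fn()
            log.info("stage=%s status=ok", name)
        except MplexcogError as exc:
            errors.append(f"{name}: {exc}")
            log.error("stage=%s status=failed error=%s", name, exc)

    fpn_spec = _blockspec("ecfpn", covariates)
    dan_spec = _blockspec("ecdan", covariates)
    ecc_spec = _blockspec("ecc", covariates)

    def regression_stage(name, spec):
        def _run():
            res = stats_models.hierarchical_regression(design, spec)
            res.to_frame().to_csv(out / f"regression_{name}.tsv", sep="\t", index=False)
            (out / f"regression_{name}.json").write_text(res.to_json() + "\n")
            return res
        return _run

    stage("regression_fpn", regression_stage("fpn", fpn_spec))
    stage("regression_dan", regression_stage("dan", dan_spec))
    stage("regression_ecc", regression_stage("ecc", ecc_spec))

    def quad_stage():
        subset = design[design["group"] == "HC"] if "group" in design.columns else design
        res = stats_models.quadratic_age_model(
            subset["ecfpn_multiplex"].to_numpy(), subset["age"].to_numpy()
        )
        res.to_frame().to_csv(out / "quadratic_age.tsv", sep="\t", index=False)
        (out / "quadratic_age.json").write_text(res.to_json() + "\n")
        return res

    stage("quadratic_age", quad_stage)

    def cv_stage(name, spec):
        def _run():
            res = stats_models.leave_site_out_cv(
                design, spec, r2_baseline=config.r2_baseline
            )
            res.to_frame().to_csv(out / f"lso_cv_{name}.tsv", sep="\t", index=False)
            return res
        return _run

    if design["site"].nunique() >= 2:
        stage("lso_cv_fpn", cv_stage("fpn", fpn_spec))
        stage("lso_cv_ecc", cv_stage("ecc", ecc_spec))

    count, proportion = stats_models.impairment_rate(design["sdmt_z"].to_numpy())
    reports["impairment"] = {"count": count, "proportion": proportion}

    summary = {
        "seed": config.seed,
        "mode": config.mode,
        "parcellation": parcellation.name,
        "n_regions": parcellation.n_regions,
        "n_subjects": len(design),
        "failures": failures,
        "impairment": reports["impairment"],
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stage_errors": errors,
    }
    for name in ("lso_cv_fpn", "lso_cv_ecc"):
        if name in reports:
            cv = reports[name]
            summary[name] = {
                "n_folds": len(cv.folds),
                "mean_r2": cv.mean_r2,
                "sd_r2": cv.sd_r2,
                "levene_f": cv.levene_f,
                "levene_p": cv.levene_p,
            }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    if errors:
        raise PipelineError("; ".join(errors))
    reports["summary"] = summary
    return reports
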