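"""End-to-end orchestration: run every stage and write result tables.

Artifacts are tidy TSV tables written in stage order (QC report,
variability, differential screens, trajectory clusters, clinical
correlations, panel definitions and scores, burden labels, lipoprotein
aggregates) plus a machine-readable JSON manifest with the configuration
hash, seed and per-stage row counts.  A stage failure aborts the run with
the stage name and leaves a ``FAILED`` marker next to the partial
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clinical_mod
from . import differential, io, lipoproteins, panels, preprocess, qc, trajectories
from . import variability as variability_mod
from .config import PipelineConfig
from .model import NotEvaluableError, PlasmaProfilerError, ValidationError
from .panels import EmptyPanelError
from .simulate import generate_cohort
from .trajectories import zscored_profiles

logger = logging.getLogger(__name__)


class StageError(PlasmaProfilerError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t")
    return len(df)


def run_pipeline(config: PipelineConfig | str | Path) -> Path:
    """Run all stages under ``config`` (a :class:`PipelineConfig` or YAML path)."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("plasmaprofiler")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }
    thr = config.thresholds
    stage = "load"
    t0 = time.monotonic()
    try:
        if config.synthetic:
            cohort = generate_cohort(config.cohort)
            matrix, clin, annotations, truth = cohort
            manifest["truth"] = {
                "n_proteins": int(len(truth.proteins)),
                "n_runs": int(len(truth.runs)),
                "n_individuals": int(len(truth.individuals)),
            }
        else:
            matrix = io.read_intensity_matrix(
                config.intensity_path,
                dialect=config.intensity_dialect,
                samples=config.samples_path,
            )
            annotations = io.read_annotations(config.annotations_path)
            clin = (
                io.read_clinical_table(config.clinical_path)
                if config.clinical_path
                else None
            )
        logger.info("stage load done in %.2fs", time.monotonic() - t0)

        stage = "qc"
        t0 = time.monotonic()
        report = qc.qc_report(
            matrix,
            annotations,
            lysis_threshold_log2=thr.lysis_threshold_log2,
            coagulation_threshold_log2=thr.coagulation_threshold_log2,
            min_shared=thr.min_shared_proteins,
        )
        manifest["stages"]["qc_runs"] = _write(report.run_scores, outdir / "qc_runs.tsv")
        manifest["stages"]["qc_replicates"] = _write(
            report.replicate_groups, outdir / "qc_replicates.tsv"
        )
        manifest["cohort_mean_replicate_r"] = report.cohort_mean_r
        if thr.exclude_flagged_runs:
            bad = set(report.lysis_flagged) | set(report.coagulation_flagged)
            keep = [r for r in matrix.values.columns if r not in bad]
            matrix = matrix.subset_runs(keep)
            logger.info("excluded %d QC-flagged run(s)", len(bad))
        logger.info("stage qc done in %.2fs", time.monotonic() - t0)

        stage = "preprocess"
        t0 = time.monotonic()
        matrix = preprocess.remove_flagged_proteins(matrix)
        agg = preprocess.aggregate_replicates(matrix, method=thr.aggregation_method)
        manifest["stages"]["aggregated_proteins"] = agg.values.shape[0]
        logger.info("stage preprocess done in %.2fs", time.monotonic() - t0)

        stage = "variability"
        t0 = time.monotonic()
        records = variability_mod.variability_records(agg)
        manifest["stages"]["variability_records"] = _write(
            records, outdir / "variability.tsv"
        )
        if len(records):
            summary = variability_mod.cohort_specificity_summary(records)
            manifest["specificity_summary"] = summary
        logger.info("stage variability done in %.2fs", time.monotonic() - t0)

        stage = "differential"
        t0 = time.monotonic()
        post_weeks = tuple(w for w in agg.weeks if w > -8)
        for w in post_weeks:
            screen = differential.differential_screen(
                agg, -8, w, alpha=thr.fdr_alpha, high_p=thr.high_significance_p
            )
            manifest["stages"][f"differential_w{w}"] = _write(
                screen, outdir / f"differential_week{w}.tsv"
            )
        longterm = differential.long_term_effects(
            agg, weeks=post_weeks, alpha=thr.fdr_alpha,
            min_weeks=min(thr.min_consistent_weeks, len(post_weeks)),
        )
        manifest["stages"]["long_term"] = _write(longterm, outdir / "long_term.tsv")
        high_sig = differential.highly_significant_proteins(
            agg, weeks=post_weeks, high_p=thr.high_significance_p
        )
        logger.info("stage differential done in %.2fs", time.monotonic() - t0)

        stage = "trajectories"
        t0 = time.monotonic()
        traj = trajectories.trajectory_table(
            agg, high_sig, k=thr.n_clusters
        ) if len(high_sig) >= 2 else pd.DataFrame()
        manifest["stages"]["trajectories"] = _write(
            traj, outdir / "trajectory_clusters.tsv"
        )
        logger.info("stage trajectories done in %.2fs", time.monotonic() - t0)

        stage = "clinical_correlation"
        corr_tables: dict[str, pd.DataFrame] = {}
        if clin is not None:
            t0 = time.monotonic()
            corr_tables = clinical_mod.correlate_variables(
                agg, clin, min_n=thr.min_corr_n, alpha=thr.fdr_alpha
            )
            for var, table in corr_tables.items():
                safe = var.replace("/", "_").replace(" ", "_")
                manifest["stages"][f"correlation_{safe}"] = _write(
                    table, outdir / f"correlation_{safe}.tsv"
                )
            logger.info("stage clinical done in %.2fs", time.monotonic() - t0)

        stage = "panels"
        t0 = time.monotonic()
        high_sig_genes = set(matrix.proteins.loc[high_sig, "gene_symbol"])
        panel_info: dict = {}
        try:
            inflammation = panels.build_inflammation_set(
                high_sig_genes, annotations,
                matrix_genes=set(matrix.proteins["gene_symbol"]),
            )
            panel_info["inflammation"] = list(inflammation.members)
            slopes = panels.cohort_panel_slopes(agg, inflammation)
            manifest["stages"]["panel_slopes"] = _write(
                slopes, outdir / "panel_member_slopes.tsv"
            )
            bmi_panel = None
            if "BMI" in corr_tables:
                try:
                    bmi_panel = panels.select_bmi_panel(
                        inflammation, corr_tables["BMI"]
                    )
                    panel_info["bmi_panel"] = list(bmi_panel.members)
                except EmptyPanelError as exc:
                    logger.warning("BMI panel selection: %s", exc)
            score_panel = bmi_panel or inflammation
            benefit = panels.benefit_table(
                agg, score_panel, min_weeks=thr.min_panel_weeks
            )
            manifest["stages"]["benefit"] = _write(
                benefit, outdir / "panel_benefit.tsv"
            )
            manifest["n_benefit_negative_slope"] = int(benefit["benefit"].sum())
            if "HOMA-IR" in corr_tables:
                pro, anti = panels.build_ir_panels(
                    corr_tables["HOMA-IR"], annotations,
                    k_pos=thr.k_pro_ir, k_neg=thr.k_anti_ir,
                )
                panel_info["pro_IR"] = list(pro.members)
                panel_info["anti_IR"] = list(anti.members)
                burden = panels.stratify_burden(agg, score_panel, pro, anti)
                manifest["stages"]["burden"] = _write(
                    burden, outdir / "burden_labels.tsv"
                )
        except EmptyPanelError as exc:
            logger.warning("panel stage: %s", exc)
        with open(outdir / "panel_definitions.json", "w", encoding="utf-8") as fh:
            json.dump(panel_info, fh, indent=2, sort_keys=True)
        logger.info("stage panels done in %.2fs", time.monotonic() - t0)

        stage = "lipoproteins"
        t0 = time.monotonic()
        gene_profiles = trajectories.median_profiles(agg)
        gene_profiles.index = matrix.proteins.loc[gene_profiles.index, "gene_symbol"]
        z_prof = zscored_profiles(gene_profiles).dropna()
        particles = lipoproteins.particle_profiles(z_prof, annotations)
        gobp = lipoproteins.gobp_keyword_profiles(z_prof, annotations)
        rows = [
            {"level": "GOCC_particle", "term": p.term,
             "members": ";".join(p.members),
             **{f"week_{w}": v for w, v in p.profile.items()}}
            for p in particles
        ] + [
            {"level": "GOBP_term", "term": p.term,
             "members": ";".join(p.members),
             **{f"week_{w}": v for w, v in p.profile.items()}}
            for p in gobp
        ]
        lipo = pd.DataFrame(rows)
        manifest["stages"]["lipoproteins"] = _write(
            lipo.set_index("term") if len(lipo) else lipo,
            outdir / "lipoprotein_aggregates.tsv",
        )
        try:
            ratio = lipoproteins.cohort_apob_apoa1(agg)
            manifest["stages"]["apob_apoa1"] = _write(
                ratio, outdir / "apob_apoa1_ratio.tsv"
            )
        except NotEvaluableError as exc:
            logger.warning("APOB/APOA1 ratio: %s", exc)
        logger.info("stage lipoproteins done in %.2fs", time.monotonic() - t0)

        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    except Exception as exc:  # noqa: BLE001 - annotate with stage and re-raise
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n", encoding="utf-8")
        raise StageError(stage, exc) from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir
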