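"""Pipeline configuration: a single YAML document with analysis thresholds.

Every threshold named in the analysis stages is a configuration key whose
default is the value used in the study; the synthetic block mirrors
:class:`plasmaprofiler.simulate.CohortConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import ValidationError
from .simulate import CohortConfig


@dataclass
class Thresholds:
    """Analysis-stage thresholds (study defaults)."""

    lysis_threshold_log2: float = 3.0
    coagulation_threshold_log2: float = -2.0
    min_shared_proteins: int = 10
    exclude_flagged_runs: bool = False
    aggregation_method: str = "median"
    cv_cutoff: float = 0.30
    fold_cutoff_2x_log2: float = 1.0
    fold_cutoff_5x_log2: float = float(np.log2(5))
    tight_fold_log2: float = float(np.log2(1.3))
    tight_cv: float = 0.20
    fdr_alpha: float = 0.05
    high_significance_p: float = 5e-4
    min_consistent_weeks: int = 5
    n_clusters: int = 7
    min_corr_n: int = 10
    k_pro_ir: int = 4
    k_anti_ir: int = 5
    min_panel_weeks: int = 3


@dataclass
class PipelineConfig:
    """Inputs (files or a synthetic request), output directory, thresholds."""

    outdir: str = "results"
    seed: int = 0
    synthetic: bool = True
    intensity_path: str | None = None
    intensity_dialect: str = "proteingroups"
    samples_path: str | None = None
    clinical_path: str | None = None
    annotations_path: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self) -> None:
        if not self.outdir:
            raise ValidationError("an output directory must be configured")
        if not self.synthetic:
            for name in ("intensity_path", "samples_path", "annotations_path"):
                if getattr(self, name) is None:
                    raise ValidationError(f"{name} is required without synthetic data")
        self.cohort.seed = int(self.seed)
        self.cohort.validate()

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["archetype_probs"] = dict(d["cohort"]["archetype_probs"])
        d["cohort"]["clinical_links"] = {
            k: [list(t) for t in v] for k, v in d["cohort"]["clinical_links"].items()
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if "clinical_links" in cohort and cohort["clinical_links"] is not None:
            cohort["clinical_links"] = {
                k: tuple((g, float(r)) for g, r in v)
                for k, v in cohort["clinical_links"].items()
            }
        for key in ("weeks", "baseline_log2_range", "roster_log2_range",
                    "sigma_b_range", "sigma_t_range", "down_pct_range",
                    "up_pct_range", "bmi_range"):
            if key in cohort and cohort[key] is not None:
                cohort[key] = tuple(cohort[key])
        thresholds = d.pop("thresholds", {})
        return cls(
            cohort=CohortConfig(**cohort),
            thresholds=Thresholds(**thresholds),
            **d,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def content_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("outdir", None)
        payload = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
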