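"""Validated pipeline configuration.

A :class:`PipelineConfig` describes one reproducible end-to-end run:
either simulated or on-disk inputs for the bulk and single-cell stages,
plus every stage's thresholds and seeds. Unknown keys are rejected, the
config round-trips losslessly through YAML, and a canonical hash of the
parameter values identifies the run.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BulkSimConfig(_Strict):
    n_genes: int = 2000
    n_reps: int = 3
    baseline_log_mu: float = 4.0
    baseline_log_sigma: float = 1.0
    dispersion: float = 0.1
    effect_wt_only: float = 16.0
    effect_shared: float = 16.0
    effect_ko_only: float = 16.0
    effect_down: float = 1.0 / 16.0
    n_per_class: int = 100
    libsize_min: float = 0.5
    libsize_max: float = 2.0
    seed: int = 1


class BulkInputConfig(_Strict):
    counts: str
    design: str


class DEConfig(_Strict):
    min_count: int = 10
    min_total: int = 15
    fc_threshold: float = 8.0
    adjp_threshold: float = 0.01


class HomologConfig(_Strict):
    table: str | None = None  # path to a TSV; None simulates one
    p_unmapped: float = 0.2
    p_one_to_many: float = 0.1
    seed: int = 2


class SCSimConfig(_Strict):
    n_kc: int = 800
    n_myeloid: int = 400
    n_tc: int = 400
    n_mel: int = 400
    n_background_genes: int = 1500
    depth: float = 5000.0
    dispersion: float = 0.1
    stressed_fraction: float = 0.2
    activity_fold: float = 8.0
    coupling_fold: float = 8.0
    qc_fail_fraction: float = 0.05
    n_signature_genes: int = 11
    seed: int = 3


class SCInputConfig(_Strict):
    mtx_dir: str
    metadata: str


class ScoreConfig(_Strict):
    dataset_preset: str = "psor"  # psor | hs | ad
    scale: float = 10_000.0
    high_pct: float = 95.0
    med_pct: float = 75.0
    association_genes: tuple[str, ...] = ("KRT6A", "KRT17")

    @model_validator(mode="after")
    def _check(self):
        if self.dataset_preset not in ("psor", "hs", "ad"):
            raise ValueError("dataset_preset must be one of psor, hs, ad")
        if self.high_pct <= self.med_pct:
            raise ValueError("high_pct must be > med_pct")
        return self


class ClassifyConfig(_Strict):
    table: str | None = None  # None uses the bundled TAR11 table
    ratio_threshold: float = 2.0


class PipelineConfig(_Strict):
    version: str = "1"
    out_dir: str = "tarsig_run"
    bulk_sim: BulkSimConfig | None = BulkSimConfig()
    bulk_input: BulkInputConfig | None = None
    de: DEConfig = DEConfig()
    homolog: HomologConfig = HomologConfig()
    sc_sim: SCSimConfig | None = SCSimConfig()
    sc_input: SCInputConfig | None = None
    score: ScoreConfig = ScoreConfig()
    classify: ClassifyConfig = ClassifyConfig()

    @model_validator(mode="after")
    def _check(self):
        if self.bulk_sim is None and self.bulk_input is None:
            raise ValueError("either bulk_sim or bulk_input must be given")
        if self.sc_sim is None and self.sc_input is None:
            raise ValueError("either sc_sim or sc_input must be given")
        return self

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def load_config(path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)
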