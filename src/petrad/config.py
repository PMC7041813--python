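"""Pipeline configuration: every analysis constant in one place.

Defaults are the study's stated values: SUV threshold 2.5 (strict) and
40% of SUVmax (inclusive) for segmentation; 0.25 SUV fixed bin width and
64 fixed bins for discretization; 30% coefficient-of-repeatability
cut-off (15% alternative); |rho| >= 0.5 independence discard (0.7
alternative); elastic net with 20-fold CV, 100 repetitions of an 80/20
train/validation split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features.registry import ExtractionConfig

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # segmentation + binning
    abs_threshold: float = 2.5
    rel_fraction: float = 0.40
    bin_width: float = 0.25
    bin_count: int = 64
    # repeatability
    cr_threshold_pct: float = 30.0       # PERCIST-derived; 15.0 = phantom-study alternative
    cr_convention: str = "bland_altman"  # or "within_subject"
    # independence
    rho_cutoff: float = 0.5              # 0.7 supported as an alternative
    # modelling
    l1_ratio: float = 0.5
    cv_folds: int = 20
    n_repetitions: int = 100
    train_fraction: float = 0.8
    n_lambda: int = 50
    best_model_rule: str = "max_auc"     # or "median_auc"
    # simulation sizes
    n_patients: int = 252
    n_repeat_patients: int = 70
    n_external: int = 40
    # seeds
    seed: int = 0

    def extraction(self) -> ExtractionConfig:
        return ExtractionConfig(
            abs_threshold=self.abs_threshold,
            rel_fraction=self.rel_fraction,
            bin_width=self.bin_width,
            bin_count=self.bin_count,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
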