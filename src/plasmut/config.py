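"""Run configuration loaded from JSON or YAML."""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .amplicon import SNP_EXCLUDED_LABELS
from .error_model import ALPHA_DEFAULT, RATIO_CUTOFF_DEFAULT


class RunConfig(BaseModel):
    """Paths and statistical settings for one pipeline run."""

    panel: Path | None = None
    models: Path | None = None
    reads: Path | None = None
    sam: Path | None = None
    counts: Path | None = None
    index_table: Path | None = None
    out_dir: Path = Path(".")
    alpha: float = ALPHA_DEFAULT
    ratio_cutoff: float = RATIO_CUTOFF_DEFAULT
    ddof: int = 0
    bonferroni: bool = False
    excluded_snps: list[str] = Field(default_factory=lambda: list(SNP_EXCLUDED_LABELS))
    seed: int = 0
    verbosity: int = 1

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: float) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.model_validate(data or {})

    def config_hash(self) -> str:
        import hashlib

        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
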