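"""Run configuration: schema-validated parameters for the pipeline.

Defaults are the analysis' standard parameters: minimum read length 24 nt,
ISR window offsets 12 nt (upstream of the canonical stop) and 22 nt
(upstream of the downstream stop), conservation threshold 0.8, sense-strand
mapping.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class RunConfig(BaseModel):
    """Validated configuration for :func:`tcrkit.pipeline.run_pipeline`."""

    # inputs
    fasta: Optional[Path] = None
    cds: Optional[Path] = None
    fastq: list[Path] = Field(default_factory=list)
    peptides: Optional[Path] = None
    luciferase: Optional[Path] = None
    with_stop: str = "with_stop"
    no_stop: str = "no_stop"
    background: Optional[str] = None
    # parameters
    upstream_offset: int = Field(default=12, ge=0)
    downstream_offset: int = Field(default=22, ge=0)
    min_read_len: int = Field(default=24, ge=1)
    tau: float = Field(default=0.8, gt=0.0, le=1.0)
    strand: Literal["sense", "both"] = "sense"
    adapter: Optional[str] = None
    assignment_rule: Literal["five_prime", "majority"] = "five_prime"
    paired_comparison: bool = False
    seed: int = 0
    outdir: Path = Path("tcr_out")

    @field_validator("adapter")
    @classmethod
    def _adapter_alphabet(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and (not v or set(v.upper()) - set("ACGT")):
            raise ValueError("adapter must be a non-empty ACGT string")
        return v.upper() if v else v


def load_config(path: Path | str) -> RunConfig:
    """Load and validate a YAML config; field-level errors name the field."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    return RunConfig(**data)
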