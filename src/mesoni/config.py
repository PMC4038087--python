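"""Run configuration: every threshold the pipeline uses, in one place.

Printed quantities (substitution counts, PED values, cluster counts) are
threshold-sensitive, so every report embeds the resolved configuration and
its hash; results always travel with the parameters that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .orf_architecture import ArchitectureParams
from .pairwise import AlignParams


@dataclass
class PipelineConfig:
    # genome_io
    polya_min_run: int = 5
    allow_ambiguous: bool = False
    # orf_architecture
    min_orf1a_nt: int = 3000
    min_orf2a_nt: int = 2000
    min_orf3a_nt: int = 500
    orf4_range_nt: tuple[int, int] = (120, 200)
    min_small_orf_nt: int = 180
    # pairwise
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    protein_matrix: str = "BLOSUM62"
    band: int = 2000          # diagonal half-width for genome-scale pairs
    exact: bool = False       # full-matrix alignment regardless of size
    insertion_min_block: int = 30
    insertion_min_identity: float = 0.30
    insertion_scan_nt: int = 2600   # 5' ORF1a window scanned vs the reference
    repeat_seed: str = "SKRKGK"
    repeat_max_mismatch: int = 2
    # demarcation
    model: str = "WAG"
    gamma_shape: float | None = None   # None = no rate heterogeneity (default)
    species_threshold: float = 0.032
    linkage: str = "single"
    window: int = 100
    window_step: int = 25
    reference_domains: str | None = None  # FASTA path; None = packaged set

    def arch_params(self) -> ArchitectureParams:
        return ArchitectureParams(
            min_orf1a_nt=self.min_orf1a_nt,
            min_orf2a_nt=self.min_orf2a_nt,
            min_orf3a_nt=self.min_orf3a_nt,
            orf4_range_nt=tuple(self.orf4_range_nt),
            min_small_orf_nt=self.min_small_orf_nt,
        )

    def align_params(self) -> AlignParams:
        return AlignParams(
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            protein_matrix=self.protein_matrix,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
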