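"""Pipeline configuration: every tunable threshold in one validated object.

The config round-trips through a simple ``key = value`` text format; CLI
flags override file values and the effective config is echoed into the
output directory for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields


@dataclass
class PipelineConfig:
    # QC
    low_quality_threshold: int = 20  # Phred; "low quality" = below this
    max_low_fraction: float = 0.5  # drop pair if either mate exceeds this
    # element geometry
    ltr_length: int = 610
    terminal_length: int = 90
    # classification
    min_element_match: int = 15
    min_identity: float = 0.9
    min_genomic_tail: int = 20
    full_match_slack: int = 3
    # aligner
    terminal_k: int = 11  # seeds for read-vs-terminal matching
    genome_k: int = 13  # seeds for genome mapping
    match: int = 1
    mismatch: int = -2
    gap: int = -3
    # assembly
    assembly_k: int = 21
    min_kmer_count: int = 2
    # locus calling
    cluster_window: int = 100
    hc_min_support: int = 3
    node_attach_dist: int = 700
    min_mapped_len: int = 20
    min_map_identity: float = 0.9
    min_map_coverage: float = 0.8
    min_span: int = 3
    # stats
    fst_window: int = 100
    # simulation
    seed: int = 1

    def validate(self) -> "PipelineConfig":
        if not 0 <= self.max_low_fraction <= 1:
            raise ValueError("max_low_fraction must be in [0, 1]")
        if self.low_quality_threshold < 0:
            raise ValueError("low_quality_threshold must be >= 0")
        if not 0 < self.terminal_length <= self.ltr_length:
            raise ValueError("need 0 < terminal_length <= ltr_length")
        if self.min_element_match < 1 or self.min_genomic_tail < 1:
            raise ValueError("classification minima must be positive")
        if not 0 <= self.min_identity <= 1 or not 0 <= self.min_map_identity <= 1:
            raise ValueError("identity thresholds must be in [0, 1]")
        if not 0 <= self.min_map_coverage <= 1:
            raise ValueError("min_map_coverage must be in [0, 1]")
        if self.terminal_k < 8 or self.genome_k < 8:
            raise ValueError("seed k-mers must be >= 8")
        if not (15 <= self.assembly_k <= 31) or self.assembly_k % 2 == 0:
            raise ValueError("assembly_k must be odd and within [15, 31]")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")
        if self.cluster_window < 0 or self.node_attach_dist < 0:
            raise ValueError("windows must be non-negative")
        if self.hc_min_support < 1 or self.min_span < 1:
            raise ValueError("support thresholds must be >= 1")
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("scoring must have positive match, negative mismatch/gap")
        return self

    def to_text(self) -> str:
        lines = ["# tntscan pipeline configuration"]
        for f in fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        values: dict[str, object] = {}
        types = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value', got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in types:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            caster = float if types[key] == "float" else int
            values[key] = caster(value)
        return cls(**values).validate()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_text(fh.read())

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:12]
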