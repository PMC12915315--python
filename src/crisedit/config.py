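"""Run configuration: the design constants shared by all subcommands.

Defaults are the constants of the host Type I-G system: 5'-TAT-3' PAM, 35 bp
spacers, an 8-position PAM-proximal seed, 600/1000 bp homology-arm presets,
and 100 bp upstream + 400 bp coding deletion windows. Precedence is CLI flag
> config file > built-in default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .seqio import DNA_ALPHABET


@dataclass
class RunConfig:
    pam: str = "TAT"
    spacer_len: int = 35
    seed_len: int = 8
    arm_presets: list[int] = field(default_factory=lambda: [600, 1000])
    upstream_bp: int = 100
    coding_bp: int = 400
    max_total_mismatches: int = 5
    k_spacers: int = 3
    enzyme_motifs: dict = field(
        default_factory=lambda: {"PciI": "ACATGT", "BspHI": "TCATGA"}
    )
    fixture_seed: int = 42

    def validate(self) -> "RunConfig":
        if not self.pam or set(self.pam) - DNA_ALPHABET:
            raise ConfigError(f"pam: invalid motif {self.pam!r}")
        if self.spacer_len < 1:
            raise ConfigError(f"spacer_len: must be positive, got {self.spacer_len}")
        if not 0 <= self.seed_len <= self.spacer_len:
            raise ConfigError(
                f"seed_len: must lie in [0, spacer_len], got {self.seed_len}"
            )
        if not self.arm_presets or any(a < 1 for a in self.arm_presets):
            raise ConfigError(f"arm_presets: invalid {self.arm_presets!r}")
        if self.upstream_bp < 0 or self.coding_bp < 1:
            raise ConfigError("upstream_bp/coding_bp: must be non-negative/positive")
        if self.max_total_mismatches < 0:
            raise ConfigError("max_total_mismatches: must be non-negative")
        if self.k_spacers < 1:
            raise ConfigError("k_spacers: must be positive")
        for name, motif in self.enzyme_motifs.items():
            if len(motif) < 4 or set(motif) - DNA_ALPHABET:
                raise ConfigError(f"enzyme_motifs.{name}: invalid motif {motif!r}")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load YAML or JSON; unknown keys raise ConfigError naming them."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        known = set(cls().__dict__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data).validate()

    def digest(self) -> str:
        """Short stable digest of the effective configuration."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
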