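"""Run configuration.

Defaults follow the conventional choices for genus-level Cytb surveys:
pairwise deletion of gapped/ambiguous sites, sample (n-1) standard
deviations, K2P distances in percent.  A YAML config file can set any field;
CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigError

_DELETION_MODES = ("pairwise", "complete")
_SD_DENOMINATORS = ("sample", "population")


@dataclass
class RunConfig:
    """Configuration shared by the CLI and :func:`genusrank.twosigma.run_protocol`.

    deletion_mode      -- "pairwise" (default) or "complete" site deletion
    sd_denominator     -- "sample" (n-1, default) or "population" (n) for
                          per-comparison and within-genus SDs
    exclusions         -- genera removed from the sister analysis entirely
    aliases            -- analysis label -> list of genera merged under it
                          (sensu-lato analyses as pure configuration)
    allow_nonmonophyletic -- audit-and-continue instead of halting on a
                          non-monophyletic genus
    root_on            -- tip species_id to reroot the input tree on
    header_regex       -- FASTA header parsing override (named groups)
    seed               -- random seed for simulation subcommands
    plot               -- write bar-chart figures alongside reports
    """

    deletion_mode: str = "pairwise"
    sd_denominator: str = "sample"
    exclusions: tuple = ()
    aliases: dict = field(default_factory=dict)
    allow_nonmonophyletic: bool = False
    root_on: str | None = None
    header_regex: str | None = None
    output_dir: str = "."
    seed: int = 0
    plot: bool = False

    def __post_init__(self):
        if self.deletion_mode not in _DELETION_MODES:
            raise ConfigError(
                f"deletion_mode must be one of {_DELETION_MODES}, "
                f"got {self.deletion_mode!r}"
            )
        if self.sd_denominator not in _SD_DENOMINATORS:
            raise ConfigError(
                f"sd_denominator must be one of {_SD_DENOMINATORS}, "
                f"got {self.sd_denominator!r}"
            )
        self.exclusions = tuple(self.exclusions)
        self.aliases = {k: tuple(v) for k, v in dict(self.aliases).items()}

    @property
    def ddof(self) -> int:
        """Delta degrees of freedom matching ``sd_denominator``."""
        return 1 if self.sd_denominator == "sample" else 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
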