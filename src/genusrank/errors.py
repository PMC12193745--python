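"""Exception hierarchy for genusrank.

All package errors derive from :class:`GenusRankError` so callers can catch
one base class at a pipeline boundary (the CLI maps them to exit codes).
"""


class GenusRankError(Exception):
    """Base class for all genusrank errors."""


class InputError(GenusRankError):
    """Malformed or empty input file."""


class AlignmentLengthError(InputError):
    """Sequences in one alignment have unequal lengths."""


class SequenceValidationError(InputError):
    """A residue outside the IUPAC DNA alphabet (plus gap/missing codes)."""


class SchemaError(InputError):
    """Taxonomy table is missing a required column."""


class DuplicateSpeciesError(InputError):
    """Taxonomy table contains the same species_id twice."""


class NoOverlapError(GenusRankError):
    """A sequence pair shares no unambiguous A/C/G/T columns."""


class TreeError(GenusRankError):
    """Base class for phylogeny-related errors."""


class UnmatchedTipError(TreeError):
    """Tree tips that do not resolve to a taxonomy-table species."""


class RootingError(TreeError):
    """Tree cannot be interpreted as rooted without user guidance."""


class MonophylyError(TreeError):
    """A genus required to be monophyletic is not."""


class GenusNotFoundError(TreeError):
    """A genus name that has no tips in the tree."""


class EmptyComparisonError(GenusRankError):
    """A sister comparison with zero defined pairwise distances."""


class InsufficientDataError(GenusRankError):
    """Too few observations for the requested statistic."""


class DegenerateDistributionError(GenusRankError):
    """A distribution with zero spread where spread is required."""


class SimulationSpecError(GenusRankError):
    """Invalid simulation specification (branch lengths, sizes, depths)."""


class ConfigError(GenusRankError):
    """Invalid run configuration value."""
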