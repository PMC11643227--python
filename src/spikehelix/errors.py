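"""Typed exceptions raised across the package.

All inherit from :class:`SpikeHelixError` so callers can catch the package's
failures with a single except clause; most double as ``ValueError`` so that
generic validation code keeps working.
"""


class SpikeHelixError(Exception):
    """Base class for all spikehelix errors."""


class InvalidWindowError(SpikeHelixError, ValueError):
    """Analysis window length is not a positive number."""


class OutOfWindowError(SpikeHelixError, ValueError):
    """A spike time falls outside the analysis window [0, T]."""


class InvalidSizeError(SpikeHelixError, ValueError):
    """Population size N is not a positive integer."""


class InvalidHelixError(SpikeHelixError, ValueError):
    """Helix index k outside the valid range 1..N."""


class InvalidPermutationError(SpikeHelixError, ValueError):
    """A neuron relabeling is not a bijection on 1..N."""


class UndefinedDirectionError(SpikeHelixError, ValueError):
    """Spike attribution requested for a helix with zero contribution."""


class DegeneratePatternError(SpikeHelixError, ValueError):
    """An operation that needs spikes was handed an empty pattern."""


class InsufficientTrialsError(SpikeHelixError, ValueError):
    """A per-condition operation was given too few trials."""


class ShapeMismatchError(SpikeHelixError, ValueError):
    """Two objects that must share a population size N (or length) do not."""


class InvalidDimensionError(SpikeHelixError, ValueError):
    """Requested embedding dimension outside 2..N_T."""


class StratificationError(SpikeHelixError, ValueError):
    """A cross-validation fold would miss one of the classes."""


class DegenerateClustersError(SpikeHelixError, ValueError):
    """Cluster geometry is degenerate (zero inter- and intra-cluster spread)."""


class SpikeFileError(SpikeHelixError, ValueError):
    """A spike/paths CSV file is malformed (missing columns, bad types, empty)."""
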