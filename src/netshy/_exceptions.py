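"""Exception hierarchy for netshy.

All errors raised by the library derive from :class:`NetshyError` so callers
can catch one base class at the CLI boundary.
"""


class NetshyError(Exception):
    """Base class for all netshy errors."""


class InvalidNetworkError(NetshyError):
    """Adjacency matrix violates the weighted-network contract
    (asymmetry, negative weights, nonzero diagonal, bad size)."""


class NoHubError(NetshyError):
    """A hub node was requested on a network with no edges."""


class AlignmentError(NetshyError):
    """Profile feature labels do not match network node labels."""


class DegenerateInputError(NetshyError):
    """Input carries no usable variation (constant matrix/vector,
    zero-norm loading)."""


class DegenerateTopologyError(NetshyError):
    """Network topology makes the requested summarization meaningless
    (e.g. Laplacian of an empty graph is the zero matrix)."""


class ScheduleError(NetshyError):
    """A subsampling schedule is inconsistent with the master sample size."""


class ConfigError(NetshyError):
    """A configuration document failed validation."""
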