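"""Exception hierarchy.

Everything raised by hemlink derives from :class:`HemlinkError`, so callers
(and the CLI) can catch one type. Each subclass also inherits the matching
builtin so idiomatic ``except ValueError`` code keeps working.
"""


class HemlinkError(Exception):
    """Base class for all hemlink errors."""


class ParameterError(HemlinkError, ValueError):
    """An operation was called with invalid numeric parameters."""


class ConfigurationError(HemlinkError, ValueError):
    """An index or run configuration is malformed (e.g. unknown index name)."""


class GraphError(HemlinkError, ValueError):
    """A graph violates the undirected-simple-graph contract."""


class EdgeListParseError(GraphError):
    """An edge-list file contains a malformed line."""


class EmptyGraphError(GraphError):
    """An edge-list file or pipeline stage produced a graph with no edges."""


class DisconnectedGraphError(GraphError):
    """An operation requiring a connected graph received a disconnected one."""


class GenerationError(HemlinkError, RuntimeError):
    """A random generator failed to produce a valid graph within its restart budget."""


class WalkOverflowError(HemlinkError, OverflowError):
    """Walk counts exceeded the exactly-representable integer range of float64 (2**53)."""


class ConvergenceError(HemlinkError, ArithmeticError):
    """A series-based index was configured outside its convergence region."""


class MetricUndefinedError(HemlinkError, ValueError):
    """An evaluation metric is undefined for the given input (e.g. no nonexistent pairs)."""
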