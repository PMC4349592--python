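"""Exception taxonomy shared across the pipeline stages."""


class FormatError(ValueError):
    """Malformed input file (missing columns, broken links, orphan cells)."""


class AlignmentError(RuntimeError):
    """Temporal or spatial alignment cannot be computed (too few matches,
    degenerate geometry)."""


class StateError(RuntimeError):
    """An operation was invoked out of order (e.g. defect calling on an
    unaligned embryo)."""


class QueryError(KeyError):
    """A reference query outside a cell's lifetime or for an unknown cell."""


class ConfigError(ValueError):
    """Invalid analysis configuration."""
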