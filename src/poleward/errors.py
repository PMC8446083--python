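"""Exception hierarchy.

Every validation failure raises a subclass of :class:`PolewardError` with a
message naming the offending field, feature, station or node, so that CLI
users see actionable errors (exit code 2) rather than tracebacks.
"""


class PolewardError(Exception):
    """Base class for all package errors."""


class ConfigError(PolewardError):
    """Invalid configuration value; the message names the field."""


class InputError(PolewardError):
    """Malformed or out-of-domain input data."""


class TaxonomyError(PolewardError):
    """Unknown node, cycle, or multiple roots in a taxonomy."""


class ImputationError(TaxonomyError):
    """A target node has no valued ancestor to impute from."""


class NormalizationError(PolewardError):
    """Missing/non-positive copy number or an all-zero station row."""


class ModelError(PolewardError):
    """Degenerate statistical model (rank deficiency, constant constraint)."""


class GridError(PolewardError):
    """Mismatched climate-grid shapes, coordinates or masks."""


class ScenarioError(PolewardError):
    """Gap-fill scenario with an empty donor pool."""
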