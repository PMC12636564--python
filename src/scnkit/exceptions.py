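"""Exception hierarchy used across the pipeline.

The CLI maps these onto exit codes: configuration problems (2), data
problems (3), numerical failures (4).
"""


class SCNError(Exception):
    """Base class for all scnkit errors."""


class ConfigError(SCNError):
    """Invalid or inconsistent run configuration."""


class DataError(SCNError):
    """Malformed, mismatched or insufficient input data."""


class NumericalError(SCNError):
    """A computation could not be carried out (singularity, divergence)."""


class RankDeficiencyError(NumericalError):
    """Covariance inversion requested with n_subjects <= n_variables."""


class DisconnectedGraphError(NumericalError):
    """Shortest-path metrics requested on a disconnected graph."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components


class DegenerateClusteringError(NumericalError):
    """A cluster-quality score is undefined for the given partition."""
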