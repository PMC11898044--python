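"""Exception hierarchy shared across the pipeline.

Each error class maps to a distinct command-line exit code so that batch
callers can dispatch on failure class without parsing log text.
"""


class SlbindError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class PDBParseError(SlbindError):
    """The input file could not be parsed as PDB."""

    exit_code = 2


class EmptyStructureError(SlbindError):
    """The parsed file contains no protein (ATOM) records."""

    exit_code = 2


class ChainSpecError(SlbindError):
    """Partner chain IDs are missing, overlapping, or absent from the model."""

    exit_code = 3


class GapRejectionError(SlbindError):
    """Strict mode: backbone gaps were found and the structure was rejected."""

    exit_code = 4

    def __init__(self, gaps):
        self.gaps = list(gaps)
        lines = ", ".join(
            f"chain {g.chain} {g.res_before}->{g.res_after} ({g.reason})" for g in self.gaps
        )
        super().__init__(f"structure rejected, backbone gaps: {lines}")


class CapabilityError(SlbindError):
    """A required external capability (descriptor engine) is unavailable."""

    exit_code = 5


class SchemaError(SlbindError):
    """A descriptor table or vector does not conform to its feature schema."""

    exit_code = 6


class DegenerateMetricError(SlbindError):
    """A metric is undefined for the given inputs (e.g. zero variance)."""

    exit_code = 1
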