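"""Exception hierarchy for the workflow engine.

Every engine-raised error derives from :class:`ProvflowError` so callers
(notably the CLI) can catch one type for the failing-fast initiation phase.
"""


class ProvflowError(Exception):
    """Base class for all engine errors."""


# --- configuration / parsing -------------------------------------------------

class ParseError(ProvflowError):
    """The YAML text is malformed or violates the documented config schema."""


class ConfigError(ProvflowError):
    """A configuration value is invalid (bad param, unknown constant, ...)."""


class UnknownStepError(ProvflowError):
    """A step type name is not present in the step registry."""


class UnknownDependencyError(ProvflowError):
    """A step's ``_depends`` entry names no configured step."""


class UnknownToolError(ProvflowError):
    """A step references a tool that the configuration does not declare."""


class DuplicateStepError(ProvflowError):
    """Two step definitions were registered under one type name."""


# --- graph construction ------------------------------------------------------

class CycleError(ProvflowError):
    """The step dependency relation contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("dependency cycle: " + " -> ".join(self.cycle + self.cycle[:1]))


class ConnectionMismatchError(ProvflowError):
    """An in-connection cannot be wired to exactly the required producers."""


class MergeMismatchError(ProvflowError):
    """Upstream steps of a merging step disagree on their run identifiers."""


# --- provenance --------------------------------------------------------------

class SerializationError(ProvflowError):
    """A run contains a value outside the canonical serialization domain."""


class FileMissingError(ProvflowError):
    """A required file (input, output, checksum target) does not exist."""


# --- execution / state -------------------------------------------------------

class StagingError(ProvflowError):
    """The staging (temp) directory could not be created."""


class ToolMissingError(ProvflowError):
    """A command's executable could not be found at spawn time."""


class VolatilizeRefusedError(ProvflowError):
    """Volatilization refused: a consumer of the run is not finished."""


class VolatilizedInputError(ProvflowError):
    """A run needs an input whose producing run has been volatilized."""

    def __init__(self, step_id, run_id, path):
        self.step_id = step_id
        self.run_id = run_id
        self.path = path
        super().__init__(
            f"input {path!r} was volatilized; re-execute run "
            f"{step_id}/{run_id} to restore it"
        )


class MalformedFastqError(ProvflowError):
    """A FASTQ file violates the 4-line record structure."""
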