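"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`RassError` so callers (and the CLI)
can distinguish user-input problems from internal failures.
"""


class RassError(Exception):
    """Base class for all package errors."""


class InputError(RassError):
    """Invalid user input (empty sequence, mismatched lengths, ...)."""


class ParameterError(RassError):
    """Inconsistent parameter combination (e.g. p_low > p_high)."""


class FormatError(RassError):
    """Unparseable or internally inconsistent file content."""


class SelectionError(RassError):
    """A requested chain, ligand or atom selection matched nothing."""


class CorrespondenceError(RassError):
    """Too few residues could be matched between two structures."""


class MetricError(RassError):
    """A similarity metric could not be computed on the given selection."""


class BackendError(RassError):
    """The external structure-prediction backend failed.

    Carries the subprocess diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: str = ""):
        super().__init__(message)
        self.diagnostics = diagnostics


class DegenerateEnsembleError(RassError):
    """All conformers are (numerically) identical; clustering is meaningless."""


class PipelineError(RassError):
    """A pipeline stage was invoked before its dependencies produced output."""
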