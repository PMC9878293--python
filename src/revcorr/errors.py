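"""Exception hierarchy for the toolkit.

Every error raised by revcorr derives from :class:`RevcorrError`, so callers
(and the CLI) can catch toolkit failures without swallowing programming bugs.
"""


class RevcorrError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(RevcorrError):
    """Invalid generation/simulation parameters; message names the field."""


class InputError(RevcorrError):
    """Malformed user input (images, trial logs, rating tables)."""


class SetMismatchError(RevcorrError):
    """A session, table, or CI refers to a stimulus set it was not built on."""


class CoverageError(RevcorrError):
    """A positivity table or score lookup lacks entries for required pairs."""

    def __init__(self, message: str, pair_ids=()):
        super().__init__(message)
        self.pair_ids = list(pair_ids)


class EmptySessionError(RevcorrError):
    """A session has zero answered trials and cannot be averaged or scored."""


class DegenerateDataError(RevcorrError):
    """A statistic is undefined on this input (zero variance, constant data)."""


class CollinearityError(RevcorrError):
    """The regression design matrix is rank deficient after standardization."""
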