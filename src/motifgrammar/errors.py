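"""Exception hierarchy.

Every error raised by this package derives from :class:`MotifGrammarError`
so callers (and the CLI) can catch simulator failures without swallowing
programming errors.
"""


class MotifGrammarError(Exception):
    """Base class for all simulator errors."""


class ConfigurationError(MotifGrammarError):
    """Invalid parameter or configuration value; names the offending field."""


class ParseError(MotifGrammarError):
    """A motif or instruction file did not parse under the declared dialect."""


class DataError(MotifGrammarError):
    """Input data is structurally valid but semantically unusable."""


class PlacementError(MotifGrammarError):
    """An instance cannot be placed at the requested coordinates."""


class SamplingError(MotifGrammarError):
    """A sampling step hit an undefined state (e.g. unseen Markov context)."""


class OutputError(MotifGrammarError):
    """Output directory or file problem (unwritable, would overwrite)."""
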