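"""Exception hierarchy for phraseseg."""


class PhrasesegError(Exception):
    """Base class for all package errors."""


class ParseError(PhrasesegError):
    """A file could not be parsed; message names the offending location."""


class MonophonicityError(ParseError):
    """Overlapping notes in an input that must be monophonic."""


class DomainError(PhrasesegError, ValueError):
    """An argument is outside its mathematical domain."""


class InsufficientDataError(PhrasesegError, ValueError):
    """Not enough observations/events for the requested computation."""


class AlignmentError(PhrasesegError, ValueError):
    """Two structures that must share a reference do not."""


class ConfigError(PhrasesegError, ValueError):
    """Invalid or inconsistent configuration."""


class DesignError(PhrasesegError, ValueError):
    """Experimental design is incomplete or unbalanced."""
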