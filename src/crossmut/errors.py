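"""Exception hierarchy shared across the pipeline.

Each error class carries the process exit code the command-line layer maps
it to: 2 for configuration problems, 3 for malformed input text, 4 for
internally inconsistent data (e.g. a call referencing an unknown contig).
"""


class CrossmutError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigError(CrossmutError):
    """Invalid configuration value or missing input path."""

    exit_code = 2


class ParseError(CrossmutError):
    """Malformed FASTA or mpileup text."""

    exit_code = 3


class FormatError(ParseError):
    """Alias used by the FASTA layer; same exit code as ParseError."""


class IntegrityError(CrossmutError):
    """Inputs that parse but contradict each other or their own ordering."""

    exit_code = 4


class ValidationError(IntegrityError):
    """Precondition violation on an in-memory object (unsorted input, duplicate id)."""
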