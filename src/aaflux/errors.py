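"""Exception hierarchy shared across the pipeline."""


class AafluxError(Exception):
    """Base class for all package errors."""


class FormatError(AafluxError, ValueError):
    """Malformed input file (FASTA, Newick, annotation, scale table)."""


class ConsistencyError(AafluxError, ValueError):
    """Inputs are individually valid but disagree with each other."""


class ContractError(AafluxError, ValueError):
    """An operation was called outside its stated precondition."""


class EligibilityError(AafluxError, ValueError):
    """A statistical test was requested on an ineligible sample."""


class ConfigError(AafluxError, ValueError):
    """Invalid or unknown configuration key/value."""
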