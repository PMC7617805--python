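"""Exception hierarchy for wadjetscan."""


class WadjetscanError(Exception):
    """Base class for all package errors."""


class ParseError(WadjetscanError):
    """Malformed input file (FASTA, gene table, catalog, config)."""


class ValidationError(WadjetscanError):
    """Domain-object invariant or precondition violated."""
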