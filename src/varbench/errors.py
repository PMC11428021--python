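"""Exception hierarchy shared across the toolkit."""


class VarbenchError(Exception):
    """Base class for all toolkit errors."""


class ParseError(VarbenchError):
    """A standard-format input file could not be parsed."""


class UnsupportedVariantError(VarbenchError):
    """A variant record uses a representation the comparator cannot evaluate
    (symbolic alleles such as <DEL>, breakends, star alleles)."""


class ReferenceMismatchError(VarbenchError):
    """A record's REF allele disagrees with the reference sequence."""


class ConfigError(VarbenchError):
    """An evaluation run configuration is invalid or incomplete."""
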