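"""Typed exceptions raised across the pipeline stages."""


class WrkyfamError(Exception):
    """Base class for all package errors."""


class FormatError(WrkyfamError):
    """Malformed input file (FASTA/GFF3/table)."""


class ReferenceError_(WrkyfamError):
    """A feature refers to an unknown sequence or parent."""


class AnnotationError(WrkyfamError):
    """Gene model lacks the feature an operation needs (e.g. no CDS)."""


class TranslationError(WrkyfamError):
    """CDS cannot be translated (internal stop, frame)."""


class InputError(WrkyfamError):
    """Invalid value passed to an operation (bad residue, empty sequence)."""


class SaturationError(WrkyfamError):
    """Substitution proportion at or beyond the Jukes-Cantor ceiling (p >= 3/4)."""
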