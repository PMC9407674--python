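"""Exception hierarchy for classdiv."""


class ClassdivError(Exception):
    """Base class for all classdiv errors."""


class FormatError(ClassdivError):
    """Input file does not conform to the expected dialect."""


class ValidationError(ClassdivError):
    """Data fail a semantic check (bad counts, non-canonical residues, ...)."""


class EmptyRepertoireError(ClassdivError):
    """An operation received a repertoire (or file) with no sequences."""


class DegenerateFitError(ClassdivError):
    """A distribution fit is undefined for the given sample."""
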