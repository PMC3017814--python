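"""Exception hierarchy shared across the package."""


class CrossmaskError(Exception):
    """Base class for all crossmask errors."""


class FormatError(CrossmaskError):
    """A file does not conform to its interchange format."""


class DesignError(CrossmaskError):
    """Sample design is inconsistent with the data it describes."""


class ParameterError(CrossmaskError):
    """A parameter is outside its valid range."""


class EstimationError(CrossmaskError):
    """A statistical estimate cannot be formed from the data given."""


class SelectionError(CrossmaskError):
    """No threshold satisfies the selection constraints."""


class LayoutReferenceError(CrossmaskError):
    """A probe or probe-set ID does not exist in the chip layout."""


class InputError(CrossmaskError):
    """Inputs to an analysis are mutually inconsistent."""
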