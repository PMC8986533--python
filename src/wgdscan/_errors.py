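"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but carries no usable signal (e.g. all-zero counts)."""


class GridMismatchError(ValueError):
    """Two objects that must share a bin grid do not."""


class PloidyConstraintError(ValueError):
    """No global scale places the ground ploidy inside the requested bounds."""
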