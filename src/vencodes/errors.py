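"""Exception hierarchy shared across the package."""


class VencodeError(Exception):
    """Base class for all package errors."""


class InputError(VencodeError):
    """Malformed or inconsistent user input (bad matrix, unknown id, ...)."""


class EmptyLandscapeError(VencodeError):
    """No regulatory element survives the target-activity filter."""


class UnsatisfiableFilterError(VencodeError):
    """The sparsity filter cannot retain k REs at any admissible cutoff."""


class NoVEnCodeError(VencodeError):
    """A search or scoring step that requires at least one VEnCode found none."""
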