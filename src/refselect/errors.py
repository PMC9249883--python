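"""Structured exceptions raised across the toolkit."""


class RefselectError(Exception):
    """Base class for all refselect errors."""


class DataFormatError(RefselectError):
    """Malformed or inconsistent input data (duplicate ids, bad cells, ...)."""


class MetadataError(RefselectError):
    """Sample metadata missing, incomplete, or inconsistent with a matrix."""


class DesignError(RefselectError):
    """A statistical design that cannot be fit (confounding, empty cells,
    too few samples or groups)."""


class SpecError(RefselectError):
    """Invalid simulation specification."""
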