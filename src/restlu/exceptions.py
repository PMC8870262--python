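"""Shared exception types."""


class RestluError(Exception):
    """Base class for package-specific errors."""


class VolumeFormatError(RestluError):
    """A file is not a readable 3D NIfTI image."""


class ConsistencyError(RestluError):
    """Two objects that must agree (shapes, counts) do not."""


class SpecError(RestluError):
    """An architecture or phantom specification is internally inconsistent."""


class DataError(RestluError):
    """A dataset is empty or missing required pieces (e.g. masks)."""
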