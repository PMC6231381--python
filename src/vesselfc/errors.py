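"""Exception taxonomy shared by all pipeline stages."""


class VesselFCError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(VesselFCError):
    """Unreadable file or unsupported image format."""


class GridError(VesselFCError):
    """Two volumes that must share a grid (shape/spacing) do not."""


class ParameterError(VesselFCError):
    """A numeric parameter is outside its documented range."""


class DegenerateInputError(VesselFCError):
    """Input data cannot support the requested operation (e.g. constant image)."""


class SizeError(VesselFCError):
    """Volume too small for the requested operation."""


class GenerationError(VesselFCError):
    """Phantom parameters produce geometry outside the volume."""
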