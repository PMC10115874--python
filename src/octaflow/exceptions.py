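"""Exception hierarchy for the OCTA pipeline."""


class OctaflowError(Exception):
    """Base class for all package-specific errors."""


class PatternError(OctaflowError):
    """Scan-pattern definition or repeat count is invalid."""


class GeometryError(OctaflowError):
    """Phantom or slab geometry does not fit inside the voxel grid."""


class SegmentationError(OctaflowError):
    """Surface segmentation failed on too many A-lines."""


class MissingPatternError(OctaflowError):
    """A scan pattern required by a layer's fusion rule was not supplied."""

    def __init__(self, missing, layer=""):
        self.missing = tuple(missing)
        msg = "missing contributing pattern(s): " + ", ".join(
            str(m) for m in self.missing
        )
        if layer:
            msg += f" for layer '{layer}'"
        super().__init__(msg)


class SidecarError(OctaflowError):
    """Volume sidecar metadata is missing or inconsistent with the TIFF."""


class BaselineError(OctaflowError):
    """A subject/layer series lacks a usable baseline record."""
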