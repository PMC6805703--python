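"""Exception hierarchy.

Parameter misuse raises plain :class:`ValueError`; everything that can go
wrong with actual data (files, images, tables) derives from
:class:`TriquantError` so callers can distinguish "you called it wrong"
from "this input cannot be processed".
"""


class TriquantError(Exception):
    """Base class for data-dependent failures."""


class ImageFormatError(TriquantError):
    """Image decodes but is not an 8/16-bit gray/RGB/RGBA raster."""


class NoTissueError(TriquantError):
    """Foreground segmentation found no tissue."""


class DegenerateSplitError(TriquantError):
    """Hemisphere split left one side empty."""


class CalibrationError(TriquantError):
    """Standard-curve fitting impossible (e.g. a single concentration)."""


class InputError(TriquantError):
    """Malformed measurement table / CSV / manifest."""
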