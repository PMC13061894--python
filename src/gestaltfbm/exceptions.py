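"""Exception hierarchy used across the package."""


class GestaltFBMError(Exception):
    """Base class for package errors."""


class SpecificationError(GestaltFBMError, ValueError):
    """A stimulus or analysis specification is invalid (e.g. unknown cue)."""


class GeometryError(GestaltFBMError, ValueError):
    """A stimulus does not fit the screen / aperture constraints."""


class PlacementError(GestaltFBMError, ValueError):
    """Strip placement violates an RF-distance or anti-alignment rule."""


class EstimationError(GestaltFBMError, RuntimeError):
    """An estimator has too little data or failed to converge."""
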