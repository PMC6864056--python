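"""Exception types shared across the pipeline stages."""


class HistodensityError(Exception):
    """Base class for package errors."""


class InfeasibleCompositionError(HistodensityError):
    """Requested epithelial area exceeds the available tissue area."""


class EmptySlideError(HistodensityError):
    """A label map contains no tissue pixels (labels 1-3)."""


class NoEpitheliumError(HistodensityError):
    """Voronoi influence zones are undefined: the map has no epithelial regions."""


class DegenerateStratumError(HistodensityError):
    """A classification stratum has a single outcome class in train or test."""
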