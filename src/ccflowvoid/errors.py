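"""Exception types shared across the pipeline."""


class CcFlowVoidError(Exception):
    """Base class for all package errors."""


class GeometryError(CcFlowVoidError):
    """Raster/boundary geometry is inconsistent (inverted slab, mismatched shapes, grid off the raster)."""


class DegenerateInputError(CcFlowVoidError):
    """Input carries no usable information (constant image, empty pixel set, zero variance)."""


class ParameterError(CcFlowVoidError):
    """A parameter is outside its valid domain."""


class SampleSizeError(CcFlowVoidError):
    """Too few observations for the requested statistic."""


class CohortError(CcFlowVoidError):
    """A cohort-level run cannot proceed (e.g., no eye survives the quality gate)."""
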