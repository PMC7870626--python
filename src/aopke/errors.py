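"""Exception hierarchy shared across the pipeline stages."""


class AopkeError(Exception):
    """Base class for all pipeline errors."""


class DegenerateInput(AopkeError):
    """Input violates a structural precondition (too few concentrations, etc.)."""


class FlatCurve(AopkeError):
    """Concentration series shows too little effect to support a potency estimate."""


class UndefinedEC(AopkeError):
    """An effective concentration was requested from a non-converged fit."""


class SchemaError(AopkeError):
    """An interchange table is missing columns or contains unparseable values."""


class AllSamplesRemoved(AopkeError):
    """The count-matrix prefilter removed every sample."""


class NoReferenceGenes(AopkeError):
    """Median-of-ratios normalization found no gene with all-positive counts."""


class InsufficientReplicates(AopkeError):
    """A contrast has fewer than two treated or two control samples."""


class ZeroBaseline(AopkeError):
    """An OCR trace cannot be normalized because the equilibration value is zero."""


class NonPositiveMitoBaseline(AopkeError):
    """Baseline OCR does not exceed non-mitochondrial OCR."""


class TooFewControls(AopkeError):
    """Not enough vehicle-control values to define a noise band."""


class UndefinedAtConcentration(AopkeError):
    """Neither data nor fit covers the requested screen concentration."""
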