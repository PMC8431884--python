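"""Exception types shared across the package."""


class GenecaptureError(Exception):
    """Base class for all package errors."""


class GenotypeFormatError(GenecaptureError):
    """Malformed genotype table (bad columns, duplicate ids, missing bunch)."""


class EmptyDatasetError(GenecaptureError):
    """An operation produced or received a dataset with no usable data."""


class UndefinedStatisticError(GenecaptureError):
    """A statistic is mathematically undefined for the given input
    (e.g. Fis on an entirely monomorphic group)."""
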