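"""Exception hierarchy shared across the pipeline stages."""


class MirvarError(Exception):
    """Base class for all package errors."""


class SchemaError(MirvarError):
    """A measurement table is missing or misnames a mandatory column."""


class ValidationError(MirvarError):
    """A row violates an invariant (unknown label, impossible count, ...)."""


class MissingLevelError(MirvarError):
    """All replicate wells of a sample x assay were undetermined."""

    def __init__(self, sample_id: str, assay: str, platform: str):
        self.sample_id = sample_id
        self.assay = assay
        self.platform = platform
        super().__init__(
            f"no usable well for sample {sample_id!r}, assay {assay!r}, "
            f"platform {platform!r}: all replicates undetermined"
        )


class SaturationError(MirvarError):
    """Every droplet positive: the Poisson occupancy model cannot invert k = n."""


class DegenerateVarianceError(MirvarError):
    """A test statistic is undefined because a group has zero variance."""
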