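"""Exception hierarchy for icrcall."""


class IcrCallError(Exception):
    """Base class for all icrcall errors."""


class InputError(IcrCallError, ValueError):
    """Malformed or out-of-range input."""


class EmptyRegionError(IcrCallError):
    """No probes fall inside the requested region."""

    def __init__(self, region_name: str):
        self.region_name = region_name
        super().__init__(f"no probes located inside region {region_name!r}")


class NoDataError(IcrCallError):
    """All values needed for a computation are missing."""


class SaturationError(IcrCallError):
    """Every partition of a dPCR channel is positive; lambda is undefined."""


class NoTemplateError(IcrCallError):
    """Both dPCR channels are empty; the methylated fraction is undefined."""


class UndefinedCorrelationError(IcrCallError):
    """A sample profile is constant, so Pearson correlation is undefined."""

    def __init__(self, sample_id: str):
        self.sample_id = sample_id
        super().__init__(
            f"sample {sample_id!r} has a constant CpG profile; "
            "Pearson correlation is undefined"
        )
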