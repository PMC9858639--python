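"""Exception types shared across the calibration pipeline."""


class WoundkitError(Exception):
    """Base class for all package-specific errors."""


class ResolutionError(WoundkitError):
    """Requested raster resolution is too coarse to keep markers decodable."""


class ChartNotFoundError(WoundkitError):
    """The full set of chart markers could not be detected in an image."""

    def __init__(self, missing_ids, found_ids=()):
        self.missing_ids = tuple(sorted(missing_ids))
        self.found_ids = tuple(sorted(found_ids))
        super().__init__(
            f"calibration chart not found: missing marker ids {self.missing_ids} "
            f"(found {self.found_ids})"
        )


class SamplingError(WoundkitError):
    """A projected patch-sampling window falls outside the image."""

    def __init__(self, patch_index, message=""):
        self.patch_index = patch_index
        super().__init__(
            f"patch {patch_index}: sampling window outside image. {message}".strip()
        )


class IllConditionedFitError(WoundkitError):
    """The source color matrix is rank deficient; the linear fit is unstable."""


class PlacementError(WoundkitError):
    """Synthetic scene elements collide (e.g. wound overlapping the chart)."""


class ConfigError(WoundkitError):
    """Invalid model or training configuration."""
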