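"""Structured exceptions shared across the toolkit."""


class PRFThermoError(Exception):
    """Base class for all toolkit errors."""


class MetadataError(PRFThermoError):
    """A required acquisition attribute is missing or contradictory.

    Parameters
    ----------
    attribute : str
        Name of the offending metadata attribute.
    """

    def __init__(self, attribute: str, message: str = ""):
        self.attribute = attribute
        super().__init__(message or f"missing or contradictory metadata: {attribute!r}")


class GeometryError(PRFThermoError):
    """Frames or masks disagree in shape, spacing or orientation."""


class MaskError(PRFThermoError):
    """An ROI mask is empty, overlapping or otherwise unusable."""


class UnisolvencyError(PRFThermoError):
    """Nodes do not uniquely determine the polynomial tail (e.g. collinear)."""


class ConditioningError(PRFThermoError):
    """The interpolation system is singular beyond tolerance.

    Carries the estimated condition number of the assembled system.
    """

    def __init__(self, condition_number: float, message: str = ""):
        self.condition_number = condition_number
        super().__init__(
            message
            or f"interpolation system singular beyond tolerance "
            f"(estimated condition number {condition_number:.3e})"
        )


class RankDeficiencyError(PRFThermoError):
    """A least-squares design matrix is rank deficient."""


class DegenerateInputError(PRFThermoError):
    """Statistical input is degenerate (e.g. all paired differences zero)."""


class UnknownMethodError(PRFThermoError):
    """Unknown reconstruction method name; carries the list of valid names."""

    def __init__(self, name: str, valid: list[str]):
        self.name = name
        self.valid = list(valid)
        super().__init__(f"unknown method {name!r}; valid methods: {', '.join(valid)}")
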