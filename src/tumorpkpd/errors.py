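"""Exception hierarchy for the tumorpkpd package."""


class TumorPKPDError(Exception):
    """Base class for all package-specific errors."""


class InputDomainError(TumorPKPDError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class CalibrationError(TumorPKPDError, RuntimeError):
    """A calibration stage cannot run (missing data, wrong arm, bad ordering).

    Parameters
    ----------
    stage
        Name of the calibration stage that failed, e.g. ``"fit_growth_rate"``.
    message
        Human-readable description.
    """

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class ConfigurationError(TumorPKPDError, ValueError):
    """Inconsistent run configuration (mismatched arms, unknown labels, ...)."""
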