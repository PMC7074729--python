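"""Exception hierarchy for the respiro pipeline."""


class RespiroError(Exception):
    """Base class for all pipeline errors."""


class NegativeCO2Error(RespiroError):
    """Back-titration volume exceeds the blank (would imply negative CO2)."""

    def __init__(self, day: float, blank_volume: float, sample_volume: float):
        self.day = day
        super().__init__(
            f"negative CO2 at day {day}: sample volume {sample_volume} mL "
            f"exceeds blank volume {blank_volume} mL"
        )


class DayGridError(RespiroError):
    """Two series do not share a common sampling-day grid."""

    def __init__(self, missing_days):
        self.missing_days = list(missing_days)
        super().__init__(f"mismatched day grids; days missing from one series: {self.missing_days}")


class OverdrawError(RespiroError):
    """Stoichiometric overdraw: more substrate consumed than initially present."""


class FitError(RespiroError):
    """A kinetic fit cannot be performed on the given data."""


class BalanceError(RespiroError):
    """A carbon-balance component is out of range."""


class ConfigError(RespiroError):
    """Invalid simulation or pipeline configuration."""


class InputError(RespiroError):
    """Malformed or missing input data."""
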