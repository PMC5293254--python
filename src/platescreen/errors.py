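"""Exception hierarchy shared across the pipeline."""


class ScreenError(Exception):
    """Base class for all platescreen errors."""


class InputError(ScreenError):
    """Malformed or out-of-range input data (files, labels, volumes)."""


class ConfigurationError(ScreenError):
    """Invalid layout, design or run configuration."""


class CapacityError(ConfigurationError):
    """A layout or campaign cannot accommodate the requested compounds."""


class QCError(ScreenError):
    """Control wells missing or control statistics not computable."""


class UndefinedStatisticError(QCError):
    """A statistic (e.g. Z') is undefined for the given control values."""


class DegenerateDataError(ScreenError):
    """Data carry no information for the requested fit (e.g. flat viability)."""
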