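"""Exception hierarchy."""


class SubcountyLEError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SubcountyLEError):
    """Invalid configuration: unknown scheme, bad threshold, unknown key."""


class DataError(SubcountyLEError):
    """Malformed or inconsistent input data."""


class LifeTableError(SubcountyLEError):
    """Life-table construction failed."""


class FinalBandError(LifeTableError):
    """The open-ended terminal band has no deaths or no exposure, so the
    terminal rate m_w (and hence e0 and its variance) is not computable."""


class ZeroExposureDeathsError(DataError):
    """A band reports deaths but zero person-years — inconsistent counts."""
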