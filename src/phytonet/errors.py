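"""Exception hierarchy for phytonet."""


class PhytonetError(Exception):
    """Base class for all phytonet errors."""


class SchemaError(PhytonetError):
    """A required column or field is missing from an input table."""


class TableParseError(PhytonetError):
    """A cell could not be parsed; the message carries the row/line number."""


class ConfigurationError(PhytonetError):
    """An invalid or inconsistent configuration value."""


class DegenerateNetworkError(PhytonetError):
    """The constructed network has no edges and cannot be analysed."""


class EmptyPopulationError(PhytonetError):
    """A median was requested over an empty population."""
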