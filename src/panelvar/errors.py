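"""Exception taxonomy shared across the pipeline stages."""


class PanelvarError(Exception):
    """Base class for all panelvar errors."""


class ConfigurationError(PanelvarError, ValueError):
    """Invalid configuration value or missing declared input."""


class GenerationError(PanelvarError, RuntimeError):
    """The synthetic generator could not satisfy its constraints."""


class CoordinateError(PanelvarError, ValueError):
    """A position or interval falls outside the genome."""


class ConsistencyError(PanelvarError, ValueError):
    """Inputs contradict each other (e.g. conflicting focal alleles)."""


class GeneModelError(PanelvarError, ValueError):
    """A gene model violates its structural invariants."""


class AlignmentDialectError(PanelvarError, ValueError):
    """Sequences handed to the toy comparator are not in one coordinate frame."""


class DegenerateUniverseError(PanelvarError, ValueError):
    """The mutation universe has no focal-specific sites (p = 0)."""


class BedParseError(PanelvarError, ValueError):
    """Malformed BED line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number
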