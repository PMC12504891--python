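"""Exception hierarchy for penkit."""


class PenkitError(Exception):
    """Base class for all penkit errors."""


class FormatError(PenkitError):
    """A file does not conform to the expected on-disk format."""


class SamplingError(PenkitError):
    """The time base of a recording is not uniformly sampled."""


class ValidationError(PenkitError):
    """A domain object violates one of its invariants."""


class SchemaError(PenkitError):
    """Tabular inputs disagree on their column/indicator schema."""


class GenerationError(PenkitError):
    """Synthetic-data generation was asked for an impossible configuration."""


class ParameterError(PenkitError):
    """A parameter value is outside its admissible domain."""


class LabelError(PenkitError):
    """A word-label track is missing or inconsistent."""
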