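"""Exception hierarchy for symptom-matrix validation and analysis."""


class SymptomOverlapError(ValueError):
    """Base class for all package errors."""


class CodingError(SymptomOverlapError):
    """A cell holds a code outside {0, 1, 2}."""


class ConflictError(SymptomOverlapError):
    """The same (symptom, instrument) cell was given two different codes."""


class CategoryError(SymptomOverlapError):
    """A symptom has no category, an empty category, or two categories."""


class InstrumentLookupError(SymptomOverlapError):
    """An instrument identifier is not present in the matrix/metadata."""


class DuplicateItemError(SymptomOverlapError):
    """An item identifier occurs twice within one instrument."""


class FlagError(SymptomOverlapError):
    """An instrument was used as a reference list without being flagged as one."""


class InsufficientInstrumentsError(SymptomOverlapError):
    """Fewer than two non-reference instruments; pairwise analysis undefined."""


class DegenerateInputError(SymptomOverlapError):
    """A correlation input vector is constant or too short."""


class ConfigError(SymptomOverlapError):
    """Invalid simulation or pipeline configuration."""


class PipelineError(SymptomOverlapError):
    """A report-pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
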