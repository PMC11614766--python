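"""Exception hierarchy for the tewskit pipeline."""


class TewskitError(Exception):
    """Base class for all tewskit errors."""


class ConfigurationError(TewskitError):
    """A configuration table or parameter set is incomplete or inconsistent."""


class SchemaError(TewskitError):
    """An input table does not conform to its declared schema."""


class StageError(TewskitError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
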