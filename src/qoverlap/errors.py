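"""Exception hierarchy for the qoverlap pipeline."""


class QOverlapError(Exception):
    """Base class for all package errors."""


class ValidationError(QOverlapError):
    """Input data violates a documented invariant (bad column, duplicate id, ...)."""


class EmptyResultError(QOverlapError):
    """A filter or computation produced an empty result where items are required."""


class BackendError(QOverlapError):
    """An embedding or assignment backend failed for a specific item."""

    def __init__(self, message: str, item_id: str | None = None):
        super().__init__(message)
        self.item_id = item_id


class PipelineError(QOverlapError):
    """A pipeline stage aborted; carries the stage name and stratum."""

    def __init__(self, stage: str, stratum: str, message: str):
        super().__init__(f"[stage={stage} stratum={stratum}] {message}")
        self.stage = stage
        self.stratum = stratum
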