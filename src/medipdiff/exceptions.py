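"""Exception hierarchy for medipdiff."""


class MedipdiffError(Exception):
    """Base class for all medipdiff errors."""


class ValidationError(MedipdiffError, ValueError):
    """An input record or parameter violates a contract."""


class SizingError(MedipdiffError, ValueError):
    """A synthetic genome cannot accommodate the requested features."""


class DegenerateInputError(MedipdiffError, ValueError):
    """An input is structurally valid but analytically empty (e.g. no CpG)."""


class PipelineError(MedipdiffError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
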