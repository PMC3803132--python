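"""Exception hierarchy shared across the pipeline stages."""


class SpermwaveError(Exception):
    """Base class for all package-specific errors."""


class SizeError(SpermwaveError):
    """A synthetic head (plus tail) does not fit its canvas."""


class PlacementError(SpermwaveError):
    """Heads could not be placed without overlap within the retry budget."""


class DegenerateComponentError(SpermwaveError):
    """Morphological tail removal erased the whole component."""


class ContourError(SpermwaveError):
    """A mask is unsuitable for boundary tracing (multi-component or too small)."""


class PipelineError(SpermwaveError):
    """A pipeline stage failed; carries the stage name and the sperm id."""

    def __init__(self, stage: str, sperm_id: object = None, message: str = ""):
        self.stage = stage
        self.sperm_id = sperm_id
        detail = f"stage={stage!r}"
        if sperm_id is not None:
            detail += f" sperm_id={sperm_id!r}"
        super().__init__(f"{detail}: {message}" if message else detail)
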