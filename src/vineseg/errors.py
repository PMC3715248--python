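"""Exception hierarchy for vineseg.

Data errors (bad rasters, dimension mismatches, degenerate content) derive
from :class:`VinesegError` so the CLI can map them to a single exit code.
"""


class VinesegError(Exception):
    """Base class for all vineseg data and pipeline errors."""


class DimensionMismatchError(VinesegError):
    """Raster shapes disagree; the message names the offending channel."""


class MissingChannelError(VinesegError):
    """A required channel file is absent from a scene bundle."""


class DegenerateInputError(VinesegError):
    """Input has too little structure for the requested operation
    (e.g. a single-intensity band offered to a 2-cluster split)."""


class PipelineStageError(VinesegError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
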