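"""Exception hierarchy shared by all cavatrack modules.

Exit-code mapping used by the CLI: configuration problems exit with 2,
tracking failures with 3; everything else is a plain error (exit 1).
"""


class CavatrackError(Exception):
    """Base class for all package errors."""


class InputError(CavatrackError):
    """A user-supplied input (path, seed point, geometry) is invalid."""


class ConfigError(CavatrackError):
    """A configuration value is missing, unknown or out of range."""


class FormatError(CavatrackError):
    """An input file exists but cannot be interpreted as a cine loop."""


class GenerationError(CavatrackError):
    """A phantom specification produces unphysical geometry."""


class TrackingLostError(CavatrackError):
    """Edge tracking failed on a frame; carries the frame index."""

    def __init__(self, frame_index: int, message: str = ""):
        self.frame_index = frame_index
        super().__init__(
            message or f"tracking lost at frame {frame_index}"
        )
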