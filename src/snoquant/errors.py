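"""Exception hierarchy.

``ValidationError`` marks bad user input (CLI exit code 2);
``StageError`` marks a pipeline stage that failed mid-run (exit code 3).
"""


class SnoquantError(Exception):
    """Base class for package errors."""


class ValidationError(SnoquantError):
    """Invalid input data or configuration."""


class StageError(SnoquantError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
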