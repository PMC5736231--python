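"""Exception types shared across the package."""


class InvalidConfigError(ValueError):
    """A configuration value violates its documented invariants."""


class MeshFormatError(ValueError):
    """A mesh file or mesh object is malformed or unsupported."""


class StageError(RuntimeError):
    """A study stage failed; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
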