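"""Exception hierarchy shared across the package."""


class ToothSSMError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ToothSSMError, ValueError):
    """An argument violates a documented precondition on its values."""


class MeshFormatError(ToothSSMError, ValueError):
    """A mesh file could not be parsed in the declared dialect."""

    def __init__(self, message: str, path=None, offset=None):
        detail = message
        if path is not None:
            detail += f" [file: {path}]"
        if offset is not None:
            detail += f" [byte offset: {offset}]"
        super().__init__(detail)
        self.path = path
        self.offset = offset


class PreconditionError(ToothSSMError, ValueError):
    """A geometric precondition (e.g. closedness) does not hold."""


class RegistrationError(ToothSSMError, RuntimeError):
    """Elastic or rigid registration failed to make progress."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class LandmarkError(ToothSSMError, RuntimeError):
    """An anatomical landmark could not be identified."""

    def __init__(self, message: str, landmark: str | None = None):
        super().__init__(message)
        self.landmark = landmark
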