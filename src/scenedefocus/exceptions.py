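"""Exception hierarchy for the scenedefocus pipeline."""


class SceneDefocusError(Exception):
    """Base class for all scenedefocus errors."""


class InvalidConfigurationError(SceneDefocusError, ValueError):
    """A camera, scene, cohort or pipeline configuration violates its invariants."""


class InvalidInputError(SceneDefocusError, ValueError):
    """Input data (frames, arrays) are empty, mismatched or malformed."""


class CalibrationError(SceneDefocusError, ValueError):
    """Depth-map calibration cannot proceed (e.g. unreadable centre pixel)."""


class DegenerateInputError(SceneDefocusError, ValueError):
    """A statistical operation received degenerate input (constant vector, perfect control)."""


class CollinearityError(SceneDefocusError, ValueError):
    """The regression design matrix is singular after coding."""

    def __init__(self, message, terms=()):
        super().__init__(message)
        self.terms = tuple(terms)


class InsufficientGroupError(SceneDefocusError, ValueError):
    """A group comparison has a group with fewer than two observations."""


class SchemaError(SceneDefocusError, ValueError):
    """A cohort table is missing required columns; lists all of them."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(
            "cohort table is missing required column(s): " + ", ".join(self.missing)
        )
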