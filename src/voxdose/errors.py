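"""Exception hierarchy shared across the toolkit."""


class VoxdoseError(Exception):
    """Base class for all voxdose errors."""


class ConfigurationError(VoxdoseError):
    """Invalid user-supplied configuration or geometry specification."""


class GeometryError(VoxdoseError):
    """Grids, fields of view or transforms are geometrically incompatible."""


class SeriesError(VoxdoseError):
    """A DICOM/NIfTI series is inconsistent or cannot be interpreted."""


class RegistrationError(VoxdoseError):
    """Co-registration failed (empty overlap, non-finite cost, ...)."""


class FiducialNotFoundError(RegistrationError):
    """No fiducial candidate component was found in the volume."""


class FitError(VoxdoseError):
    """A model fit could not be performed on the given samples."""


class StageError(VoxdoseError):
    """A pipeline stage failed; carries the stage name for resumability."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
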