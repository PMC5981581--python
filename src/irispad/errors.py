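"""Exception hierarchy shared across the pipeline stages."""


class IrisPadError(Exception):
    """Base class for all irispad errors."""


class ValidationError(IrisPadError):
    """Invalid parameter, manifest row, or configuration value."""


class GeometryError(IrisPadError):
    """A sampling geometry (circle, neighborhood, ROI) leaves the image."""


class DetectionFailure(IrisPadError):
    """No pupil/iris candidate satisfied the detector's conditions."""


class TrainingError(IrisPadError):
    """Model training could not proceed (e.g. single-class data)."""
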