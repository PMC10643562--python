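"""Exception hierarchy shared across the package."""


class MisalignError(Exception):
    """Base class for all package-specific errors."""


class LesionPlacementError(MisalignError):
    """Raised when a phantom lesion cannot be placed inside the gland."""


class PipelineOrderError(MisalignError):
    """Raised when misalignment augmentation is composed after a global
    spatial augmentation stage."""


class RegistrationError(MisalignError):
    """Raised when a registration run fails (divergence, empty masks,
    incompatible domains)."""


class ManifestError(MisalignError):
    """Raised on malformed manifests (missing columns, duplicate ids,
    missing files)."""


class VolumeIOError(MisalignError):
    """Raised on unreadable or unsupported image volumes."""
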