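"""Exception hierarchy.

Every domain failure raises a subclass of :class:`ScanVaultError`; the CLI maps
these to exit status 1 and anything else is a bug.
"""


class ScanVaultError(Exception):
    """Base class for all domain errors."""


class InvalidKeyError(ScanVaultError):
    """Asset key is malformed (empty components, wrong shape)."""


class UnknownKindError(ScanVaultError):
    """Asset kind has not been registered with the identifier subsystem."""


class CollisionError(ScanVaultError):
    """A deterministic identifier is already present in the registry.

    This is the expected failure mode when re-extracting or re-processing
    content that is already managed: identical bytes or identical activity
    invocations always map to the identical identifier.
    """


class NotFoundError(ScanVaultError):
    """Referenced entity (asset, series, project, timepoint...) does not exist."""


class IntegrityError(ScanVaultError):
    """Checksum mismatch or descriptor/content inconsistency."""


class AnonymizationError(ScanVaultError):
    """Archive has not been confirmed anonymized and cannot be assigned."""


class ConfigurationError(ScanVaultError):
    """Invalid configuration value (empty watchlist, malformed constraint...)."""


class StateError(ScanVaultError):
    """Illegal job state transition."""


class ImportError_(ScanVaultError):
    """Tabular import could not be performed at the file level."""
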