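"""Exception hierarchy for the SIA/PCA pipeline."""


class SiapcaError(Exception):
    """Base class for all package errors."""


class ValidationError(SiapcaError):
    """A domain object violates one of its invariants."""


class SpectrumFormatError(SiapcaError):
    """A spectrum file does not parse under the named dialect."""


class DimensionalityError(SpectrumFormatError):
    """A file holds data that is not a single real 2D plane."""


class EnsembleError(SiapcaError):
    """Spectra supplied for one position do not form a valid ensemble."""


class DegenerateInputError(SiapcaError):
    """PCA input carries no variance at all (all-zero matrix)."""


class PairingError(SiapcaError):
    """Free and bound peak lists cannot be matched by assignment id."""


class PlacementError(SiapcaError):
    """A peak falls outside the ppm range of the simulation grid."""


class ConfigurationError(SiapcaError):
    """A simulation or run configuration is internally inconsistent."""
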