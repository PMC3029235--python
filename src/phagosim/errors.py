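"""Exception hierarchy for phagosim."""


class PhagosimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhagosimError):
    """Invalid scenario or solver configuration."""


class GeometryError(PhagosimError):
    """Inconsistent or impossible geometric setup."""


class RemeshError(PhagosimError):
    """Mesh motion or smoothing produced an invalid mesh."""


class NumericalError(PhagosimError):
    """Linear solve failed or did not converge to tolerance."""


class SimulationError(PhagosimError):
    """A full run aborted (e.g. repeated remesh failure)."""


class InputError(PhagosimError):
    """Invalid input data passed to an analysis routine."""
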