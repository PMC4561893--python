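"""Exception hierarchy shared across the package."""


class CytosersError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CytosersError, ValueError):
    """A scalar or array argument is outside its physical domain."""


class GeometryError(CytosersError, ValueError):
    """A point or particle lies in a forbidden region (e.g. inside the substrate)."""


class PackingError(CytosersError, RuntimeError):
    """Requested particle configuration cannot be placed without overlap."""


class SingularResonanceError(CytosersError, ZeroDivisionError):
    """Quasi-static polarizability evaluated exactly at the Froehlich pole."""


class SolverError(CytosersError, RuntimeError):
    """Coupled-dipole linear system is singular or too ill-conditioned to trust."""


class SpectrumError(CytosersError, ValueError):
    """Malformed spectrum, axis, or band definition."""


class UndefinedRatioError(CytosersError, ZeroDivisionError):
    """A band-intensity ratio has a non-positive denominator."""


class ConfigError(CytosersError, ValueError):
    """Run configuration is missing keys or contains unknown ones."""
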