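"""Exception types shared across the package."""


class CapnetError(Exception):
    """Base class for all package-specific errors."""


class DegenerateGeometry(CapnetError):
    """Capillary too narrow for the two-phase core/sleeve decomposition.

    The RBC-core radius law r0 = 0.3 um + 0.8 rc has the fixed point
    rc = 1.5 um; at or below it the plasma sleeve vanishes (r0 >= rc)
    and the two-viscosity model degenerates.
    """


class OutOfDomain(CapnetError):
    """A coordinate lies outside the physical domain of a field."""


class SingularSystem(CapnetError):
    """A linear system could not be solved (singular or ill-posed)."""


class ConfigError(CapnetError):
    """Invalid or inconsistent user-supplied configuration."""


class FitUnderdetermined(CapnetError):
    """Too few distinct abscissae to determine a least-squares line."""
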