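"""Exception hierarchy for microwet."""


class MicrowetError(Exception):
    """Base class for all microwet errors."""


class InvalidGeometryError(MicrowetError, ValueError):
    """Microstructure dimensions violate their invariants (e.g. r0 <= 0)."""


class InvalidRoughnessError(MicrowetError, ValueError):
    """Roughness arguments outside their admissible range (r < 1, f not in [0, 1])."""


class DepthDomainError(MicrowetError, ValueError):
    """Penetration depth outside the domain of the requested branch."""


class DivergentShapeError(MicrowetError, ZeroDivisionError):
    """Spherical-cap shape function vanished; droplet radius diverges (theta -> 0)."""


class NoWettedEquilibriumError(MicrowetError):
    """The Wenzel equation r*cos(theta_Y) = cos(theta_W) has no solution (|r cos theta_Y| > 1)."""


class BarrierDefinitionError(MicrowetError, ValueError):
    """Energy-barrier evaluation point does not lie beyond the composite minimum."""
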