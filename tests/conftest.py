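import pytest

from microwet import MicrostructureGeometry, Packing, WettingConstants

R0 = 5e-6  # reference base radius, m


@pytest.fixture
def constants() -> WettingConstants:
    """Default study conditions: theta_Y = 104 deg, water, 5 uL drop."""
    return WettingConstants()


@pytest.fixture
def hex_geom():
    """Factory for hexagonally packed geometries given (delta, eta)."""

    def make(delta: float = 1.0, eta: float = 0.0, r0: float = R0, packing=Packing.HEXAGONAL):
        return MicrostructureGeometry(
            base_radius_r0=r0,
            cylinder_height_h0=eta * r0,
            half_spacing_d0=delta * r0,
            packing=packing,
        )

    return make


@pytest.fixture
def lotus_geom(hex_geom):
    """2r0 = 2d0 = 2h0 = 10 um capped-cylinder papilla."""
    return hex_geom(delta=1.0, eta=1.0, r0=5e-6)


@pytest.fixture
def pachyphylla_geom(hex_geom):
    """r0 = 2d0 = 9 um hemisphere papilla."""
    return hex_geom(delta=0.5, eta=0.0, r0=9e-6)
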