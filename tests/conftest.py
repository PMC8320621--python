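import numpy as np
import pytest

from lungsurf.adsa import DropProfile, PhysicalParams, integrate_drop_profile
from lungsurf.simulate import CyclingProtocol, FilmModelParams, simulate_trace

# Bond-number grid with pedestal at ~90% of each shape's equatorial bulge
# radius, so every contour is a deep, well-identified cap (apex radius 2 mm,
# water-air density difference).
BETA_GRID_GEOMETRY = {
    0.05: 1.79,
    0.2: 1.75,
    0.5: 1.68,
    1.0: 1.59,
    2.0: 1.47,
}
APEX_RADIUS_MM = 2.0
DELTA_RHO = 1000.0
CONTOUR_STEP_MM = 0.00125
COORD_NOISE_MM = 1e-3  # 1 um imaging noise


def gamma_for_beta(beta: float, r0: float = APEX_RADIUS_MM) -> float:
    return DELTA_RHO * 9.81 * r0**2 * 1e-3 / beta


def grid_profile(beta: float, step: float = CONTOUR_STEP_MM) -> DropProfile:
    params = PhysicalParams(
        surface_tension=gamma_for_beta(beta),
        density_difference=DELTA_RHO,
        apex_radius=APEX_RADIUS_MM,
        pedestal_radius=BETA_GRID_GEOMETRY[beta],
    )
    return integrate_drop_profile(params, step=step)


def add_coordinate_noise(profile: DropProfile, sigma: float, rng: np.random.Generator) -> DropProfile:
    return DropProfile(
        s=profile.s,
        r=np.abs(profile.r + rng.normal(0.0, sigma, len(profile))),
        z=profile.z + rng.normal(0.0, sigma, len(profile)),
        phi=profile.phi,
    )


@pytest.fixture(scope="session")
def beta_half_profile() -> DropProfile:
    """Forward profile at Bond number 0.5 reused across tests."""
    return grid_profile(0.5)


@pytest.fixture()
def functional_trace():
    """Noise-free baseline trace: no inhibitor, minima at the 2 mN/m floor."""
    protocol = CyclingProtocol(duration=60.0)
    film = FilmModelParams(deposition_flux=0.0, noise_sd=0.0)
    return simulate_trace(protocol, film)


@pytest.fixture()
def inhibited_trace():
    """Noise-free trace whose floor crosses 10 mN/m mid-trace."""
    protocol = CyclingProtocol(duration=120.0)
    film = FilmModelParams(deposition_flux=40.0, d50=20.0, noise_sd=0.0)
    return simulate_trace(protocol, film), film, protocol
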