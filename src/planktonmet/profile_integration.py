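"""Trapezoidal depth integration of volumetric rates to the 1% light depth,
with propagation of the random error of the volumetric measurements.

The integral of a sampled rate profile v(z) from the surface to the euphotic
depth is written as a weighted sum sum_i w_i v_i, where the w_i are the
trapezoid weights of the sample grid:

    w_1 = (z_2 - z_1)/2 (+ z_1 when the shallowest sample is extended to the
    surface at constant value), w_i = (z_{i+1} - z_{i-1})/2,
    w_n = (z_n - z_{n-1})/2.

Writing the integral this way makes error propagation immediate: treating
levels as independent, sd_int = sqrt(sum_i (w_i se_i)^2).

The shallowest bottle (typically the ~97% light depth, a few metres down)
is extended to 0 m at constant value by default — the standard
oceanographic convention; disable with ``surface_extension=False`` to start
the integral at the shallowest sample.  The integral never extrapolates
downward: if the deepest sample sits between 0.8 and 1.0 of the euphotic
depth, the profile is truncated there (and the shortfall logged); shallower
than that is an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bottle_rates import VolumetricRates
from .data_io import StationMeta
from .errors import ExtrapolationError

logger = logging.getLogger(__name__)


@dataclass
class StationProfile:
    """Ordered depth profile of volumetric rates for one station."""

    meta: StationMeta
    levels: list[VolumetricRates]  # sorted by increasing depth
    euphotic_depth: float          # depth of 1% surface PAR, m

    def __post_init__(self) -> None:
        depths = [v.depth for v in self.levels]
        if len(self.levels) < 2:
            raise ValueError("profile needs >= 2 levels")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("level depths must be strictly increasing")
        fr = [v.light_fraction for v in self.levels]
        if any(b > a for a, b in zip(fr, fr[1:])):
            raise ValueError("light_fraction must be non-increasing with depth")
        if self.euphotic_depth <= 0:
            raise ValueError("euphotic_depth must be positive")


@dataclass
class IntegratedRates:
    """Euphotic-zone integrals of NCP, R and P with propagated s.d.
    (mmol O2 m-2 d-1)."""

    station_id: str
    ncp_int: float
    r_int: float
    p_int: float
    sd_ncp_int: float
    sd_r_int: float
    sd_p_int: float
    integration_depth: float


def trapezoid_weights(depths: np.ndarray, euphotic_depth: float,
                      surface_extension: bool = True) -> tuple[np.ndarray, float]:
    """Trapezoid weights for a sample grid, and the integration depth.

    Raises :class:`ExtrapolationError` if the deepest sample is shallower
    than 0.8 x euphotic depth; truncates (with a log message) when it lies
    between 0.8 and 1.0 of it.
    """
    z = np.asarray(depths, dtype=float)
    if z[-1] < 0.8 * euphotic_depth:
        raise ExtrapolationError(
            f"deepest sample {z[-1]:.1f} m < 0.8 x euphotic depth "
            f"{euphotic_depth:.1f} m; refusing to extrapolate")
    z_bot = min(z[-1], euphotic_depth)
    if z[-1] < euphotic_depth:
        logger.info("integration truncated at %.1f m (euphotic %.1f m)",
                    z[-1], euphotic_depth)
    w = np.empty_like(z)
    w[0] = (z[1] - z[0]) / 2.0 + (z[0] if surface_extension else 0.0)
    w[-1] = (z[-1] - z[-2]) / 2.0
    if len(z) > 2:
        w[1:-1] = (z[2:] - z[:-2]) / 2.0
    return w, z_bot


def integrate_trapezoid(profile: StationProfile,
                        surface_extension: bool = True) -> IntegratedRates:
    """Integrate NCP, R and P over the euphotic zone and propagate errors."""
    z = np.array([v.depth for v in profile.levels])
    w, z_bot = trapezoid_weights(z, profile.euphotic_depth, surface_extension)
    ncp = np.array([v.ncp for v in profile.levels])
    r = np.array([v.r for v in profile.levels])
    sd_ncp, sd_r, sd_p = propagate_integration_error(profile,
                                                     surface_extension)
    ncp_int = float(w @ ncp)
    r_int = float(w @ r)
    return IntegratedRates(
        station_id=profile.meta.station_id,
        ncp_int=ncp_int, r_int=r_int, p_int=ncp_int + r_int,
        sd_ncp_int=sd_ncp, sd_r_int=sd_r, sd_p_int=sd_p,
        integration_depth=float(z_bot))


def propagate_integration_error(profile: StationProfile,
                                surface_extension: bool = True
                                ) -> tuple[float, float, float]:
    """Propagated s.d. of the NCP, R and P integrals, levels independent."""
    z = np.array([v.depth for v in profile.levels])
    w, _ = trapezoid_weights(z, profile.euphotic_depth, surface_extension)

    def prop(se):
        return float(np.sqrt(np.sum((w * np.asarray(se)) ** 2)))

    return (prop([v.se_ncp for v in profile.levels]),
            prop([v.se_r for v in profile.levels]),
            prop([v.se_p for v in profile.levels]))
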