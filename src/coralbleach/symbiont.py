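"""Symbiont population dynamics: reserve-limited growth, nutrient uptake,
pigment synthesis and ROS-triggered expulsion.

The population is characterised by the nitrogen mass of its structural
material (``cs``, mg N m-2) and by internal reserves of nitrogen, carbon
and phosphorus shared across the population.  The maximum of each reserve
equals the structural equivalent of that element (Redfield-ratio scaled for
C and P), so normalised reserves are dimensionless quota in [0, 1] and
dilute automatically as the population grows.  Producing new structural
material consumes all three reserves at the Redfield ratio; growth persists
while every reserve is positive and ceases when any is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PhotoParams, SymbiontParams

__all__ = [
    "ReservePools",
    "normalised_reserves",
    "growth_rate",
    "growth_fluxes",
    "nutrient_uptake",
    "carbon_fixation_flux",
    "pigment_synthesis",
    "expulsion_rate",
    "cell_density",
    "projected_area_layers",
    "area_cap_factor",
]


@dataclass
class ReservePools:
    """Structural biomass and the three internal reserves (areal)."""

    cs: float   # mg N m-2, structural
    r_n: float  # mg N m-2
    r_c: float  # mg C m-2
    r_p: float  # mg P m-2

    def maxima(self, params: SymbiontParams) -> tuple[float, float, float]:
        return (
            self.cs,
            self.cs * params.redfield_c,
            self.cs * params.redfield_p,
        )


def normalised_reserves(
    pools: ReservePools, params: SymbiontParams
) -> tuple[float, float, float]:
    """Reserves normalised to their structural-equivalent maxima, in [0,1]."""
    if pools.cs <= 0:
        raise ValueError("cs must be positive to normalise reserves")
    max_n, max_c, max_p = pools.maxima(params)
    return (
        min(max(pools.r_n / max_n, 0.0), 1.0),
        min(max(pools.r_c / max_c, 0.0), 1.0),
        min(max(pools.r_p / max_p, 0.0), 1.0),
    )


def growth_rate(
    reserves_norm: tuple[float, float, float], params: SymbiontParams,
    cap_factor: float = 1.0,
) -> float:
    """Specific growth rate mu = mu_max * R_N* * R_C* * R_P* (d-1),
    optionally damped by the projected-area packing factor."""
    r_n, r_c, r_p = reserves_norm
    return params.mu_max * r_n * r_c * r_p * cap_factor


def growth_fluxes(
    pools: ReservePools, mu: float, params: SymbiontParams
) -> tuple[float, float, float, float]:
    """(dCS, dR_N, dR_C, dR_P)/dt from growth alone.

    New structure is built at rate mu*cs, consuming the nitrogen reserve
    one-for-one and the carbon and phosphorus reserves at the Redfield
    ratios.  Dilution of the normalised reserves emerges automatically
    because the maxima scale with cs.
    """
    build = mu * pools.cs
    return (
        build,
        -build,
        -build * params.redfield_c,
        -build * params.redfield_p,
    )


def nutrient_uptake(
    reserves_norm: tuple[float, float, float],
    din_mg: float,
    dip_mg: float,
    density: float,
    params: SymbiontParams,
) -> tuple[float, float]:
    """Diffusion-limited areal uptake (dR_N, dR_P)/dt, mg m-2 d-1.

    Linear in the ambient concentration (mg element m-3) and in cell
    density, and shut off as the corresponding reserve fills.
    """
    if din_mg < 0 or dip_mg < 0:
        raise ValueError("nutrient concentrations must be non-negative")
    r_n, _, r_p = reserves_norm
    up_n = params.uptake_n * din_mg * density * (1.0 - r_n)
    up_p = params.uptake_p * dip_mg * density * (1.0 - r_p)
    return up_n, up_p


def carbon_fixation_flux(to_fixation: float, params: PhotoParams) -> float:
    """dR_C/dt from photosynthesis: fix_yield * photons routed to fixation.

    The upstream photon partitioning already withdraws fixation as the
    carbon reserve fills; the hard cap at the reserve maximum is enforced
    by the integrator's flux limiting.
    """
    if to_fixation < 0:
        raise ValueError("to_fixation must be non-negative")
    return params.fix_yield * to_fixation


def pigment_synthesis(
    cs: float,
    r_c_norm: float,
    q_in_frac: float,
    optical_depth: float,
    params: SymbiontParams,
) -> float:
    """Chlorophyll-a synthesis rate dChl/dt, mg m-2 d-1 (non-negative).

    Pigment is added in proportion to its incremental benefit to
    photosynthesis: reduced when carbon reserves are replete, when the
    photosystem is inhibited, and by self-shading of the existing canopy.
    Newly synthesised xanthophyll accompanies chlorophyll at the fixed
    total-xanthophyll:Chl ratio (handled by the caller), entering the
    photosynthetic (diadinoxanthin) pool.
    """
    rate = (
        params.chl_synth_rate
        * cs
        * max(1.0 - r_c_norm, 0.0)
        * max(1.0 - q_in_frac, 0.0)
        * np.exp(-optical_depth)
    )
    return float(max(rate, 0.0))


def expulsion_rate(
    ros_percell: float,
    photo: PhotoParams,
    symb: SymbiontParams,
) -> float:
    """Specific expulsion rate e (d-1): zero at or below the bleaching
    threshold, proportional to the relative excess above it.

    Expulsion removes the same fraction of every areal pool, so per-cell
    contents are unchanged by the loss.
    """
    if ros_percell < 0:
        raise ValueError("ros_percell must be non-negative")
    theta = photo.ros_threshold
    if ros_percell <= theta:
        return 0.0
    return symb.expulsion_gain * symb.mu_max * (ros_percell - theta) / theta


def cell_density(cs: float, params: SymbiontParams) -> float:
    """Cells per m2: structural nitrogen / per-cell structural nitrogen."""
    if cs < 0:
        raise ValueError("cs must be non-negative")
    return cs / params.m_n


def projected_area_layers(cs: float, params: SymbiontParams) -> float:
    """Projected-area layers occupied by the population."""
    return cell_density(cs, params) * np.pi * params.cell_radius**2


def area_cap_factor(layers: float, params: SymbiontParams) -> float:
    """Smooth growth damping enforcing the two-layer gastrodermal packing:
    max(0, 1 - (layers/cap)^4)."""
    return max(0.0, 1.0 - (layers / params.area_cap) ** 4)
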