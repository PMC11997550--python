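"""Photon and energy pathways of the symbiont photosystem.

Every photon absorbed by the photochemical pigments (chlorophyll a and
diadinoxanthin) meets one of four fates, set by the state of the PSII
reaction centre it strikes:

* oxidised centre, RuBisCO active, carbon reserves unfilled -> carbon
  fixation;
* oxidised centre otherwise -> the centre becomes reduced;
* reduced centre -> the centre becomes inhibited;
* inhibited centre -> a reactive oxygen species (ROS) is generated.

Diatoxanthin intercepts a share of the remaining light and dissipates it as
heat (non-photochemical quenching).  Inhibited centres are repaired back to
the oxidised state; ROS is detoxified at a rate set by the cell's internal
reserves, either proportionally to [ROS] (legacy law) or piecewise with a
floor at half the bleaching threshold (revised law).

All operations are pure functions over numpy scalars/arrays; the areal unit
convention is mol photon m-2 d-1 for photon fluxes, mg m-2 for pigment and
reaction-centre pools and mg O m-2 for areal ROS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PhotoParams

__all__ = [
    "ReactionCentres",
    "PhotonBudget",
    "rubisco_activity",
    "photon_absorption",
    "partition_photons",
    "rc_transition_rates",
    "rc_repair_rate",
    "rc_propagator",
    "ros_generation_rate",
    "ros_detox_rate",
    "ros_detox_rate_legacy",
    "xanthophyll_switch",
]

#: PAR unit conversion: umol photon m-2 s-1 -> mol photon m-2 d-1
PAR_TO_MOL_DAY = 86400.0 * 1e-6


@dataclass
class ReactionCentres:
    """Areal PSII reaction-centre pools (mg m-2)."""

    q_ox: float
    q_red: float
    q_in: float

    def __post_init__(self) -> None:
        if min(self.q_ox, self.q_red, self.q_in) < 0:
            raise ValueError("reaction-centre pools must be non-negative")

    @property
    def q_t(self) -> float:
        return self.q_ox + self.q_red + self.q_in

    @property
    def fractions(self) -> tuple[float, float, float]:
        total = self.q_t
        if total <= 0:
            raise ValueError("no reaction centres (q_t = 0)")
        return self.q_ox / total, self.q_red / total, self.q_in / total


@dataclass
class PhotonBudget:
    """The five photon sinks, mol photon m-2 d-1.

    ``k_i`` is the absorption rate by the photochemical pigments; the four
    photochemical sinks partition it exactly, and ``to_heat`` is the
    additional photoprotective interception.
    """

    k_i: float
    to_heat: float = 0.0
    to_fixation: float = 0.0
    to_reduction: float = 0.0
    to_inhibition: float = 0.0
    to_ros: float = 0.0


def rubisco_activity(delta_t):
    """Temperature-dependent RuBisCO activity, dimensionless in [0, 1].

    ``delta_t`` is the instantaneous temperature anomaly against the
    maximum monthly mean (degC).  Fully active at or below the climatology,
    fully inactive at 2 degC above it, and continuous and monotone
    non-increasing in between:  a* = (1 - e^-(2-dT)) / (1 - e^-2).
    """
    dt = np.asarray(delta_t, dtype=float)
    mid = (1.0 - np.exp(-(2.0 - np.clip(dt, 0.0, 2.0)))) / (1.0 - np.exp(-2.0))
    out = np.clip(mid, 0.0, 1.0)
    if np.ndim(delta_t) == 0:
        return float(out)
    return out


def photon_absorption(par, chl, x_p, x_h, params: PhotoParams,
                      optical_cap: float | None = None) -> PhotonBudget:
    """Split downwelling PAR into photochemical absorption and NPQ heat.

    Beer-Lambert self-shading over the joint pigment bed: the bed absorbs
    ``E (1 - exp(-(tau_pq + tau_h)))`` with photochemical optical depth
    ``tau_pq = chl_absorb*Chl + xp_absorb*Xp`` and photoprotective depth
    ``tau_h = xh_absorb*Xh``.  In the default ``competitive`` optics the
    two absorber classes are optically mixed, so diatoxanthin sheds the
    fraction ``tau_h/(tau_pq + tau_h)`` of the absorbed light as heat and
    the xanthophyll switch directly modulates the photon flux reaching the
    reaction centres.  The ``sequential`` option instead places
    diatoxanthin behind the photochemical pigments
    (``k_i = E (1 - exp(-tau_pq))``; heat from the transmitted light only).
    ``optical_cap`` ceilings the total optical depth (two-layer packing).
    """
    if min(float(chl), float(x_p), float(x_h)) < 0:
        raise ValueError("pigment concentrations must be non-negative")
    e_d = np.asarray(par, dtype=float) * PAR_TO_MOL_DAY
    tau_pq = params.chl_absorb * chl + params.xp_absorb * x_p
    tau_h = params.xh_absorb * x_h
    if optical_cap is not None and tau_pq + tau_h > optical_cap > 0:
        scale = optical_cap / (tau_pq + tau_h)
        tau_pq *= scale
        tau_h *= scale
    if params.npq_optics == "sequential":
        k_i = e_d * -np.expm1(-tau_pq)
        to_heat = e_d * np.exp(-tau_pq) * -np.expm1(-tau_h)
    else:
        tau_tot = tau_pq + tau_h
        if tau_tot > 0:
            absorbed = e_d * -np.expm1(-tau_tot)
            k_i = absorbed * tau_pq / tau_tot
            to_heat = absorbed * tau_h / tau_tot
        else:
            k_i = e_d * 0.0
            to_heat = e_d * 0.0
    return PhotonBudget(k_i=float(k_i), to_heat=float(to_heat))


def partition_photons(
    budget: PhotonBudget,
    rc: ReactionCentres,
    activity: float,
    r_c_norm: float,
) -> PhotonBudget:
    """Land absorbed photons on reaction-centre states.

    Photons strike states in proportion to their normalised fractions.  A
    hit on an oxidised centre fixes carbon with probability
    ``activity * (1 - r_c_norm)`` (active RuBisCO, unfilled carbon reserve)
    and otherwise reduces the centre; a hit on a reduced centre inhibits
    it; a hit on an inhibited centre generates ROS.  The four sinks sum to
    ``k_i`` exactly.
    """
    f_ox, f_red, f_in = rc.fractions
    k_i = budget.k_i
    p_fix = activity * (1.0 - r_c_norm)
    to_fixation = k_i * f_ox * p_fix
    to_reduction = k_i * f_ox * (1.0 - p_fix)
    to_inhibition = k_i * f_red
    to_ros = k_i * f_in
    return PhotonBudget(
        k_i=k_i,
        to_heat=budget.to_heat,
        to_fixation=to_fixation,
        to_reduction=to_reduction,
        to_inhibition=to_inhibition,
        to_ros=to_ros,
    )


def rc_transition_rates(
    budget: PhotonBudget, rc: ReactionCentres, params: PhotoParams
) -> tuple[float, float, float]:
    """Photochemical state-transition derivatives (dQ_ox, dQ_red, dQ_in)/dt.

    Oxidised->reduced flux is ``to_reduction / m_RCII`` and
    reduced->inhibited flux is ``to_inhibition / m_RCII``; the total pool is
    conserved (the three derivatives sum to zero).
    """
    flux_ox_red = budget.to_reduction / params.m_rcii
    flux_red_in = budget.to_inhibition / params.m_rcii
    return (-flux_ox_red, flux_ox_red - flux_red_in, flux_red_in)


def rc_repair_rate(q_in: float, params: PhotoParams) -> float:
    """Repair flux inhibited->oxidised, mg m-2 d-1.

    ``repair_const * m_RCII * Q_in``; the constant derives from the
    10 mol photon m-2 d-1 light level whose damage the repair machinery is
    assumed able to match.  An optional temperature factor (default 1) is
    left as a configuration hook.
    """
    if q_in < 0:
        raise ValueError("q_in must be non-negative")
    return params.repair_const * params.repair_temp_factor * params.m_rcii * q_in


def _rc_rate_constants(
    k_i: float, activity: float, r_c_norm: float, q_t: float, params: PhotoParams
) -> tuple[float, float, float]:
    """First-order rate constants (alpha: ox->red, beta: red->in,
    gamma: in->ox) implied by the photon-flux formulas at total pool q_t."""
    gamma = params.repair_const * params.repair_temp_factor * params.m_rcii
    if q_t <= 0 or k_i <= 0:
        return 0.0, 0.0, gamma
    per_photon = k_i / (params.m_rcii * q_t)
    alpha = per_photon * (1.0 - activity * (1.0 - r_c_norm))
    beta = per_photon
    return alpha, beta, gamma


def rc_propagator(
    rc: ReactionCentres,
    k_i: float,
    activity: float,
    r_c_norm: float,
    params: PhotoParams,
    dt: float,
) -> ReactionCentres:
    """Advance the reaction-centre pools exactly over one step.

    The subsystem is linear in (Q_ox, Q_red, Q_in) once the slowly varying
    drivers (absorbed flux, RuBisCO activity, carbon reserve) are frozen
    over the step, and it is stiff: both the repair constant and the
    photon-driven transition constants are large compared with 1/dt.  The
    exact matrix exponential is therefore used instead of an explicit
    update, which is unconditionally stable and reproduces the pure-repair
    closed form Q_in(t) = Q_in(0) exp(-268 m_RCII t) to machine precision.
    """
    q = np.array([rc.q_ox, rc.q_red, rc.q_in], dtype=float)
    q_t = q.sum()
    if q_t <= 0:
        return rc
    alpha, beta, gamma = _rc_rate_constants(k_i, activity, r_c_norm, q_t, params)
    if alpha == 0.0 and beta == 0.0:
        # dark: pure repair, scalar closed form
        decay = np.exp(-gamma * dt)
        q_in_new = q[2] * decay
        return ReactionCentres(q[0] + q[2] - q_in_new, q[1], q_in_new)
    gen = np.array(
        [
            [-alpha, 0.0, gamma],
            [alpha, -beta, 0.0],
            [0.0, beta, -gamma],
        ]
    )
    q_new = _expm_apply(gen * dt, q)
    # the generator conserves the total exactly; renormalise away the
    # floating-point drift of the exponential
    q_new = np.clip(q_new, 0.0, None)
    total = q_new.sum()
    if total > 0:
        q_new *= q_t / total
    return ReactionCentres(*q_new)


def _expm_apply(a: np.ndarray, v: np.ndarray) -> np.ndarray:
    """exp(a) @ v for a 3x3 generator, via eigendecomposition with a
    scaling-and-squaring fallback."""
    try:
        w, vec = np.linalg.eig(a)
        out = (vec @ (np.exp(w) * np.linalg.solve(vec, v.astype(complex))))
        out = out.real
        if np.all(np.isfinite(out)):
            return out
    except np.linalg.LinAlgError:
        pass
    from scipy.linalg import expm

    return expm(a) @ v


def ros_generation_rate(budget: PhotonBudget, rc: ReactionCentres,
                        params: PhotoParams) -> float:
    """Areal ROS production, mg O m-2 d-1:  (Q_in/Q_T) k_I / m_RCII / m_P2R.

    All generated ROS enters the pool (no diffusion loss).
    """
    if rc.q_t <= 0:
        raise ValueError("no reaction centres (q_t = 0)")
    return (rc.q_in / rc.q_t) * budget.k_i / params.m_rcii / params.m_p2r


def ros_detox_rate(
    ros_percell: float,
    reserves_norm: tuple[float, float, float],
    mu_max: float,
    cell_density: float,
    params: PhotoParams,
) -> float:
    """Revised piecewise detoxification, areal rate mg O m-2 d-1.

    Healthy cells (full reserves) detoxify back to half the bleaching
    threshold: no detoxification at or below threshold/2, a rate
    proportional to the excess above threshold/2 up to the threshold, and a
    constant ceiling of mu_max * R* * (threshold/2) * cells above it.
    Continuous at both breakpoints.
    """
    theta = params.ros_threshold
    half = 0.5 * theta
    r_n, r_c, r_p = reserves_norm
    scale = mu_max * r_n * r_c * r_p * cell_density
    if ros_percell <= half:
        return 0.0
    if ros_percell <= theta:
        return scale * (ros_percell - half)
    return scale * half


def ros_detox_rate_legacy(
    ros_percell: float,
    reserves_norm: tuple[float, float, float],
    mu_max: float,
) -> float:
    """Legacy proportional detoxification, per-cell rate mg O cell-1 d-1.

    mu_max * R_N* * R_C* * R_P* * [ROS]; lets [ROS] decay to zero.  Kept
    selectable for comparison with the revised law.
    """
    r_n, r_c, r_p = reserves_norm
    return mu_max * r_n * r_c * r_p * ros_percell


def xanthophyll_switch(
    x_p: float, x_h: float, q_in_frac: float, params: PhotoParams
) -> tuple[float, float]:
    """Xanthophyll-cycle fluxes (dXp/dt, dXh/dt), mg m-2 d-1.

    When more than half the reaction centres are inhibited the cycle runs
    photoprotective (diadinoxanthin -> diatoxanthin); otherwise it relaxes
    back.  The switch conserves the total xanthophyll pool.
    """
    if x_p < 0 or x_h < 0:
        raise ValueError("xanthophyll pools must be non-negative")
    rate = params.xanth_switch_rate
    if q_in_frac > 0.5:
        flux = rate * x_p
        return -flux, flux
    flux = rate * x_h
    return flux, -flux
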