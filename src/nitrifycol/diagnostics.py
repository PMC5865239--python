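"""Post-processing: R* competition diagnostics, PNM metrics, rates, budgets.

The central diagnostic is the subsistence concentration

    R* = K L / (y Vmax - L)

— the resource level at which a population's Monod growth exactly balances
its loss rate L. The population with the lowest R* for a shared resource
excludes the others at steady state, and the ambient concentration relaxes
to the winner's R*. Comparing depth profiles of R* for phytoplankton and
the two nitrifier types against the equilibrium NH4+/NO2- profiles shows
where each group controls the nutrient field and why a primary nitrite
maximum (PNM) forms at the base of the euphotic zone.

Where maximum growth does not exceed loss, R* is undefined; it is reported
masked (numpy masked arrays), not negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import FMOL_PER_MOL, ML_PER_M3, MOL_M3_TO_NM
from .column import (
    ColumnGrid,
    EquilibriumSolution,
    light_theta_profiles,
    temperature_profile,
)
from .ecosystem import (
    EcosystemParams,
    NitrifierParams,
    grazing_rate,
    monod_growth,
    photosynthetic_rate,
    temperature_factor,
)

__all__ = [
    "RStarProfile",
    "PnmMetrics",
    "TracerIncubation",
    "loss_rate",
    "rstar_nitrifier",
    "rstar_phyto",
    "rstar_profiles",
    "pnm_metrics",
    "oxidation_rate_profiles",
    "biomass_to_cells",
    "nitrogen_budget",
    "tracer_aor",
]


@dataclass
class RStarProfile:
    """Depth-resolved loss rate and subsistence concentrations (mol N m^-3).

    Masked entries mark depths where maximum growth does not exceed loss
    and the population cannot subsist at any concentration.
    """

    depth: np.ndarray
    loss: np.ndarray  # d^-1
    aoo_nh4: np.ma.MaskedArray
    noo_no2: np.ma.MaskedArray
    phyto_nh4: np.ma.MaskedArray
    phyto_no2: np.ma.MaskedArray
    phyto_no3: np.ma.MaskedArray


@dataclass
class PnmMetrics:
    """Peak positions and magnitudes characterizing the simulated PNM."""

    pnm_present: bool
    no2_peak: float  # mol N m^-3
    no2_peak_depth: float  # m
    nh4_peak: float
    nh4_peak_depth: float
    peak_ratio: float  # peak [NH4+] : peak [NO2-]
    dcm_depth: float
    nh4_oxidation_peak: float  # nmol N L^-1 d^-1
    nh4_oxidation_peak_depth: float
    no2_oxidation_peak: float
    no2_oxidation_peak_depth: float


@dataclass(frozen=True)
class TracerIncubation:
    """A 15N-ammonium tracer incubation for the ammonia-oxidation rate.

    a_no2_i, a_no2_f : atom % 15N of the NO2- pool at start and end
    a_nh4 : atom % 15N of the NH4+ pool after spiking
    no2_f : final NO2- concentration (nM)
    v : sample volume (L)
    dt : incubation duration (days)
    """

    a_no2_i: float
    a_no2_f: float
    a_nh4: float
    no2_f: float
    v: float = 1.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        for a in (self.a_no2_i, self.a_no2_f, self.a_nh4):
            if not 0.0 <= a <= 100.0:
                raise ValueError("atom percents must lie in [0, 100]")
        if self.dt <= 0.0 or self.v <= 0.0:
            raise ValueError("volume and duration must be positive")


def loss_rate(
    solution: EquilibriumSolution | None = None,
    *,
    state=None,
    params: EcosystemParams | None = None,
    grid: ColumnGrid | None = None,
) -> np.ndarray:
    """Specific loss rate L(z) = m_B + g(z) Z(z) (d^-1).

    Identical for all four microbial prey: the mortality m_B is shared and
    the grazing rate depends only on total prey biomass.
    """
    if solution is not None:
        state = solution.vector()
        params = solution.params
        grid = solution.grid
    t_prof = temperature_profile(grid)
    gt = temperature_factor(t_prof, params.temperature)
    g = grazing_rate(state, params, gt)
    return params.m_b + g * state.z


def _masked_rstar(
    k: float, max_growth: np.ndarray | float, loss: np.ndarray
) -> np.ma.MaskedArray:
    loss = np.asarray(loss, dtype=float)
    denom = np.asarray(max_growth, dtype=float) - loss
    mask = denom <= 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = k * loss / np.where(mask, 1.0, denom)
    return np.ma.MaskedArray(r, mask=mask)


def rstar_nitrifier(
    nit: NitrifierParams, loss: np.ndarray | float
) -> np.ma.MaskedArray:
    """Subsistence concentration K L / (y Vmax - L); masked where y Vmax <= L."""
    return _masked_rstar(nit.k, nit.max_growth, np.atleast_1d(loss))


def rstar_phyto(
    solution: EquilibriumSolution,
    loss: np.ndarray | None = None,
    replete_theta: bool = False,
) -> dict[str, np.ma.MaskedArray]:
    """Phytoplankton per-DIN-species R* using the light-limited maximum growth.

    mu_light = mu_max gamma_T (1 - exp(-Gamma theta / (mu_max gamma_T)))
    is the growth rate with nutrient limitation removed, evaluated with the
    equilibrium photoacclimation state; R* is masked below the depth where
    light can no longer sustain the population (mu_light <= L).

    With ``replete_theta`` the Chl:C ratio is re-evaluated for a
    nutrient-replete cell at the same light, which makes mu_light an
    invasion bound: in a nutrient-starved surface layer the incumbents'
    acclimated theta collapses along with their growth, and using it would
    mask the diagnostic exactly where the exclusion argument applies.
    """
    params = solution.params
    phyto = params.phyto
    if loss is None:
        loss = loss_rate(solution)
    prof = light_theta_profiles(
        solution.state, params, solution.physics, solution.grid
    )
    gt = temperature_factor(
        temperature_profile(solution.grid), params.temperature
    )
    gamma = photosynthetic_rate(prof["irradiance"], phyto)
    mu_cap = phyto.mu_max * gt
    theta = prof["theta"]
    if replete_theta:
        theta = phyto.theta_max / (
            1.0 + gamma * phyto.theta_max / (2.0 * mu_cap)
        )
    with np.errstate(over="ignore"):
        mu_light = mu_cap * (1.0 - np.exp(-gamma * theta / mu_cap))
    return {
        "nh4": _masked_rstar(phyto.k_nh4, mu_light, loss),
        "no2": _masked_rstar(phyto.k_no2, mu_light, loss),
        "no3": _masked_rstar(phyto.k_no3, mu_light, loss),
        "mu_light": mu_light,
    }


def rstar_profiles(solution: EquilibriumSolution) -> RStarProfile:
    """Loss rate and all subsistence-concentration profiles at equilibrium."""
    loss = loss_rate(solution)
    p = rstar_phyto(solution, loss)
    return RStarProfile(
        depth=solution.grid.z_centers,
        loss=loss,
        aoo_nh4=rstar_nitrifier(solution.params.aoo, loss),
        noo_no2=rstar_nitrifier(solution.params.noo, loss),
        phyto_nh4=p["nh4"],
        phyto_no2=p["no2"],
        phyto_no3=p["no3"],
    )


def _refined_peak(
    profile: np.ndarray, z: np.ndarray
) -> tuple[float, float, bool]:
    """Discrete maximum with parabolic sub-cell refinement.

    Returns (peak value, peak depth, interior flag). Ties break toward the
    shallower depth (argmax returns the first maximum). The peak is
    'interior' when it is not at either boundary cell.
    """
    i = int(np.argmax(profile))
    interior = 0 < i < profile.size - 1
    if not interior:
        return float(profile[i]), float(z[i]), False
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:  # flat or non-concave: keep the grid point
        return float(y1), float(z[i]), True
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    dz = z[1] - z[0]
    value = y1 - 0.25 * (y0 - y2) * shift
    return float(value), float(z[i] + shift * dz), True


def oxidation_rate_profiles(
    solution: EquilibriumSolution,
) -> dict[str, np.ndarray]:
    """NH4+ and NO2- oxidation rates (nmol N L^-1 d^-1).

    NH4+ oxidation is the AOO DIN processing rate mu B / y; NO2- oxidation
    likewise for the NOO.
    """
    sv = solution.vector()
    params = solution.params
    gt_nit = (
        1.0
        if params.nitrifier_temperature_exempt
        else temperature_factor(
            temperature_profile(solution.grid), params.temperature
        )
    )
    mu_aoo = gt_nit * monod_growth(
        sv.nh4, params.aoo.vmax, params.aoo.k, params.aoo.yield_y
    )
    mu_noo = gt_nit * monod_growth(
        sv.no2, params.noo.vmax, params.noo.k, params.noo.yield_y
    )
    return {
        "nh4_oxidation": mu_aoo * sv.b_aoo / params.aoo.yield_y * MOL_M3_TO_NM,
        "no2_oxidation": mu_noo * sv.b_noo / params.noo.yield_y * MOL_M3_TO_NM,
    }


def pnm_metrics(
    solution: EquilibriumSolution, exclude_bottom_m: float = 150.0
) -> PnmMetrics:
    """Locate the NO2-/NH4+/chlorophyll/rate maxima of an equilibrium column.

    A PNM is flagged present only when the NO2- maximum is an interior peak
    (a monotone or boundary-peaked profile yields pnm_present=False). The
    bottom ``exclude_bottom_m`` of the column is excluded from the search:
    the no-flux bottom with its boundary mixed layer accumulates sinking
    detritus as a crude sediment, and the nutrient buildup there is an
    artifact of the closed domain, not part of the water-column signal.
    """
    zc = solution.grid.z_centers
    keep = zc <= solution.grid.h - exclude_bottom_m
    if keep.sum() < 3:
        keep = np.ones_like(zc, dtype=bool)
    z = zc[keep]
    sv = solution.vector()
    no2_peak, no2_z, no2_interior = _refined_peak(np.asarray(sv.no2)[keep], z)
    nh4_peak, nh4_z, _ = _refined_peak(np.asarray(sv.nh4)[keep], z)
    prof = light_theta_profiles(
        solution.state, solution.params, solution.physics, solution.grid
    )
    _, dcm_z, _ = _refined_peak(np.asarray(prof["chlorophyll"])[keep], z)
    rates = oxidation_rate_profiles(solution)
    aor_peak, aor_z, _ = _refined_peak(rates["nh4_oxidation"][keep], z)
    nor_peak, nor_z, _ = _refined_peak(rates["no2_oxidation"][keep], z)
    ratio = nh4_peak / no2_peak if no2_peak > 0 else float("nan")
    return PnmMetrics(
        pnm_present=bool(no2_interior and no2_peak > 0.0),
        no2_peak=no2_peak,
        no2_peak_depth=no2_z,
        nh4_peak=nh4_peak,
        nh4_peak_depth=nh4_z,
        peak_ratio=ratio,
        dcm_depth=dcm_z,
        nh4_oxidation_peak=aor_peak,
        nh4_oxidation_peak_depth=aor_z,
        no2_oxidation_peak=nor_peak,
        no2_oxidation_peak_depth=nor_z,
    )


def biomass_to_cells(
    biomass: np.ndarray | float, quota_fmol: float
) -> np.ndarray | float:
    """Cells per mL from biomass (mol N m^-3) and a cell quota (fmol N per cell)."""
    if quota_fmol <= 0:
        raise ValueError("quota must be positive")
    return biomass * FMOL_PER_MOL / ML_PER_M3 / quota_fmol


def nitrogen_budget(solution: EquilibriumSolution) -> dict[str, object]:
    """Column nitrogen inventory history, relative drift, and clip ledger.

    drift_per_year is the relative inventory change per 365 days; with
    clipping active the drift should reconcile with the clipped-mass ledger.
    """
    hist = solution.inventory_history
    times = np.asarray([t for t, _ in hist])
    inv = np.asarray([v for _, v in hist])
    span = times[-1] - times[0]
    drift = (inv[-1] - inv[0]) / inv[0] if inv[0] > 0 else float("nan")
    per_year = drift * 365.0 / span if span > 0 else float("nan")
    return {
        "times": times,
        "inventory": inv,
        "relative_drift": float(drift),
        "drift_per_year": float(per_year),
        "clipped_mass": solution.clipped_mass,
        "clipped_relative": (
            solution.clipped_mass / inv[0] if inv[0] > 0 else float("nan")
        ),
    }


def tracer_aor(
    inc: TracerIncubation, include_volume: bool = True
) -> tuple[float, bool]:
    """Ammonia oxidation rate from a 15N tracer incubation (nM d^-1).

    AOR = (a_NO2,f - a_NO2,i) / a_NH4 * [NO2-]_f / (V dt), exactly as the
    field formula is printed (the sample-volume term makes the nominal
    units nM L^-1 d^-1; pass include_volume=False for the per-liter-free
    variant). Returns (rate, warning_flag); the flag marks a negative rate
    (final labeling below initial).
    """
    if inc.a_nh4 <= 0:
        raise ValueError("spiked NH4+ atom percent must be positive")
    denom = inc.v * inc.dt if include_volume else inc.dt
    rate = (inc.a_no2_f - inc.a_no2_i) / inc.a_nh4 * inc.no2_f / denom
    flagged = rate < 0.0
    if flagged:
        warnings.warn(
            "final NO2- labeling below initial: negative oxidation rate",
            stacklevel=2,
        )
    return rate, flagged
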