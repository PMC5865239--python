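"""The nine-variable nitrogen-cycle ecosystem: local biological tendencies.

State variables (all in mol N m^-3): three DIN species (NH4+, NO2-, NO3-),
sinking organic detritus, and the nitrogen biomass of five microbial
functional types — heterotrophic bacteria, ammonia oxidizers (AOO), nitrite
oxidizers (NOO), picophytoplankton, and a microzooplankton grazer.

The interaction structure: phytoplankton assimilate all three DIN species
with light-, nutrient- and temperature-limited growth; heterotrophs consume
detritus and remineralize the non-assimilated fraction to NH4+; AOO oxidize
NH4+ to NO2- and NOO oxidize NO2- to NO3-, each keeping only a small yield
of the DIN they process as biomass N; the grazer consumes the four
microbial prey, keeping a fraction zeta and excreting the rest as NH4+;
linear microbial mortality and quadratic grazer mortality feed detritus.

Every biological flux is declared once, with the set of state variables it
moves nitrogen between, and tendencies are assembled from that ledger — so
local nitrogen conservation holds to machine precision by construction,
and a test can audit that each flux enters the system twice with opposite
signs.

All rate functions are vectorized: state fields may be scalars or
depth-profiles (1D arrays).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .constants import C_G_PER_MOL, UM_TO_MOL_M3

__all__ = [
    "VAR_NAMES",
    "CellStateVector",
    "LocalEnvironment",
    "NitrifierParams",
    "HetParams",
    "PhytoParams",
    "GrazingParams",
    "TemperatureParams",
    "O2Limitation",
    "EcosystemParams",
    "temperature_factor",
    "monod_growth",
    "gamma_n",
    "phyto_growth",
    "din_uptake_rates",
    "het_growth",
    "grazing_rate",
    "Flux",
    "biological_fluxes",
    "biological_tendencies",
]

#: Canonical ordering of the nine state variables.
VAR_NAMES = (
    "nh4",
    "no2",
    "no3",
    "det",
    "b_het",
    "b_aoo",
    "b_noo",
    "p",
    "z",
)


@dataclass
class CellStateVector:
    """Concentrations of the nine state variables (mol N m^-3).

    Fields may be scalars (a point model) or 1D depth profiles.
    """

    nh4: np.ndarray | float = 0.0
    no2: np.ndarray | float = 0.0
    no3: np.ndarray | float = 0.0
    det: np.ndarray | float = 0.0
    b_het: np.ndarray | float = 0.0
    b_aoo: np.ndarray | float = 0.0
    b_noo: np.ndarray | float = 0.0
    p: np.ndarray | float = 0.0
    z: np.ndarray | float = 0.0

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CellStateVector":
        """Build from a (9,) or (9, nz) array in VAR_NAMES order."""
        return cls(**{name: arr[i] for i, name in enumerate(VAR_NAMES)})

    def to_array(self) -> np.ndarray:
        return np.asarray([getattr(self, name) for name in VAR_NAMES])

    def total_n(self) -> np.ndarray | float:
        return sum(getattr(self, name) for name in VAR_NAMES)


class LocalEnvironment(NamedTuple):
    """Irradiance (umol photons m^-2 s^-1) and temperature (deg C)."""

    irradiance: np.ndarray | float
    temperature: np.ndarray | float


@dataclass(frozen=True)
class NitrifierParams:
    """One chemoautotrophic nitrifier functional type.

    vmax : mol DIN per mol biomass N per day
    k    : half-saturation, mol N m^-3
    yield_y : mol biomass N per mol DIN oxidized
    """

    vmax: float
    k: float
    yield_y: float

    def __post_init__(self) -> None:
        if not 0.0 < self.yield_y < 1.0:
            raise ValueError("yield must lie in (0, 1)")
        if self.vmax <= 0.0 or self.k <= 0.0:
            raise ValueError("vmax and k must be positive")

    @classmethod
    def from_traits(cls, traits, yield_y: float) -> "NitrifierParams":
        """From a :class:`~nitrifycol.traits.KineticTraits` (k in uM)."""
        return cls(
            vmax=traits.vmax, k=traits.k * UM_TO_MOL_M3, yield_y=yield_y
        )

    @property
    def max_growth(self) -> float:
        """Maximum growth rate y * vmax (d^-1)."""
        return self.yield_y * self.vmax


@dataclass(frozen=True)
class HetParams:
    """Heterotrophic bacteria growing on detritus."""

    vmax_d: float = 1.0  # mol D per mol biomass N per day (calibrated)
    k_d: float = 0.02 * UM_TO_MOL_M3  # mol N m^-3 (calibrated)
    y_d: float = 0.14  # open-ocean mean bacterial growth efficiency

    def __post_init__(self) -> None:
        if not 0.0 < self.y_d < 1.0:
            raise ValueError("y_d must lie in (0, 1)")


@dataclass(frozen=True)
class PhytoParams:
    """Picophytoplankton growth, uptake and photoacclimation parameters."""

    mu_max: float  # d^-1
    k_nh4: float  # mol N m^-3
    k_no2: float  # mol N m^-3
    k_no3: float  # mol N m^-3
    phi: float = 0.06  # mol C per mol photons (calibrated)
    a_chl: float = 0.02  # m^2 per mg Chl (calibrated)
    theta_max: float = 0.05  # g Chl per g C (calibrated)
    cn_ratio: float = 6.6  # mol C per mol N


@dataclass(frozen=True)
class GrazingParams:
    """Single microzooplankton grazer on the four microbial prey."""

    g_max: float = 1.0  # d^-1
    k_g: float = 1.0 * UM_TO_MOL_M3  # mol N m^-3
    zeta: float = 0.5  # grazer N growth efficiency
    m_z: float = 1.0 / UM_TO_MOL_M3  # quadratic mortality, m^3 per mol N per day

    def __post_init__(self) -> None:
        if not 0.0 < self.zeta < 1.0:
            raise ValueError("zeta must lie in (0, 1)")


@dataclass(frozen=True)
class TemperatureParams:
    """Arrhenius-form temperature modification of rates.

    gamma_T = tau * exp(a_e * (1/(T+273.15) - 1/t0)). With the negative
    default a_e, gamma_T increases with temperature and equals tau at the
    reference temperature t0.
    """

    tau: float = 0.8
    a_e: float = -4000.0  # K
    t0: float = 293.15  # K


@dataclass(frozen=True)
class O2Limitation:
    """Optional Monod O2 limitation hook for the nitrifiers (off by default).

    The modeled domain is oxygenated well above nitrifier half-saturations,
    so the column model does not carry O2 as a state variable; this hook
    applies a fixed O2 concentration profile if provided.
    """

    o2: float | np.ndarray  # mol O2 m^-3
    k_o2_aoo: float = 0.333e-3
    k_o2_noo: float = 0.778e-3


@dataclass(frozen=True)
class EcosystemParams:
    """All biological parameters of the nine-variable model."""

    aoo: NitrifierParams
    noo: NitrifierParams
    het: HetParams = field(default_factory=HetParams)
    phyto: PhytoParams | None = None
    grazing: GrazingParams = field(default_factory=GrazingParams)
    m_b: float = 0.01  # linear microbial mortality, d^-1 (calibrated)
    temperature: TemperatureParams = field(default_factory=TemperatureParams)
    nitrifier_temperature_exempt: bool = True
    o2_limitation: O2Limitation | None = None

    def replace(self, **kw) -> "EcosystemParams":
        return replace(self, **kw)


def temperature_factor(
    t_celsius: np.ndarray | float,
    params: TemperatureParams | EcosystemParams,
    nitrifier: bool = False,
) -> np.ndarray | float:
    """Dimensionless Arrhenius factor gamma_T.

    Returns 1 for nitrifying types when the ecosystem exempts them from
    temperature modification (their culture-derived rates are used as-is).
    """
    if isinstance(params, EcosystemParams):
        if nitrifier and params.nitrifier_temperature_exempt:
            return np.ones_like(np.asarray(t_celsius, dtype=float))
        tp = params.temperature
    else:
        if nitrifier:
            return np.ones_like(np.asarray(t_celsius, dtype=float))
        tp = params
    t_kelvin = np.asarray(t_celsius, dtype=float) + 273.15
    return tp.tau * np.exp(tp.a_e * (1.0 / t_kelvin - 1.0 / tp.t0))


def monod_growth(
    r: float | np.ndarray | Sequence,
    vmax: float,
    k: float | Sequence,
    y: float,
) -> np.ndarray | float:
    """Monod growth rate mu = y * vmax * R/(R+K) (d^-1).

    With several potentially limiting resources, pass matching sequences of
    concentrations and half-saturations; the scarcest (Liebig) saturation
    term is used.
    """
    if isinstance(r, (list, tuple)):
        if not isinstance(k, (list, tuple)) or len(k) != len(r):
            raise ValueError("need one half-saturation per resource")
        sat = np.minimum.reduce(
            [np.asarray(ri) / (np.asarray(ri) + ki) for ri, ki in zip(r, k)]
        )
    else:
        r = np.asarray(r, dtype=float)
        sat = r / (r + k)
    return y * vmax * sat


def gamma_n(
    nh4: np.ndarray | float,
    no2: np.ndarray | float,
    no3: np.ndarray | float,
    phyto: PhytoParams,
) -> np.ndarray | float:
    """Nutrient limitation as the sum of the three DIN saturation terms.

    Deliberately not clipped at 1: the same sum normalizes the uptake
    partition, so the apportioned uptakes always total mu_P.
    """
    nh4, no2, no3 = (np.asarray(x, dtype=float) for x in (nh4, no2, no3))
    return (
        nh4 / (nh4 + phyto.k_nh4)
        + no2 / (no2 + phyto.k_no2)
        + no3 / (no3 + phyto.k_no3)
    )


#: Conversion factor: phi [mol C / mol photons] * a_chl [m^2/mgChl] *
#: I [umol photons m^-2 s^-1] -> Gamma [g C / g Chl / day].
#: 12 g C/mol C * 1e-6 mol/umol * 1000 mg/g * 86400 s/day = 12 * 86.4.
_GAMMA_UNITS = C_G_PER_MOL * 1e-6 * 1000.0 * 86400.0


def photosynthetic_rate(
    irradiance: np.ndarray | float, phyto: PhytoParams
) -> np.ndarray | float:
    """Instantaneous chlorophyll-specific photosynthetic rate Gamma (gC/gChl/d)."""
    return phyto.phi * phyto.a_chl * np.asarray(irradiance, float) * _GAMMA_UNITS


def phyto_growth(
    env: LocalEnvironment,
    nh4: np.ndarray | float,
    no2: np.ndarray | float,
    no3: np.ndarray | float,
    params: EcosystemParams,
    gamma_t: np.ndarray | float | None = None,
) -> dict[str, np.ndarray | float]:
    """Phytoplankton growth rate, photoacclimated Chl:C, nutrient limitation.

    The chlorophyll-to-carbon ratio theta takes its balanced-growth value
    theta_max / (1 + Gamma theta_max / (2 mu_max gamma_N gamma_T)); growth
    saturates exponentially in Gamma*theta. Returns raw theta — the 0.1
    theta_max floor applies only to reported chlorophyll, not to growth.
    """
    phyto = params.phyto
    if gamma_t is None:
        gamma_t = temperature_factor(env.temperature, params.temperature)
    gn = gamma_n(nh4, no2, no3, phyto)
    gamma = photosynthetic_rate(env.irradiance, phyto)
    mu_net = phyto.mu_max * gn * gamma_t
    mu_net = np.asarray(mu_net, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(
            mu_net > 0.0,
            phyto.theta_max
            / (1.0 + gamma * phyto.theta_max / (2.0 * np.where(mu_net > 0, mu_net, 1.0))),
            np.where(gamma > 0.0, 0.0, phyto.theta_max),
        )
        mu_p = np.where(
            (mu_net > 0.0) & (gamma * theta > 0.0),
            mu_net
            * (1.0 - np.exp(-gamma * theta / np.where(mu_net > 0, mu_net, 1.0))),
            0.0,
        )
    if mu_p.ndim == 0:
        return {
            "mu_p": float(mu_p),
            "theta": float(theta),
            "gamma_n": float(gn),
        }
    return {"mu_p": mu_p, "theta": theta, "gamma_n": gn}


def din_uptake_rates(
    mu_p: np.ndarray | float,
    nh4: np.ndarray | float,
    no2: np.ndarray | float,
    no3: np.ndarray | float,
    params: EcosystemParams | PhytoParams,
) -> dict[str, np.ndarray | float]:
    """Apportion phytoplankton growth among the three DIN species.

    Each specific uptake rate V (d^-1) is mu_P weighted by that species'
    Monod term over the sum of the three; the three always total mu_P, and
    all are zero when no DIN is present.
    """
    phyto = params.phyto if isinstance(params, EcosystemParams) else params
    nh4, no2, no3 = (np.asarray(x, dtype=float) for x in (nh4, no2, no3))
    t_nh4 = nh4 / (nh4 + phyto.k_nh4)
    t_no2 = no2 / (no2 + phyto.k_no2)
    t_no3 = no3 / (no3 + phyto.k_no3)
    total = t_nh4 + t_no2 + t_no3
    safe = np.where(total > 0.0, total, 1.0)
    frac = np.where(total > 0.0, 1.0, 0.0)
    return {
        "v_nh4": mu_p * t_nh4 / safe * frac,
        "v_no2": mu_p * t_no2 / safe * frac,
        "v_no3": mu_p * t_no3 / safe * frac,
    }


def het_growth(
    det: np.ndarray | float,
    params: EcosystemParams,
    gamma_t: np.ndarray | float = 1.0,
) -> np.ndarray | float:
    """Heterotroph growth rate y_D * Vmax_D * D/(D+K_D) * gamma_T (d^-1)."""
    het = params.het
    det = np.asarray(det, dtype=float)
    return het.y_d * het.vmax_d * det / (det + het.k_d) * gamma_t


def grazing_rate(
    state: CellStateVector,
    params: EcosystemParams,
    gamma_t: np.ndarray | float = 1.0,
) -> np.ndarray | float:
    """Grazing rate g = g_max/(total prey + K_g) * gamma_T (m^3 per mol N per day).

    The grazing flux on prey i is g * Z * B_i.
    """
    gp = params.grazing
    prey = state.p + state.b_het + state.b_aoo + state.b_noo
    return gp.g_max / (prey + gp.k_g) * gamma_t


@dataclass(frozen=True)
class Flux:
    """One biological nitrogen flux and its destination coefficients.

    ``rate`` is the flux magnitude (mol N m^-3 d^-1); ``moves`` maps each
    affected state variable to its signed coefficient. Coefficients sum to
    zero for every flux, so assembling tendencies from the ledger conserves
    nitrogen exactly.
    """

    name: str
    rate: np.ndarray | float
    moves: dict[str, float]


def _nitrifier_mu(
    b: NitrifierParams,
    din: np.ndarray | float,
    o2_hook: tuple | None,
) -> np.ndarray | float:
    if o2_hook is None:
        return monod_growth(din, b.vmax, b.k, b.yield_y)
    o2, k_o2 = o2_hook
    return monod_growth([din, o2], b.vmax, [b.k, k_o2], b.yield_y)


def biological_fluxes(
    state: CellStateVector,
    env: LocalEnvironment,
    params: EcosystemParams,
    gamma_t: np.ndarray | float | None = None,
) -> list[Flux]:
    """The full ledger of local biological nitrogen fluxes."""
    if gamma_t is None:
        gamma_t = temperature_factor(env.temperature, params.temperature)
    o2 = params.o2_limitation
    y_a = params.aoo.yield_y
    y_n = params.noo.yield_y
    y_d = params.het.y_d
    zeta = params.grazing.zeta

    gt_nit = 1.0 if params.nitrifier_temperature_exempt else gamma_t
    mu_aoo = gt_nit * _nitrifier_mu(
        params.aoo, state.nh4, (o2.o2, o2.k_o2_aoo) if o2 else None
    )
    mu_noo = gt_nit * _nitrifier_mu(
        params.noo, state.no2, (o2.o2, o2.k_o2_noo) if o2 else None
    )
    mu_het = het_growth(state.det, params, gamma_t)
    g = grazing_rate(state, params, gamma_t)

    fluxes = [
        Flux(
            "aoo_growth",
            mu_aoo * state.b_aoo,
            {"nh4": -1.0 / y_a, "no2": 1.0 / y_a - 1.0, "b_aoo": 1.0},
        ),
        Flux(
            "noo_growth",
            mu_noo * state.b_noo,
            {
                "no2": -1.0 / y_n,
                "no3": 1.0 / y_n,
                "nh4": -1.0,  # assimilatory N source for cell synthesis
                "b_noo": 1.0,
            },
        ),
        Flux(
            "het_growth",
            mu_het * state.b_het,
            {"det": -1.0 / y_d, "nh4": 1.0 / y_d - 1.0, "b_het": 1.0},
        ),
    ]

    if params.phyto is not None:
        pg = phyto_growth(
            env, state.nh4, state.no2, state.no3, params, gamma_t
        )
        v = din_uptake_rates(
            pg["mu_p"], state.nh4, state.no2, state.no3, params
        )
        fluxes += [
            Flux("p_uptake_nh4", v["v_nh4"] * state.p, {"nh4": -1.0, "p": 1.0}),
            Flux("p_uptake_no2", v["v_no2"] * state.p, {"no2": -1.0, "p": 1.0}),
            Flux("p_uptake_no3", v["v_no3"] * state.p, {"no3": -1.0, "p": 1.0}),
        ]

    for prey in ("p", "b_het", "b_aoo", "b_noo"):
        fluxes.append(
            Flux(
                f"grazing_{prey}",
                g * state.z * getattr(state, prey),
                {prey: -1.0, "z": zeta, "nh4": 1.0 - zeta},
            )
        )
        fluxes.append(
            Flux(
                f"mortality_{prey}",
                params.m_b * getattr(state, prey),
                {prey: -1.0, "det": 1.0},
            )
        )
    fluxes.append(
        Flux(
            "z_mortality",
            params.grazing.m_z * state.z**2 * gamma_t,
            {"z": -1.0, "det": 1.0},
        )
    )
    return fluxes


def biological_tendencies(
    state: CellStateVector,
    env: LocalEnvironment,
    params: EcosystemParams,
    gamma_t: np.ndarray | float | None = None,
) -> CellStateVector:
    """Per-variable d/dt from all local biological sources and sinks.

    Transport (mixing, sinking) is handled by the column module. The sum of
    the nine tendencies is zero for any state: nitrogen only moves between
    pools locally.
    """
    template = np.zeros_like(np.asarray(state.nh4, dtype=float))
    tend = {name: template.copy() for name in VAR_NAMES}
    for flux in biological_fluxes(state, env, params, gamma_t):
        for var, coeff in flux.moves.items():
            tend[var] = tend[var] + coeff * flux.rate
    return CellStateVector(**tend)
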