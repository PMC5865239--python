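"""Kinetic traits of the microbial functional types.

Culture measurements of nitrifier uptake kinetics are reported per mg of
cell protein; the ecosystem model needs rates per mol of biomass nitrogen.
This module performs those conversions, applies allometric (cell-size)
scaling between the small ammonia-oxidizing archaea and the larger
nitrite-oxidizing bacteria, and builds phytoplankton traits from generic
power-law allometries ``trait = a * v**b`` in cell volume v.

The canonical anchor values: the cultured ammonia-oxidizer maximum uptake
rate of 24.2 umol NH4+ per mg protein per hour converts (at 16% protein N)
to 50.8 mol NH4+ per mol biomass N per day; with a half-saturation of
133 nM the specific affinity is 382 L per umol biomass N per day. A 10-fold
larger nitrite-oxidizer cell volume implies a radius factor 10^(1/3) = 2.2,
halving the specific maximum uptake rate, doubling the half-saturation, and
reducing specific affinity 10^(2/3) = 4.6-fold.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import HOURS_PER_DAY, N_G_PER_MOL, PROTEIN_N_FRACTION

__all__ = [
    "KineticTraits",
    "CellProperties",
    "AllometricCoefficients",
    "PhytoAllometry",
    "specific_rate_from_protein_rate",
    "per_cell_rate",
    "sd_by_ratio",
    "n_quota_from_protein",
    "allometric_scaling",
    "specific_affinity",
    "phyto_traits_from_volume",
    "build_noo_traits",
    "AOO_TRAITS",
    "AOO_CELL",
    "NOO_CELL",
    "DEFAULT_NOO_VOLUME_FACTOR",
    "PROCHLOROCOCCUS_VOLUME_UM3",
    "DEFAULT_PHYTO_ALLOMETRY",
    "trait_table",
]


@dataclass(frozen=True)
class KineticTraits:
    """Uptake kinetics of one population for one resource.

    vmax : mol resource per mol biomass N per day
    k    : half-saturation concentration, umol L^-1
    """

    vmax: float
    k: float

    def __post_init__(self) -> None:
        if self.vmax <= 0.0 or self.k <= 0.0:
            raise ValueError("vmax and k must be positive")

    @property
    def affinity(self) -> float:
        """Specific affinity vmax/k, L per umol biomass N per day."""
        return self.vmax / self.k


@dataclass(frozen=True)
class CellProperties:
    """Per-cell protein content and the implied nitrogen quota."""

    protein_per_cell: float  # fg protein per cell
    protein_n_fraction: float = PROTEIN_N_FRACTION  # g N per g protein
    volume_factor: float = 1.0  # cell volume relative to the reference cell

    def __post_init__(self) -> None:
        if self.protein_per_cell <= 0.0:
            raise ValueError("protein_per_cell must be positive")
        if not 0.0 < self.protein_n_fraction < 1.0:
            raise ValueError("protein_n_fraction must lie in (0, 1)")
        if self.volume_factor <= 0.0:
            raise ValueError("volume_factor must be positive")

    @property
    def n_quota(self) -> float:
        """fmol N per cell."""
        return n_quota_from_protein(
            self.protein_per_cell, self.protein_n_fraction
        )


def specific_rate_from_protein_rate(
    rate: float, n_fraction: float = PROTEIN_N_FRACTION
) -> float:
    """Protein-normalized rate to biomass-N-specific rate.

    Parameters
    ----------
    rate : umol substrate per mg protein per hour
    n_fraction : g N per g protein

    Returns
    -------
    mol substrate per mol biomass N per day. One mg protein holds
    1000 * n_fraction / 14 umol N, so the conversion is
    ``rate * 24 / (1000 * n_fraction / 14)``.
    """
    if rate < 0.0:
        raise ValueError("rate must be non-negative")
    if not 0.0 < n_fraction < 1.0:
        raise ValueError("n_fraction must lie in (0, 1)")
    umol_n_per_mg = 1000.0 * n_fraction / N_G_PER_MOL
    return rate * HOURS_PER_DAY / umol_n_per_mg


def per_cell_rate(rate: float, protein_per_cell: float) -> float:
    """Protein-normalized rate to a per-cell rate.

    ``rate`` in umol per mg protein per hour equals amol per fg protein per
    hour (1 umol/mg = 1e-18 mol/fg), so a cell of ``protein_per_cell`` fg
    turns over ``rate * protein_per_cell * 24 / 1000`` fmol per day.
    """
    if rate < 0.0 or protein_per_cell <= 0.0:
        raise ValueError("inputs must be positive")
    return rate * protein_per_cell * HOURS_PER_DAY / 1000.0


def sd_by_ratio(sd_ref: float, value: float, ref: float) -> float:
    """Scale a reference standard deviation onto a proportional quantity."""
    if ref <= 0.0:
        raise ValueError("ref must be positive")
    return sd_ref * value / ref


def n_quota_from_protein(
    protein_per_cell: float, n_fraction: float = PROTEIN_N_FRACTION
) -> float:
    """Nitrogen quota (fmol N per cell) from protein content (fg per cell)."""
    if protein_per_cell <= 0.0 or n_fraction <= 0.0:
        raise ValueError("inputs must be positive")
    return protein_per_cell * n_fraction / N_G_PER_MOL


def allometric_scaling(volume_factor: float) -> dict[str, float]:
    """Trait scale factors for a cell ``volume_factor`` times larger.

    Specific uptake scales with surface:volume as r^-1, the half-saturation
    as r, hence specific affinity as r^-2, with r = volume_factor^(1/3).
    """
    if volume_factor <= 0.0:
        raise ValueError("volume_factor must be positive")
    rho = volume_factor ** (1.0 / 3.0)
    return {
        "vmax_factor": 1.0 / rho,
        "k_factor": rho,
        "affinity_factor": rho**-2,
    }


def specific_affinity(t: KineticTraits) -> float:
    """Specific affinity vmax/k in L per umol biomass N per day."""
    return t.affinity


def build_noo_traits(
    aoo: KineticTraits, volume_factor: float
) -> KineticTraits:
    """Nitrite-oxidizer traits from ammonia-oxidizer traits by allometry."""
    s = allometric_scaling(volume_factor)
    return KineticTraits(
        vmax=aoo.vmax * s["vmax_factor"], k=aoo.k * s["k_factor"]
    )


@dataclass(frozen=True)
class AllometricCoefficients:
    """One power law trait = a * v**b (v: cell volume, um^3)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0.0:
            raise ValueError("coefficient a must be positive")

    def __call__(self, v: float) -> float:
        if v <= 0.0:
            raise ValueError("cell volume must be positive")
        return self.a * v**self.b


@dataclass(frozen=True)
class PhytoAllometry:
    """Coefficient set for the four phytoplankton trait power laws.

    mu_max : d^-1; vmax_n : umol N per cell per day;
    k_n : umol N L^-1; q_min : umol N per cell.
    """

    mu_max: AllometricCoefficients
    vmax_n: AllometricCoefficients
    k_n: AllometricCoefficients
    q_min: AllometricCoefficients


# Calibrated defaults for the picophytoplankton power laws. The K_N, V_max
# and Q_min coefficients follow published volume regressions for marine
# nitrate traits; together they give a specific affinity
# V_max/(Q_min K_N) of ~88 L per umol biomass N per day for a 0.6 um cell,
# the right magnitude for picophytoplankton. The mu_max law is a mild size
# dependence anchored at ~1.4 d^-1 for that same cell.
DEFAULT_PHYTO_ALLOMETRY = PhytoAllometry(
    mu_max=AllometricCoefficients(a=1.0, b=-0.15),
    vmax_n=AllometricCoefficients(a=9.1e-9, b=0.67),
    k_n=AllometricCoefficients(a=0.17, b=0.27),
    q_min=AllometricCoefficients(a=1.36e-9, b=0.77),
)

#: Volume of a 0.6 um diameter spherical cell (um^3).
PROCHLOROCOCCUS_VOLUME_UM3 = 4.0 / 3.0 * 3.141592653589793 * 0.3**3


def phyto_traits_from_volume(
    v: float, coeffs: PhytoAllometry | None = None
) -> dict[str, float]:
    """Phytoplankton growth/uptake traits at cell volume v (um^3).

    Returns mu_max (d^-1) and the effective half-saturations for growth,
    k_nox = K_N * mu_max * Q_min / V_max (uM), with the ammonium
    half-saturation assumed half that of the oxidized species.
    """
    if coeffs is None:
        coeffs = DEFAULT_PHYTO_ALLOMETRY
    for name in ("mu_max", "vmax_n", "k_n", "q_min"):
        if getattr(coeffs, name, None) is None:
            raise ValueError(f"incomplete allometric configuration: {name}")
    mu_max = coeffs.mu_max(v)
    k_nox = coeffs.k_n(v) * mu_max * coeffs.q_min(v) / coeffs.vmax_n(v)
    return {"mu_max": mu_max, "k_nox": k_nox, "k_nh4": 0.5 * k_nox}


#: Ammonia-oxidizer (archaeal) reference traits from culture: 24.2 umol NH4+
#: per mg protein per hour at 16% protein N -> 50.8 mol NH4+ per mol biomass
#: N per day; half-saturation 133 nM.
AOO_PROTEIN_RATE = 24.2  # umol NH4+ per mg protein per hour
AOO_K_UM = 0.133  # umol L^-1
AOO_TRAITS = KineticTraits(
    vmax=specific_rate_from_protein_rate(AOO_PROTEIN_RATE), k=AOO_K_UM
)

AOO_CELL = CellProperties(protein_per_cell=10.2)
NOO_CELL = CellProperties(protein_per_cell=102.0, volume_factor=10.0)

#: Headline nitrite-oxidizer cell-volume factor (a 50-fold factor has also
#: been suggested by recent size observations; configurable, not default).
DEFAULT_NOO_VOLUME_FACTOR = 10.0


def trait_table(rows: dict[str, dict[str, float]]) -> "pd.DataFrame":
    """Assemble a trait table (one row per functional type) for CSV export.

    ``rows`` maps a type name to a dict with keys among vmax, k, affinity,
    quota, note.
    """
    import pandas as pd

    records = []
    for name, vals in rows.items():
        rec = {"functional_type": name}
        rec.update(vals)
        records.append(rec)
    return pd.DataFrame(records)
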