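"""Parameter-perturbation ensemble for the column model.

Uncertainty in the biological parameters is communicated by re-running the
column to equilibrium under randomly drawn parameter sets and summarizing
per-depth mean and standard-deviation envelopes. Nitrifier kinetics are
drawn from the normal distributions of the culture measurements; the
nitrite-oxidizer cell-volume factor is uniform on 1–20 (entering the
kinetics through its cube root); the remaining poorly known rates are drawn
uniformly over ±50% of their defaults.

Each member's draw comes from its own counter-based substream of the master
seed, so the draws are independent of execution order or parallel
scheduling, and the full ensemble is bitwise reproducible given
(seed, n_members, configuration).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .column import EquilibriumSolution
from .config import RunConfig, build_ecosystem_params, run_column
from .constants import UM_TO_MOL_M3
from .ecosystem import EcosystemParams, VAR_NAMES
from .traits import allometric_scaling

__all__ = ["EnsembleSpec", "EnsembleResult", "sample_parameters", "run_ensemble"]


@dataclass(frozen=True)
class EnsembleSpec:
    """Distributions of the perturbation experiment.

    The desk-scale default is 50 members; set n_members ~1000 for the
    full-scale envelope.
    """

    n_members: int = 50
    seed: int = 0
    aoo_vmax_mean: float = 50.82  # mol NH4+ (mol N)^-1 d^-1
    aoo_vmax_sd: float = 4.68
    aoo_k_um_mean: float = 0.133
    aoo_k_um_sd: float = 0.038
    noo_volume_range: tuple[float, float] = (1.0, 20.0)
    #: parameters drawn uniformly over +-50% of the base value
    pm50: tuple[str, ...] = (
        "phyto_mu_max",
        "phyto_k_nox",
        "het_vmax_d",
        "het_k_d",
        "het_y_d",
        "g_max",
        "k_g",
        "m_b",
        "m_z",
        "zeta",
    )

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


def _member_rng(seed: int, member: int) -> np.random.Generator:
    """Independent substream for one member (order-invariant)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(member,))
    )


def _positive_normal(
    rng: np.random.Generator, mean: float, sd: float
) -> tuple[float, int]:
    """Normal draw redrawn while non-positive; returns (value, redraws)."""
    redraws = 0
    x = rng.normal(mean, sd)
    while x <= 0.0:
        redraws += 1
        x = rng.normal(mean, sd)
    return float(x), redraws


def sample_parameters(
    base: EcosystemParams, spec: EnsembleSpec, member: int
) -> tuple[EcosystemParams, dict[str, float]]:
    """One member's parameter set; deterministic given (seed, member).

    Returns the perturbed parameters and a flat record of the draws
    (including the redraw count for invalid candidates).
    """
    rng = _member_rng(spec.seed, member)
    redraws = 0
    vmax, r = _positive_normal(rng, spec.aoo_vmax_mean, spec.aoo_vmax_sd)
    redraws += r
    k_um, r = _positive_normal(rng, spec.aoo_k_um_mean, spec.aoo_k_um_sd)
    redraws += r
    vf = float(rng.uniform(*spec.noo_volume_range))
    u = {name: float(rng.uniform(0.5, 1.5)) for name in spec.pm50}
    # zeta and y_d must stay in (0, 1); +-50% of the defaults always does,
    # but guard (and log) against pathological base values.
    while not 0.0 < u["zeta"] * base.grazing.zeta < 1.0:
        redraws += 1
        u["zeta"] = float(rng.uniform(0.5, 1.5))
    while not 0.0 < u["het_y_d"] * base.het.y_d < 1.0:
        redraws += 1
        u["het_y_d"] = float(rng.uniform(0.5, 1.5))

    scale = allometric_scaling(vf)
    aoo = dataclasses.replace(
        base.aoo, vmax=vmax, k=k_um * UM_TO_MOL_M3
    )
    noo = dataclasses.replace(
        base.noo,
        vmax=vmax * scale["vmax_factor"],
        k=k_um * UM_TO_MOL_M3 * scale["k_factor"],
    )
    k_nox = base.phyto.k_no3 * u["phyto_k_nox"]
    phyto = dataclasses.replace(
        base.phyto,
        mu_max=base.phyto.mu_max * u["phyto_mu_max"],
        k_no2=k_nox,
        k_no3=k_nox,
        k_nh4=0.5 * k_nox,
    )
    het = dataclasses.replace(
        base.het,
        vmax_d=base.het.vmax_d * u["het_vmax_d"],
        k_d=base.het.k_d * u["het_k_d"],
        y_d=base.het.y_d * u["het_y_d"],
    )
    grazing = dataclasses.replace(
        base.grazing,
        g_max=base.grazing.g_max * u["g_max"],
        k_g=base.grazing.k_g * u["k_g"],
        zeta=base.grazing.zeta * u["zeta"],
        m_z=base.grazing.m_z * u["m_z"],
    )
    params = base.replace(
        aoo=aoo,
        noo=noo,
        phyto=phyto,
        het=het,
        grazing=grazing,
        m_b=base.m_b * u["m_b"],
    )
    record = {
        "member": member,
        "aoo_vmax": vmax,
        "aoo_k_um": k_um,
        "noo_volume_factor": vf,
        **{f"u_{k}": v for k, v in u.items()},
        "redraws": redraws,
    }
    return params, record


@dataclass
class EnsembleResult:
    """Per-member profiles and the converged-member envelope."""

    spec: EnsembleSpec
    depth: np.ndarray
    profiles: np.ndarray  # (n_members, 9, nz)
    converged: np.ndarray  # (n_members,) bool
    manifest: pd.DataFrame
    solutions: list[EquilibriumSolution] = field(default_factory=list)

    @property
    def n_converged(self) -> int:
        return int(self.converged.sum())

    def envelope(self) -> dict[str, np.ndarray]:
        """Per-depth mean and s.d. over converged members, per variable."""
        sel = self.profiles[self.converged]
        if sel.shape[0] == 0:
            raise ValueError("no converged members")
        return {
            "mean": sel.mean(axis=0),
            "sd": sel.std(axis=0, ddof=0),
            "variables": VAR_NAMES,
        }


def run_ensemble(
    spec: EnsembleSpec,
    config: RunConfig,
    keep_solutions: bool = False,
) -> EnsembleResult:
    """Run the full perturbation ensemble on one column configuration.

    Members are independent: the result is identical regardless of the
    order they are executed in. Non-converged members are flagged in the
    manifest and excluded from the envelope.
    """
    base = build_ecosystem_params(config.ecosystem, config.experiment)
    nz = config.grid.nz
    profiles = np.zeros((spec.n_members, len(VAR_NAMES), nz))
    converged = np.zeros(spec.n_members, dtype=bool)
    records = []
    solutions: list[EquilibriumSolution] = []
    for m in range(spec.n_members):
        params, record = sample_parameters(base, spec, m)
        sol = run_column(config, params=params)
        profiles[m] = sol.state
        converged[m] = sol.converged
        record["converged"] = bool(sol.converged)
        records.append(record)
        if keep_solutions:
            solutions.append(sol)
    manifest = pd.DataFrame(records)
    manifest.insert(1, "seed", spec.seed)
    return EnsembleResult(
        spec=spec,
        depth=config.grid.z_centers,
        profiles=profiles,
        converged=converged,
        manifest=manifest,
        solutions=solutions,
    )
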