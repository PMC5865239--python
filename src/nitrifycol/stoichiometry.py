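"""Electron-balanced whole-organism stoichiometries for marine nitrifiers.

Ammonia-oxidizing (AOO) and nitrite-oxidizing (NOO) chemoautotrophs gain
energy by oxidizing reduced dissolved inorganic nitrogen (DIN) with oxygen,
and fix CO2 into biomass. Each full metabolism is the sum of three redox
half-reactions — DIN oxidation (electron donor), O2 reduction (acceptor),
and biomass synthesis — weighted by the electron partition fraction ``f``:
the fraction of donor electrons routed to synthesis rather than respiration.

Normalizing the summed reaction to 1 mol biomass nitrogen yields, for
ammonia oxidation::

    (1 + d/(6f)) NH4+ + (1-f)d/(4f) O2 + (c/n) CO2 -> B + d/(6f) NO2-

and for nitrite oxidation::

    d/(2f) NO2- + 1 NH4+ + (1-f)d/(4f) O2 + (c/n) CO2 -> B + d/(2f) NO3-

where ``d = 4c + h - 2o - 3n`` is the number of electron equivalents of
generic biomass C_c H_h O_o N_n (d = 20 for the canonical C5H7O2N), and the
NOO assimilates its 1 mol of cell nitrogen from ammonium. Water, protons
and bicarbonate are not tracked; N2O formation is neglected.

With f = 0.03 and d = 20 the ammonia-oxidizer reaction rounds to
112 NH4+ + 162 O2 -> B + 111 NO2-, i.e. a yield of ~1/112 mol biomass N per
mol NH4+, roughly three times the nitrite-oxidizer yield of 2f/d = 1/333.
That factor of three in DIN demand is the energetic half of the explanation
for why nitrite accumulates above ammonium at the primary nitrite maximum.
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "BiomassComposition",
    "ElectronPartition",
    "MetabolismKind",
    "WholeOrganismStoichiometry",
    "electron_equivalents",
    "nitrifier_yield",
    "infer_f",
    "whole_organism_reaction",
    "propagate_coefficient_uncertainty",
    "format_reaction",
    "reaction_table",
    "read_culture_yields",
    "infer_f_table",
]


class MetabolismKind(enum.Enum):
    """The two chemoautotrophic nitrification steps resolved here."""

    AMMONIA_OXIDATION = "ammonia_oxidation"
    NITRITE_OXIDATION = "nitrite_oxidation"


@dataclass(frozen=True)
class BiomassComposition:
    """Generic biomass elemental composition C_c H_h O_o N_n.

    The default C5H7O2N is the standard composition for microbial biomass,
    giving a C:N of 5 and d = 20 electron equivalents.
    """

    c: int = 5
    h: int = 7
    o: int = 2
    n: int = 1

    def __post_init__(self) -> None:
        if min(self.c, self.h, self.o) < 0 or self.n < 1:
            raise ValueError("atom counts must be non-negative with n >= 1")
        if self.d <= 0:
            raise ValueError(
                f"composition C{self.c}H{self.h}O{self.o}N{self.n} has "
                f"non-positive electron equivalents d={self.d}"
            )

    @property
    def d(self) -> int:
        """Electron equivalents 4c + h - 2o - 3n."""
        return 4 * self.c + self.h - 2 * self.o - 3 * self.n

    @property
    def cn_ratio(self) -> float:
        """mol C per mol N."""
        return self.c / self.n


@dataclass(frozen=True)
class ElectronPartition:
    """Fraction f of donor electrons channeled to biomass synthesis."""

    f: float = 0.03
    f_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"f must lie in (0, 1), got {self.f}")
        if self.f_sd < 0.0:
            raise ValueError("f_sd must be non-negative")


@dataclass
class WholeOrganismStoichiometry:
    """Reaction coefficients per 1 mol biomass N produced.

    All coefficients are exact reals; integer presentation happens only in
    :func:`format_reaction` (half-up rounding). ``sd`` holds per-coefficient
    standard deviations once :func:`propagate_coefficient_uncertainty` has
    been applied.
    """

    kind: MetabolismKind
    nh4_consumed: float
    no2_consumed: float
    no2_produced: float
    no3_produced: float
    o2_consumed: float
    co2_consumed: float
    yield_y: float
    composition: BiomassComposition
    f: float
    sd: dict[str, float] = field(default_factory=dict)

    @property
    def limiting_din_coefficient(self) -> float:
        """Coefficient of the energy-yielding (limiting) DIN species."""
        if self.kind is MetabolismKind.AMMONIA_OXIDATION:
            return self.nh4_consumed
        return self.no2_consumed

    def nitrogen_balance(self) -> float:
        """Consumed N minus (biomass N + produced N); zero by construction."""
        return (self.nh4_consumed + self.no2_consumed) - (
            1.0 + self.no2_produced + self.no3_produced
        )


def electron_equivalents(comp: BiomassComposition) -> int:
    """Electron equivalents d = 4c + h - 2o - 3n of a biomass formula."""
    return comp.d


def nitrifier_yield(
    kind: MetabolismKind, f: float | ElectronPartition, d: int
) -> float:
    """Yield y (mol biomass N per mol limiting DIN) of a nitrifier metabolism.

    Ammonia oxidation: y = 1 / (1 + d/(6f)); nitrite oxidation: y = 2f/d.
    """
    fv = f.f if isinstance(f, ElectronPartition) else float(f)
    if not 0.0 <= fv < 1.0:
        raise ValueError(f"f must lie in [0, 1), got {fv}")
    if d <= 0:
        raise ValueError("d must be positive")
    if kind is MetabolismKind.AMMONIA_OXIDATION:
        if fv == 0.0:
            return 0.0
        return 1.0 / (1.0 + d / (6.0 * fv))
    return 2.0 * fv / d


def infer_f(observed_yield: float, kind: MetabolismKind, d: int) -> float:
    """Invert the yield formula: electron fraction f from an observed yield.

    Exact algebraic inverse of :func:`nitrifier_yield`; round-trips to
    machine precision.
    """
    y = float(observed_yield)
    if d <= 0:
        raise ValueError("d must be positive")
    if kind is MetabolismKind.AMMONIA_OXIDATION:
        if not 0.0 < y < 1.0:
            raise ValueError(
                f"ammonia-oxidizer yield must lie in (0, 1), got {y}"
            )
        return d * y / (6.0 * (1.0 - y))
    if y <= 0.0:
        raise ValueError("yield must be positive")
    return y * d / 2.0


def whole_organism_reaction(
    kind: MetabolismKind,
    f: float | ElectronPartition = 0.03,
    comp: BiomassComposition | None = None,
) -> WholeOrganismStoichiometry:
    """Sum the three half-reactions and normalize to 1 mol biomass N."""
    if comp is None:
        comp = BiomassComposition()
    part = f if isinstance(f, ElectronPartition) else ElectronPartition(f=f)
    fv = part.f
    d = comp.d
    o2 = (1.0 - fv) * d / (4.0 * fv)
    co2 = comp.cn_ratio
    if kind is MetabolismKind.AMMONIA_OXIDATION:
        no2_prod = d / (6.0 * fv)
        return WholeOrganismStoichiometry(
            kind=kind,
            nh4_consumed=1.0 + no2_prod,
            no2_consumed=0.0,
            no2_produced=no2_prod,
            no3_produced=0.0,
            o2_consumed=o2,
            co2_consumed=co2,
            yield_y=1.0 / (1.0 + no2_prod),
            composition=comp,
            f=fv,
        )
    no2 = d / (2.0 * fv)
    return WholeOrganismStoichiometry(
        kind=kind,
        nh4_consumed=1.0,
        no2_consumed=no2,
        no2_produced=0.0,
        no3_produced=no2,
        o2_consumed=o2,
        co2_consumed=co2,
        yield_y=1.0 / no2,
        composition=comp,
        f=fv,
    )


#: Default s.d. of d implied by a 1 mol/mol s.d. on C:N with only the carbon
#: count varying (d = 4c + h - 2o - 3n, so sd(d) = 4*sd(c)).
DEFAULT_D_SD = 4.0


def propagate_coefficient_uncertainty(
    reaction: WholeOrganismStoichiometry, d_sd: float = DEFAULT_D_SD
) -> dict[str, float]:
    """Linear uncertainty propagation through d at fixed f.

    sd(coefficient) = |d coefficient / d d| * d_sd. The CO2 coefficient is
    c/n with c = (d - h + 2o + 3n)/4, hence its derivative is 1/(4n). The
    result is stored on ``reaction.sd`` and returned.
    """
    if d_sd < 0.0:
        raise ValueError("d_sd must be non-negative")
    fv = reaction.f
    comp = reaction.composition
    d = comp.d
    sd: dict[str, float] = {}
    if reaction.kind is MetabolismKind.AMMONIA_OXIDATION:
        sd["nh4_consumed"] = d_sd / (6.0 * fv)
        sd["no2_produced"] = d_sd / (6.0 * fv)
        sd["no2_consumed"] = 0.0
        sd["no3_produced"] = 0.0
        # y = (1 + d/(6f))^-1, dy/dd = -y^2/(6f)
        sd["yield_y"] = reaction.yield_y**2 / (6.0 * fv) * d_sd
    else:
        sd["no2_consumed"] = d_sd / (2.0 * fv)
        sd["no3_produced"] = d_sd / (2.0 * fv)
        sd["nh4_consumed"] = 0.0
        sd["no2_produced"] = 0.0
        # y = 2f/d, dy/dd = -2f/d^2
        sd["yield_y"] = 2.0 * fv / d**2 * d_sd
    sd["o2_consumed"] = (1.0 - fv) / (4.0 * fv) * d_sd
    sd["co2_consumed"] = d_sd / (4.0 * comp.n)
    reaction.sd = sd
    return sd


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def format_reaction(
    reaction: WholeOrganismStoichiometry, rounded: bool = True
) -> str:
    """Plain-text rendering of a whole-organism reaction.

    With ``rounded`` the coefficients are presented as half-up-rounded
    integers (the conventional presentation); otherwise one decimal place.
    Uncertainties are shown when present.
    """

    def fmt(name: str, value: float) -> str:
        body = (
            f"{_round_half_up(value)}" if rounded else f"{value:.1f}"
        )
        if reaction.sd:
            s = reaction.sd.get(name, 0.0)
            su = f"{_round_half_up(s)}" if rounded else f"{s:.1f}"
            return f"({body} ± {su})"
        return body

    label = (
        "B_AOO"
        if reaction.kind is MetabolismKind.AMMONIA_OXIDATION
        else "B_NOO"
    )
    lhs = []
    if reaction.kind is MetabolismKind.AMMONIA_OXIDATION:
        lhs.append(f"{fmt('nh4_consumed', reaction.nh4_consumed)} NH4+")
    else:
        lhs.append(f"{fmt('no2_consumed', reaction.no2_consumed)} NO2-")
        lhs.append("1 NH4+")
    lhs.append(f"{fmt('o2_consumed', reaction.o2_consumed)} O2")
    lhs.append(f"{fmt('co2_consumed', reaction.co2_consumed)} CO2")
    rhs = [label]
    if reaction.no2_produced > 0:
        rhs.append(f"{fmt('no2_produced', reaction.no2_produced)} NO2-")
    if reaction.no3_produced > 0:
        rhs.append(f"{fmt('no3_produced', reaction.no3_produced)} NO3-")
    return " + ".join(lhs) + " -> " + " + ".join(rhs)


def reaction_table(
    reaction: WholeOrganismStoichiometry,
) -> pd.DataFrame:
    """One-row-per-coefficient table (exact value, sd, rounded value)."""
    rows = []
    for name in (
        "nh4_consumed",
        "no2_consumed",
        "no2_produced",
        "no3_produced",
        "o2_consumed",
        "co2_consumed",
        "yield_y",
    ):
        value = getattr(reaction, name)
        rows.append(
            {
                "coefficient": name,
                "value": value,
                "sd": reaction.sd.get(name, float("nan")),
                "rounded": _round_half_up(value),
            }
        )
    return pd.DataFrame(rows)


_CULTURE_COLUMNS = ["organism", "metabolism", "yield_value", "yield_sd"]


def read_culture_yields(path_or_buf: str | io.IOBase) -> pd.DataFrame:
    """Read a culture-yield CSV (organism, metabolism, yield_value, yield_sd).

    ``metabolism`` must be ``ammonia_oxidation`` or ``nitrite_oxidation``.
    """
    df = pd.read_csv(path_or_buf)
    missing = [c for c in _CULTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"culture-yield CSV missing columns: {missing}")
    kinds = {k.value for k in MetabolismKind}
    bad = set(df["metabolism"]) - kinds
    if bad:
        raise ValueError(f"unknown metabolism labels: {sorted(bad)}")
    return df[_CULTURE_COLUMNS]


def infer_f_table(
    yields: pd.DataFrame, comp: BiomassComposition | None = None
) -> pd.DataFrame:
    """Batch f-inference over a culture-yield table.

    Returns the input table with an ``f`` column appended (the electron
    fraction implied by each observed yield at the given biomass d).
    """
    if comp is None:
        comp = BiomassComposition()
    out = yields.copy()
    out["f"] = [
        infer_f(y, MetabolismKind(m), comp.d)
        for y, m in zip(out["yield_value"], out["metabolism"])
    ]
    return out
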