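"""Growth laws, uptake partitioning and the conservation structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitrifycol.config import EcosystemConfig, build_ecosystem_params
from nitrifycol.ecosystem import (
    VAR_NAMES,
    CellStateVector,
    LocalEnvironment,
    TemperatureParams,
    biological_fluxes,
    biological_tendencies,
    din_uptake_rates,
    gamma_n,
    grazing_rate,
    het_growth,
    monod_growth,
    phyto_growth,
    temperature_factor,
)


@pytest.fixture(scope="module")
def params():
    return build_ecosystem_params(EcosystemConfig())


class TestTemperatureFactor:
    def test_reference_temperature_gives_tau(self):
        tp = TemperatureParams(tau=0.8, a_e=-4000.0, t0=293.15)
        assert temperature_factor(20.0, tp) == pytest.approx(0.8)

    def test_zero_activation_energy_is_flat(self):
        tp = TemperatureParams(tau=0.8, a_e=0.0, t0=293.15)
        for t in (0.0, 10.0, 30.0):
            assert temperature_factor(t, tp) == pytest.approx(0.8)

    def test_monotone_increasing_for_negative_a_e(self):
        """d(gamma)/dT > 0 requires a_e < 0 in the printed Arrhenius form."""
        tp = TemperatureParams()
        temps = np.linspace(0.0, 30.0, 20)
        vals = temperature_factor(temps, tp)
        assert np.all(np.diff(vals) > 0)

    def test_nitrifiers_exempt(self, params):
        assert temperature_factor(5.0, params, nitrifier=True) == 1.0
        no_exempt = params.replace(nitrifier_temperature_exempt=False)
        assert temperature_factor(5.0, no_exempt, nitrifier=True) != 1.0


class TestMonodGrowth:
    def test_half_saturation(self):
        assert monod_growth(0.2, 10.0, 0.2, 0.1) == pytest.approx(0.5)

    def test_saturation_limit(self):
        assert monod_growth(1e9, 10.0, 0.2, 0.1) == pytest.approx(1.0, rel=1e-6)

    def test_aoo_growth_at_culture_half_saturation(self, params):
        """At R = K the ammonia oxidizer grows at half its maximum rate."""
        mu = monod_growth(
            params.aoo.k, params.aoo.vmax, params.aoo.k, params.aoo.yield_y
        )
        assert mu == pytest.approx(0.5 * 50.82 / 112.111, rel=1e-3)

    def test_liebig_minimum_over_resources(self):
        mu = monod_growth([1.0, 0.1], 10.0, [1.0, 1.0], 0.1)
        assert mu == pytest.approx(1.0 * 0.1 / 1.1)
        with pytest.raises(ValueError):
            monod_growth([1.0, 0.1], 10.0, 1.0, 0.1)


class TestGammaN:
    def test_limits(self, params):
        phyto = params.phyto
        assert gamma_n(0.0, 0.0, 0.0, phyto) == 0.0
        assert gamma_n(phyto.k_nh4, 0.0, 0.0, phyto) == pytest.approx(0.5)
        assert gamma_n(
            phyto.k_nh4, phyto.k_no2, phyto.k_no3, phyto
        ) == pytest.approx(1.5)


class TestPhytoGrowth:
    def test_dark_growth_is_zero(self, params):
        env = LocalEnvironment(irradiance=0.0, temperature=20.0)
        out = phyto_growth(env, 1e-3, 1e-3, 1e-3, params)
        assert out["mu_p"] == 0.0
        assert out["theta"] == params.phyto.theta_max

    def test_saturates_at_photoacclimation_cap(self, params):
        """Under bright light theta relaxes to 2 mu_net / Gamma, so growth
        saturates at (1 - e^-2) of the nutrient-temperature cap."""
        env = LocalEnvironment(irradiance=1e5, temperature=20.0)
        out = phyto_growth(env, 1.0, 1.0, 1.0, params)
        gn = gamma_n(1.0, 1.0, 1.0, params.phyto)
        gt = temperature_factor(20.0, params.temperature)
        mu_net = params.phyto.mu_max * gn * gt
        assert out["mu_p"] == pytest.approx(
            mu_net * (1.0 - np.exp(-2.0)), rel=1e-2
        )
        assert out["mu_p"] < mu_net

    def test_light_limited_linear_regime(self, params):
        """For weak light, growth is linear in Gamma * theta."""
        from nitrifycol.ecosystem import photosynthetic_rate

        env = LocalEnvironment(irradiance=1e-4, temperature=20.0)
        out = phyto_growth(env, 1.0, 1.0, 1.0, params)
        gamma = photosynthetic_rate(env.irradiance, params.phyto)
        assert out["mu_p"] == pytest.approx(gamma * out["theta"], rel=1e-3)

    def test_zero_nutrients_means_zero_growth(self, params):
        env = LocalEnvironment(irradiance=700.0, temperature=20.0)
        assert phyto_growth(env, 0.0, 0.0, 0.0, params)["mu_p"] == 0.0


class TestUptakePartition:
    def test_single_source_gets_everything(self, params):
        v = din_uptake_rates(1.0, 1e-3, 0.0, 0.0, params)
        assert v["v_nh4"] == pytest.approx(1.0)
        assert v["v_no2"] == 0.0 and v["v_no3"] == 0.0

    def test_symmetric_split_at_half_saturations(self, params):
        phyto = params.phyto
        v = din_uptake_rates(1.0, phyto.k_nh4, 0.0, phyto.k_no3, params)
        assert v["v_nh4"] == pytest.approx(v["v_no3"])

    @given(
        nh4=st.floats(0.0, 1e-2),
        no2=st.floats(0.0, 1e-2),
        no3=st.floats(0.0, 1e-2),
        mu=st.floats(0.0, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_partition_sums_to_growth(self, nh4, no2, no3, mu):
        params = build_ecosystem_params(EcosystemConfig())
        v = din_uptake_rates(mu, nh4, no2, no3, params)
        total = v["v_nh4"] + v["v_no2"] + v["v_no3"]
        if nh4 == no2 == no3 == 0.0:
            assert total == 0.0
        else:
            assert total == pytest.approx(mu, rel=1e-9, abs=1e-12)


def test_het_growth_limits(params):
    assert het_growth(0.0, params) == 0.0
    half = het_growth(params.het.k_d, params, gamma_t=1.0)
    assert half == pytest.approx(0.5 * params.het.y_d * params.het.vmax_d)
    # saturated growth is of order 0.1 per day
    sat = het_growth(1.0, params, gamma_t=params.temperature.tau)
    assert 0.05 < sat < 0.2


def test_grazing_rate_forms(params):
    gp = params.grazing
    state = CellStateVector(p=gp.k_g, z=1e-4)
    assert grazing_rate(state, params, 1.0) == pytest.approx(
        gp.g_max / (2 * gp.k_g)
    )
    empty = CellStateVector(z=1e-4)
    assert grazing_rate(empty, params, 1.0) == pytest.approx(gp.g_max / gp.k_g)


class TestTendencies:
    def test_nitrogen_conservation_on_random_states(self, params):
        """The nine tendencies sum to zero at every point, to roundoff."""
        rng = np.random.default_rng(7)
        state = CellStateVector.from_array(rng.uniform(0.0, 1e-2, (9, 1000)))
        env = LocalEnvironment(
            irradiance=rng.uniform(0, 1000, 1000),
            temperature=rng.uniform(0, 30, 1000),
        )
        tend = biological_tendencies(state, env, params).to_array()
        scale = np.abs(tend).max()
        assert np.abs(tend.sum(axis=0)).max() < 1e-12 * scale

    def test_flux_ledger_coefficients_balance(self, params):
        """Every declared flux moves N between pools with zero net creation."""
        state = CellStateVector.from_array(
            np.full((9,), 1e-4)
        )
        env = LocalEnvironment(irradiance=100.0, temperature=15.0)
        fluxes = biological_fluxes(state, env, params)
        assert len(fluxes) >= 12
        for flux in fluxes:
            assert sum(flux.moves.values()) == pytest.approx(0.0, abs=1e-12)
            assert all(v in VAR_NAMES for v in flux.moves)

    def test_inert_without_organisms(self, params):
        state = CellStateVector(nh4=1e-3, no2=1e-3, no3=1e-3, det=1e-3)
        env = LocalEnvironment(irradiance=500.0, temperature=20.0)
        tend = biological_tendencies(state, env, params).to_array()
        assert np.all(tend == 0.0)

    def test_identical_nitrifiers_differ_only_by_assimilation(self, params):
        """With shared traits, AOO and NOO tendencies differ only through the
        nitrite oxidizer's 1 mol NH4+ assimilation per mol biomass N."""
        twin = params.replace(noo=params.aoo)
        state = CellStateVector(
            nh4=2e-4, no2=2e-4, no3=0.0, det=0.0, b_aoo=1e-4, b_noo=1e-4
        )
        env = LocalEnvironment(irradiance=0.0, temperature=10.0)
        tend = biological_tendencies(state, env, twin)
        mu = monod_growth(2e-4, twin.aoo.vmax, twin.aoo.k, twin.aoo.yield_y)
        assert tend.b_aoo == pytest.approx(tend.b_noo, rel=1e-12)
        # NO3 produced by NOO equals NO2 produced by AOO minus nothing else;
        # the NH4 budget carries the extra mu*B assimilation sink.
        fluxes = {f.name: f for f in biological_fluxes(state, env, twin)}
        assert fluxes["noo_growth"].moves["nh4"] == -1.0
        assert "nh4" not in {
            k for k, v in fluxes["aoo_growth"].moves.items() if k == "nh4" and v == -1.0
        } or fluxes["aoo_growth"].moves["nh4"] != -1.0

    def test_hand_computed_point_state(self, params):
        """Term-by-term tally at a uniform 0.1 uM-N state, dark and cold.

        Expected values assembled independently from the rate definitions
        (growth, grazing, mortality) with a hand calculator.
        """
        c = 0.1e-3  # 0.1 uM-N in mol m^-3
        state = CellStateVector(**{name: c for name in VAR_NAMES})
        env = LocalEnvironment(irradiance=0.0, temperature=2.0)
        gt = temperature_factor(2.0, params.temperature)
        tend = biological_tendencies(state, env, params)

        mu_a = params.aoo.yield_y * params.aoo.vmax * c / (c + params.aoo.k)
        mu_n = params.noo.yield_y * params.noo.vmax * c / (c + params.noo.k)
        mu_h = (
            params.het.y_d * params.het.vmax_d * c / (c + params.het.k_d) * gt
        )
        g = params.grazing.g_max / (4 * c + params.grazing.k_g) * gt
        loss = params.m_b + g * c
        assert tend.b_aoo == pytest.approx((mu_a - loss) * c, rel=1e-12)
        assert tend.b_noo == pytest.approx((mu_n - loss) * c, rel=1e-12)
        assert tend.b_het == pytest.approx((mu_h - loss) * c, rel=1e-12)
        assert tend.p == pytest.approx(-loss * c, rel=1e-12)  # dark
        assert tend.z == pytest.approx(
            params.grazing.zeta * g * c * 4 * c
            - params.grazing.m_z * c**2 * gt,
            rel=1e-12,
        )
        assert tend.no3 == pytest.approx(mu_n * c / params.noo.yield_y, rel=1e-12)
        exp_no2 = (
            (1 / params.aoo.yield_y - 1) * mu_a * c
            - mu_n * c / params.noo.yield_y
        )
        assert tend.no2 == pytest.approx(exp_no2, rel=1e-12)


def test_optional_oxygen_limitation_hook(params):
    """With a fixed low-O2 profile supplied, nitrifier growth takes the
    Liebig minimum of the DIN and O2 saturation terms."""
    from nitrifycol.ecosystem import O2Limitation

    state = CellStateVector(nh4=1.0, b_aoo=1e-4)  # DIN-replete
    env = LocalEnvironment(irradiance=0.0, temperature=10.0)
    free = biological_tendencies(state, env, params)
    limited_params = params.replace(
        o2_limitation=O2Limitation(o2=0.333e-3)  # O2 at the AOO half-saturation
    )
    limited = biological_tendencies(state, env, limited_params)
    assert limited.b_aoo < free.b_aoo
    # back out the growth rates (tendency = (mu - m_b) * B with no grazers)
    mu_free = free.b_aoo / 1e-4 + params.m_b
    mu_lim = limited.b_aoo / 1e-4 + params.m_b
    assert mu_lim == pytest.approx(0.5 * mu_free, rel=0.01)
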