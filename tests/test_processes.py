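import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chlorolake.params import LakeConfig, ParameterSet, SpeciesSpec
from chlorolake.processes import (
    ForcingSample,
    LakeState,
    benthos_grazing,
    compute_rates,
    detritus_balance,
    mortality,
    phosphorus_diffusion,
    phytoplankton_settling,
    producer_growth,
    respiration,
    state_derivative,
    zooplankton_grazing,
)

from reference_model import params_as_dicts, reference_derivative


def _single_producer_set(**overrides) -> ParameterSet:
    defaults = dict(species_id="p", name="producer", guild="phytoplankton",
                    maxg=0.5, maxm=0.1, maxr=0.05, ip=1e-12, ik=1e-12, tk=1.1,
                    sk=0.0, smk=0.0, kcc=0.01, ser=0.0)
    defaults.update(overrides)
    return ParameterSet(species=[SpeciesSpec(**defaults)], lake=LakeConfig(),
                        diet_matrix={})


class TestProducerGrowth:
    def test_saturating_limit_is_maxg_times_biom(self, default_ps):
        s = default_ps.get("b")
        lake = default_ps.lake
        spec = SpeciesSpec(**{**vars(s), "sk": 0.0, "smk": 0.0})
        rate = producer_growth(spec, 2.0, 1e12, 20.0, 1e12, 100.0, lake)
        assert rate == pytest.approx(spec.maxg * 2.0, rel=1e-9)

    def test_term_by_term_scalar_oracle(self, default_ps):
        b = default_ps.get("b")
        # biom=1, pw=1, ip=1 -> P factor 0.5; sr=ik -> light factor 0.5
        spec = SpeciesSpec(**{**vars(b), "ip": 1.0, "sk": 0.06, "smk": 0.0038})
        rate = producer_growth(spec, 1.0, 1.0, 25.0, spec.ik, 100.0, default_ps.lake)
        expected = (1.3 * 1.0 * 0.5 * 1.1 ** 5 * 0.5
                    * math.exp(-0.06 * 1.0) * math.exp(-0.0038 * 100.0))
        assert rate == pytest.approx(expected, rel=1e-12)

    def test_macrophyte_not_self_shaded(self, default_ps):
        a = default_ps.get("a")
        spec = SpeciesSpec(**{**vars(a), "smk": 0.5})
        with_canopy = producer_growth(spec, 1.0, 1.0, 20.0, 10.0, 500.0, default_ps.lake)
        without = producer_growth(spec, 1.0, 1.0, 20.0, 10.0, 0.0, default_ps.lake)
        assert with_canopy == without

    def test_degenerate_zero_over_zero(self, default_ps):
        spec = SpeciesSpec(species_id="x", name="x", guild="periphyton",
                           maxg=1.0, ip=0.0, ik=0.0, tk=1.1)
        assert producer_growth(spec, 1.0, 0.0, 20.0, 0.0, 0.0, default_ps.lake) == 0.0

    def test_crowding_optimum_at_inverse_sk(self, default_ps):
        """Growth as a function of density alone peaks at Biom = 1/sk."""
        spec = SpeciesSpec(species_id="x", name="x", guild="phytoplankton",
                           maxg=1.0, ip=1e-12, ik=1e-12, tk=1.1, sk=0.2, ser=0.0)
        grid = np.linspace(0.1, 20, 4000)
        rates = [producer_growth(spec, b, 1.0, 20.0, 1.0, 0.0, default_ps.lake)
                 for b in grid]
        assert grid[int(np.argmax(rates))] == pytest.approx(1 / 0.2, abs=0.01)


class TestMortality:
    def test_neutral_conditions(self, default_ps):
        s = default_ps.get("b")
        assert mortality(s, 3.0, 20.0, 0.0) == pytest.approx(3.0 * s.maxm)

    def test_chlorine_factor_scalar_oracle(self, default_ps):
        s = default_ps.get("b")  # kcc=0.001, M=1000
        base = mortality(s, 1.0, 20.0, 0.0)
        dosed = mortality(s, 1.0, 20.0, 0.188)
        assert dosed / base == pytest.approx(math.exp(0.188), rel=1e-12)

    def test_benthos_uses_100x_multiplier(self, default_ps):
        s = default_ps.get("l")
        spec = SpeciesSpec(**{**vars(s), "kcc": 0.1})
        assert (mortality(spec, 1.0, 20.0, 0.01) / mortality(spec, 1.0, 20.0, 0.0)
                == pytest.approx(math.exp(0.1 * 0.01 * 100), rel=1e-12))

    @given(cc=st.floats(0, 0.01), kcc=st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_chlorine_factor_at_least_one_and_monotone(self, cc, kcc):
        spec = SpeciesSpec(species_id="x", name="x", guild="zooplankton",
                           maxm=0.1, tk=1.05, kcc=kcc, ae=0.3, ib=1.0, rf=0.1, kpz=1.0)
        base = mortality(spec, 1.0, 20.0, 0.0)
        assert mortality(spec, 1.0, 20.0, cc) >= base
        assert mortality(spec, 1.0, 20.0, cc * 2) >= mortality(spec, 1.0, 20.0, cc)


class TestRespirationAndSettling:
    def test_reference_temperature(self, default_ps):
        s = default_ps.get("f")
        assert respiration(s, 2.0, 20.0) == pytest.approx(2.0 * s.maxr)

    def test_q10_style_scaling(self, default_ps):
        s = default_ps.get("f")  # tk = 1.1
        assert (respiration(s, 1.0, 30.0) / respiration(s, 1.0, 20.0)
                == pytest.approx(1.1 ** 10, rel=1e-12))

    def test_zero_biomass(self, default_ps):
        assert respiration(default_ps.get("f"), 0.0, 35.0) == 0.0

    def test_settling_reference_case(self):
        spec = SpeciesSpec(species_id="x", name="x", guild="phytoplankton", ser=0.019)
        lake = LakeConfig(depth=1.0)
        assert phytoplankton_settling(spec, 3.0, 20.0, lake) == pytest.approx(0.019 * 3.0)

    def test_settling_linear_in_temperature(self):
        spec = SpeciesSpec(species_id="x", name="x", guild="phytoplankton", ser=0.019)
        lake = LakeConfig(depth=0.8)
        assert (phytoplankton_settling(spec, 5.0, 10.0, lake)
                == pytest.approx(phytoplankton_settling(spec, 5.0, 20.0, lake) / 2))
        assert (phytoplankton_settling(spec, 5.0, 28.0, lake)
                == pytest.approx(0.019 / 0.8 * 28 / 20 * 5, rel=1e-12))


class TestGrazing:
    def _zoo(self, **kw):
        base = dict(species_id="z", name="z", guild="zooplankton", maxm=0.1,
                    tk=1.05, sk=0.0001, ae=0.3, ib=1.45, rf=0.07, kpz=1.0)
        base.update(kw)
        return SpeciesSpec(**base)

    def test_refuge_threshold_and_floor(self):
        z = self._zoo()
        assert zooplankton_grazing(z, 1.0, 0.5, 20.0) == 0.0
        assert zooplankton_grazing(z, 1.0, 0.2, 20.0) == 0.0

    def test_term_by_term_oracle(self):
        z = self._zoo()
        rate = zooplankton_grazing(z, 1.0, 10.0, 20.0)
        expected = (1.0 * 0.3 * 1.45 * (1 - 0.07) * (10 - 0.5) / (10 + 1.0)
                    * math.exp(-0.0001 * 1.0))
        assert rate == pytest.approx(expected, rel=1e-12)

    def test_benthos_grazing_linear_in_detritus(self, default_ps):
        ben = default_ps.get("l")
        assert benthos_grazing(ben, 5.0, 0.0, 25.0) == 0.0
        r1 = benthos_grazing(ben, 5.0, 10.0, 25.0)
        assert benthos_grazing(ben, 5.0, 20.0, 25.0) == pytest.approx(2 * r1, rel=1e-12)

    def test_benthos_grazing_scalar_oracle(self):
        ben = SpeciesSpec(species_id="x", name="x", guild="benthos",
                          ae=0.023, ib=0.001, tk=1.05)
        rate = benthos_grazing(ben, 10.0, 50.0, 25.0)
        assert rate == pytest.approx(0.023 * 0.001 * 1.05 ** 5 * 10 * 50, rel=1e-12)


class TestPoolBalances:
    def test_all_zero_state(self, default_ps):
        state = LakeState(biom=np.zeros(14))
        rates = compute_rates(state, ForcingSample(20.0, 10.0), default_ps)
        assert detritus_balance(state, rates, default_ps) == 0.0

    def test_abiotic_detritus_decay_hand_value(self):
        """det=100, dr=0.01, serd=0.019, d=1, T=20: d(det)/dt = -2.9."""
        lake = LakeConfig(depth=1.0, detritus_decomposition_rate=0.01,
                          detritus_settling_rate=0.019)
        ps_set = ParameterSet(species=[], lake=lake, diet_matrix={})
        state = LakeState(biom=np.zeros(0), det=100.0)
        rates = compute_rates(state, ForcingSample(20.0, 10.0), ps_set)
        assert detritus_balance(state, rates, ps_set) == pytest.approx(-2.9, rel=1e-12)

    def test_detritus_gain_equals_non_benthos_mortality(self, default_ps, rng):
        state = LakeState(biom=rng.uniform(0.1, 10, 14), det=0.0, pw=0.5, ps=1.0)
        f = ForcingSample(24.0, 12.0, cc=0.001)
        rates = compute_rates(state, f, default_ps)
        expected = sum(
            mortality(s, state.biom[i], 24.0, 0.001)
            for i, s in enumerate(default_ps.species) if s.guild != "benthos")
        # det = 0, so settling/grazing/decomposition vanish
        assert detritus_balance(state, rates, default_ps) == pytest.approx(
            expected, rel=1e-12)

    def test_diffusion_zero_at_equilibrium(self):
        lake = LakeConfig()
        assert phosphorus_diffusion(0.7, 0.7, lake) == 0.0

    def test_diffusion_scalar_oracle(self):
        lake = LakeConfig(depth=0.8, active_sediment_layer=0.05,
                          phosphorus_diffusion_rate=0.1)
        assert phosphorus_diffusion(0.5, 2.0, lake) == pytest.approx(
            0.1 * 1.5 * 0.0625, rel=1e-12)

    def test_closed_abiotic_two_pool_exchange_conserves_total(self):
        """With no biota/detritus and no TP settling, diffusion only moves
        phosphorus between pools: pw + ps is constant under Euler stepping."""
        lake = LakeConfig(phosphorus_settling_rate=0.0)
        ps_set = ParameterSet(species=[], lake=lake, diet_matrix={})
        state = LakeState(biom=np.zeros(0), det=0.0, pw=0.1, ps=2.0)
        total0 = state.pw + state.ps
        f = ForcingSample(20.0, 10.0)
        for _ in range(200):
            d = state_derivative(state, f, ps_set)
            state = LakeState(np.zeros(0), 0.0, state.pw + d.pw, state.ps + d.ps)
        assert state.pw + state.ps == pytest.approx(total0, rel=1e-12)
        assert abs(state.pw - state.ps) < abs(0.1 - 2.0)  # pools converged


class TestStateDerivative:
    def test_zero_state_zero_derivative(self, default_ps):
        state = LakeState(biom=np.zeros(14))
        d = state_derivative(state, ForcingSample(25.0, 10.0, cc=0.1), default_ps)
        assert np.all(d.as_vector() == 0.0)

    def test_single_producer_closed_form(self):
        """Saturating resources, sk=0: d(biom)/dt = (maxg - maxm e^{kcc cc M} - maxr) biom."""
        ps_set = _single_producer_set()
        spec = ps_set.species[0]
        cc = 0.001
        state = LakeState(biom=np.array([2.0]), pw=1e12)
        d = state_derivative(state, ForcingSample(20.0, 1e12, cc=cc), ps_set)
        expected = (spec.maxg - spec.maxm * math.exp(spec.kcc * cc * 1000)
                    - spec.maxr) * 2.0
        assert d.biom[0] == pytest.approx(expected, rel=1e-9)

    def test_dimension_mismatch_rejected(self, default_ps):
        with pytest.raises(ValueError, match="species"):
            state_derivative(LakeState(biom=np.zeros(3)),
                             ForcingSample(20.0, 10.0), default_ps)

    def test_non_finite_state_reported(self):
        ps_set = _single_producer_set(kcc=1.0)  # exp(kcc*cc*1000) overflows
        state = LakeState(biom=np.array([1.0]), pw=1e12)
        with pytest.raises(FloatingPointError):
            with np.errstate(over="ignore"):
                state_derivative(state, ForcingSample(20.0, 1e12, cc=1.0), ps_set)

    def test_assembly_matches_individual_rates(self, default_ps, rng):
        state = LakeState(biom=rng.uniform(0, 5, 14), det=3.0, pw=0.4, ps=1.2)
        f = ForcingSample(26.0, 11.0, cc=0.002)
        d, rates = state_derivative(state, f, default_ps, return_rates=True)
        for i, s in enumerate(default_ps.species):
            if s.guild in ("submerged_macrophyte", "periphyton"):
                expected = rates.growth[i] - rates.mortality[i] - rates.respiration[i]
            elif s.guild == "phytoplankton":
                expected = (rates.growth[i] - rates.mortality[i] - rates.respiration[i]
                            - rates.settling[i] - rates.prey_loss[i])
            else:
                expected = rates.grazing[i] - rates.mortality[i] - rates.respiration[i]
            assert d.biom[i] == pytest.approx(expected, rel=1e-12)

    def test_grazing_mass_flow_bookkeeping(self, default_ps, rng):
        """Prey debit equals assimilated gain inflated by ae and (1-rf)."""
        state = LakeState(biom=rng.uniform(0.5, 8, 14), det=2.0, pw=0.5, ps=1.0)
        f = ForcingSample(24.0, 12.0)
        rates = compute_rates(state, f, default_ps)
        expected_debit = sum(
            rates.grazing[i] / (s.ae * (1 - s.rf))
            for i, s in enumerate(default_ps.species) if s.guild == "zooplankton")
        assert rates.prey_loss.sum() == pytest.approx(expected_debit, rel=1e-12)

    def test_strict_as_printed_debits_equal_credits(self, default_ps, rng):
        state = LakeState(biom=rng.uniform(0.5, 8, 14), det=2.0, pw=0.5, ps=1.0)
        f = ForcingSample(24.0, 12.0)
        rates = compute_rates(state, f, default_ps, strict_as_printed=True)
        zoo_gain = sum(rates.grazing[i] for i, s in enumerate(default_ps.species)
                       if s.guild == "zooplankton")
        ben_gain = sum(rates.grazing[i] for i, s in enumerate(default_ps.species)
                       if s.guild == "benthos")
        assert rates.prey_loss.sum() == pytest.approx(zoo_gain, rel=1e-12)
        assert rates.det_grazed == pytest.approx(ben_gain, rel=1e-12)

    def test_zero_focal_biomass_gives_zero_rates(self, default_ps, rng):
        biom = rng.uniform(0.5, 5, 14)
        i = default_ps.index("c")
        biom[i] = 0.0
        state = LakeState(biom=biom, det=1.0, pw=0.5, ps=1.0)
        rates = compute_rates(state, ForcingSample(24.0, 12.0, cc=0.001), default_ps)
        assert rates.growth[i] == rates.mortality[i] == rates.respiration[i] == 0.0
        assert rates.settling[i] == 0.0


class TestTranscriptionOracle:
    def test_matches_straight_line_reference_on_random_states(self, default_ps):
        """Term-by-term agreement with an independent flat transcription of
        all state balances on 100 seeded random states."""
        species, lake, diet = params_as_dicts(default_ps)
        ids = default_ps.species_ids
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            biom = rng.uniform(0, 50, 14)
            det = rng.uniform(0, 100)
            pw = rng.uniform(0, 2)
            psed = rng.uniform(0, 3)
            cc = rng.uniform(0, 0.003)
            T = rng.uniform(10, 35)
            sr = rng.uniform(0, 25)
            state = LakeState(biom=biom, det=det, pw=pw, ps=psed)
            d = state_derivative(state, ForcingSample(T, sr, cc=cc), default_ps)
            ref_b, ref_det, ref_pw, ref_ps = reference_derivative(
                dict(zip(ids, biom)), det, pw, psed, cc, T, sr, species, lake, diet)
            got = np.concatenate([d.biom, [d.det, d.pw, d.ps]])
            ref = np.array([ref_b[i] for i in ids] + [ref_det, ref_pw, ref_ps])
            scale = np.maximum(np.abs(ref), 1.0)
            worst = max(worst, float(np.max(np.abs(got - ref) / scale)))
        assert worst < 1e-12


def test_chlorine_neutrality_of_rates(default_ps, rng):
    """cc = 0 gives identical rates to kcc = 0 everywhere, bitwise."""
    from chlorolake.params import set_parameter
    ps0 = default_ps
    for s in default_ps.species:
        ps0 = set_parameter(ps0, f"{s.species_id}.kcc", 0.0)
    state = LakeState(biom=rng.uniform(0, 5, 14), det=1.0, pw=0.5, ps=1.0)
    d_cc0 = state_derivative(state, ForcingSample(24.0, 12.0, cc=0.0), default_ps)
    d_kcc0 = state_derivative(state, ForcingSample(24.0, 12.0, cc=0.002), ps0)
    assert np.array_equal(d_cc0.as_vector(), d_kcc0.as_vector())
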