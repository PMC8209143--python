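"""Plant growth core: every governing equation against an independent
straight-line reference on randomized inputs, plus the cut/season logic."""

import dataclasses

import numpy as np
import pytest

import reference as ref
from dynagrass.plant import (
    COMPARTMENTS,
    PhotosynthesisKernel,
    PlantParams,
    PlantState,
    allocation_fractions,
    apply_cut,
    gross_photosynthesis,
    redistribute_nitrogen,
    respiration_and_exudation,
    rubisco_activity,
    season_transition,
    senescence,
    update_development,
)

RNG = np.random.default_rng(20240917)


def _random_state(rng) -> PlantState:
    st = PlantState(
        m_storage=float(rng.uniform(0, 2000)),
        m_root=float(rng.uniform(100, 4000)),
        m_leaf=float(rng.uniform(50, 4000)),
        m_stem=float(rng.uniform(20, 2000)),
        dvs=float(rng.uniform(0, 1)),
        first_cut_done=bool(rng.integers(0, 2)),
        season_active=True,
    )
    st.plant_n = float(rng.uniform(5, 150))
    return st


class TestDevelopment:
    def test_base_temperature_gives_zero_increment(self, params):
        st = PlantState(season_active=True)
        update_development(st, params.t_base, params)
        assert st.gdd == 0.0 and st.dvs == 0.0

    def test_dvs_caps_at_one(self, params):
        st = PlantState(season_active=True, gdd=params.gdd)
        st.dvs = 1.0
        update_development(st, params.t_base + 50.0, params)
        assert st.dvs == 1.0

    def test_increment_sequence_matches_brute_force_sum(self):
        p = PlantParams(gdd=100.0, t_base=0.0)
        st = PlantState(season_active=True)
        for t in (2.0, 3.0, 5.0):
            update_development(st, t, p)
        assert st.dvs == pytest.approx(0.10)
        assert st.dvs == pytest.approx(ref.ref_dvs([2, 3, 5], 100.0))


class TestAllocation:
    def test_zero_development_gives_zero_storage_share(self, params):
        st = PlantState(dvs=0.0)
        assert allocation_fractions(st, params)["storage"] == 0.0

    def test_fractions_sum_to_one_on_random_states(self, params):
        for _ in range(200):
            st = _random_state(RNG)
            theta = allocation_fractions(st, params)
            assert sum(theta.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(v >= 0 for v in theta.values())

    def test_equal_weight_arithmetic_example(self):
        p = PlantParams(storage=0.2, root=0.3, leaf=0.3, stem=0.3, cut=1.0)
        st = PlantState(dvs=0.5, first_cut_done=True, m_leaf=1000.0, m_stem=1000.0)
        theta = allocation_fractions(st, p)
        assert theta["storage"] == pytest.approx(0.1)
        assert theta["root"] == pytest.approx(0.3)
        assert theta["leaf"] + theta["stem"] == pytest.approx(0.6)

    def test_matches_reference_formula_randomized(self, params):
        for _ in range(300):
            st = _random_state(RNG)
            gamma = params.cut if not st.first_cut_done else 1.0
            expect = ref.ref_allocation(st.dvs, params.storage, params.root,
                                        params.leaf, params.stem, gamma,
                                        st.m_leaf, st.m_stem)
            theta = allocation_fractions(st, params)
            got = (theta["storage"], theta["root"], theta["leaf"], theta["stem"])
            assert np.allclose(got, expect, atol=1e-9)

    def test_pre_cut_multiplier_raises_aboveground_share(self, params):
        st = PlantState(dvs=0.3, m_leaf=1000.0, m_stem=400.0)
        st.first_cut_done = False
        before = allocation_fractions(st, params)
        st.first_cut_done = True
        after = allocation_fractions(st, params)
        assert before["root"] < after["root"]


class TestRubisco:
    def test_below_wilting_shuts_photosynthesis(self, params):
        st = PlantState()
        arub, fpd, _, _ = rubisco_activity(st, 20.0, 22.0, 52.0, 15.0, params)
        assert fpd == 0.0 and float(arub) == 0.0

    def test_warm_hours_unlimited(self, params):
        st = PlantState()
        _, _, fpt, _ = rubisco_activity(st, 45.0, 22.0, 52.0,
                                        np.full(24, params.limit + 5.0), params)
        assert np.all(fpt == 1.0)

    def test_optimal_leaf_nitrogen_gives_unit_response(self, params):
        st = PlantState()
        st.plant_n = st.n_target(params)
        _, _, _, fpn = rubisco_activity(st, 45.0, 22.0, 52.0, 15.0, params)
        assert fpn == pytest.approx(1.0)

    def test_matches_reference_randomized(self, params):
        for _ in range(300):
            st = _random_state(RNG)
            psi = float(RNG.uniform(15, 55))
            t = float(RNG.uniform(-5, 30))
            arub, fpd, fpt, fpn = rubisco_activity(st, psi, 22.0, 52.0, t, params)
            e_fpd = ref.ref_fp_drought(psi, 22.0, 52.0, params.h2o)
            e_fpt = ref.ref_fp_temp(t, params.limit)
            e_fpn = ref.ref_fp_nitrogen(st.c_n("leaf", params), params.nc_leaf,
                                        params.ndef_leaf)
            assert float(fpd) == pytest.approx(e_fpd, abs=1e-9)
            assert float(fpt) == pytest.approx(e_fpt, abs=1e-9)
            assert float(fpn) == pytest.approx(e_fpn, abs=1e-9)
            assert float(arub) == pytest.approx(
                ref.ref_arubisco(params.rubisco, e_fpd, e_fpt, e_fpn), abs=1e-9)


class TestPhotosynthesis:
    KERNEL = PhotosynthesisKernel()

    def test_dark_gives_zero(self):
        assert gross_photosynthesis(3.0, 0.0, 400.0, 1.0, self.KERNEL) == 0.0

    def test_multiplicative_in_rubisco_activity(self):
        full = gross_photosynthesis(3.0, 300.0, 400.0, 1.0, self.KERNEL)
        half = gross_photosynthesis(3.0, 300.0, 400.0, 0.5, self.KERNEL)
        assert half == pytest.approx(full / 2.0, rel=1e-12)

    def test_co2_doubling_increases_less_than_twofold(self):
        g400 = gross_photosynthesis(3.0, 300.0, 400.0, 1.0, self.KERNEL)
        g800 = gross_photosynthesis(3.0, 300.0, 800.0, 1.0, self.KERNEL)
        assert 1.0 < g800 / g400 < 2.0
        assert g800 / g400 == pytest.approx(
            ref.ref_gpp(1, 1, 0.5, 3.0, 300, 250.0, 800, 300.0)
            / ref.ref_gpp(1, 1, 0.5, 3.0, 300, 250.0, 400, 300.0), rel=1e-9)

    def test_saturating_monotone_in_drivers(self):
        k = self.KERNEL
        pars = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        g = gross_photosynthesis(3.0, pars, 400.0, 1.0, k)
        assert np.all(np.diff(g) > 0)
        assert np.all(np.diff(np.diff(g)) < 0)  # concave: saturating
        lais = [0.5, 1.0, 2.0, 4.0, 8.0]
        gl = [gross_photosynthesis(l, 300.0, 400.0, 1.0, k) for l in lais]
        assert np.all(np.diff(gl) > 0)

    def test_matches_reference_randomized(self):
        k = self.KERNEL
        for _ in range(200):
            lai = float(RNG.uniform(0, 8))
            par = float(RNG.uniform(0, 500))
            co2 = float(RNG.uniform(350, 950))
            arub = float(RNG.uniform(0, 1))
            got = gross_photosynthesis(lai, par, co2, arub, k)
            expect = ref.ref_gpp(k.amax, arub, k.k_ext, lai, par, k.par_half,
                                 co2, k.co2_half)
            assert float(got) == pytest.approx(expect, abs=1e-9)


class TestRespiration:
    def test_growth_respiration_fraction_of_gpp(self, params):
        st = PlantState()
        theta = allocation_fractions(st, params)
        rg, _, _ = respiration_and_exudation(st, 100.0, 20.0, theta,
                                             dataclasses.replace(params, yield_frac=0.25))
        assert rg == pytest.approx(25.0)

    def test_reference_conditions_give_unit_factors(self, params):
        p = dataclasses.replace(params, t_ref=20.0)
        st = PlantState(m_leaf=1000.0)
        theta = allocation_fractions(st, p)
        t = max(20.0, p.limit)
        _, rm, _ = respiration_and_exudation(st, 0.0, t, theta, p)
        assert rm["leaf"] == pytest.approx(1000.0 * p.c_to_dm * p.r_leaf)

    def test_empty_compartment_respires_nothing(self, params):
        st = PlantState(m_storage=0.0)
        theta = allocation_fractions(st, params)
        _, rm, _ = respiration_and_exudation(st, 10.0, 15.0, theta, params)
        assert rm["storage"] == 0.0

    def test_exudation_is_fraction_of_root_growth_respiration(self, params):
        st = PlantState()
        theta = allocation_fractions(st, params)
        rg, _, ex = respiration_and_exudation(st, 80.0, 25.0, theta, params)
        assert ex == pytest.approx(params.exudate * theta["root"] * rg, rel=1e-12)

    def test_matches_reference_randomized(self, params):
        for _ in range(100):
            st = _random_state(RNG)
            t_h = RNG.uniform(-5, 30, size=24)
            theta = allocation_fractions(st, params)
            _, rm, _ = respiration_and_exudation(st, 50.0, t_h, theta, params)
            for x in COMPARTMENTS:
                expect = ref.ref_rm(st.mass(x), params.r_maint(x), params.c_to_dm,
                                    t_h, params.limit, params.t_ref)
                assert rm[x] == pytest.approx(expect, abs=1e-9)


class TestSenescence:
    def test_benign_conditions_leave_only_age_term(self):
        p = PlantParams(sen_age=0.002)
        st = PlantState(m_leaf=1000.0)
        losses, *_ = senescence(st, 52.0, 22.0, 52.0, 10.0, 8.0, p)
        assert losses["leaf"] == pytest.approx(0.002 * 1000.0)

    def test_frost_rate_is_slope_times_magnitude(self):
        p = PlantParams(sen_frost=0.01)
        st = PlantState()
        _, _, fs_frost, _ = senescence(st, 52.0, 22.0, 52.0, -4.0, 5.0, p)
        assert fs_frost == pytest.approx(0.04)

    def test_max_rule_picks_largest_candidate(self):
        assert ref.ref_senescence_rate(0.01, 0.02, 0.005) == 0.02

    def test_below_wilting_uses_maximal_drought_rate(self, params):
        st = PlantState(m_leaf=1000.0)
        losses, fs_d, _, _ = senescence(st, 20.0, 22.0, 52.0, 10.0, 10.0, params)
        assert fs_d == params.sen_drought

    def test_matches_reference_randomized(self, params):
        for _ in range(200):
            st = _random_state(RNG)
            psi = float(RNG.uniform(15, 55))
            air_t = float(RNG.uniform(-10, 25))
            soil_t = float(RNG.uniform(-5, 20))
            losses, *_ = senescence(st, psi, 22.0, 52.0, air_t, soil_t, params)
            fs_d = ref.ref_fs_drought(psi, 22.0, 52.0, params.h2o_sen,
                                      params.sen_drought)
            for x in COMPARTMENTS:
                t = air_t if x in ("leaf", "stem") else soil_t
                rate = ref.ref_senescence_rate(
                    fs_d, ref.ref_fs_frost(t, params.sen_frost), params.sen_age)
                assert losses[x] == pytest.approx(
                    min(st.mass(x), rate * st.mass(x)), abs=1e-9)


class TestNitrogen:
    def test_ample_soil_nitrogen_fills_to_optimum(self, params):
        st = PlantState()
        st.plant_n = 0.0
        for _ in range(60):
            redistribute_nitrogen(st, 1e6, params)
        for x in COMPARTMENTS:
            assert st.c_n(x, params) == pytest.approx(params.nc(x))

    def test_no_soil_nitrogen_dilutes_leaf_concentration(self, params):
        st = PlantState(m_leaf=500.0)
        redistribute_nitrogen(st, 1e6, params)
        before = st.c_n("leaf", params)
        st.m_leaf += 1000.0  # growth without uptake
        redistribute_nitrogen(st, 0.0, params)
        assert st.c_n("leaf", params) < before

    def test_demand_target_arithmetic(self):
        p = PlantParams(nc_storage=0.01, nc_root=0.01, nc_leaf=0.03, nc_stem=0.02)
        st = PlantState(m_storage=1000.0, m_root=2000.0, m_leaf=3000.0,
                        m_stem=500.0)
        assert st.n_target(p) == pytest.approx(130.0)
        assert st.n_target(p) == pytest.approx(
            ref.ref_n_demand([1000, 2000, 3000, 500], [0.01, 0.01, 0.03, 0.02]))

    def test_uptake_respects_supply_and_cap(self, params):
        st = PlantState()
        st.plant_n = 0.0
        _, uptake, _ = redistribute_nitrogen(st, 2.0, params)
        assert uptake == pytest.approx(2.0)
        st.plant_n = 0.0
        _, uptake, _ = redistribute_nitrogen(st, 1e6, params)
        assert uptake == pytest.approx(params.n_uptake_max)


class TestCutAndSeason:
    def test_harvest_arithmetic(self, params):
        st = PlantState(m_leaf=1500.0, m_stem=900.0, m_storage=0.0)
        harvested, _, _ = apply_cut(st, 200.0, 100.0, params)
        assert harvested == pytest.approx(2100.0)
        assert harvested == pytest.approx(ref.ref_harvest(1500, 900, 200, 100))
        assert st.m_leaf == pytest.approx(200.0)
        assert st.m_stem == pytest.approx(100.0)

    def test_cut_at_residuals_changes_only_flags(self, params):
        st = PlantState(m_leaf=200.0, m_stem=100.0, m_storage=0.0)
        harvested, _, _ = apply_cut(st, 200.0, 100.0, params)
        assert harvested == 0.0
        assert st.first_cut_done

    def test_first_cut_switches_allocation_regime(self, params):
        st = PlantState(m_leaf=1500.0, m_stem=900.0, dvs=0.4)
        pre = allocation_fractions(st, params)["root"]
        apply_cut(st, 200.0, 100.0, params)
        post = allocation_fractions(st, params)["root"]
        assert post > pre  # gamma_cut < 1 no longer damps root allocation

    def test_cut_translocates_storage_mass_conserving(self, params):
        st = PlantState(m_leaf=1500.0, m_stem=900.0, m_storage=600.0,
                        m_root=2000.0)
        total_before = st.total_mass
        harvested, _, _ = apply_cut(st, 200.0, 100.0, params)
        assert st.m_storage == 0.0
        assert st.total_mass == pytest.approx(total_before - harvested)

    def test_onset_after_constant_forcing_matches_arithmetic(self, params):
        st = PlantState()
        onset_doy = None
        for doy in range(1, 200):
            st, started = season_transition(st, params.t_base + 1.0, doy, 365,
                                            params, onset_threshold=100.0)
            if started:
                onset_doy = doy
                break
        assert onset_doy == 100

    def test_zero_threshold_starts_season_on_jan1(self, params):
        st = PlantState()
        st, started = season_transition(st, 0.0, 1, 365, params,
                                        onset_threshold=0.0)
        assert started and st.season_active

    def test_onset_translocation_and_year_end_reset(self, params):
        st = PlantState(m_storage=500.0)
        total = st.total_mass
        st, started = season_transition(st, 30.0, 50, 365, params,
                                        onset_threshold=10.0)
        assert started
        assert st.m_storage == 0.0
        assert st.total_mass == pytest.approx(total)
        st.gdd = 300.0
        st.first_cut_done = True
        st, _ = season_transition(st, 0.0, 365, 365, params)
        assert st.gdd == 0.0 and st.dvs == 0.0
        assert not st.first_cut_done and not st.season_active


class TestParamLoading:
    def test_mapping_roundtrip(self, params):
        d = {"STORAGE": 0.45, "ROOT": 0.9, "GDD": 1000.0}
        p = PlantParams.from_mapping(d)
        assert p.storage == 0.45 and p.root == 0.9

    def test_unknown_and_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            PlantParams.from_mapping({"NOT_A_PARAM": 1.0})
        with pytest.raises(ValueError):
            PlantParams(gdd=-5.0)


class TestThirtyDayTrajectory:
    """A 30-day fixture advanced by the module functions matches an
    independent scalar transliteration of the whole daily carbon step."""

    def test_trajectories_agree_to_1e9(self, params):
        rng = np.random.default_rng(11)
        drivers = [
            {"psi": float(rng.uniform(30, 52)),
             "t_h": rng.uniform(2, 25, 24),
             "par_h": np.clip(rng.uniform(-50, 350, 24), 0, None),
             "co2": 400.0}
            for _ in range(30)
        ]
        st = PlantState(season_active=True, dvs=0.2)
        st.plant_n = st.n_target(params) * 0.8
        k = params.kernel

        masses = {x: st.mass(x) for x in COMPARTMENTS}
        plant_n = st.plant_n
        dvs = st.dvs
        gdd = st.gdd
        for day in drivers:
            # --- production route ---------------------------------------
            t_mean = float(np.mean(day["t_h"]))
            update_development(st, t_mean, params)
            arub, *_ = rubisco_activity(st, day["psi"], 22.0, 52.0,
                                        day["t_h"], params)
            lai = st.lai(params)
            gpp = float(np.sum(gross_photosynthesis(
                lai, day["par_h"], day["co2"], arub, k)))
            theta = allocation_fractions(st, params)
            rg, rm, ex = respiration_and_exudation(st, gpp, day["t_h"], theta,
                                                   params)
            assim = gpp - rg - sum(rm.values()) - ex
            assert assim >= 0  # fixture chosen in the growing regime
            for x in COMPARTMENTS:
                st.set_mass(x, st.mass(x) + assim / params.c_to_dm * theta[x])
            losses, *_ = senescence(st, day["psi"], 22.0, 52.0, t_mean,
                                    t_mean, params)
            for x in COMPARTMENTS:
                st.set_mass(x, st.mass(x) - losses[x])

            # --- independent scalar route --------------------------------
            gdd += max(0.0, t_mean - params.t_base)
            dvs = min(gdd / params.gdd, 1.0)
            target = ref.ref_n_demand([masses[x] for x in COMPARTMENTS],
                                      [params.nc(x) for x in COMPARTMENTS])
            c_n_leaf = params.nc_leaf * plant_n / target
            fpn = ref.ref_fp_nitrogen(c_n_leaf, params.nc_leaf, params.ndef_leaf)
            fpd = ref.ref_fp_drought(day["psi"], 22.0, 52.0, params.h2o)
            lai_r = masses["leaf"] * params.sla / 1e4
            gpp_r = 0.0
            for t, par in zip(day["t_h"], day["par_h"]):
                fpt = ref.ref_fp_temp(t, params.limit)
                gpp_r += ref.ref_gpp(k.amax, params.rubisco * fpd * fpt * fpn,
                                     k.k_ext, lai_r, par, k.par_half,
                                     day["co2"], k.co2_half)
            gamma = params.cut
            ths, thr, thl, tht = ref.ref_allocation(
                dvs, params.storage, params.root, params.leaf, params.stem,
                gamma, masses["leaf"], masses["stem"])
            theta_r = dict(zip(COMPARTMENTS, (ths, thr, thl, tht)))
            rg_r = params.yield_frac * gpp_r
            rm_r = {x: ref.ref_rm(masses[x], params.r_maint(x), params.c_to_dm,
                                  day["t_h"], params.limit, params.t_ref)
                    for x in COMPARTMENTS}
            ex_r = params.exudate * thr * rg_r
            assim_r = gpp_r - rg_r - sum(rm_r.values()) - ex_r
            for x in COMPARTMENTS:
                masses[x] += assim_r / params.c_to_dm * theta_r[x]
            fs_d = ref.ref_fs_drought(day["psi"], 22.0, 52.0, params.h2o_sen,
                                      params.sen_drought)
            for x in COMPARTMENTS:
                rate = ref.ref_senescence_rate(
                    fs_d, ref.ref_fs_frost(t_mean, params.sen_frost),
                    params.sen_age)
                masses[x] -= min(masses[x], rate * masses[x])

            for x in COMPARTMENTS:
                assert st.mass(x) == pytest.approx(masses[x], rel=1e-9)
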