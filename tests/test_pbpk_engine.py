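"""Engine checks against closed-form PK oracles and interaction-kinetics
steady states."""

import numpy as np
import pytest

from conftest import (cyp2d6_victim_net, fast_distribution_individual,
                      mono_scenario, renal_only_net, total_volume)
from ddginet.errors import DomainError
from ddginet.network_config import InteractionEdge, NetworkModel, ScenarioSpec
from ddginet.pbpk_engine import (CompoundModel, MetabolicPathway, Regimen,
                                 build_ode_system, effective_kinetics,
                                 enzyme_turnover_rhs, mass_balance, simulate,
                                 simulate_to_steady_state)
from ddginet.physiology import make_reference_individual
from ddginet.synthetic_study import default_enzymes, fraction_metabolized


class TestStateLayout:
    def test_single_compound_single_enzyme(self, ref_ind):
        net = cyp2d6_victim_net()
        system = build_ode_system(net, ref_ind, mono_scenario("VIC"))
        # 5 compartments + 1 enzyme-site + 1 cumulative-eliminated
        assert system.n_states == 7

    def test_victim_perpetrator_metabolite(self, ref_ind):
        """Three compounds, two enzyme-sites: 3*5 + 2 + 3 = 20 states."""
        from ddginet.network_config import MetaboliteLink
        victim = CompoundModel(
            id="VIC", molar_mass=300.0, fu_plasma=0.3,
            pathways=[MetabolicPathway(id="cyp2d6", enzyme="CYP2D6",
                                       site="liver", vmax=20.0, km=5.0)],
            renal_cl=1.0)
        met = CompoundModel(id="MET", molar_mass=320.0, fu_plasma=0.4,
                            renal_cl=3.0)
        perp = CompoundModel(
            id="PERP", molar_mass=350.0, fu_plasma=0.3,
            pathways=[MetabolicPathway(id="cyp3a4", enzyme="CYP3A4",
                                       site="liver", vmax=30.0, km=10.0)],
            renal_cl=1.0)
        net = NetworkModel(
            compounds={"VIC": victim, "MET": met, "PERP": perp},
            enzymes={"CYP2D6": default_enzymes()["CYP2D6"],
                     "CYP3A4": default_enzymes()["CYP2D6"].__class__(
                         "CYP3A4", sites=("liver",), kdeg=0.03)},
            metabolite_links=[MetaboliteLink("VIC", "cyp2d6", "MET", 1.0)],
            edges=[InteractionEdge("PERP", "CYP2D6", "competitive",
                                   {"ki": 0.5})])
        scenario = ScenarioSpec(
            victim="VIC", victim_regimen=Regimen(10.0, "oral"),
            perpetrators=[("PERP", Regimen(10.0, "oral"))])
        system = build_ode_system(net, ref_ind, scenario)
        assert system.n_states == 20

    def test_empty_perpetrator_set_is_monotherapy(self, ref_ind):
        net = cyp2d6_victim_net()
        a = build_ode_system(net, ref_ind, mono_scenario("VIC"))
        b = build_ode_system(net, ref_ind, ScenarioSpec(
            victim="VIC", victim_regimen=Regimen(10.0, "iv"),
            perpetrators=[]))
        assert a.n_states == b.n_states
        assert a.compound_ids == b.compound_ids


class TestEffectiveKinetics:
    def _pathway(self):
        return MetabolicPathway(id="p", enzyme="CYP2D6", site="liver",
                                vmax=100.0, km=5.0)

    def test_identity_without_inhibitors(self):
        vmax, km = effective_kinetics(self._pathway(), 1.0, {}, [])
        assert (vmax, km) == (100.0, 5.0)

    def test_competitive_scales_km(self):
        edge = InteractionEdge("I", "CYP2D6", "competitive", {"ki": 1.0})
        vmax, km = effective_kinetics(self._pathway(), 1.0, {"I": 2.0},
                                      [edge])
        assert km == pytest.approx(15.0)   # Km * (1 + 2)
        assert vmax == pytest.approx(100.0)

    def test_noncompetitive_scales_vmax_with_enzyme_loss(self):
        edge = InteractionEdge("I", "CYP2D6", "noncompetitive", {"ki": 1.0})
        vmax, km = effective_kinetics(self._pathway(), 0.5, {"I": 1.0},
                                      [edge])
        assert vmax == pytest.approx(25.0)  # 0.5 * 100 / (1 + 1)
        assert km == pytest.approx(5.0)

    def test_other_enzyme_edges_ignored(self):
        edge = InteractionEdge("I", "CYP3A4", "competitive", {"ki": 0.1})
        vmax, km = effective_kinetics(self._pathway(), 1.0, {"I": 10.0},
                                      [edge])
        assert (vmax, km) == (100.0, 5.0)


class TestEnzymeTurnover:
    def test_baseline_steady_state(self):
        assert enzyme_turnover_rhs(1.0, {}, [], kdeg=0.02) == 0.0

    def test_mbi_clamped_steady_state(self, ref_ind):
        """A clamped inactivator with kinact*Iu/(KI+Iu) = kdeg halves the
        enzyme at equilibrium (closed form kdeg / (kdeg + lambda))."""
        kdeg = 0.05
        net = cyp2d6_victim_net()
        net.enzymes["CYP2D6"].kdeg = kdeg
        net.compounds["PERP"] = CompoundModel(id="PERP", molar_mass=300.0,
                                              fu_plasma=1.0, renal_cl=1.0)
        # Iu = KI  ->  lambda = kinact / 2; choose kinact = 2 kdeg
        net.edges.append(InteractionEdge("PERP", "CYP2D6", "mbi",
                                         {"ki": 1.0, "kinact": 2 * kdeg}))
        system = build_ode_system(net, ref_ind, mono_scenario("VIC", dose=0),
                                  clamped={"PERP": 1.0})
        res = simulate(system, np.linspace(0, 8 / kdeg, 30), rtol=1e-8)
        assert res.enzyme("CYP2D6", "liver")[-1] == pytest.approx(0.5,
                                                                  rel=1e-3)

    def test_induction_clamped_steady_state(self, ref_ind):
        """A clamped inducer at Iu = EC50 with Emax = 4 triples the enzyme
        (closed form 1 + Emax/2)."""
        net = cyp2d6_victim_net()
        net.compounds["PERP"] = CompoundModel(id="PERP", molar_mass=300.0,
                                              fu_plasma=1.0, renal_cl=1.0)
        net.edges.append(InteractionEdge("PERP", "CYP2D6", "induction",
                                         {"ec50": 2.0, "emax": 4.0}))
        system = build_ode_system(net, ref_ind, mono_scenario("VIC", dose=0),
                                  clamped={"PERP": 2.0})
        res = simulate(system, np.linspace(0, 500.0, 30), rtol=1e-8)
        assert res.enzyme("CYP2D6", "liver")[-1] == pytest.approx(3.0,
                                                                  rel=1e-3)

    def test_downregulation_clamped_steady_state(self):
        """Scalar form: synthesis suppressed by Imax*Iu/(IC50+Iu)."""
        edge = InteractionEdge("P", "CYP2D6", "downregulation",
                               {"ic50": 1.0, "imax": 0.8})
        # at Iu = IC50 synthesis is scaled by 1 - 0.4; E* = 0.6
        dE = enzyme_turnover_rhs(0.6, {"P": 1.0}, [edge], kdeg=0.02)
        assert dE == pytest.approx(0.0, abs=1e-15)


class TestClosedFormOracles:
    def test_zero_dose_zero_profiles(self, ref_ind):
        net = renal_only_net()
        system = build_ode_system(net, ref_ind, mono_scenario(dose=0.0))
        res = simulate(system, np.linspace(0, 24, 25))
        assert np.all(res.conc("DRUG") == 0.0)

    def test_iv_auc_equals_dose_over_cl(self, ref_ind):
        """One-compartment IV oracle: AUC_0-inf = Dose / CL for linear
        renal elimination from the sampled compartment."""
        cl, fu, dose_mg = 5.0, 1.0, 10.0
        net = renal_only_net(cl=cl, fu=fu)
        dose_umol = net.compounds["DRUG"].dose_to_umol(dose_mg)
        ke = cl * fu / total_volume(ref_ind)
        horizon = 15 / ke * np.log(2)
        system = build_ode_system(net, ref_ind,
                                  mono_scenario(dose=dose_mg, route="iv"))
        res = simulate(system, np.linspace(0, horizon, 3000), rtol=1e-9,
                       atol=1e-12)
        auc = np.trapezoid(res.conc("DRUG"), res.times)
        assert auc == pytest.approx(dose_umol / (cl * fu), rel=1e-3)

    def test_oral_one_compartment_cmax_tmax(self):
        """Oral one-compartment closed form: with perfusion much faster
        than absorption/elimination the five compartments collapse to one
        well-mixed volume; Cmax and Tmax follow the (ka, ke) Bateman
        solution."""
        ind = fast_distribution_individual(300.0)
        cl, ka, dose_mg = 10.0, 1.0, 10.0
        net = renal_only_net(cl=cl, fu=1.0, ka=ka)
        V = total_volume(ind)
        ke = cl / V
        tmax = np.log(ka / ke) / (ka - ke)
        cmax_expected = (net.compounds["DRUG"].dose_to_umol(dose_mg) / V
                         * ka / (ka - ke)
                         * (np.exp(-ke * tmax) - np.exp(-ka * tmax)))
        system = build_ode_system(net, ind, mono_scenario(dose=dose_mg,
                                                          route="oral"))
        grid = np.linspace(0, 24, 2401)
        res = simulate(system, grid, rtol=1e-9, atol=1e-12)
        conc = res.conc("DRUG")
        assert conc.max() == pytest.approx(cmax_expected, rel=5e-3)
        assert grid[np.argmax(conc)] == pytest.approx(tmax, abs=0.05)

    def test_dose_linearity_below_km(self, ref_ind):
        """Well below Km the system is linear: doubling the dose doubles
        the profile within 1%."""
        net = cyp2d6_victim_net(vmax=30.0, km=50.0)
        grid = np.linspace(0, 48, 49)
        out = []
        for dose in (1.0, 2.0):
            system = build_ode_system(net, ref_ind,
                                      mono_scenario("VIC", dose=dose,
                                                    route="oral"))
            out.append(simulate(system, grid, rtol=1e-9,
                                atol=1e-13).conc("VIC"))
        ratio = out[1][1:] / out[0][1:]
        assert np.allclose(ratio, 2.0, rtol=0.01)

    def test_static_competitive_inhibition_auc_ratio(self, ref_ind):
        """Static DDI oracle: clamped competitive inhibitor at constant Iu
        gives AUC ratio 1 / (fm/(1 + Iu/Ki) + (1 - fm)) for a linear,
        low-extraction victim."""
        ki, iu = 0.5, 2.0
        net = cyp2d6_victim_net(vmax=15.0, km=20.0, renal=2.0, fu=0.2)
        net.compounds["PERP"] = CompoundModel(id="PERP", molar_mass=300.0,
                                              fu_plasma=1.0, renal_cl=1.0)
        net.edges.append(InteractionEdge("PERP", "CYP2D6", "competitive",
                                         {"ki": ki}))
        fm = fraction_metabolized(net, "VIC")
        grid = np.linspace(0, 600, 200)
        aucs = {}
        for clamp in (0.0, iu):
            system = build_ode_system(net, ref_ind,
                                      mono_scenario("VIC", dose=1.0,
                                                    route="iv"),
                                      clamped={"PERP": clamp})
            res = simulate(system, grid, rtol=1e-8, atol=1e-12)
            aucs[clamp] = np.trapezoid(res.conc("VIC"), grid)
        expected = 1.0 / (fm / (1 + iu / ki) + (1 - fm))
        assert aucs[iu] / aucs[0.0] == pytest.approx(expected, rel=0.05)

    def test_auc_monotone_in_clamped_inhibitor(self, ref_ind):
        """Victim AUC is non-decreasing in competitive inhibitor
        concentration."""
        net = cyp2d6_victim_net()
        net.compounds["PERP"] = CompoundModel(id="PERP", molar_mass=300.0,
                                              fu_plasma=1.0, renal_cl=1.0)
        net.edges.append(InteractionEdge("PERP", "CYP2D6", "competitive",
                                         {"ki": 0.5}))
        grid = np.linspace(0, 300, 100)
        aucs = []
        for clamp in (0.0, 0.5, 2.0, 10.0):
            system = build_ode_system(net, ref_ind,
                                      mono_scenario("VIC", dose=1.0,
                                                    route="iv"),
                                      clamped={"PERP": clamp})
            aucs.append(np.trapezoid(simulate(system, grid,
                                              rtol=1e-7).conc("VIC"), grid))
        assert all(b >= a * (1 - 1e-9) for a, b in zip(aucs, aucs[1:]))

    def test_auc_monotone_in_activity_score(self, ref_ind):
        net = cyp2d6_victim_net()
        grid = np.linspace(0, 300, 100)
        aucs = []
        for as_value in (0.0, 1.0, 2.0, 3.0):
            system = build_ode_system(
                net, ref_ind, mono_scenario("VIC", dose=1.0, route="iv",
                                            as_value=as_value))
            aucs.append(np.trapezoid(simulate(system, grid,
                                              rtol=1e-7).conc("VIC"), grid))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(aucs, aucs[1:]))


class TestMbiWashout:
    def test_enzyme_recovers_after_washout(self, ref_ind):
        """After the inactivator concentration falls below 1e-6 * KI the
        enzyme pool returns to within 1% of baseline after 5/kdeg hours."""
        kdeg = 0.1
        net = cyp2d6_victim_net()
        net.enzymes["CYP2D6"].kdeg = kdeg
        net.compounds["PERP"] = CompoundModel(
            id="PERP", molar_mass=300.0, fu_plasma=1.0, ka=2.0,
            renal_cl=60.0)  # fast washout
        net.edges.append(InteractionEdge("PERP", "CYP2D6", "mbi",
                                         {"ki": 0.5, "kinact": 2.0}))
        scenario = ScenarioSpec(
            victim="VIC", victim_regimen=Regimen(0.0, "iv"),
            perpetrators=[("PERP", Regimen(50.0, "oral"))])
        system = build_ode_system(net, ref_ind, scenario)
        grid = np.linspace(0, 200, 801)
        res = simulate(system, grid, rtol=1e-8)
        cu_liver = (res.conc("PERP", "liver")
                    / net.compounds["PERP"].kp_of("liver"))
        below = np.nonzero(cu_liver < 1e-6 * 0.5)[0]
        assert below.size, "perpetrator never washed out"
        t_clean = grid[below[0]]
        e_rel = res.enzyme("CYP2D6", "liver")
        assert e_rel.min() < 0.6   # substantial inactivation occurred
        mask = grid >= t_clean + 5 / kdeg
        assert mask.any()
        assert np.all(np.abs(e_rel[mask] - 1.0) < 0.01)


class TestKernelParity:
    def test_compiled_and_numpy_rhs_agree(self, fixture_net,
                                          fixture_scenarios, ref_ind):
        """The numba kernel and the vectorized numpy fallback compute the
        same derivative to machine precision on a populated state."""
        s = fixture_scenarios["ddgi_mbi"]
        system = build_ode_system(fixture_net, ref_ind, s,
                                  track_fluxes=True)
        rng = np.random.default_rng(0)
        y = system.initial_state()
        y[:5 * system.nC] = rng.uniform(0.1, 5.0, 5 * system.nC)
        y[system.i_enz:system.i_elim] = rng.uniform(0.3, 2.0, system.nES)
        d_fast = system.rhs(0.0, y.copy())
        d_ref = system._rhs_numpy(0.0, y.copy())
        np.testing.assert_allclose(d_fast, d_ref, rtol=1e-13, atol=1e-13)


class TestMassBalance:
    def test_fixture_scenario_conserves_mass(self, fixture_net,
                                             fixture_scenarios, ref_ind):
        s = fixture_scenarios["ddgi_mbi"]
        from dataclasses import replace
        reg = replace(s.victim_regimen, n_doses=2)
        perps = [(p, replace(r, n_doses=2)) for p, r in s.perpetrators]
        s2 = replace(s, victim_regimen=reg, perpetrators=perps)
        system = build_ode_system(fixture_net, ref_ind, s2)
        res = simulate(system, np.linspace(0, 48, 97), rtol=1e-8, atol=1e-10)
        assert mass_balance(res) <= 1e-6

    def test_defect_monotone_in_tolerance(self, fixture_net,
                                          fixture_scenarios, ref_ind):
        s = fixture_scenarios["ddi_comp"]
        from dataclasses import replace
        s2 = replace(s, victim_regimen=replace(s.victim_regimen, n_doses=1),
                     perpetrators=[(p, replace(r, n_doses=1))
                                   for p, r in s.perpetrators])
        grid = np.linspace(0, 48, 49)
        defects = {}
        for rtol, atol in ((1e-3, 1e-5), (1e-9, 1e-12)):
            system = build_ode_system(fixture_net, ref_ind, s2)
            res = simulate(system, grid, rtol=rtol, atol=atol)
            defects[rtol] = mass_balance(res)
        assert defects[1e-3] > defects[1e-9]

    def test_full_elimination_limit(self, ref_ind):
        """Single IV bolus, long horizon: cumulative eliminated approaches
        the administered amount."""
        net = renal_only_net(cl=5.0)
        dose_umol = net.compounds["DRUG"].dose_to_umol(10.0)
        system = build_ode_system(net, ref_ind,
                                  mono_scenario(dose=10.0, route="iv"))
        res = simulate(system, np.linspace(0, 2000, 50), rtol=1e-9,
                       atol=1e-12)
        assert res.cumulative_eliminated("DRUG")[-1] == pytest.approx(
            dose_umol, rel=1e-6)


class TestSteadyState:
    def test_superposition_linear_pk(self, ref_ind):
        """Linear PK: AUC_ss over one interval equals the single-dose
        AUC_0-inf (F * Dose / CL with F = 1 for a renally cleared drug)."""
        cl, dose_mg = 8.0, 10.0
        net = renal_only_net(cl=cl, fu=1.0)
        dose_umol = net.compounds["DRUG"].dose_to_umol(dose_mg)
        scenario = mono_scenario(dose=dose_mg, route="oral", interval=24.0,
                                 n_doses=None)
        ss = simulate_to_steady_state(net, ref_ind, scenario, rtol=1e-8,
                                      atol=1e-11, points_per_interval=200)
        assert ss.converged
        assert ss.auc_ss == pytest.approx(dose_umol / cl, rel=0.01)

    def test_requires_repeated_regimen(self, ref_ind):
        net = renal_only_net()
        with pytest.raises(DomainError):
            simulate_to_steady_state(net, ref_ind,
                                     mono_scenario(dose=10.0, n_doses=1))


class TestProfiles:
    def test_profile_invariants(self, fixture_net, fixture_scenarios,
                                ref_ind):
        from dataclasses import replace
        s = fixture_scenarios["ref_sens"]
        s = replace(s, victim_regimen=replace(s.victim_regimen, n_doses=1))
        system = build_ode_system(fixture_net, ref_ind, s)
        res = simulate(system, np.linspace(0, 24, 49), rtol=1e-6)
        for cid in system.compound_ids:
            prof = res.profile(cid)
            prof.check()
            assert prof.times[0] == 0.0

    def test_metabolite_is_formed(self, fixture_net, fixture_scenarios,
                                  ref_ind):
        from dataclasses import replace
        s = fixture_scenarios["ref_sens"]
        s = replace(s, victim_regimen=replace(s.victim_regimen, n_doses=1))
        system = build_ode_system(fixture_net, ref_ind, s)
        res = simulate(system, np.linspace(0, 24, 25), rtol=1e-6)
        assert res.conc("VIC_SENS_M1").max() > 0.0
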