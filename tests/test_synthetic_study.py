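import numpy as np
import pandas as pd
import pytest

from ddginet.errors import DomainError
from ddginet.network_config import NetworkModel
from ddginet.pbpk_engine import CompoundModel, Regimen
from ddginet.synthetic_study import (ARCHETYPE_KINDS, StudyArm, StudyDesign,
                                     build_fixture_network, default_enzymes,
                                     fm_recovery_design,
                                     fraction_metabolized,
                                     generate_virtual_study, load_study,
                                     make_archetype, recover_fm_from_study,
                                     resample_observation_noise, save_study)


class TestArchetypes:
    def test_determinism(self):
        a = make_archetype("sensitive_substrate", 5)
        b = make_archetype("sensitive_substrate", 5)
        assert a == b
        c = make_archetype("sensitive_substrate", 6)
        assert c != a

    @pytest.mark.parametrize("kind,lo,hi", [
        ("sensitive_substrate", 0.85, 0.95),
        ("moderate_substrate", 0.40, 0.60)])
    def test_fm_realized_by_construction(self, kind, lo, hi):
        model = make_archetype(kind, 3)
        net = NetworkModel(compounds={model.id: model},
                           enzymes=default_enzymes())
        fm = fraction_metabolized(net, model.id)
        # drawn from [lo, hi], realized within 2% of the drawn target
        assert lo - 0.02 <= fm <= hi + 0.02

    def test_mbi_schema(self):
        model = make_archetype("mbi_inhibitor", 1)
        (edge,) = [d for d in model.interactions if d["mechanism"] == "mbi"]
        assert set(edge["parameters"]) == {"ki", "kinact"}
        assert not any("emax" in d["parameters"]
                       for d in model.interactions)

    def test_downregulator_is_mixed(self):
        model = make_archetype("downregulator_inhibitor", 1)
        mechs = {d["mechanism"] for d in model.interactions}
        assert mechs == {"downregulation", "competitive"}

    def test_all_kinds_constructible(self):
        for kind in ARCHETYPE_KINDS:
            model = make_archetype(kind, 0)
            assert model.molar_mass > 0

    def test_unknown_kind(self):
        with pytest.raises(DomainError):
            make_archetype("prodrug", 0)


class TestFixtureNetwork:
    def test_mechanism_coverage(self, fixture_net):
        mechs = {e.mechanism for e in fixture_net.edges}
        assert mechs == {"competitive", "noncompetitive", "mbi",
                         "induction", "downregulation"}

    def test_metabolite_tracked(self, fixture_net):
        (link,) = fixture_net.metabolite_links
        assert link.parent == "VIC_SENS"
        assert link.metabolite == "VIC_SENS_M1"
        assert 0 < link.fraction <= 1

    def test_scenario_roster(self, fixture_net):
        labels = {s.label for s in fixture_net.scenarios}
        assert {"ref_sens", "dgi_pm", "ddi_comp", "ddgi_mbi"} <= labels

    def test_determinism(self):
        assert build_fixture_network(0) == build_fixture_network(0)


def quick_design(victim="VIC_SENS", n=3, times=None, arms=("nm", "pm")):
    times = list(times) if times is not None \
        else np.linspace(1.0, 48.0, 13).tolist()
    single = Regimen(dose_amount=10.0, route="oral", n_doses=1)
    as_map = {"nm": 2.0, "pm": 0.0}
    return StudyDesign(
        victim=victim,
        arms=[StudyArm(f"{a}_mono", as_map[a], single, [], times,
                       is_reference=(a == "nm")) for a in arms],
        n_per_arm=n)


class TestVirtualStudies:
    def test_zero_noise_observed_equals_truth(self, fixture_net):
        study = generate_virtual_study(fixture_net, quick_design(),
                                       noise_gsd=1.0, seed=4)
        truth = pd.DataFrame(study.truth["noiseless"])
        assert np.allclose(study.observed["conc"], truth["conc"])

    def test_determinism(self, fixture_net):
        a = generate_virtual_study(fixture_net, quick_design(),
                                   noise_gsd=1.3, seed=9)
        b = generate_virtual_study(fixture_net, quick_design(),
                                   noise_gsd=1.3, seed=9)
        pd.testing.assert_frame_equal(a.observed, b.observed)

    def test_noise_gsd_recovery(self, fixture_net):
        """Observed/truth ratios across 200 sampling points recover the
        prescribed noise GSD of 1.2 within Monte-Carlo tolerance."""
        design = quick_design(n=2, times=np.linspace(0.5, 36.0, 200),
                              arms=("nm",))
        study = generate_virtual_study(fixture_net, design, noise_gsd=1.2,
                                       seed=21)
        truth = pd.DataFrame(study.truth["noiseless"])
        ratio = study.observed["conc"].to_numpy() / truth["conc"].to_numpy()
        gsd = np.exp(np.log(ratio).std(ddof=1))
        assert 1.17 <= gsd <= 1.23

    def test_resample_preserves_truth(self, fixture_net):
        study = generate_virtual_study(fixture_net, quick_design(),
                                       noise_gsd=1.2, seed=2)
        rep = resample_observation_noise(study, seed=77)
        assert rep.truth is study.truth
        assert not np.allclose(rep.observed["conc"], study.observed["conc"])
        rep2 = resample_observation_noise(study, seed=77)
        assert np.allclose(rep.observed["conc"], rep2.observed["conc"])

    def test_save_load_roundtrip(self, fixture_net, tmp_path):
        study = generate_virtual_study(fixture_net, quick_design(),
                                       noise_gsd=1.2, seed=2)
        save_study(study, tmp_path / "study")
        back = load_study(tmp_path / "study")
        assert back.design == study.design
        pd.testing.assert_frame_equal(back.observed, study.observed)
        assert back.truth["noise_gsd"] == study.truth["noise_gsd"]


class TestFmRecovery:
    def test_noiseless_recovery(self, fixture_net):
        """A noiseless PM/NM study recovers the victim's CYP2D6-metabolized
        fraction within 0.02 of the flux-accounting truth."""
        truth_fm = fraction_metabolized(fixture_net, "VIC_SENS")
        study = generate_virtual_study(
            fixture_net, fm_recovery_design(n_per_arm=12), noise_gsd=1.0,
            seed=8)
        est = recover_fm_from_study(study)
        assert est.fm == pytest.approx(truth_fm, abs=0.02)
        assert est.ci_low == est.ci_high == est.fm

    def test_null_fm_for_non_cyp2d6_victim(self):
        """A victim without a CYP2D6 pathway: estimated fm within 0.05 of
        zero."""
        victim = CompoundModel(id="DRUG", molar_mass=300.0, fu_plasma=0.5,
                               ka=1.0, renal_cl=5.0)
        net = NetworkModel(compounds={"DRUG": victim},
                           enzymes=default_enzymes())
        study = generate_virtual_study(
            net, quick_design(victim="DRUG", n=4), noise_gsd=1.0, seed=3)
        est = recover_fm_from_study(study)
        assert abs(est.fm) <= 0.05

    def test_missing_arm_rejected(self, fixture_net):
        study = generate_virtual_study(
            fixture_net, quick_design(arms=("nm",)), noise_gsd=1.0, seed=1)
        with pytest.raises(DomainError):
            recover_fm_from_study(study)

    def test_bootstrap_interval_brackets_noisy_estimate(self, fixture_net):
        study = generate_virtual_study(
            fixture_net, fm_recovery_design(n_per_arm=6), noise_gsd=1.2,
            seed=13)
        est = recover_fm_from_study(study, n_boot=100, seed=5)
        assert est.ci_low < est.ci_high
        assert est.ci_low < est.fm < est.ci_high
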