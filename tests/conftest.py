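"""Shared fixtures: the archetype network and small purpose-built nets
with known closed-form behavior."""

from __future__ import annotations

import pytest

from ddginet.network_config import NetworkModel, ScenarioSpec
from ddginet.pbpk_engine import (CompoundModel, MetabolicPathway, Regimen)
from ddginet.physiology import make_reference_individual
from ddginet.synthetic_study import build_fixture_network, default_enzymes

FIXTURE_SEED = 0


@pytest.fixture(scope="session")
def fixture_net():
    return build_fixture_network(FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_scenarios(fixture_net):
    return {s.label: s for s in fixture_net.scenarios}


@pytest.fixture
def ref_ind():
    return make_reference_individual()


def renal_only_compound(cid: str = "DRUG", cl: float = 5.0,
                        fu: float = 1.0, ka: float = 1.0) -> CompoundModel:
    """A compound cleared exclusively by the kidney: linear PK with
    CL = fu * renal_cl and unit tissue partitioning."""
    return CompoundModel(id=cid, molar_mass=300.0, fu_plasma=fu, ka=ka,
                         kp={}, pathways=[], renal_cl=cl)


def renal_only_net(cl: float = 5.0, fu: float = 1.0,
                   ka: float = 1.0) -> NetworkModel:
    return NetworkModel(compounds={"DRUG": renal_only_compound(
        cl=cl, fu=fu, ka=ka)}, enzymes=default_enzymes())


def cyp2d6_victim_net(vmax: float = 30.0, km: float = 10.0,
                      renal: float = 2.0, fu: float = 0.3) -> NetworkModel:
    """Victim cleared by a hepatic CYP2D6 pathway plus the kidney."""
    victim = CompoundModel(
        id="VIC", molar_mass=300.0, fu_plasma=fu, ka=1.0,
        kp={"liver": 2.0, "peripheral": 2.0, "gut_wall": 1.5},
        pathways=[MetabolicPathway(id="cyp2d6", enzyme="CYP2D6",
                                   site="liver", vmax=vmax, km=km)],
        renal_cl=renal)
    return NetworkModel(compounds={"VIC": victim}, enzymes=default_enzymes())


def mono_scenario(cid: str = "DRUG", dose: float = 10.0, route: str = "iv",
                  as_value: float = 2.0, interval=None, n_doses=1,
                  label: str = "test") -> ScenarioSpec:
    return ScenarioSpec(
        victim=cid,
        victim_regimen=Regimen(dose_amount=dose, route=route,
                               interval=interval, n_doses=n_doses),
        activity_score=as_value, label=label)


def pure_cyp2d6_net() -> NetworkModel:
    """Linear victim cleared only by hepatic CYP2D6 (sub-Km): for oral
    dosing AUC_ss = Dose / (fu * CLint), so at activity score 1 the
    exposure exactly doubles and the exposure-matching dose is 50%."""
    from ddginet.synthetic_study import default_enzymes
    victim = CompoundModel(
        id="VIC", molar_mass=300.0, fu_plasma=0.2, ka=1.0,
        kp={"liver": 1.5, "peripheral": 1.5, "gut_wall": 1.2},
        pathways=[MetabolicPathway(id="cyp2d6", enzyme="CYP2D6",
                                   site="liver", vmax=300.0, km=20.0)],
        renal_cl=0.0)
    return NetworkModel(compounds={"VIC": victim},
                        enzymes=default_enzymes())


def total_volume(ind) -> float:
    return float(sum(ind.compartment_volumes.values()))


def fast_distribution_individual(factor: float = 300.0):
    """Reference individual with perfusion scaled up so the whole body
    behaves as a single well-mixed compartment (for one-compartment
    closed-form oracles)."""
    ind = make_reference_individual()
    for k in ind.blood_flows:
        ind.blood_flows[k] *= factor
    return ind
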