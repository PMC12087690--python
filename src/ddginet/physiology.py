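"""Virtual individuals and populations.

Demographics are mapped onto the minimal whole-body compartment set
(gut wall, liver, central, peripheral) using a shipped per-kg physiology
table. Organ volumes scale linearly with body weight, perfusion rates
allometrically with exponent 0.75. Between-subject variability in enzyme
and transporter abundance is log-normal (median 1, configurable geometric
SD), and CYP2D6 genotype enters as an activity score (AS): the reference
normal-metabolizer genotype AS = 2 leaves activity unchanged, and the
abundance multiplier scales linearly as AS / 2, which makes AS = 0 a null
pathway (poor metabolizer).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError

REFERENCE_BODY_WEIGHT_KG = 73.0
REFERENCE_AS = 2.0
CYP2D6 = "CYP2D6"

_FLOW_KEYS = {"gut_wall": "gut_wall", "liver": "hepatic_artery",
              "peripheral": "peripheral"}


def _load_defaults() -> pd.DataFrame:
    ref = importlib.resources.files("ddginet") / "data" / "physiology_defaults.csv"
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#").set_index("organ")


_DEFAULTS = _load_defaults()


@dataclass
class Individual:
    """One virtual subject: demographics, physiology and enzyme activity.

    ``enzyme_multipliers`` are dimensionless factors on baseline enzyme
    abundance (1 = reference); the CYP2D6 entry carries both expression
    variability and the activity-score factor. ``blood_flows`` holds the
    perfusion rate per lumped tissue plus the ``total`` perfusion, which by
    construction equals the sum of the tissue flows.
    """

    sex: str
    age: float
    body_weight: float
    height: float
    compartment_volumes: dict[str, float]
    blood_flows: dict[str, float]
    enzyme_multipliers: dict[str, float] = field(default_factory=dict)
    fu_overrides: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "Individual":
        return replace(
            self,
            compartment_volumes=dict(self.compartment_volumes),
            blood_flows=dict(self.blood_flows),
            enzyme_multipliers=dict(self.enzyme_multipliers),
            fu_overrides=dict(self.fu_overrides),
        )

    def check(self) -> None:
        """Raise :class:`DomainError` on any violated invariant."""
        for name, v in self.compartment_volumes.items():
            if v <= 0:
                raise DomainError(f"volume of {name} must be positive")
        for name, q in self.blood_flows.items():
            if q <= 0:
                raise DomainError(f"flow {name} must be positive")
        tissue = sum(q for k, q in self.blood_flows.items() if k != "total")
        if abs(tissue - self.blood_flows["total"]) > 1e-9 * self.blood_flows["total"]:
            raise DomainError("tissue flows do not sum to total perfusion")
        for e, m in self.enzyme_multipliers.items():
            if m < 0:
                raise DomainError(f"enzyme multiplier {e} must be >= 0")


@dataclass
class PopulationSpec:
    """Sampling specification for a virtual population."""

    n: int
    age_range: tuple[float, float] = (20.0, 50.0)
    weight_range: tuple[float, float] = (60.0, 90.0)
    height_range: tuple[float, float] = (160.0, 190.0)
    sex_ratio: float = 0.5  # fraction male
    enzyme_gsd: dict[str, float] = field(default_factory=dict)
    #: either a fixed AS (float) or a mapping AS value -> proportion
    activity_score_distribution: float | dict[float, float] = REFERENCE_AS
    seed: int = 0

    def check(self) -> None:
        if self.n < 1:
            raise DomainError("population size n must be >= 1")
        for name, (lo, hi) in (("age", self.age_range),
                               ("weight", self.weight_range),
                               ("height", self.height_range)):
            if hi < lo:
                raise DomainError(f"{name}_range is inverted")
            if lo <= 0:
                raise DomainError(f"{name}_range must be positive")
        for e, g in self.enzyme_gsd.items():
            if g < 1:
                raise DomainError(f"geometric SD for {e} must be >= 1")
        if isinstance(self.activity_score_distribution, dict):
            tot = sum(self.activity_score_distribution.values())
            if abs(tot - 1.0) > 1e-9:
                raise DomainError("activity score proportions must sum to 1")
            if any(a < 0 for a in self.activity_score_distribution):
                raise DomainError("activity scores must be >= 0")


@dataclass
class Population:
    individuals: list[Individual]
    spec: PopulationSpec
    seed: int

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)


def default_volumes(body_weight: float) -> dict[str, float]:
    return {o: float(_DEFAULTS.loc[o, "volume_l_per_kg"]) * body_weight
            for o in _DEFAULTS.index}


def default_flows(body_weight: float) -> dict[str, float]:
    scale = (body_weight / REFERENCE_BODY_WEIGHT_KG) ** 0.75
    flows = {}
    for organ, key in _FLOW_KEYS.items():
        flows[key] = float(_DEFAULTS.loc[organ, "flow_l_per_h_at_ref"]) * scale
    flows["total"] = sum(flows.values())
    return flows


def make_reference_individual(
    enzymes: tuple[str, ...] = (CYP2D6, "CYP3A4", "PGP"),
) -> Individual:
    """The deterministic reference subject used for dose adaptations:
    a European male, 30 years, 73 kg, 176 cm, with all enzyme abundances at
    baseline (multiplier 1, i.e. CYP2D6 activity score 2)."""
    ind = Individual(
        sex="male",
        age=30.0,
        body_weight=73.0,
        height=176.0,
        compartment_volumes=default_volumes(73.0),
        blood_flows=default_flows(73.0),
        enzyme_multipliers={e: 1.0 for e in enzymes},
    )
    ind.check()
    return ind


def apply_activity_score(ind: Individual, as_value: float) -> Individual:
    """Return a copy of ``ind`` with CYP2D6 activity scaled by AS / 2.

    The factor multiplies the prior CYP2D6 multiplier, so expression
    variability sampled for a population is preserved and the operation is
    linear in AS (applying AS a then scaling by c equals applying a * c).
    """
    if as_value < 0:
        raise DomainError("activity score must be >= 0")
    out = ind.copy()
    prior = out.enzyme_multipliers.get(CYP2D6, 1.0)
    out.enzyme_multipliers[CYP2D6] = prior * as_value / REFERENCE_AS
    return out


def phenotype_of(as_value: float) -> str:
    """Map a CYP2D6 activity score to a phenotype label (CPIC-style bands):
    PM at 0, IM in (0, 1], NM in (1, 2.25], UM above 2.25."""
    if as_value < 0:
        raise DomainError("activity score must be >= 0")
    if as_value == 0:
        return "PM"
    if as_value <= 1:
        return "IM"
    if as_value <= 2.25:
        return "NM"
    return "UM"


def sample_population(spec: PopulationSpec) -> Population:
    """Draw a reproducible virtual population.

    Demographics are uniform within the spec ranges. Volumes scale linearly
    with body weight and flows with body weight^0.75. Enzyme multipliers are
    log-normal with median 1 and the stated geometric SD, and the CYP2D6
    multiplier is additionally scaled by the sampled activity score / 2.
    """
    spec.check()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    ages = rng.uniform(*spec.age_range, n)
    weights = rng.uniform(*spec.weight_range, n)
    heights = rng.uniform(*spec.height_range, n)
    sexes = np.where(rng.random(n) < spec.sex_ratio, "male", "female")

    gsd_map = dict(spec.enzyme_gsd)
    mult_draws = {
        e: rng.lognormal(mean=0.0, sigma=np.log(g), size=n) if g > 1
        else np.ones(n)
        for e, g in gsd_map.items()
    }

    asd = spec.activity_score_distribution
    if isinstance(asd, dict):
        levels = np.array(sorted(asd))
        probs = np.array([asd[a] for a in levels], dtype=float)
        as_values = rng.choice(levels, size=n, p=probs / probs.sum())
    else:
        if asd < 0:
            raise DomainError("activity score must be >= 0")
        as_values = np.full(n, float(asd))

    individuals = []
    for i in range(n):
        mult = {e: float(draw[i]) for e, draw in mult_draws.items()}
        mult.setdefault(CYP2D6, 1.0)
        ind = Individual(
            sex=str(sexes[i]),
            age=float(ages[i]),
            body_weight=float(weights[i]),
            height=float(heights[i]),
            compartment_volumes=default_volumes(float(weights[i])),
            blood_flows=default_flows(float(weights[i])),
            enzyme_multipliers=mult,
        )
        ind = apply_activity_score(ind, float(as_values[i]))
        ind.check()
        individuals.append(ind)
    return Population(individuals=individuals, spec=spec, seed=spec.seed)
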