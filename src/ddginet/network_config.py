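"""Declarative DDGI network configuration: schema, validation, scenarios.

A network document is a single versioned JSON object (YAML is accepted as a
convenience dialect of the same schema) with ``compounds``, ``enzymes``,
``edges``, ``metabolite_links`` and optional ``scenarios`` sections; the
field-by-field schema is documented in ``docs/schema.md``. Internally all
math is in µmol / L / h; doses are declared in mg and converted using the
compound's molar mass when the dosing schedule is compiled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence, Union

import yaml

from .errors import ConfigError, DomainError, NetworkReferenceError
from .pbpk_engine import CompoundModel, MetabolicPathway, PgpParams, Regimen

SCHEMA_VERSION = 1

MECHANISMS = ("competitive", "noncompetitive", "mbi", "induction",
              "downregulation")

#: required positive parameters per interaction mechanism
MECHANISM_PARAMS = {
    "competitive": ("ki",),
    "noncompetitive": ("ki",),
    "mbi": ("ki", "kinact"),
    "induction": ("ec50", "emax"),
    "downregulation": ("ic50", "imax"),
}

#: activity scores used throughout for scenario grids (extensible)
DEFAULT_AS_GRID = (0.0, 0.25, 0.5, 1.0, 1.25, 1.5, 2.0, 3.0)


@dataclass
class EnzymeSpec:
    name: str
    sites: tuple[str, ...]
    kdeg: float                     # 1/h turnover
    baseline_abundance: float = 1.0


@dataclass
class InteractionEdge:
    perpetrator: str
    target: str
    mechanism: str
    parameters: dict[str, float]


@dataclass
class MetaboliteLink:
    parent: str
    pathway: str
    metabolite: str
    fraction: float


@dataclass
class ScenarioSpec:
    victim: str
    victim_regimen: Regimen
    perpetrators: list[tuple[str, Regimen]] = field(default_factory=list)
    activity_score: float = 2.0
    population_ref: str = "reference"
    label: str = ""


@dataclass
class NetworkModel:
    compounds: dict[str, CompoundModel] = field(default_factory=dict)
    enzymes: dict[str, EnzymeSpec] = field(default_factory=dict)
    edges: list[InteractionEdge] = field(default_factory=list)
    metabolite_links: list[MetaboliteLink] = field(default_factory=list)
    scenarios: list[ScenarioSpec] = field(default_factory=list)


@dataclass
class Violation:
    """One broken invariant; ``kind`` is ``reference`` (dangling id) or
    ``domain`` (value outside its mathematical domain)."""

    entity: str
    rule: str
    kind: str = "domain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity}: {self.rule}"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _metabolite_cycle(links: Sequence[MetaboliteLink]) -> Optional[list[str]]:
    """Return one compound cycle in the parent -> metabolite graph, if any
    (depth-first search with a grey/black coloring)."""
    adj: dict[str, list[str]] = {}
    for l in links:
        adj.setdefault(l.parent, []).append(l.metabolite)
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    stack_trace: list[str] = []

    def visit(node: str) -> Optional[list[str]]:
        color[node] = GREY
        stack_trace.append(node)
        for nxt in adj.get(node, ()):
            c = color.get(nxt, WHITE)
            if c == GREY:
                return stack_trace[stack_trace.index(nxt):] + [nxt]
            if c == WHITE:
                found = visit(nxt)
                if found:
                    return found
        stack_trace.pop()
        color[node] = BLACK
        return None

    for start in adj:
        if color.get(start, WHITE) == WHITE:
            found = visit(start)
            if found:
                return found
    return None


def validate_network(net: NetworkModel) -> list[Violation]:
    """Check every type invariant; violations are returned as data (an
    empty list means the network is valid)."""
    v: list[Violation] = []

    for name, enz in net.enzymes.items():
        ent = f"enzyme {name}"
        if enz.kdeg <= 0:
            v.append(Violation(ent, "kdeg must be > 0"))
        if enz.baseline_abundance <= 0:
            v.append(Violation(ent, "baseline_abundance must be > 0"))
        if not enz.sites:
            v.append(Violation(ent, "sites must be non-empty"))

    for cid, c in net.compounds.items():
        ent = f"compound {cid}"
        if c.molar_mass <= 0:
            v.append(Violation(ent, "molar_mass must be > 0"))
        if not (0 < c.fu_plasma <= 1):
            v.append(Violation(ent, "fu_plasma must be in (0, 1]"))
        if c.ka <= 0:
            v.append(Violation(ent, "ka must be > 0"))
        if not (0 < c.f_dissolved <= 1):
            v.append(Violation(ent, "f_dissolved must be in (0, 1]"))
        if c.renal_cl < 0:
            v.append(Violation(ent, "renal_cl must be >= 0"))
        for tissue, kp in c.kp.items():
            if kp <= 0:
                v.append(Violation(ent, f"Kp[{tissue}] must be > 0"))
        if c.pgp_substrate is not None:
            if c.pgp_substrate.vmax <= 0 or c.pgp_substrate.km <= 0:
                v.append(Violation(ent, "P-gp Vmax and Km must be > 0"))
        for pw in c.pathways:
            pent = f"compound {cid} pathway {pw.id}"
            if pw.vmax <= 0:
                v.append(Violation(pent, "Vmax must be > 0"))
            if pw.km <= 0:
                v.append(Violation(pent, "Km must be > 0"))
            if pw.enzyme not in net.enzymes:
                v.append(Violation(pent, f"unknown enzyme {pw.enzyme!r}",
                                   kind="reference"))
            elif pw.site not in net.enzymes[pw.enzyme].sites:
                v.append(Violation(
                    pent, f"enzyme {pw.enzyme!r} is not active at site "
                          f"{pw.site!r}", kind="reference"))

    for i, e in enumerate(net.edges):
        ent = f"edge[{i}] {e.perpetrator}->{e.target}"
        if e.perpetrator not in net.compounds:
            v.append(Violation(ent, f"unknown perpetrator {e.perpetrator!r}",
                               kind="reference"))
        if e.target not in net.enzymes:
            v.append(Violation(ent, f"unknown target enzyme {e.target!r}",
                               kind="reference"))
        if e.mechanism not in MECHANISMS:
            v.append(Violation(ent, f"unknown mechanism {e.mechanism!r}"))
            continue
        for p in MECHANISM_PARAMS[e.mechanism]:
            if p not in e.parameters:
                v.append(Violation(ent, f"missing parameter {p!r}"))
            elif not e.parameters[p] > 0 and not (
                    e.mechanism == "induction" and p == "emax"
                    and e.parameters[p] >= 0):
                v.append(Violation(ent, f"parameter {p!r} must be positive"))
        if e.mechanism == "downregulation":
            imax = e.parameters.get("imax")
            if imax is not None and not (0 < imax <= 1):
                v.append(Violation(ent, "imax must be in (0, 1]"))

    pathway_ids = {(cid, pw.id) for cid, c in net.compounds.items()
                   for pw in c.pathways}
    for i, l in enumerate(net.metabolite_links):
        ent = f"metabolite_link[{i}] {l.parent}->{l.metabolite}"
        if l.parent not in net.compounds:
            v.append(Violation(ent, f"unknown parent {l.parent!r}",
                               kind="reference"))
        elif (l.parent, l.pathway) not in pathway_ids:
            v.append(Violation(ent, f"unknown pathway {l.pathway!r}",
                               kind="reference"))
        if l.metabolite not in net.compounds:
            v.append(Violation(ent, f"unknown metabolite {l.metabolite!r}",
                               kind="reference"))
        if not (0 < l.fraction <= 1):
            v.append(Violation(ent, "fraction must be in (0, 1]"))
    cycle = _metabolite_cycle(net.metabolite_links)
    if cycle:
        v.append(Violation("metabolite_links",
                           "cycle " + " -> ".join(cycle)))

    for i, s in enumerate(net.scenarios):
        ent = f"scenario[{i}] {s.label or s.victim}"
        if s.victim not in net.compounds:
            v.append(Violation(ent, f"unknown victim {s.victim!r}",
                               kind="reference"))
        for pid, _ in s.perpetrators:
            if pid not in net.compounds:
                v.append(Violation(ent, f"unknown perpetrator {pid!r}",
                                   kind="reference"))
            if pid == s.victim:
                v.append(Violation(ent, "victim cannot be its own perpetrator"))
        if s.activity_score < 0:
            v.append(Violation(ent, "activity_score must be >= 0"))
    return v


# ---------------------------------------------------------------------------
# document parsing / serialization
# ---------------------------------------------------------------------------

def _req(obj: dict, key: str, path: str) -> Any:
    if key not in obj:
        raise ConfigError(f"{path}.{key}: missing required field")
    return obj[key]


def _regimen_from_doc(doc: dict, path: str) -> Regimen:
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: regimen must be an object")
    reg = Regimen(
        dose_amount=float(_req(doc, "dose_amount_mg", path)),
        route=doc.get("route", "oral"),
        interval=(None if doc.get("interval_h") is None
                  else float(doc["interval_h"])),
        n_doses=(None if doc.get("n_doses", 1) is None
                 else int(doc.get("n_doses", 1))),
        start_time=float(doc.get("start_time_h", 0.0)),
    )
    try:
        reg.check()
    except DomainError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    return reg


def _regimen_to_doc(reg: Regimen) -> dict:
    return {"dose_amount_mg": reg.dose_amount, "route": reg.route,
            "interval_h": reg.interval, "n_doses": reg.n_doses,
            "start_time_h": reg.start_time}


def load_network(source: Union[str, Path, dict]) -> NetworkModel:
    """Parse and fully validate a network document.

    ``source`` may be a path to a ``.json``/``.yaml`` file or an already
    parsed mapping. Raises :class:`ConfigError` for schema violations
    (message names the offending path), :class:`NetworkReferenceError` for
    dangling references and :class:`DomainError` for out-of-domain
    constants.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    else:
        doc = source
    if not isinstance(doc, dict):
        raise ConfigError("$: document must be a mapping")
    version = doc.get("version")
    if version is None:
        raise ConfigError("$.version: missing required field")
    if int(version) != SCHEMA_VERSION:
        raise ConfigError(f"$.version: unsupported schema version {version}")

    net = NetworkModel()
    for name, edoc in _req(doc, "enzymes", "$").items():
        p = f"$.enzymes.{name}"
        net.enzymes[name] = EnzymeSpec(
            name=name,
            sites=tuple(_req(edoc, "sites", p)),
            kdeg=float(_req(edoc, "kdeg", p)),
            baseline_abundance=float(edoc.get("baseline_abundance", 1.0)),
        )
    for cid, cdoc in _req(doc, "compounds", "$").items():
        p = f"$.compounds.{cid}"
        pgp = cdoc.get("pgp_substrate")
        pathways = []
        for k, pwdoc in enumerate(cdoc.get("pathways", [])):
            pp = f"{p}.pathways[{k}]"
            pathways.append(MetabolicPathway(
                id=_req(pwdoc, "id", pp),
                enzyme=_req(pwdoc, "enzyme", pp),
                site=_req(pwdoc, "site", pp),
                vmax=float(_req(pwdoc, "vmax", pp)),
                km=float(_req(pwdoc, "km", pp)),
                metabolite=pwdoc.get("metabolite"),
            ))
        net.compounds[cid] = CompoundModel(
            id=cid,
            molar_mass=float(_req(cdoc, "molar_mass", p)),
            fu_plasma=float(_req(cdoc, "fu_plasma", p)),
            ka=float(cdoc.get("ka", 1.0)),
            f_dissolved=float(cdoc.get("f_dissolved", 1.0)),
            kp={k: float(x) for k, x in cdoc.get("kp", {}).items()},
            pathways=pathways,
            renal_cl=float(cdoc.get("renal_cl", 0.0)),
            pgp_substrate=(None if pgp is None else PgpParams(
                vmax=float(_req(pgp, "vmax", f"{p}.pgp_substrate")),
                km=float(_req(pgp, "km", f"{p}.pgp_substrate")))),
            interactions=[
                {"target": d["target"], "mechanism": d["mechanism"],
                 "parameters": {k: float(x)
                                for k, x in d["parameters"].items()}}
                for d in cdoc.get("interactions", [])],
        )
    for i, edoc in enumerate(doc.get("edges", [])):
        p = f"$.edges[{i}]"
        net.edges.append(InteractionEdge(
            perpetrator=_req(edoc, "perpetrator", p),
            target=_req(edoc, "target", p),
            mechanism=_req(edoc, "mechanism", p),
            parameters={k: float(x)
                        for k, x in _req(edoc, "parameters", p).items()},
        ))
    for i, ldoc in enumerate(doc.get("metabolite_links", [])):
        p = f"$.metabolite_links[{i}]"
        net.metabolite_links.append(MetaboliteLink(
            parent=_req(ldoc, "parent", p),
            pathway=_req(ldoc, "pathway", p),
            metabolite=_req(ldoc, "metabolite", p),
            fraction=float(_req(ldoc, "fraction", p)),
        ))
    for i, sdoc in enumerate(doc.get("scenarios", [])):
        p = f"$.scenarios[{i}]"
        net.scenarios.append(ScenarioSpec(
            victim=_req(sdoc, "victim", p),
            victim_regimen=_regimen_from_doc(
                _req(sdoc, "victim_regimen", p), f"{p}.victim_regimen"),
            perpetrators=[
                (_req(pd, "compound", f"{p}.perpetrators[{j}]"),
                 _regimen_from_doc(_req(pd, "regimen",
                                        f"{p}.perpetrators[{j}]"),
                                   f"{p}.perpetrators[{j}].regimen"))
                for j, pd in enumerate(sdoc.get("perpetrators", []))],
            activity_score=float(sdoc.get("activity_score", 2.0)),
            population_ref=sdoc.get("population", "reference"),
            label=sdoc.get("label", ""),
        ))

    violations = validate_network(net)
    if violations:
        msg = "; ".join(str(x) for x in violations)
        if any(x.kind == "reference" for x in violations):
            raise NetworkReferenceError(msg)
        raise DomainError(msg)
    return net


def network_to_dict(net: NetworkModel) -> dict:
    """Serialize to the normalized document form (JSON-ready)."""
    return {
        "version": SCHEMA_VERSION,
        "enzymes": {
            name: {"sites": list(e.sites), "kdeg": e.kdeg,
                   "baseline_abundance": e.baseline_abundance}
            for name, e in net.enzymes.items()},
        "compounds": {
            cid: {
                "molar_mass": c.molar_mass,
                "fu_plasma": c.fu_plasma,
                "ka": c.ka,
                "f_dissolved": c.f_dissolved,
                "kp": dict(c.kp),
                "renal_cl": c.renal_cl,
                "pgp_substrate": (None if c.pgp_substrate is None else
                                  {"vmax": c.pgp_substrate.vmax,
                                   "km": c.pgp_substrate.km}),
                "interactions": [
                    {"target": d["target"], "mechanism": d["mechanism"],
                     "parameters": dict(d["parameters"])}
                    for d in c.interactions],
                "pathways": [
                    {"id": pw.id, "enzyme": pw.enzyme, "site": pw.site,
                     "vmax": pw.vmax, "km": pw.km,
                     "metabolite": pw.metabolite}
                    for pw in c.pathways],
            } for cid, c in net.compounds.items()},
        "edges": [
            {"perpetrator": e.perpetrator, "target": e.target,
             "mechanism": e.mechanism, "parameters": dict(e.parameters)}
            for e in net.edges],
        "metabolite_links": [
            {"parent": l.parent, "pathway": l.pathway,
             "metabolite": l.metabolite, "fraction": l.fraction}
            for l in net.metabolite_links],
        "scenarios": [
            {"label": s.label, "victim": s.victim,
             "victim_regimen": _regimen_to_doc(s.victim_regimen),
             "perpetrators": [
                 {"compound": pid, "regimen": _regimen_to_doc(reg)}
                 for pid, reg in s.perpetrators],
             "activity_score": s.activity_score,
             "population": s.population_ref}
            for s in net.scenarios],
    }


def save_network(net: NetworkModel, path: Union[str, Path]) -> None:
    path = Path(path)
    doc = network_to_dict(net)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# scenario enumeration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioGrid:
    """Cross-product specification: one victim, a list of activity scores
    and an explicit list of perpetrator combinations (use ``[]`` inside
    ``perpetrator_sets`` for monotherapy)."""

    victim: str
    victim_regimen: Regimen
    as_values: Sequence[float] = DEFAULT_AS_GRID
    perpetrator_sets: Sequence[Sequence[tuple[str, Regimen]]] = ((),)


def enumerate_scenarios(net: NetworkModel,
                        grid: ScenarioGrid) -> list[ScenarioSpec]:
    """Deterministic cross-product of activity scores and perpetrator
    combinations: AS ascending, then perpetrator sets in lexicographic
    order of their compound-id tuples."""
    if len(grid.as_values) == 0:
        raise DomainError("activity-score grid must not be empty")
    if grid.victim not in net.compounds:
        raise NetworkReferenceError(f"unknown victim {grid.victim!r}")
    sets = sorted((tuple(ps) for ps in grid.perpetrator_sets),
                  key=lambda ps: tuple(pid for pid, _ in ps))
    out = []
    for a in sorted(grid.as_values):
        if a < 0:
            raise DomainError("activity scores must be >= 0")
        for ps in sets:
            for pid, _ in ps:
                if pid == grid.victim:
                    raise DomainError("victim cannot be its own perpetrator")
                if pid not in net.compounds:
                    raise NetworkReferenceError(f"unknown perpetrator {pid!r}")
            combo = "+".join(pid for pid, _ in ps) or "mono"
            out.append(ScenarioSpec(
                victim=grid.victim,
                victim_regimen=grid.victim_regimen,
                perpetrators=list(ps),
                activity_score=float(a),
                label=f"{grid.victim}|AS{a:g}|{combo}",
            ))
    return out
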