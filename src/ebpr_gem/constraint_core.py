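"""Stoichiometric model containers and the linear programs behind the cycle simulator.

The model here is a deliberately small constraint-based representation of a
polyphosphate-accumulating organism (PAO): a stoichiometric matrix with flux
bounds, plus explicit knowledge of which reactions are the biomass drain, the
ATP maintenance demand, the O2 exchange, the carbon-source exchanges and the
amino-acid exchanges, and which metabolites are intracellular storage pools
(PHA, glycogen, polyphosphate).

Sign conventions follow the COBRA community: exchange fluxes are negative for
uptake and positive for secretion; storage-sink fluxes are positive when the
pool accumulates and negative when it is consumed. All fluxes are in
mmol.gDW^-1.h^-1 and growth rates in h^-1.

Three solves are provided:

* :func:`solve_fba` - plain flux balance analysis (maximize/minimize one flux);
* :func:`solve_pfba` - parsimonious FBA (fix biomass at its optimum, then
  minimize total absolute flux);
* :func:`solve_min_total_flux` - minimize total absolute flux under a fixed
  substrate-uptake rate, the anaerobic "energy-efficient storage" objective.

All three are solved with HiGHS through :func:`scipy.optimize.linprog`; the L1
objective uses the standard split of every flux into two non-negative halves.
"""

from __future__ import annotations

import copy as _copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "FluxSolution",
    "ModelValidationError",
    "SBMLParseError",
    "COMPARTMENTS",
    "ROLES",
    "TAGS",
    "DEFAULT_NGAM",
    "solve_fba",
    "solve_pfba",
    "solve_min_total_flux",
    "apply_anaerobic",
    "apply_aerobic",
    "set_maintenance",
    "read_sbml",
    "write_sbml",
    "write_flux_tsv",
    "flux_solution_to_json",
]

COMPARTMENTS = ("cytosol", "extracellular", "pool")
ROLES = (
    "carbon_substrate",
    "amino_acid",
    "storage_PHA",
    "storage_glycogen",
    "storage_polyP",
    "gas",
    "ion",
    "generic",
)
TAGS = ("exchange", "transport", "internal", "ETC", "maintenance", "biomass", "storage_sink")

#: non-growth-associated maintenance, mmol ATP.gDW^-1.h^-1
DEFAULT_NGAM = 0.398

_STEADY_STATE_TOL = 1e-6
_LP_TOL = 1e-9
#: relative slack on the biomass optimum before the pFBA L1 minimization
PFBA_SLACK = 1e-6


class ModelValidationError(ValueError):
    """A model (or one of its components) violates a structural invariant."""


class SBMLParseError(ValueError):
    """An SBML document could not be interpreted as a MetabolicModel."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    carbon_atoms: int = 0
    phosphorus_atoms: int = 0
    role: str = "generic"

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(f"unknown compartment {self.compartment!r} for {self.id}")
        if self.role not in ROLES:
            raise ModelValidationError(f"unknown role {self.role!r} for {self.id}")
        if self.carbon_atoms < 0 or self.phosphorus_atoms < 0:
            raise ModelValidationError(f"negative atom count on {self.id}")
        if self.role == "ion" and self.carbon_atoms != 0:
            raise ModelValidationError(f"ion {self.id} must have carbon_atoms = 0")
        if self.role.startswith("storage_") and self.compartment != "pool":
            raise ModelValidationError(f"storage metabolite {self.id} must live in the pool compartment")


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    tags: frozenset = field(default_factory=frozenset)
    name: str = ""

    def __post_init__(self) -> None:
        self.tags = frozenset(self.tags)
        unknown = self.tags - set(TAGS)
        if unknown:
            raise ModelValidationError(f"unknown tags {sorted(unknown)} on reaction {self.id}")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > upper_bound {self.upper_bound}"
            )

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            tags=self.tags,
            name=self.name,
        )


@dataclass
class MetabolicModel:
    """A tagged stoichiometric network.

    ``o2_uptake_limit`` is the magnitude of the O2 uptake bound restored by
    :func:`apply_aerobic` (default 1000, i.e. effectively unbounded).
    """

    id: str
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    biomass_reaction: str
    maintenance_reaction: str
    o2_exchange: Optional[str] = None
    carbon_exchanges: Set[str] = field(default_factory=set)
    amino_acid_exchanges: Dict[str, str] = field(default_factory=dict)
    o2_uptake_limit: float = 1000.0

    def __post_init__(self) -> None:
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups --------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            id=self.id,
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction=self.biomass_reaction,
            maintenance_reaction=self.maintenance_reaction,
            o2_exchange=self.o2_exchange,
            carbon_exchanges=set(self.carbon_exchanges),
            amino_acid_exchanges=dict(self.amino_acid_exchanges),
            o2_uptake_limit=self.o2_uptake_limit,
        )

    def set_bounds(self, rxn_id: str, lower: float, upper: float) -> None:
        rxn = self.reaction(rxn_id)
        if lower > upper:
            raise ModelValidationError(f"{rxn_id}: lower {lower} > upper {upper}")
        rxn.lower_bound = float(lower)
        rxn.upper_bound = float(upper)

    # -- structural checks ---------------------------------------------
    def validate(self) -> None:
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id}")
            seen.add(m.id)
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelValidationError(f"duplicate reaction id {r.id}")
            seen.add(r.id)
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelValidationError(f"reaction {r.id} references unknown metabolite {met_id}")
            if "exchange" in r.tags:
                touched = [self.metabolite(m) for m in r.stoichiometry]
                ext = [m for m in touched if m.compartment == "extracellular"]
                if len(touched) != 1 or len(ext) != 1:
                    raise ModelValidationError(
                        f"exchange reaction {r.id} must touch exactly one extracellular metabolite"
                    )
            if "storage_sink" in r.tags:
                touched = [self.metabolite(m) for m in r.stoichiometry]
                pools = [m for m in touched if m.compartment == "pool"]
                if len(touched) != 1 or len(pools) != 1:
                    raise ModelValidationError(
                        f"storage sink {r.id} must touch exactly one pool metabolite"
                    )
        for attr in ("biomass_reaction", "maintenance_reaction"):
            rid = getattr(self, attr)
            if rid not in self._rxn_index:
                raise ModelValidationError(f"{attr} {rid!r} not in model")
        if "biomass" not in self.reaction(self.biomass_reaction).tags:
            raise ModelValidationError("biomass reaction is not tagged 'biomass'")
        maint = self.reaction(self.maintenance_reaction)
        if "maintenance" not in maint.tags:
            raise ModelValidationError("maintenance reaction is not tagged 'maintenance'")
        atp_coeffs = [
            c for m, c in maint.stoichiometry.items() if "atp" in m.lower() and c < 0
        ]
        if not any(abs(c + 1.0) < 1e-12 for c in atp_coeffs):
            raise ModelValidationError("maintenance reaction must consume ATP with unit stoichiometry")
        if self.o2_exchange is not None and self.o2_exchange not in self._rxn_index:
            raise ModelValidationError(f"o2_exchange {self.o2_exchange!r} not in model")
        for rid in self.carbon_exchanges:
            if rid not in self._rxn_index:
                raise ModelValidationError(f"carbon exchange {rid!r} not in model")

    # -- numerics -------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S (metabolites x reactions); every metabolite is balanced,
        with exchanges and storage sinks acting as the boundary fluxes."""
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met_id, coeff in r.stoichiometry.items():
                S[self._met_index[met_id], j] = coeff
        return S

    def bounds(self) -> List[Tuple[float, float]]:
        return [(r.lower_bound, r.upper_bound) for r in self.reactions]

    def storage_sinks(self) -> Dict[str, str]:
        """Map sink reaction id -> pool metabolite id."""
        out = {}
        for r in self.reactions:
            if "storage_sink" in r.tags:
                (met_id,) = r.stoichiometry.keys()
                out[r.id] = met_id
        return out


@dataclass
class FluxSolution:
    fluxes: Dict[str, float]
    objective_value: float
    growth_rate: float
    status: str  # "optimal" | "infeasible"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def total_absolute_flux(self) -> float:
        return float(sum(abs(v) for v in self.fluxes.values()))


_INFEASIBLE = object()


def _run_lp(
    model: MetabolicModel,
    c: np.ndarray,
    bounds: Sequence[Tuple[float, float]],
    split: bool = False,
):
    """Solve min c.v s.t. S v = 0, bounds. With ``split`` the variable vector is
    (p, q), v = p - q, both halves non-negative (L1 reformulation)."""
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    if split:
        A_eq = np.hstack([S, -S])
        var_bounds = []
        for lb, ub in bounds:
            if lb >= 0:
                var_bounds.append((lb, ub))
            else:
                var_bounds.append((0.0, max(ub, 0.0)))
        for lb, ub in bounds:
            if ub <= 0:
                var_bounds.append((-ub, -lb))
            else:
                var_bounds.append((0.0, max(-lb, 0.0)))
    else:
        A_eq = S
        var_bounds = list(bounds)
    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=var_bounds,
        method="highs",
        options={
            "primal_feasibility_tolerance": _LP_TOL,
            "dual_feasibility_tolerance": _LP_TOL,
        },
    )
    if res.status == 2:
        return _INFEASIBLE
    if res.status != 0:
        raise RuntimeError(f"LP terminated with status {res.status}: {res.message}")
    if split:
        v = res.x[:n] - res.x[n:]
    else:
        v = res.x
    return v, float(res.fun)


def _solution(model: MetabolicModel, v: Optional[np.ndarray], objective_value: float) -> FluxSolution:
    if v is None:
        return FluxSolution(fluxes={}, objective_value=math.nan, growth_rate=math.nan, status="infeasible")
    fluxes = {r.id: float(x) for r, x in zip(model.reactions, v)}
    return FluxSolution(
        fluxes=fluxes,
        objective_value=objective_value,
        growth_rate=fluxes.get(model.biomass_reaction, 0.0),
        status="optimal",
    )


def solve_fba(model: MetabolicModel, objective: Optional[str] = None, sense: str = "max") -> FluxSolution:
    """Flux balance analysis: optimize one reaction's flux at steady state.

    ``objective`` defaults to the biomass reaction. ``sense`` is "max" or "min".
    """
    if objective is None:
        objective = model.biomass_reaction
    if not model.has_reaction(objective):
        raise KeyError(f"unknown objective reaction {objective!r}")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    n = len(model.reactions)
    c = np.zeros(n)
    j = model.reaction_ids.index(objective)
    c[j] = -1.0 if sense == "max" else 1.0
    out = _run_lp(model, c, model.bounds())
    if out is _INFEASIBLE:
        return _solution(model, None, math.nan)
    v, fun = out
    obj = -fun if sense == "max" else fun
    return _solution(model, v, obj)


def solve_pfba(model: MetabolicModel, slack: float = PFBA_SLACK) -> FluxSolution:
    """Parsimonious FBA: among flux vectors within ``slack`` of the biomass
    optimum, return one minimizing the total absolute flux over all reactions.

    The returned ``objective_value`` is the minimized total |v|; the growth
    rate equals the plain FBA optimum within the slack.
    """
    base = solve_fba(model, model.biomass_reaction, "max")
    if base.status != "optimal":
        return base
    mu_opt = base.growth_rate
    fixed = model.copy()
    rxn = fixed.reaction(model.biomass_reaction)
    lo = mu_opt * (1.0 - slack) if mu_opt >= 0 else mu_opt * (1.0 + slack)
    rxn.lower_bound = max(rxn.lower_bound, lo)
    n = len(fixed.reactions)
    c = np.ones(2 * n)
    out = _run_lp(fixed, c, fixed.bounds(), split=True)
    if out is _INFEASIBLE:  # pragma: no cover - slack prevents this
        return _solution(model, None, math.nan)
    v, fun = out
    return _solution(model, v, fun)


def solve_min_total_flux(model: MetabolicModel, substrate_exchange: str, uptake_rate: float) -> FluxSolution:
    """Minimize total |v| with the substrate exchange flux fixed at ``-uptake_rate``.

    This is the anaerobic-phase objective: with no growth allowed and a fixed
    carbon feed, the least-total-flux distribution routes carbon into storage
    with the fewest enzymatic steps, approximating energy-efficient storage
    metabolism. Maintenance and all other bounds stay in force. Infeasibility
    (e.g. no route satisfying maintenance) is reported in ``status``, not
    raised.
    """
    if uptake_rate < 0:
        raise ValueError("uptake_rate must be >= 0")
    if substrate_exchange not in model.carbon_exchanges:
        raise ValueError(f"{substrate_exchange!r} is not a carbon exchange of model {model.id}")
    fixed = model.copy()
    fixed.set_bounds(substrate_exchange, -uptake_rate, -uptake_rate)
    n = len(fixed.reactions)
    c = np.ones(2 * n)
    out = _run_lp(fixed, c, fixed.bounds(), split=True)
    if out is _INFEASIBLE:
        return _solution(model, None, math.nan)
    v, fun = out
    return _solution(fixed, v, fun)


# ---------------------------------------------------------------------------
# phase constraints
# ---------------------------------------------------------------------------

def apply_anaerobic(model: MetabolicModel) -> MetabolicModel:
    """Return a copy constrained to the anaerobic phase: O2 uptake shut off
    (secretion still allowed up to the original upper bound) and every
    ETC-tagged reaction fixed to zero. Idempotent; the input is untouched."""
    out = model.copy()
    if out.o2_exchange is not None:
        rxn = out.reaction(out.o2_exchange)
        rxn.lower_bound = 0.0
        rxn.upper_bound = max(rxn.upper_bound, 0.0)
    for r in out.reactions:
        if "ETC" in r.tags:
            r.lower_bound = 0.0
            r.upper_bound = 0.0
    return out


def apply_aerobic(model: MetabolicModel) -> MetabolicModel:
    """Return a copy constrained to the aerobic phase: O2 uptake re-opened to
    the model's configured limit, every carbon-source exchange blocked for
    uptake (secretion allowed), and storage sinks opened in the pool-consuming
    direction. Amino-acid exchanges are not carbon exchanges and are left
    alone. Idempotent."""
    out = model.copy()
    if out.o2_exchange is not None:
        rxn = out.reaction(out.o2_exchange)
        rxn.lower_bound = -abs(out.o2_uptake_limit)
    for rid in out.carbon_exchanges:
        rxn = out.reaction(rid)
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
        rxn.upper_bound = max(rxn.upper_bound, 0.0)
    for r in out.reactions:
        if "storage_sink" in r.tags:
            r.lower_bound = min(r.lower_bound, -abs(out.o2_uptake_limit))
    return out


def set_maintenance(model: MetabolicModel, ngam: float = DEFAULT_NGAM) -> MetabolicModel:
    """Return a copy with the maintenance ATP demand's lower bound set to
    ``ngam`` (mmol ATP.gDW^-1.h^-1; default 0.398)."""
    if ngam < 0:
        raise ValueError("ngam must be >= 0")
    out = model.copy()
    rxn = out.reaction(out.maintenance_reaction)
    rxn.lower_bound = float(ngam)
    rxn.upper_bound = max(rxn.upper_bound, float(ngam))
    return out


# ---------------------------------------------------------------------------
# SBML I/O (Level 3 + FBC, via cobrapy/libsbml)
# ---------------------------------------------------------------------------

_COMPARTMENT_CODES = {"cytosol": "c", "extracellular": "e", "pool": "pool"}
_CODE_COMPARTMENTS = {v: k for k, v in _COMPARTMENT_CODES.items()}

#: id keywords used to tag ETC reactions when SBML annotations are absent
ETC_KEYWORDS = ("etc", "cytochrome", "oxidative_phosphorylation", "nadh_dehydrogenase")


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.id)
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id,
            name=m.name or m.id,
            compartment=_COMPARTMENT_CODES[m.compartment],
        )
        formula = ""
        if m.carbon_atoms:
            formula += f"C{m.carbon_atoms}"
        if m.phosphorus_atoms:
            formula += f"P{m.phosphorus_atoms}"
        if formula:
            cmet.formula = formula
        cmet.notes["role"] = m.role
        cmet.notes["carbon_atoms"] = str(m.carbon_atoms)
        cmet.notes["phosphorus_atoms"] = str(m.phosphorus_atoms)
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions:
        crxn = cobra.Reaction(r.id, name=r.name or r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[mid]: coeff for mid, coeff in r.stoichiometry.items()})
        crxn.notes["tags"] = ",".join(sorted(r.tags))
    cm.objective = cm.reactions.get_by_id(model.biomass_reaction)
    cm.notes["maintenance_reaction"] = model.maintenance_reaction
    cm.notes["o2_exchange"] = model.o2_exchange or ""
    cm.notes["carbon_exchanges"] = ",".join(sorted(model.carbon_exchanges))
    cm.notes["amino_acid_exchanges"] = ";".join(
        f"{aa}:{rid}" for aa, rid in sorted(model.amino_acid_exchanges.items())
    )
    cm.notes["o2_uptake_limit"] = str(model.o2_uptake_limit)
    return cm


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write the model as SBML Level 3 + FBC. Tags and roles ride along in
    notes so that :func:`read_sbml` round-trips structurally."""
    from cobra.io import write_sbml_model

    model.validate()
    write_sbml_model(_to_cobra(model), str(path))


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML Level 3 (FBC) model.

    Tags, roles and atom counts are taken from the notes written by
    :func:`write_sbml` when present; otherwise they are inferred from id
    conventions (``EX_`` prefix for exchanges, ``SINK_`` for storage sinks,
    :data:`ETC_KEYWORDS` for the electron transport chain) and metabolite
    formulas. The biomass reaction is the FBC objective; its absence is an
    error.
    """
    from cobra.io import read_sbml_model

    try:
        cm = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a mix of IO/CobraSBMLError
        raise SBMLParseError(f"could not parse SBML file {path}: {exc}") from exc

    mets = []
    for cmet in cm.metabolites:
        comp = _CODE_COMPARTMENTS.get(cmet.compartment, None)
        if comp is None:
            comp = "extracellular" if str(cmet.compartment).startswith("e") else "cytosol"
        notes = dict(cmet.notes or {})
        carbon = int(notes.get("carbon_atoms", cmet.elements.get("C", 0) if cmet.formula else 0))
        phos = int(notes.get("phosphorus_atoms", cmet.elements.get("P", 0) if cmet.formula else 0))
        role = notes.get("role", "generic")
        if role not in ROLES:
            role = "generic"
        mets.append(
            Metabolite(
                id=cmet.id,
                name=cmet.name or cmet.id,
                compartment=comp,
                carbon_atoms=carbon,
                phosphorus_atoms=phos,
                role=role,
            )
        )
    met_by_id = {m.id: m for m in mets}

    rxns = []
    biomass_id = None
    for crxn in cm.reactions:
        if crxn.objective_coefficient:
            biomass_id = crxn.id
        notes = dict(crxn.notes or {})
        if "tags" in notes:
            tags = frozenset(t for t in notes["tags"].split(",") if t)
        else:
            tags = _infer_tags(crxn, met_by_id)
        rxns.append(
            Reaction(
                id=crxn.id,
                name=crxn.name or crxn.id,
                stoichiometry={m.id: coeff for m, coeff in crxn.metabolites.items()},
                lower_bound=crxn.lower_bound,
                upper_bound=crxn.upper_bound,
                tags=tags,
            )
        )
    if biomass_id is None:
        for r in rxns:
            if "biomass" in r.tags:
                biomass_id = r.id
                break
    if biomass_id is None:
        raise SBMLParseError(f"{path}: no biomass objective in SBML (FBC objective missing)")

    model_notes = dict(cm.notes or {})
    maintenance = model_notes.get("maintenance_reaction") or _find_tagged(rxns, "maintenance")
    if maintenance is None:
        raise SBMLParseError(f"{path}: no maintenance (ATPM) reaction identified")
    o2_exchange = model_notes.get("o2_exchange") or None
    if o2_exchange is None:
        for r in rxns:
            if "exchange" in r.tags and any("o2" in m.lower() for m in r.stoichiometry):
                o2_exchange = r.id
                break
    carbon_exchanges = set(
        x for x in (model_notes.get("carbon_exchanges", "") or "").split(",") if x
    )
    if not carbon_exchanges:
        for r in rxns:
            if "exchange" in r.tags:
                (mid,) = r.stoichiometry
                m = met_by_id[mid]
                if m.role == "carbon_substrate" or (m.carbon_atoms > 0 and m.role == "generic"):
                    carbon_exchanges.add(r.id)
    aa_raw = model_notes.get("amino_acid_exchanges", "") or ""
    aa_exchanges = {}
    for item in aa_raw.split(";"):
        if ":" in item:
            aa, rid = item.split(":", 1)
            aa_exchanges[aa] = rid
    if not aa_exchanges:
        for r in rxns:
            if "exchange" in r.tags:
                (mid,) = r.stoichiometry
                if met_by_id[mid].role == "amino_acid":
                    aa_exchanges[met_by_id[mid].name or mid] = r.id

    model = MetabolicModel(
        id=cm.id or "model",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction=biomass_id,
        maintenance_reaction=maintenance,
        o2_exchange=o2_exchange,
        carbon_exchanges=carbon_exchanges,
        amino_acid_exchanges=aa_exchanges,
        o2_uptake_limit=float(model_notes.get("o2_uptake_limit", 1000.0)),
    )
    model.validate()
    return model


def _infer_tags(crxn, met_by_id) -> frozenset:
    rid = crxn.id.lower()
    tags = set()
    if len(crxn.metabolites) == 1:
        (cmet,) = crxn.metabolites
        comp = met_by_id[cmet.id].compartment
        if comp == "extracellular" or rid.startswith("ex_"):
            tags.add("exchange")
        elif comp == "pool" or rid.startswith("sink_"):
            tags.add("storage_sink")
    if any(k in rid for k in ETC_KEYWORDS):
        tags.add("ETC")
    if "atpm" in rid or "maintenance" in rid:
        tags.add("maintenance")
    if "biomass" in rid or crxn.objective_coefficient:
        tags.add("biomass")
    comps = {met_by_id[m.id].compartment for m in crxn.metabolites}
    if not tags and {"cytosol", "extracellular"} <= comps:
        tags.add("transport")
    if not tags:
        tags.add("internal")
    return frozenset(tags)


def _find_tagged(rxns: Iterable[Reaction], tag: str) -> Optional[str]:
    for r in rxns:
        if tag in r.tags:
            return r.id
    return None


# ---------------------------------------------------------------------------
# flat-file output
# ---------------------------------------------------------------------------

def write_flux_tsv(solution: FluxSolution, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("reaction_id\tflux\n")
        for rid, v in solution.fluxes.items():
            fh.write(f"{rid}\t{v:.10g}\n")


def flux_solution_to_json(solution: FluxSolution) -> dict:
    return {
        "status": solution.status,
        "objective_value": solution.objective_value,
        "growth_rate": solution.growth_rate,
        "fluxes": dict(solution.fluxes),
    }
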