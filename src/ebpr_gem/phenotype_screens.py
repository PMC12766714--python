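"""Auxotrophy, amino-acid secretion, and carbon-substrate utilization screens.

All three screens run on a defined minimal medium: one carbon source
(acetate by default), inorganic ions, and oxygen. The auxotrophy screen
opens all 20 amino-acid uptakes, then blocks each in turn and calls a model
auxotrophic for an amino acid when the predicted growth rate falls below
0.01 h^-1. The secretion screen closes amino-acid uptake, pins growth at a
fraction of its optimum and maximizes each amino acid's export flux
(flux-variability style); the substrate screen runs a full anaerobic-aerobic
cycle per model x substrate and calls a substrate utilizable when the cycle
completes with biomass yield above threshold, recording the failure stage
(missing transporter, anaerobic infeasibility, zero yield) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .constraint_core import MetabolicModel, solve_fba
from .ebpr_cycle import CycleConfig, biomass_yield, simulate_cycle

__all__ = [
    "AuxotrophyProfile",
    "SubstrateReport",
    "SecretionProfile",
    "AUXOTROPHY_THRESHOLD",
    "MINIMAL_MEDIUM_IONS",
    "set_minimal_medium",
    "screen_auxotrophy",
    "screen_secretion",
    "screen_substrates",
    "prototrophy_summary",
]

#: growth rate (h^-1) below which a model is called auxotrophic
AUXOTROPHY_THRESHOLD = 0.01

#: exchange-id stems of the inorganic ions left open in the minimal medium
MINIMAL_MEDIUM_IONS = ("nh4", "pi", "so4", "mg2", "fe2", "k", "h2o", "h")


@dataclass
class AuxotrophyProfile:
    model_id: str
    baseline_growth: float
    per_aa_growth: Dict[str, float]
    threshold: float = AUXOTROPHY_THRESHOLD

    @property
    def calls(self) -> Dict[str, str]:
        return {
            aa: ("auxotroph" if mu < self.threshold else "prototroph")
            for aa, mu in self.per_aa_growth.items()
        }

    @property
    def auxotrophies(self) -> Set[str]:
        return {aa for aa, call in self.calls.items() if call == "auxotroph"}

    @property
    def fully_prototrophic(self) -> bool:
        return not self.auxotrophies


@dataclass
class SubstrateReport:
    model_id: str
    substrate: str
    utilizable: bool
    yield_value: Optional[float]           # gDW per C-mmol, None when undefined
    failure_stage: str                     # "none" | "no_transporter" | "anaerobic_infeasible" | "zero_yield"


@dataclass
class SecretionProfile:
    model_id: str
    secretable: Set[str]
    growth_fraction: float
    flux_tol: float
    reason: str = ""


def set_minimal_medium(
    model: MetabolicModel,
    carbon_exchange: str = "EX_ac",
    carbon_bound: float = 10.0,
    aa_uptake_bound: float = 10.0,
    open_amino_acids: bool = True,
) -> MetabolicModel:
    """Return a copy on the defined minimal medium: the chosen carbon source
    plus inorganic ions and O2 open for uptake, every other carbon exchange
    closed; amino-acid uptakes open at ``aa_uptake_bound`` (the screen
    baseline) or closed."""
    out = model.copy()
    for rid in out.carbon_exchanges:
        rxn = out.reaction(rid)
        if rid == carbon_exchange:
            rxn.lower_bound = -abs(carbon_bound)
        else:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    if out.o2_exchange:
        out.reaction(out.o2_exchange).lower_bound = -abs(out.o2_uptake_limit)
    for r in out.reactions:
        if "exchange" not in r.tags:
            continue
        (mid,) = r.stoichiometry
        met = out.metabolite(mid)
        if met.role == "ion" or any(mid.lower().startswith(stem) for stem in MINIMAL_MEDIUM_IONS):
            r.lower_bound = min(r.lower_bound, -1000.0)
    for rid in out.amino_acid_exchanges.values():
        rxn = out.reaction(rid)
        rxn.lower_bound = -abs(aa_uptake_bound) if open_amino_acids else max(rxn.lower_bound, 0.0)
    # storage pools are not a medium component: block pool consumption so
    # growth is supported by the carbon source alone
    for r in out.reactions:
        if "storage_sink" in r.tags:
            r.lower_bound = max(r.lower_bound, 0.0)
    return out


def screen_auxotrophy(
    model: MetabolicModel,
    threshold: float = AUXOTROPHY_THRESHOLD,
    carbon_exchange: str = "EX_ac",
) -> AuxotrophyProfile:
    """Sequentially block each amino-acid uptake and record the growth
    optimum; one FBA solve per amino acid, all other conditions unchanged."""
    medium = set_minimal_medium(model, carbon_exchange, open_amino_acids=True)
    baseline = solve_fba(medium)
    if baseline.status != "optimal":
        raise RuntimeError(f"model {model.id}: medium cannot support the model (baseline infeasible)")
    per_aa: Dict[str, float] = {}
    for aa, rid in sorted(model.amino_acid_exchanges.items()):
        blocked = medium.copy()
        rxn = blocked.reaction(rid)
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
        sol = solve_fba(blocked)
        per_aa[aa] = sol.growth_rate if sol.status == "optimal" else 0.0
    return AuxotrophyProfile(model.id, baseline.growth_rate, per_aa, threshold)


def screen_secretion(
    model: MetabolicModel,
    growth_fraction: float = 0.5,
    flux_tol: float = 1e-6,
    carbon_exchange: str = "EX_ac",
) -> SecretionProfile:
    """Amino acids whose maximum export flux exceeds ``flux_tol`` while
    growth is held at ``growth_fraction`` of its optimum, on the minimal
    medium with amino-acid uptake closed."""
    if not model.amino_acid_exchanges:
        return SecretionProfile(model.id, set(), growth_fraction, flux_tol, "no amino-acid exchanges")
    medium = set_minimal_medium(model, carbon_exchange, open_amino_acids=False)
    base = solve_fba(medium)
    if base.status != "optimal" or base.growth_rate <= flux_tol:
        return SecretionProfile(model.id, set(), growth_fraction, flux_tol, "zero baseline growth")
    pinned = medium.copy()
    rxn = pinned.reaction(pinned.biomass_reaction)
    rxn.lower_bound = max(rxn.lower_bound, growth_fraction * base.growth_rate)
    secretable: Set[str] = set()
    for aa, rid in sorted(model.amino_acid_exchanges.items()):
        sol = solve_fba(pinned, objective=rid, sense="max")
        if sol.status == "optimal" and sol.fluxes[rid] > flux_tol:
            secretable.add(aa)
    return SecretionProfile(model.id, secretable, growth_fraction, flux_tol)


def _has_transporter(model: MetabolicModel, exchange_id: str) -> bool:
    """True when some non-exchange reaction moves the substrate's
    extracellular metabolite (i.e. a transport route exists)."""
    if not model.has_reaction(exchange_id):
        return False
    (met_id,) = model.reaction(exchange_id).stoichiometry
    for r in model.reactions:
        if r.id == exchange_id or "exchange" in r.tags:
            continue
        if met_id in r.stoichiometry:
            return True
    return False


def screen_substrates(
    models: Iterable[MetabolicModel],
    substrates: Mapping[str, str],
    config: CycleConfig,
    yield_threshold: float = 1e-6,
) -> List[SubstrateReport]:
    """One cycle simulation per model x substrate.

    ``substrates`` maps substrate name -> exchange reaction id. A substrate
    is utilizable when the cycle completes and the biomass yield exceeds
    ``yield_threshold`` gDW per C-mmol; otherwise the failure stage is
    recorded. A missing exchange or transport route is reported as
    ``no_transporter``, not raised.
    """
    reports: List[SubstrateReport] = []
    for model in models:
        for name, exchange_id in substrates.items():
            if not model.has_reaction(exchange_id) or not _has_transporter(model, exchange_id):
                reports.append(SubstrateReport(model.id, name, False, None, "no_transporter"))
                continue
            traj = simulate_cycle(model, exchange_id, config)
            if not traj.complete:
                stage = "anaerobic_infeasible" if traj.phase and _failed_anaerobic(traj) else "zero_yield"
                reports.append(SubstrateReport(model.id, name, False, None, stage))
                continue
            y = biomass_yield(traj, model, exchange_id)
            if y.value is not None and y.value > yield_threshold:
                reports.append(SubstrateReport(model.id, name, True, y.value, "none"))
            else:
                reports.append(SubstrateReport(model.id, name, False, y.value, "zero_yield"))
    return reports


def _failed_anaerobic(traj) -> bool:
    n_done = len(traj.step_fluxes)
    n_anaerobic = sum(1 for p in traj.phase[1:] if p == "anaerobic")
    # failure during the anaerobic phase: fewer completed steps than scheduled anaerobic steps
    import math

    cfg = traj.config
    scheduled = math.ceil(round(cfg.anaerobic_hours / cfg.dt, 9))
    return n_done < scheduled


def yields_table(reports: Iterable[SubstrateReport]) -> pd.DataFrame:
    """Model x substrate biomass-yield matrix (NaN where not utilizable)."""
    rows: Dict[str, Dict[str, float]] = {}
    for r in reports:
        rows.setdefault(r.model_id, {})[r.substrate] = (
            r.yield_value if r.yield_value is not None else float("nan")
        )
    return pd.DataFrame(rows).T


def prototrophy_summary(profiles: Sequence[AuxotrophyProfile]) -> Dict[str, object]:
    """Fraction of fully prototrophic models and per-amino-acid auxotroph
    counts across a collection of profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    n_full = sum(1 for p in profiles if p.fully_prototrophic)
    counts: Dict[str, int] = {}
    for p in profiles:
        for aa in p.per_aa_growth:
            counts.setdefault(aa, 0)
        for aa in p.auxotrophies:
            counts[aa] += 1
    return {
        "fraction_fully_prototrophic": n_full / len(profiles),
        "auxotroph_counts": counts,
        "n_models": len(profiles),
    }
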