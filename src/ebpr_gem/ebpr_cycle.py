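"""Time-resolved anaerobic-aerobic EBPR cycle simulation.

The cycle mimics enhanced biological phosphorus removal operation: a 1.5 h
anaerobic feed phase followed by a 3.5 h aerobic phase, stepped at 0.2 h.
At each step a linear program is solved on the quasi-steady-state metabolic
network and the explicit pools - extracellular substrate, CO2, the PHA /
glycogen / polyphosphate storage polymers and biomass - are advanced by
forward Euler:

    Q(t + dt) = Q(t) + v_Q * X(t) * dt        (pools, substrate, CO2)
    X(t + dt) = X(t) * (1 + mu * dt)          (biomass)

Anaerobic steps block O2 and the electron transport chain, fix growth to
zero, fix the substrate uptake to the configured rate (capped by remaining
substrate) and minimize total flux - energy-efficient storage metabolism
driven by polyphosphate hydrolysis. Aerobic steps block carbon uptake, open
O2 and run parsimonious FBA on stored carbon. Pool-consuming fluxes are
bounded each step so no pool can go negative; an infeasible step terminates
the trajectory with a status flag rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .constraint_core import (
    DEFAULT_NGAM,
    FluxSolution,
    MetabolicModel,
    apply_aerobic,
    apply_anaerobic,
    set_maintenance,
    solve_min_total_flux,
    solve_pfba,
)

__all__ = ["CycleConfig", "CycleTrajectory", "simulate_cycle", "biomass_yield", "carbon_balance"]

_EPS = 1e-9


@dataclass
class CycleConfig:
    """Operating parameters of one simulated EBPR cycle.

    ``uptake_rate`` is the fixed anaerobic substrate-uptake rate in
    mmol.gDW^-1.h^-1 and has no default: it is an operating choice of the
    reactor being emulated. Pool initial contents are intracellular
    (C-mmol or P-mmol per gDW); the reactor volume is fixed at 1 L so that
    extracellular mmol and mM coincide.
    """

    uptake_rate: float
    anaerobic_hours: float = 1.5
    aerobic_hours: float = 3.5
    dt: float = 0.2
    ngam: float = DEFAULT_NGAM
    initial_substrate: float = 5.0          # mmol
    initial_glycogen: float = 2.0           # C-mmol / gDW
    initial_polyP: float = 15.0             # P-mmol / gDW
    initial_PHA: float = 0.1                # C-mmol / gDW
    initial_biomass: float = 1.0            # gDW
    random_seed: int = 0                    # reserved; the core is deterministic

    def __post_init__(self) -> None:
        if self.anaerobic_hours <= 0 or self.aerobic_hours <= 0 or self.dt <= 0:
            raise ValueError("durations and dt must be positive")
        if self.dt > min(self.anaerobic_hours, self.aerobic_hours) + _EPS:
            raise ValueError("dt must not exceed either phase duration")
        if self.uptake_rate < 0:
            raise ValueError("uptake_rate must be >= 0")
        for name in ("initial_substrate", "initial_glycogen", "initial_polyP", "initial_PHA"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.initial_biomass <= 0:
            raise ValueError("initial_biomass must be > 0")


@dataclass
class CycleTrajectory:
    times: List[float]
    phase: List[str]                      # phase of the step ending at times[i] ("" at t=0)
    substrate: List[float]                # mmol
    co2: List[float]                      # mmol
    glycogen: List[float]                 # C-mmol, absolute
    polyP: List[float]                    # P-mmol, absolute
    PHA: List[float]                      # C-mmol, absolute
    biomass: List[float]                  # gDW
    step_fluxes: List[FluxSolution]
    maintenance_bounds: List[float]       # NGAM lower bound active in each step's LP
    status: str = "complete"              # "complete" | "infeasible"
    failed_step: Optional[int] = None
    config: Optional[CycleConfig] = None
    substrate_exchange: str = ""

    @property
    def complete(self) -> bool:
        return self.status == "complete"

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("time_h\tphase\tsubstrate_mmol\tco2_mmol\tglycogen\tpolyP\tPHA\tbiomass_gDW\n")
            for i in range(len(self.times)):
                fh.write(
                    f"{self.times[i]:.6g}\t{self.phase[i]}\t{self.substrate[i]:.10g}\t"
                    f"{self.co2[i]:.10g}\t{self.glycogen[i]:.10g}\t{self.polyP[i]:.10g}\t"
                    f"{self.PHA[i]:.10g}\t{self.biomass[i]:.10g}\n"
                )


def _phase_steps(hours: float, dt: float) -> List[float]:
    """Split a phase into full dt steps plus one truncated step so the
    cumulative time is exact (1.5 h at dt 0.2 -> seven 0.2 h steps + 0.1 h)."""
    n_full = int(math.floor(round(hours / dt, 9)))
    steps = [dt] * n_full
    rem = hours - n_full * dt
    if rem > 1e-9:
        steps.append(rem)
    return steps


def _pool_roles(model: MetabolicModel) -> Dict[str, Dict[str, object]]:
    """Map storage role -> {sink reaction id, atoms per pool unit}."""
    out: Dict[str, Dict[str, object]] = {}
    for sink_id, met_id in model.storage_sinks().items():
        met = model.metabolite(met_id)
        if met.role == "storage_PHA":
            out["PHA"] = {"sink": sink_id, "atoms": met.carbon_atoms}
        elif met.role == "storage_glycogen":
            out["glycogen"] = {"sink": sink_id, "atoms": met.carbon_atoms}
        elif met.role == "storage_polyP":
            out["polyP"] = {"sink": sink_id, "atoms": met.phosphorus_atoms}
    return out


def simulate_cycle(model: MetabolicModel, substrate: str, config: CycleConfig) -> CycleTrajectory:
    """Simulate one anaerobic-aerobic cycle feeding ``substrate``.

    ``substrate`` must be one of the model's carbon exchanges. All other
    carbon exchanges and amino-acid uptakes are closed for the duration of
    the cycle (defined minimal medium). Anaerobic growth is fixed to zero;
    the aerobic phase grows on the storage pools laid down anaerobically.
    """
    if substrate not in model.carbon_exchanges:
        raise ValueError(f"{substrate!r} is not a carbon exchange of model {model.id}")
    model.validate()

    base = set_maintenance(model, config.ngam)
    for rid in base.carbon_exchanges:
        if rid != substrate:
            rxn = base.reaction(rid)
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for rid in base.amino_acid_exchanges.values():
        rxn = base.reaction(rid)
        rxn.lower_bound = max(rxn.lower_bound, 0.0)

    ana = apply_anaerobic(base)
    ana.set_bounds(ana.biomass_reaction, 0.0, 0.0)
    aer = apply_aerobic(base)

    pools = _pool_roles(base)
    X = config.initial_biomass
    state = {
        "substrate": config.initial_substrate,
        "co2": 0.0,
        "glycogen": config.initial_glycogen * config.initial_biomass,
        "polyP": config.initial_polyP * config.initial_biomass,
        "PHA": config.initial_PHA * config.initial_biomass,
    }

    traj = CycleTrajectory(
        times=[0.0],
        phase=[""],
        substrate=[state["substrate"]],
        co2=[state["co2"]],
        glycogen=[state["glycogen"]],
        polyP=[state["polyP"]],
        PHA=[state["PHA"]],
        biomass=[X],
        step_fluxes=[],
        maintenance_bounds=[],
        config=config,
        substrate_exchange=substrate,
    )

    t = 0.0
    step_index = 0
    schedule = [("anaerobic", d) for d in _phase_steps(config.anaerobic_hours, config.dt)]
    schedule += [("aerobic", d) for d in _phase_steps(config.aerobic_hours, config.dt)]

    for phase, dt in schedule:
        phase_model = (ana if phase == "anaerobic" else aer).copy()
        # cap pool-consuming sink fluxes so no pool can be driven negative
        for pool_name, info in pools.items():
            rxn = phase_model.reaction(info["sink"])
            atoms = max(int(info["atoms"]), 1)
            cap = state[pool_name] / (atoms * X * dt)
            rxn.lower_bound = max(rxn.lower_bound, -cap)
            rxn.upper_bound = max(rxn.upper_bound, rxn.lower_bound)

        if phase == "anaerobic":
            u_eff = min(config.uptake_rate, max(state["substrate"], 0.0) / (X * dt))
            sol = solve_min_total_flux(phase_model, substrate, u_eff)
        else:
            sol = solve_pfba(phase_model)

        if sol.status != "optimal":
            traj.status = "infeasible"
            traj.failed_step = step_index
            break

        traj.step_fluxes.append(sol)
        traj.maintenance_bounds.append(phase_model.reaction(phase_model.maintenance_reaction).lower_bound)

        v_sub = sol.fluxes.get(substrate, 0.0)
        v_co2 = sol.fluxes.get(_co2_exchange(base), 0.0)
        state["substrate"] = max(state["substrate"] + v_sub * X * dt, 0.0)
        state["co2"] += v_co2 * X * dt
        for pool_name, info in pools.items():
            atoms = max(int(info["atoms"]), 1)
            v_sink = sol.fluxes.get(info["sink"], 0.0)
            state[pool_name] = max(state[pool_name] + v_sink * atoms * X * dt, 0.0)
        mu = sol.growth_rate if phase == "aerobic" else 0.0
        X = X * (1.0 + mu * dt)

        t += dt
        step_index += 1
        traj.times.append(round(t, 9))
        traj.phase.append(phase)
        traj.substrate.append(state["substrate"])
        traj.co2.append(state["co2"])
        traj.glycogen.append(state["glycogen"])
        traj.polyP.append(state["polyP"])
        traj.PHA.append(state["PHA"])
        traj.biomass.append(X)

    return traj


def _co2_exchange(model: MetabolicModel) -> str:
    for r in model.reactions:
        if "exchange" in r.tags:
            (mid,) = r.stoichiometry
            if "co2" in mid.lower():
                return r.id
    return ""


@dataclass
class YieldResult:
    value: Optional[float]          # gDW per C-mmol, or None when undefined
    reason: str = ""

    def __bool__(self) -> bool:
        return self.value is not None


def biomass_yield(traj: CycleTrajectory, model: MetabolicModel, substrate: str) -> YieldResult:
    """Biomass yield over the cycle in gDW per C-mmol of substrate consumed."""
    if not traj.complete:
        return YieldResult(None, f"trajectory incomplete ({traj.status} at step {traj.failed_step})")
    rxn = model.reaction(substrate)
    (met_id,) = rxn.stoichiometry
    carbon = model.metabolite(met_id).carbon_atoms
    if carbon <= 0:
        raise ValueError(f"substrate metabolite {met_id} has no carbon")
    consumed_mmol = traj.substrate[0] - traj.substrate[-1]
    consumed_c = consumed_mmol * carbon
    if consumed_c <= _EPS:
        return YieldResult(None, "no substrate consumed")
    return YieldResult((traj.biomass[-1] - traj.biomass[0]) / consumed_c)


@dataclass
class CarbonBalance:
    carbon_in: float                 # C-mmol: substrate consumed + net pool drawdown
    carbon_out: float                # C-mmol: CO2 + net pool accumulation + biomass C + other exchanges
    residual: float                  # in - out, C-mmol
    relative_residual: float         # residual / carbon_in (0 when no input)
    detail: Dict[str, float] = field(default_factory=dict)


def carbon_balance(traj: CycleTrajectory, model: MetabolicModel) -> CarbonBalance:
    """Close the cycle's carbon budget from the recorded series.

    Inputs are substrate consumed plus any net drawdown of the carbon storage
    pools; outputs are CO2 emitted, net pool accumulation, carbon fixed into
    biomass and any other carbon leaving through exchanges (e.g. secreted
    amino acids). With carbon-balanced reactions the forward-Euler bookkeeping
    is conservative, so the residual reflects only LP solver tolerance.
    """
    sub_rxn = model.reaction(traj.substrate_exchange)
    (sub_met,) = sub_rxn.stoichiometry
    sub_c = model.metabolite(sub_met).carbon_atoms

    detail: Dict[str, float] = {}
    consumed = (traj.substrate[0] - traj.substrate[-1]) * sub_c
    detail["substrate_consumed"] = consumed

    cin = max(consumed, 0.0)
    cout = max(-consumed, 0.0)
    for pool_name in ("glycogen", "PHA"):
        series = getattr(traj, pool_name)
        net = series[-1] - series[0]
        detail[f"{pool_name}_net"] = net
        if net >= 0:
            cout += net
        else:
            cin += -net
    detail["co2"] = traj.co2[-1] - traj.co2[0]
    cout += detail["co2"]

    biomass_carbon_per_gdw = 0.0
    for mid, coeff in model.reaction(model.biomass_reaction).stoichiometry.items():
        if coeff < 0:
            biomass_carbon_per_gdw += -coeff * model.metabolite(mid).carbon_atoms
    detail["biomass_carbon"] = (traj.biomass[-1] - traj.biomass[0]) * biomass_carbon_per_gdw
    cout += detail["biomass_carbon"]

    # carbon leaving through exchanges other than the substrate and CO2
    other = 0.0
    co2_ex = _co2_exchange(model)
    dt_steps = [traj.times[i + 1] - traj.times[i] for i in range(len(traj.step_fluxes))]
    for i, sol in enumerate(traj.step_fluxes):
        X = traj.biomass[i]
        for r in model.reactions:
            if "exchange" not in r.tags or r.id in (traj.substrate_exchange, co2_ex):
                continue
            (mid,) = r.stoichiometry
            c = model.metabolite(mid).carbon_atoms
            if c:
                other += sol.fluxes.get(r.id, 0.0) * c * X * dt_steps[i]
    detail["other_exchanges"] = other
    cout += other

    residual = cin - cout
    rel = residual / cin if cin > _EPS else 0.0
    return CarbonBalance(cin, cout, residual, rel, detail)
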