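"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its arguments (identical seeds give
byte-identical outputs) and each produced artifact satisfies the invariants
of the consuming module, so recovery tests can compare pipeline output
against the planted ground truth. A single global seed fans out to
per-generator substreams through :func:`substream`, so adding a generator
never perturbs existing fixtures.

The centrepiece is :func:`make_pao_model`: a condensed (~100-reaction,
including the 20 amino-acid branches) polyphosphate-accumulating-organism
network with acetate / propionate / lactate / glucose / glycerol uptake
routes, lumped glycolysis and TCA, PHA / glycogen / polyphosphate storage
pools with sink reactions, an ETC-tagged oxidative phosphorylation lump, an
ATP maintenance demand, and a biomass reaction drawing on all 20 amino
acids. Named knockouts (amino-acid biosynthesis pathways, substrate
transporters) plant auxotrophies and utilization defects for the screens to
recover. The network is built carbon-balanced so that cycle simulations
close their carbon budget exactly.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import pandas as pd

from .constraint_core import DEFAULT_NGAM, Metabolite, MetabolicModel, Reaction
from .ecology_links import AbundanceTable, Spacer, _revcomp
from .genome_sets import ANIMatrix, GenomeQuality
from .pangenome_evolution import PhyloTree, PresenceMatrix

__all__ = [
    "AMINO_ACIDS",
    "TRANSPORTER_KNOCKOUTS",
    "KNOCKOUT_CATALOG",
    "SUBSTRATE_EXCHANGES",
    "substream",
    "make_pao_model",
    "make_gene_matrix",
    "make_ani_fixture",
    "make_spacer_fixture",
    "make_abundance_fixture",
]

#: the 20 proteinogenic amino acids, three-letter lower-case codes
AMINO_ACIDS = (
    "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr", "val",
)

#: transporter knockout names -> transport reaction ids removed
TRANSPORTER_KNOCKOUTS: Dict[str, Tuple[str, ...]] = {
    "acetate_transporter": ("T_ac",),
    "propionate_transporter": ("T_prop",),
    "lactate_transporter": ("T_lac_lldP", "T_lac_lctP"),
    "lldP": ("T_lac_lldP",),
    "lctP": ("T_lac_lctP",),
    "glucose_transporter": ("T_glc_ptsG", "T_glc_manX"),
    "ptsG": ("T_glc_ptsG",),
    "manX": ("T_glc_manX",),
    "glycerol_transporter": ("T_glyc_glpF",),
    "glpF": ("T_glyc_glpF",),
}

KNOCKOUT_CATALOG: Tuple[str, ...] = AMINO_ACIDS + tuple(TRANSPORTER_KNOCKOUTS)

#: substrate name -> exchange reaction id convention used by the screens
SUBSTRATE_EXCHANGES: Dict[str, str] = {
    "acetate": "EX_ac",
    "propionate": "EX_prop",
    "lactate": "EX_lac",
    "glucose": "EX_glc",
    "glycerol": "EX_glyc",
}


def substream(seed: int, label: str) -> np.random.Generator:
    """Derive an independent, reproducible random stream from a global seed
    and a generator label (stable across generator additions)."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


# ---------------------------------------------------------------------------
# PAO metabolic model
# ---------------------------------------------------------------------------

def make_pao_model(
    knockouts: Iterable[str] = (),
    model_id: str = "pao_toy",
    include_storage: bool = True,
    carbon_uptake_bound: float = 10.0,
    aa_uptake_bound: float = 10.0,
    o2_uptake_limit: float = 1000.0,
    ngam: float = DEFAULT_NGAM,
    biomass_atp: float = 40.0,
) -> MetabolicModel:
    """Build the synthetic PAO network, minus the requested knockouts.

    Knockout names come from :data:`KNOCKOUT_CATALOG`: an amino-acid code
    removes that amino acid's biosynthesis reaction; a transporter name
    removes the corresponding membrane transport reaction(s). With
    ``include_storage=False`` the PHA / glycogen / polyphosphate pools and
    their reactions are omitted (the model then cannot satisfy maintenance
    anaerobically - the storage pools are what make the anaerobic phase
    feasible).
    """
    knockouts = set(knockouts)
    unknown = knockouts - set(KNOCKOUT_CATALOG)
    if unknown:
        raise ValueError(
            f"unknown knockout(s) {sorted(unknown)}; catalog: {sorted(KNOCKOUT_CATALOG)}"
        )

    mets: List[Metabolite] = []
    rxns: List[Reaction] = []

    def met(mid, name, comp, c=0, p=0, role="generic"):
        mets.append(Metabolite(mid, name, comp, c, p, role))

    def rxn(rid, stoich, lb, ub, tags, name=""):
        rxns.append(Reaction(rid, stoich, lb, ub, frozenset(tags), name or rid))

    # extracellular species
    met("ac_e", "acetate", "extracellular", 2, 0, "carbon_substrate")
    met("prop_e", "propionate", "extracellular", 3, 0, "carbon_substrate")
    met("lac_e", "lactate", "extracellular", 3, 0, "carbon_substrate")
    met("glc_e", "glucose", "extracellular", 6, 0, "carbon_substrate")
    met("glyc_e", "glycerol", "extracellular", 3, 0, "carbon_substrate")
    met("o2_e", "oxygen", "extracellular", 0, 0, "gas")
    met("co2_e", "carbon dioxide", "extracellular", 1, 0, "gas")
    met("nh4_e", "ammonium", "extracellular", 0, 0, "ion")
    met("pi_e", "phosphate", "extracellular", 0, 1, "ion")

    # cytosolic species
    met("ac_c", "acetate", "cytosol", 2)
    met("prop_c", "propionate", "cytosol", 3)
    met("lac_c", "lactate", "cytosol", 3)
    met("glc_c", "glucose", "cytosol", 6)
    met("glyc_c", "glycerol", "cytosol", 3)
    met("pyr_c", "pyruvate", "cytosol", 3)
    met("accoa_c", "acetyl-CoA (C2 unit)", "cytosol", 2)
    met("ppcoa_c", "propionyl-CoA (C3 unit)", "cytosol", 3)
    met("atp_c", "ATP (energy currency)", "cytosol", 0)
    met("nadh_c", "NADH (redox currency)", "cytosol", 0)
    met("nh4_c", "ammonium", "cytosol", 0, 0, "ion")
    met("pi_c", "phosphate", "cytosol", 0, 1, "ion")
    met("o2_c", "oxygen", "cytosol", 0, 0, "gas")
    met("co2_c", "carbon dioxide", "cytosol", 1, 0, "gas")

    # exchanges (negative flux = uptake)
    rxn("EX_ac", {"ac_e": -1}, -carbon_uptake_bound, 1000, {"exchange"})
    rxn("EX_prop", {"prop_e": -1}, -carbon_uptake_bound, 1000, {"exchange"})
    rxn("EX_lac", {"lac_e": -1}, -carbon_uptake_bound, 1000, {"exchange"})
    rxn("EX_glc", {"glc_e": -1}, -carbon_uptake_bound, 1000, {"exchange"})
    rxn("EX_glyc", {"glyc_e": -1}, -carbon_uptake_bound, 1000, {"exchange"})
    rxn("EX_o2", {"o2_e": -1}, -o2_uptake_limit, 1000, {"exchange"})
    rxn("EX_co2", {"co2_e": -1}, 0, 1000, {"exchange"})
    rxn("EX_nh4", {"nh4_e": -1}, -1000, 1000, {"exchange"})
    rxn("EX_pi", {"pi_e": -1}, -1000, 1000, {"exchange"})

    # membrane transport
    rxn("T_ac", {"ac_e": -1, "ac_c": 1}, 0, 1000, {"transport"}, "acetate transport (actP)")
    rxn("T_prop", {"prop_e": -1, "prop_c": 1}, 0, 1000, {"transport"})
    rxn("T_lac_lldP", {"lac_e": -1, "lac_c": 1}, 0, 1000, {"transport"}, "L-lactate permease (lldP)")
    rxn("T_lac_lctP", {"lac_e": -1, "lac_c": 1}, 0, 1000, {"transport"}, "lactate permease (lctP)")
    rxn("T_glc_ptsG", {"glc_e": -1, "glc_c": 1}, 0, 1000, {"transport"}, "glucose PTS (ptsG)")
    rxn("T_glc_manX", {"glc_e": -1, "glc_c": 1}, 0, 1000, {"transport"}, "mannose-family PTS (manX)")
    rxn("T_glyc_glpF", {"glyc_e": -1, "glyc_c": 1}, 0, 1000, {"transport"}, "glycerol facilitator (glpF)")
    rxn("T_o2", {"o2_e": -1, "o2_c": 1}, 0, 1000, {"transport"})
    rxn("T_co2", {"co2_c": -1, "co2_e": 1}, 0, 1000, {"transport"})
    rxn("T_nh4", {"nh4_e": -1, "nh4_c": 1}, 0, 1000, {"transport"})
    rxn("T_pi", {"pi_e": -1, "pi_c": 1}, -1000, 1000, {"transport"})

    # central carbon metabolism (lumped, carbon-balanced)
    # activation costs are tuned so the anaerobic P-release : C-uptake ratio
    # lands near the experimentally observed ~0.3 P-mol per C-mol for VFAs
    rxn("ACS", {"ac_c": -1, "atp_c": -0.7, "accoa_c": 1}, 0, 1000, {"internal"}, "acetyl-CoA synthetase")
    rxn("PRO_ACT", {"prop_c": -1, "atp_c": -0.7, "ppcoa_c": 1}, 0, 1000, {"internal"})
    rxn("PPCOA_DEG", {"ppcoa_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, 1000, {"internal"})
    rxn("LDH", {"lac_c": -1, "pyr_c": 1, "nadh_c": 1}, 0, 1000, {"internal"}, "lactate dehydrogenase")
    rxn("GLYCOLYSIS", {"glc_c": -1, "pyr_c": 2, "atp_c": 2, "nadh_c": 2}, 0, 1000, {"internal"})
    rxn("GLYC_DEG", {"glyc_c": -1, "pyr_c": 1, "atp_c": 1, "nadh_c": 2}, 0, 1000, {"internal"})
    rxn("PDH", {"pyr_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1}, 0, 1000, {"internal"})
    rxn("TCA", {"accoa_c": -1, "co2_c": 2, "nadh_c": 4, "atp_c": 1}, 0, 1000, {"internal"}, "TCA cycle (lumped)")

    # electron transport chain + maintenance
    rxn("ETC_NADH_OX", {"nadh_c": -1, "o2_c": -0.5, "atp_c": 2}, 0, 1000, {"ETC"}, "oxidative phosphorylation")
    rxn("ATPM", {"atp_c": -1}, ngam, 1000, {"maintenance"}, "non-growth-associated maintenance")

    # storage pools
    if include_storage:
        met("phb_p", "PHA (C4 hydroxybutyrate unit)", "pool", 4, 0, "storage_PHA")
        met("gly_p", "glycogen (C6 glucosyl unit)", "pool", 6, 0, "storage_glycogen")
        met("pp_p", "polyphosphate (P1 unit)", "pool", 0, 1, "storage_polyP")
        # degradation reactions carry finite enzyme-capacity (Vmax) bounds:
        # they pace pool consumption so a hard maintenance demand can be met
        # across the whole aerobic phase instead of the pools being drained
        # in a single greedy step by the growth-maximizing LP
        # redox-neutral anaerobic storage shunts: with the ETC off, reduced
        # substrates cannot dump surplus NADH, so (as in real PAOs, which shift
        # PHA composition by substrate) each is condensed straight into storage
        rxn("PROP_STORAGE", {"ppcoa_c": -2, "phb_p": 1, "co2_c": 2}, 0, 1000, {"internal"})
        rxn("LAC_STORAGE", {"lac_c": -2, "atp_c": -1, "phb_p": 1, "co2_c": 2}, 0, 1000, {"internal"})
        rxn("GLYC_STORAGE", {"glyc_c": -2, "atp_c": -0.5, "phb_p": 1, "co2_c": 2}, 0, 1000, {"internal"})
        rxn("GLY_SYN_GLC", {"glc_c": -1, "atp_c": -0.5, "gly_p": 1}, 0, 1000, {"internal"}, "glycogen synthesis from glucose")
        rxn("PHA_SYN", {"accoa_c": -2, "nadh_c": -1, "phb_p": 1}, 0, 1000, {"internal"})
        rxn("PHA_DEG", {"phb_p": -1, "accoa_c": 2, "nadh_c": 1}, 0, 1.0, {"internal"})
        rxn("GLY_SYN", {"accoa_c": -3, "atp_c": -4, "gly_p": 1}, 0, 1000, {"internal"}, "gluconeogenesis to glycogen")
        rxn("GLY_DEG", {"gly_p": -1, "pyr_c": 2, "atp_c": 3, "nadh_c": 2}, 0, 0.3, {"internal"})
        rxn("PPK", {"atp_c": -1, "pi_c": -1, "pp_p": 1}, 0, 1000, {"internal"}, "polyphosphate kinase")
        rxn("PPX", {"pp_p": -1, "atp_c": 1, "pi_c": 1}, 0, 2.6, {"internal"}, "polyphosphate hydrolysis")
        rxn("SINK_PHA", {"phb_p": -1}, -1000, 1000, {"storage_sink"})
        rxn("SINK_GLY", {"gly_p": -1}, -1000, 1000, {"storage_sink"})
        rxn("SINK_PP", {"pp_p": -1}, -1000, 1000, {"storage_sink"})

    # amino acids: biosynthesis, transport, exchange (each AA is a lumped C4 unit)
    aa_exchanges: Dict[str, str] = {}
    biomass_stoich: Dict[str, float] = {"atp_c": -biomass_atp}
    for aa in AMINO_ACIDS:
        met(f"{aa}_c", aa.capitalize(), "cytosol", 4, 0, "amino_acid")
        met(f"{aa}_e", aa.capitalize(), "extracellular", 4, 0, "amino_acid")
        if aa not in knockouts:
            rxn(
                f"BS_{aa}",
                {"accoa_c": -2, "atp_c": -2, "nadh_c": -1, "nh4_c": -1, f"{aa}_c": 1},
                0, 1000, {"internal"}, f"{aa} biosynthesis (lumped)",
            )
        rxn(f"T_{aa}", {f"{aa}_e": -1, f"{aa}_c": 1}, -1000, 1000, {"transport"})
        rxn(f"EX_{aa}", {f"{aa}_e": -1}, -aa_uptake_bound, 1000, {"exchange"})
        aa_exchanges[aa] = f"EX_{aa}"
        biomass_stoich[f"{aa}_c"] = -0.5

    rxn("BIOMASS", biomass_stoich, 0, 1000, {"biomass"}, "biomass (lumped, 40 C-mmol/gDW)")

    for name in knockouts & set(TRANSPORTER_KNOCKOUTS):
        removed = set(TRANSPORTER_KNOCKOUTS[name])
        rxns = [r for r in rxns if r.id not in removed]

    model = MetabolicModel(
        id=model_id,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction="BIOMASS",
        maintenance_reaction="ATPM",
        o2_exchange="EX_o2",
        carbon_exchanges=set(SUBSTRATE_EXCHANGES.values()),
        amino_acid_exchanges=aa_exchanges,
        o2_uptake_limit=o2_uptake_limit,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# gene matrices on trees
# ---------------------------------------------------------------------------

def _random_tree(n_leaves: int, rng: np.random.Generator) -> PhyloTree:
    """A random rooted binary tree over leaves g000..g{n-1}."""
    taxa = dendropy.TaxonNamespace([f"g{i:03d}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for t in taxa:
        node = dendropy.Node(taxon=t)
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return PhyloTree(tree)


@dataclass
class GeneMatrixTruth:
    origin_node: Dict[str, str]           # family -> node label where it first appeared
    classification: Dict[str, str]        # family -> "ancestral" | "derived" (wrt the LCA node)
    gain_branches: Dict[str, List[str]]
    loss_branches: Dict[str, List[str]]


def make_gene_matrix(
    tree: Optional[PhyloTree] = None,
    n_leaves: int = 20,
    n_families: int = 500,
    gain_rate: float = 0.02,
    loss_rate: float = 0.1,
    root_presence: float = 0.5,
    seed: int = 0,
    clade_split_depth: int = 1,
) -> Tuple[PresenceMatrix, PhyloTree, GeneMatrixTruth]:
    """Evolve binary gene families root-to-leaves under per-branch Bernoulli
    gain/loss. Families are planted present at the root with probability
    ``root_presence``; each branch flips presence->absence with ``loss_rate``
    and absence->presence with ``gain_rate``. Clade labels are assigned from
    the subtrees at ``clade_split_depth`` below the root. Families absent
    from every leaf are redrawn (the presence-matrix type forbids them)."""
    if not (0 <= gain_rate <= 1 and 0 <= loss_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = substream(seed, "gene_matrix")
    if tree is None:
        tree = _random_tree(n_leaves, rng)
    leaves = sorted(tree.leaf_labels)

    # clade labels from subtrees near the root
    clade_of: Dict[str, str] = {}
    roots = [tree.tree.seed_node]
    for _ in range(clade_split_depth):
        nxt = []
        for r in roots:
            nxt.extend(r.child_nodes() or [r])
        roots = nxt
    for ci, r in enumerate(roots):
        for lf in r.leaf_iter():
            clade_of[lf.taxon.label] = f"clade_{ci}"
    for lf in leaves:
        clade_of.setdefault(lf, "clade_0")

    counts = pd.DataFrame(0, index=[f"fam{i:04d}" for i in range(n_families)], columns=leaves)
    origin_node: Dict[str, str] = {}
    classification: Dict[str, str] = {}
    gain_branches: Dict[str, List[str]] = {}
    loss_branches: Dict[str, List[str]] = {}

    fam = 0
    attempts = 0
    while fam < n_families:
        attempts += 1
        if attempts > 50 * n_families:
            raise RuntimeError("could not generate families present in at least one leaf")
        name = f"fam{fam:04d}"
        root_state = int(rng.random() < root_presence)
        states: Dict[int, int] = {id(tree.tree.seed_node): root_state}
        gains: List[str] = []
        losss: List[str] = []
        first: Optional[str] = tree.tree.seed_node.label if root_state else None
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_state = states[id(node.parent_node)]
            label = node.label if not node.is_leaf() else node.taxon.label
            if parent_state:
                state = 0 if rng.random() < loss_rate else 1
                if state == 0:
                    losss.append(label)
            else:
                state = 1 if rng.random() < gain_rate else 0
                if state == 1:
                    gains.append(label)
                    if first is None:
                        first = label
            states[id(node)] = state
        leaf_states = {
            lf.taxon.label: states[id(lf)] for lf in tree.tree.leaf_node_iter()
        }
        if not any(leaf_states.values()):
            continue
        counts.loc[name] = pd.Series(leaf_states)
        origin_node[name] = first if first is not None else ""
        classification[name] = "ancestral" if root_state else "derived"
        gain_branches[name] = gains
        loss_branches[name] = losss
        fam += 1

    matrix = PresenceMatrix(counts.astype(int), clade_of)
    truth = GeneMatrixTruth(origin_node, classification, gain_branches, loss_branches)
    return matrix, tree, truth


# ---------------------------------------------------------------------------
# ANI fixtures
# ---------------------------------------------------------------------------

def make_ani_fixture(
    cluster_sizes: Sequence[int],
    within_ani: float = 99.5,
    between_ani: float = 90.0,
    jitter: float = 0.1,
    within_af: float = 0.92,
    between_af: float = 0.5,
    seed: int = 0,
) -> Tuple[ANIMatrix, List[GenomeQuality], List[Set[str]]]:
    """Block-structured ANI matrix with planted clusters plus randomized
    CheckM-style quality records (QS in [50, 100])."""
    if within_ani <= between_ani:
        raise ValueError("within_ani must exceed between_ani")
    rng = substream(seed, "ani_fixture")
    genomes: List[str] = []
    truth: List[Set[str]] = []
    for ci, size in enumerate(cluster_sizes):
        members = {f"c{ci}_g{k}" for k in range(size)}
        truth.append(members)
        genomes.extend(sorted(members))
    n = len(genomes)
    block = np.array(
        [[within_ani if any(g1 in c and g2 in c for c in truth) else between_ani for g2 in genomes] for g1 in genomes]
    )
    noise = rng.normal(0, jitter, size=(n, n)) if jitter > 0 else np.zeros((n, n))
    ani = np.clip(block + (noise + noise.T) / 2, 0, 100)
    np.fill_diagonal(ani, 100.0)
    af_block = np.array(
        [[within_af if any(g1 in c and g2 in c for c in truth) else between_af for g2 in genomes] for g1 in genomes]
    )
    np.fill_diagonal(af_block, 1.0)
    matrix = ANIMatrix(
        pd.DataFrame(ani, index=genomes, columns=genomes),
        pd.DataFrame(af_block, index=genomes, columns=genomes),
    )
    quality = []
    for g in genomes:
        contamination = float(rng.uniform(0, 4))
        completeness = float(rng.uniform(50 + 5 * contamination, 100))
        quality.append(GenomeQuality(g, completeness, contamination))
    return matrix, quality, truth


# ---------------------------------------------------------------------------
# spacer / vOTU fixtures
# ---------------------------------------------------------------------------

@dataclass
class PlantedSpacer:
    spacer_id: str
    votu_id: str
    position: int
    strand: str
    mismatches: int
    should_match: bool       # whether the 97/90/1 thresholds retain it


def make_spacer_fixture(
    n_spacers: int = 20,
    votu_length: int = 20_000,
    spacer_length: int = 34,
    planted: Sequence[Tuple[int, str]] = ((0, "+"), (1, "+"), (1, "-"), (2, "+")),
    n_decoys: int = 10,
    n_genomes: int = 10,
    seed: int = 0,
) -> Tuple[List[Spacer], Dict[str, str], List[PlantedSpacer]]:
    """Random vOTU with spacers embedded at controlled mismatch counts and
    strands, plus decoy spacers with no placement. ``planted`` lists
    (mismatch count, strand) pairs; the truth records whether each planted
    spacer clears the default 97% / 90% / <=1-mismatch thresholds."""
    rng = substream(seed, "spacer_fixture")
    bases = np.array(list("ACGT"))
    votu_seq = "".join(rng.choice(bases, size=votu_length))
    votus = {"vOTU_0001": votu_seq}

    spacers: List[Spacer] = []
    truth: List[PlantedSpacer] = []
    positions = rng.choice(
        np.arange(0, votu_length - spacer_length, spacer_length * 3),
        size=len(planted),
        replace=False,
    )
    for i, ((n_mm, strand), pos) in enumerate(zip(planted, positions)):
        target = votu_seq[pos : pos + spacer_length]
        seq = list(target)
        mm_sites = rng.choice(spacer_length, size=n_mm, replace=False)
        for site in mm_sites:
            alternatives = [b for b in "ACGT" if b != seq[site]]
            seq[site] = alternatives[int(rng.integers(3))]
        spacer_seq = "".join(seq)
        if strand == "-":
            spacer_seq = _revcomp(spacer_seq)
        sid = f"spacer_{i:03d}"
        host = f"MAG_{i % n_genomes:03d}"
        spacers.append(Spacer(sid, host, spacer_seq))
        identity = (spacer_length - n_mm) / spacer_length * 100.0
        truth.append(
            PlantedSpacer(sid, "vOTU_0001", int(pos), strand, n_mm, identity >= 97.0 and n_mm <= 1)
        )
    for j in range(n_decoys):
        seq = "".join(rng.choice(bases, size=spacer_length))
        spacers.append(Spacer(f"decoy_{j:03d}", f"MAG_{(len(planted) + j) % n_genomes:03d}", seq))
    return spacers, votus, truth


# ---------------------------------------------------------------------------
# abundance fixtures
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTruth:
    planted_rho: Dict[Tuple[str, str], float]
    wwtp_profiles: pd.DataFrame


def make_abundance_fixture(
    n_wwtps: int = 10,
    samples_per_wwtp: int = 3,
    n_taxa: int = 12,
    continents: Sequence[str] = ("Asia", "Europe", "North_America"),
    planted_correlations: Sequence[Tuple[int, int, float]] = ((0, 1, 0.9), (2, 3, -0.8)),
    replicate_jitter: float = 0.05,
    seed: int = 0,
) -> Tuple[AbundanceTable, AbundanceTruth]:
    """Log-normal abundance table with Gaussian-copula rank correlations at
    the planted strengths and jittered within-plant replicate samples.

    ``planted_correlations`` holds (taxon index, taxon index, rho) triples on
    the latent Gaussian scale; monotone transforms preserve the sign and
    approximate strength on the Spearman scale.
    """
    rng = substream(seed, "abundance_fixture")
    taxa = [f"taxon_{i:02d}" for i in range(n_taxa)]
    cov = np.eye(n_taxa)
    planted: Dict[Tuple[str, str], float] = {}
    for i, j, rho in planted_correlations:
        cov[i, j] = cov[j, i] = rho
        planted[(taxa[i], taxa[j])] = rho
    # make the matrix positive definite if the plants conflict
    w, v = np.linalg.eigh(cov)
    cov = (v * np.maximum(w, 1e-3)) @ v.T

    latent = rng.multivariate_normal(np.zeros(n_taxa), cov, size=n_wwtps, method="cholesky")
    base = np.exp(latent)                       # log-normal plant profiles
    wwtp_ids = [f"wwtp_{i:02d}" for i in range(n_wwtps)]
    profiles = pd.DataFrame(base, index=wwtp_ids, columns=taxa)

    rows = []
    index = []
    sample_wwtp: Dict[str, str] = {}
    sample_continent: Dict[str, str] = {}
    for wi, wwtp in enumerate(wwtp_ids):
        continent = continents[wi % len(continents)]
        for k in range(samples_per_wwtp):
            sid = f"{wwtp}_s{k}"
            jit = rng.normal(1.0, replicate_jitter, size=n_taxa) if replicate_jitter > 0 else np.ones(n_taxa)
            rows.append(np.clip(profiles.loc[wwtp].values * jit, 0, None))
            index.append(sid)
            sample_wwtp[sid] = wwtp
            sample_continent[sid] = continent
    table = AbundanceTable(pd.DataFrame(rows, index=index, columns=taxa), sample_wwtp, sample_continent)
    return table, AbundanceTruth(planted, profiles)
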