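"""Pangenome partitioning and ancestral gene-content reconstruction.

Gene families are held as a genome x family copy-number matrix; genomes carry
clade labels. Two partitioning rules are provided: *core* families (present in
at least ceil(threshold * n) genomes, default 80%) and *clade-specific*
families (present in strictly more than 75% of one clade's members and in no
genome outside that clade).

Ancestral gene content is reconstructed by asymmetric Wagner parsimony: a
Sankoff-style dynamic program over integer copy-number states on a rooted
tree, with per-edge cost gain_penalty * gains + loss_penalty * losses
(defaults 2 and 1, i.e. a gain costs twice a loss, which biases the
reconstruction toward losses and so toward ancestral presence). Families
reconstructed with at least one copy at the designated last-common-ancestor
node are classified *ancestral*; families absent there but present below it
are *derived*.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PresenceMatrix",
    "PhyloTree",
    "GainLossResult",
    "classify_core",
    "classify_clade_specific",
    "wagner_gain_loss",
    "classify_origin",
]


@dataclass
class PresenceMatrix:
    """Copy counts per gene family (rows) and genome (columns), plus a clade
    label for every genome. Families entirely absent from every genome are
    disallowed (they carry no signal and break parsimony bookkeeping)."""

    counts: pd.DataFrame                      # families x genomes, int >= 0
    genome_clades: Dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise ValueError("presence matrix is empty")
        if (self.counts.values < 0).any():
            raise ValueError("copy counts must be >= 0")
        zero_rows = self.counts.index[(self.counts == 0).all(axis=1)]
        if len(zero_rows):
            raise ValueError(f"all-zero family rows not allowed: {list(zero_rows[:5])}")
        missing = [g for g in self.counts.columns if g not in self.genome_clades]
        if missing:
            raise ValueError(f"genomes without clade labels: {missing[:5]}")

    @property
    def genomes(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def families(self) -> List[str]:
        return list(self.counts.index)

    @classmethod
    def from_tsv(cls, matrix_path: str, clades_path: str) -> "PresenceMatrix":
        """Families as rows, genomes as columns (Panaroo/Roary-style count
        export); clades as a two-column TSV ``genome<TAB>clade``."""
        counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
        clades = pd.read_csv(clades_path, sep="\t", index_col=0).iloc[:, 0].to_dict()
        return cls(counts.astype(int), clades)

    def to_tsv(self, matrix_path: str, clades_path: str) -> None:
        self.counts.to_csv(matrix_path, sep="\t")
        with open(clades_path, "w") as fh:
            fh.write("genome\tclade\n")
            for g in self.genomes:
                fh.write(f"{g}\t{self.genome_clades[g]}\n")


@dataclass
class PhyloTree:
    """A rooted tree whose leaves are genome ids, with unique internal-node
    ids and a designated last-common-ancestor (LCA) node for the focal genus
    (default: the root)."""

    tree: dendropy.Tree
    lca_node: Optional[str] = None

    def __post_init__(self) -> None:
        self._label_internal_nodes()
        labels = [n.label for n in self.tree.preorder_internal_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("internal node labels are not unique")
        if self.lca_node is None:
            self.lca_node = self.tree.seed_node.label
        elif self.lca_node not in labels:
            raise ValueError(f"LCA node {self.lca_node!r} is not an internal node of the tree")

    def _label_internal_nodes(self) -> None:
        used = {n.label for n in self.tree.preorder_internal_node_iter() if n.label}
        i = 0
        for node in self.tree.preorder_internal_node_iter():
            if not node.label:
                while f"N{i}" in used:
                    i += 1
                node.label = f"N{i}"
                used.add(f"N{i}")

    @property
    def leaf_labels(self) -> Set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}

    @classmethod
    def from_newick(cls, source: str, lca_node: Optional[str] = None, is_path: bool = True) -> "PhyloTree":
        if is_path:
            tree = dendropy.Tree.get(path=source, schema="newick")
        else:
            tree = dendropy.Tree.get(data=source, schema="newick")
        tree.is_rooted = True
        return cls(tree, lca_node)


@dataclass
class GainLossResult:
    ancestral_counts: pd.DataFrame        # families x internal nodes
    branch_gains: pd.DataFrame            # families x branches (child-node id)
    branch_losses: pd.DataFrame
    origin: Dict[str, str]                # family -> "ancestral" | "derived"
    total_cost: float
    gain_penalty: float = 2.0
    loss_penalty: float = 1.0

    def events_per_branch(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gains": self.branch_gains.sum(axis=0), "losses": self.branch_losses.sum(axis=0)}
        )


def classify_core(matrix: PresenceMatrix, threshold: float = 0.8) -> Set[str]:
    """Families present (count >= 1) in at least ceil(threshold * n_genomes)
    genomes. At the study's scale (136 genomes, threshold 0.8) the minimum
    presence count is 109."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    n = len(matrix.genomes)
    min_count = int(np.ceil(threshold * n))
    present = (matrix.counts >= 1).sum(axis=1)
    return set(matrix.counts.index[present >= min_count])


def core_min_genomes(n_genomes: int, threshold: float = 0.8) -> int:
    """Minimum number of genomes a family must appear in to be core."""
    return int(np.ceil(threshold * n_genomes))


def classify_clade_specific(matrix: PresenceMatrix, threshold: float = 0.75) -> Dict[str, Set[str]]:
    """Families present in strictly more than ``threshold`` of one clade's
    genomes and absent (count 0) from every genome outside that clade."""
    clades: Dict[str, List[str]] = {}
    for genome, clade in matrix.genome_clades.items():
        if genome in matrix.counts.columns:
            clades.setdefault(clade, []).append(genome)
    present = matrix.counts >= 1
    out: Dict[str, Set[str]] = {c: set() for c in clades}
    for clade, members in clades.items():
        others = [g for g in matrix.genomes if g not in members]
        in_clade = present[members].sum(axis=1)
        exclusive = ~present[others].any(axis=1) if others else pd.Series(True, index=present.index)
        mask = (in_clade > threshold * len(members)) & exclusive
        out[clade] = set(matrix.counts.index[mask])
    return out


def _edge_cost_matrix(max_count: int, gain_penalty: float, loss_penalty: float) -> np.ndarray:
    states = np.arange(max_count + 1)
    diff = states[None, :] - states[:, None]      # [parent, child] = child - parent
    return np.where(diff > 0, gain_penalty * diff, -loss_penalty * diff).astype(float)


def wagner_gain_loss(
    matrix: PresenceMatrix,
    tree: PhyloTree,
    gain_penalty: float = 2.0,
    loss_penalty: float = 1.0,
    max_count: Optional[int] = None,
) -> GainLossResult:
    """Asymmetric Wagner parsimony over integer copy numbers.

    Per family, finds a minimum-cost assignment of ancestral counts over
    states {0..max_count} by a Sankoff dynamic program, with edge cost
    ``gain_penalty * max(0, child - parent) + loss_penalty * max(0, parent - child)``.
    The root state is the cost-minimizing one (no root prior); backtrace ties
    prefer the smallest ancestral count, a deterministic choice that biases
    toward gains being recent. Counts above ``max_count`` are truncated with
    a warning (default cap: the per-family observed maximum).
    """
    leaves = tree.leaf_labels
    genomes = set(matrix.genomes)
    if leaves != genomes:
        raise ValueError(
            f"tree leaves and matrix genomes differ: only-in-tree={sorted(leaves - genomes)[:5]}, "
            f"only-in-matrix={sorted(genomes - leaves)[:5]}"
        )

    internal = [n.label for n in tree.tree.preorder_internal_node_iter()]
    n_fam = len(matrix.families)
    anc = pd.DataFrame(0, index=matrix.families, columns=internal)
    child_nodes = [
        n.label if not n.is_leaf() else n.taxon.label
        for n in tree.tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    gains = pd.DataFrame(0, index=matrix.families, columns=child_nodes)
    losses = pd.DataFrame(0, index=matrix.families, columns=child_nodes)
    total_cost = 0.0

    for fam in matrix.families:
        fam_counts = matrix.counts.loc[fam]
        cap = int(max_count) if max_count is not None else int(fam_counts.max())
        cap = max(cap, 1)
        if (fam_counts > cap).any():
            warnings.warn(f"family {fam}: counts above max_count={cap} truncated")
        leaf_state = {g: min(int(fam_counts[g]), cap) for g in matrix.genomes}
        cost_mat = _edge_cost_matrix(cap, gain_penalty, loss_penalty)

        node_cost: Dict[int, np.ndarray] = {}
        best_child_state: Dict[int, np.ndarray] = {}
        for node in tree.tree.postorder_node_iter():
            if node.is_leaf():
                c = np.full(cap + 1, np.inf)
                c[leaf_state[node.taxon.label]] = 0.0
                node_cost[id(node)] = c
            else:
                c = np.zeros(cap + 1)
                for child in node.child_nodes():
                    trans = cost_mat + node_cost[id(child)][None, :]   # [parent, child]
                    best_child_state[id(child)] = np.argmin(trans, axis=1)
                    c = c + np.min(trans, axis=1)
                node_cost[id(node)] = c

        root = tree.tree.seed_node
        root_costs = node_cost[id(root)]
        fam_cost = float(np.min(root_costs))
        total_cost += fam_cost
        root_state = int(np.argmin(root_costs))    # argmin -> smallest state on ties

        state_of: Dict[int, int] = {id(root): root_state}
        anc.loc[fam, root.label] = root_state
        for node in tree.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            parent_state = state_of[id(node.parent_node)]
            if node.is_leaf():
                s = leaf_state[node.taxon.label]
                label = node.taxon.label
            else:
                s = int(best_child_state[id(node)][parent_state])
                anc.loc[fam, node.label] = s
                label = node.label
            state_of[id(node)] = s
            if s > parent_state:
                gains.loc[fam, label] = s - parent_state
            elif s < parent_state:
                losses.loc[fam, label] = parent_state - s

    origin: Dict[str, str] = {}
    lca = tree.lca_node
    for fam in matrix.families:
        origin[fam] = "ancestral" if anc.loc[fam, lca] > 0 else "derived"

    return GainLossResult(
        ancestral_counts=anc,
        branch_gains=gains,
        branch_losses=losses,
        origin=origin,
        total_cost=total_cost,
        gain_penalty=gain_penalty,
        loss_penalty=loss_penalty,
    )


def classify_origin(result: GainLossResult, tree: PhyloTree) -> Dict[str, str]:
    """Classify each family as *ancestral* (reconstructed count > 0 at the
    LCA node) or *derived* (absent at the LCA but present somewhere below).
    Families with no presence at or below the LCA are excluded with a
    warning."""
    lca = tree.lca_node
    below: Set[str] = set()
    found = False
    for node in tree.tree.preorder_node_iter():
        if not node.is_leaf() and node.label == lca:
            found = True
            for sub in node.preorder_iter():
                below.add(sub.label if not sub.is_leaf() else sub.taxon.label)
            break
    if not found:
        raise ValueError(f"LCA node {lca!r} not found in tree")

    out: Dict[str, str] = {}
    for fam in result.ancestral_counts.index:
        if result.ancestral_counts.loc[fam, lca] > 0:
            out[fam] = "ancestral"
            continue
        present_below = False
        for col in result.ancestral_counts.columns:
            if col in below and result.ancestral_counts.loc[fam, col] > 0:
                present_below = True
                break
        if not present_below:
            for col in result.branch_gains.columns:
                if col in below and result.branch_gains.loc[fam, col] > 0:
                    present_below = True
                    break
        if present_below:
            out[fam] = "derived"
        else:
            warnings.warn(f"family {fam}: absent at and below the LCA; excluded from origin calls")
    return out
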