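"""Genome quality scoring and ANI-threshold dereplication / species clustering.

Quality score follows the CheckM-style convention QS = completeness - 5 x
contamination. Dereplication approximates dRep's behaviour with single-linkage
components: two genomes are joined when their (symmetrized) ANI and aligned
fraction both clear the thresholds - 99% / 0.85 for dereplication, 95% / 0.30
for species-level clustering - and each cluster is represented by its
highest-QS genome (ties broken by lexicographic id). Boundary comparisons are
inclusive (>=).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GenomeQuality",
    "ANIMatrix",
    "ClusterSet",
    "quality_score",
    "dereplicate",
    "species_cluster",
]


def quality_score(completeness: float, contamination: float) -> float:
    """QS = completeness - 5 x contamination (both in percent)."""
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValueError(f"contamination {contamination} must be >= 0")
    return completeness - 5.0 * contamination


@dataclass(frozen=True)
class GenomeQuality:
    genome: str
    completeness: float
    contamination: float

    @property
    def qs(self) -> float:
        return quality_score(self.completeness, self.contamination)


@dataclass
class ANIMatrix:
    """Symmetric pairwise ANI (%) and aligned fraction; asymmetric query /
    reference orientations are symmetrized by taking the maximum."""

    ani: pd.DataFrame
    aligned_fraction: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.ani.index) != list(self.ani.columns):
            raise ValueError("ANI matrix must be square with matching labels")
        if list(self.aligned_fraction.index) != list(self.ani.index):
            raise ValueError("aligned_fraction labels must match ANI labels")
        self.ani = self._symmetrize(self.ani)
        self.aligned_fraction = self._symmetrize(self.aligned_fraction)
        np.fill_diagonal(self.ani.values, 100.0)
        np.fill_diagonal(self.aligned_fraction.values, 1.0)
        if (self.ani.values < 0).any() or (self.ani.values > 100 + 1e-9).any():
            raise ValueError("ANI values must lie in [0, 100]")

    @staticmethod
    def _symmetrize(df: pd.DataFrame) -> pd.DataFrame:
        arr = df.values.astype(float)
        return pd.DataFrame(np.maximum(arr, arr.T), index=df.index, columns=df.columns)

    @property
    def genomes(self) -> List[str]:
        return list(self.ani.index)

    @classmethod
    def from_pairs_tsv(cls, path: str) -> "ANIMatrix":
        """FastANI-style long format: ``genome1 genome2 ani [af1 af2]``
        (aligned fractions default to 1 when absent)."""
        df = pd.read_csv(path, sep="\t", header=None)
        genomes = sorted(set(df[0]) | set(df[1]))
        ani = pd.DataFrame(0.0, index=genomes, columns=genomes)
        af = pd.DataFrame(0.0, index=genomes, columns=genomes)
        for row in df.itertuples(index=False):
            g1, g2, a = row[0], row[1], float(row[2])
            f = float(row[3]) if len(row) > 3 else 1.0
            f2 = float(row[4]) if len(row) > 4 else f
            ani.loc[g1, g2] = max(ani.loc[g1, g2], a)
            af.loc[g1, g2] = max(af.loc[g1, g2], max(f, f2))
        return cls(ani, af)

    @classmethod
    def from_square_tsv(cls, ani_path: str, af_path: Optional[str] = None) -> "ANIMatrix":
        ani = pd.read_csv(ani_path, sep="\t", index_col=0)
        if af_path:
            af = pd.read_csv(af_path, sep="\t", index_col=0)
        else:
            af = pd.DataFrame(1.0, index=ani.index, columns=ani.columns)
        return cls(ani, af)


@dataclass
class ClusterSet:
    clusters: List[Set[str]]
    representatives: List[str]
    ani_min: float
    af_min: float

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for c in self.clusters:
            if c & seen:
                raise ValueError("clusters are not disjoint")
            seen |= c

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, genome: str) -> Set[str]:
        for c in self.clusters:
            if genome in c:
                return c
        raise KeyError(genome)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("cluster_id\tgenome\trepresentative_flag\n")
            for i, (cluster, rep) in enumerate(zip(self.clusters, self.representatives)):
                for g in sorted(cluster):
                    fh.write(f"cluster_{i}\t{g}\t{int(g == rep)}\n")


def _cluster(
    ani: ANIMatrix,
    quality: Iterable[GenomeQuality],
    ani_min: float,
    af_min: float,
) -> ClusterSet:
    qs_by_genome = {q.genome: q.qs for q in quality}
    missing = [g for g in ani.genomes if g not in qs_by_genome]
    if missing:
        raise ValueError(f"no quality record for genome(s): {missing[:5]}")

    g = nx.Graph()
    g.add_nodes_from(ani.genomes)
    genomes = ani.genomes
    a = ani.ani.values
    f = ani.aligned_fraction.values
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            if a[i, j] >= ani_min and f[i, j] >= af_min:
                g.add_edge(genomes[i], genomes[j])

    clusters: List[Set[str]] = []
    reps: List[str] = []
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    for comp in components:
        comp = set(comp)
        rep = min(comp, key=lambda x: (-qs_by_genome[x], x))
        clusters.append(comp)
        reps.append(rep)
    return ClusterSet(clusters, reps, ani_min, af_min)


def dereplicate(
    ani: ANIMatrix,
    quality: Iterable[GenomeQuality],
    ani_min: float = 99.0,
    af_min: float = 0.85,
) -> ClusterSet:
    """Strain-level dereplication (ANI >= 99%, aligned fraction >= 0.85),
    keeping the highest-QS genome of each single-linkage component."""
    return _cluster(ani, quality, ani_min, af_min)


def species_cluster(
    ani: ANIMatrix,
    quality: Iterable[GenomeQuality],
    ani_min: float = 95.0,
    af_min: float = 0.30,
) -> ClusterSet:
    """Species-level clustering (ANI >= 95%, aligned fraction >= 0.30)."""
    return _cluster(ani, quality, ani_min, af_min)


def read_quality_tsv(path: str) -> List[GenomeQuality]:
    """CheckM-style TSV: ``genome completeness contamination`` (with header)."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return [
        GenomeQuality(str(r[cols[0]]), float(r[cols[1]]), float(r[cols[2]]))
        for _, r in df.iterrows()
    ]
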