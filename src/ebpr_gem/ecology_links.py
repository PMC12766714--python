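"""Virus-host linkage and biogeographic/co-occurrence statistics.

CRISPR spacers are matched against viral contigs (vOTUs) by ungapped,
mismatch-limited alignment on both strands; a match is retained only when
identity >= 97%, coverage >= 90% of the spacer and at most one mismatch hold
jointly. With at most one mismatch allowed, gapped alignment adds nothing, so
no indel handling is attempted. The host infection rate is the truncated
percentage of genomes with at least one retained link (92/136 -> 67).

The ecological half of the module selects one representative sample per
treatment plant (the sample nearest the within-plant centroid under
Bray-Curtis dissimilarity), summarizes clade proportions per continent, and
builds a Spearman co-occurrence network with Benjamini-Hochberg FDR control
(retaining |rho| > 0.3, q < 0.05).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Spacer",
    "SpacerMatch",
    "AbundanceTable",
    "NetworkEdge",
    "match_spacers",
    "infection_rate",
    "select_representative_samples",
    "bray_curtis",
    "continent_proportions",
    "correlation_network",
    "ds_size_correlation",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Spacer:
    id: str
    host_genome: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"spacer {self.id}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    votu_id: str
    identity: float            # percent over the aligned length
    coverage: float            # percent of the spacer length aligned
    mismatches: int
    strand: str                # "+" | "-", relative to the vOTU forward strand
    start: int                 # 0-based, half-open on the vOTU forward strand
    end: int


# base -> code; spacer ambiguity codes and vOTU ambiguity codes are mapped to
# distinct sentinels so a non-ACGT position always counts as a mismatch
_SPACER_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str, sentinel: int) -> np.ndarray:
    arr = np.full(len(seq), sentinel, dtype=np.int8)
    for base, code in _SPACER_CODES.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def match_spacers(
    spacers: Iterable[Spacer],
    votus: Mapping[str, str],
    min_identity: float = 97.0,
    min_coverage: float = 90.0,
    max_mismatch: int = 1,
) -> List[SpacerMatch]:
    """Scan every spacer against every vOTU on both strands.

    The full spacer is slid along the contig (partial overlap at contig ends
    allowed down to the coverage threshold); at each offset identity =
    matches / aligned length and coverage = aligned length / spacer length.
    All windows meeting the three criteria jointly are retained.
    """
    out: List[SpacerMatch] = []
    votu_codes = {vid: _encode(seq.upper(), 5) for vid, seq in votus.items()}
    for spacer in spacers:
        L = len(spacer.sequence)
        min_overlap = int(math.ceil(min_coverage / 100.0 * L))
        for vid, vseq in votus.items():
            vcode = votu_codes[vid]
            n = len(vcode)
            if n == 0:
                continue
            for strand in ("+", "-"):
                s = spacer.sequence if strand == "+" else _revcomp(spacer.sequence)
                scode = _encode(s, 4)
                # fully-contained windows, vectorized
                if n >= L:
                    windows = np.lib.stride_tricks.sliding_window_view(vcode, L)
                    mism = (windows != scode[None, :]).sum(axis=1)
                    for off in np.nonzero(mism <= max_mismatch)[0]:
                        m = int(mism[off])
                        ident = (L - m) / L * 100.0
                        if ident >= min_identity:
                            out.append(
                                SpacerMatch(
                                    spacer.id, vid, ident, 100.0, m, strand, int(off), int(off) + L
                                )
                            )
                # partial overlaps at the contig ends
                for hang in range(1, L - min_overlap + 1):
                    for left in (True, False):
                        if left:
                            ov = L - hang
                            frag, vfrag, start = scode[hang:], vcode[:ov], 0
                        else:
                            ov = L - hang
                            frag, vfrag, start = scode[:ov], vcode[n - ov:], n - ov
                        if ov > n or ov < min_overlap:
                            continue
                        m = int((frag != vfrag).sum())
                        if m > max_mismatch:
                            continue
                        ident = (ov - m) / ov * 100.0
                        cov = ov / L * 100.0
                        if ident >= min_identity and cov >= min_coverage:
                            out.append(
                                SpacerMatch(spacer.id, vid, ident, cov, m, strand, start, start + ov)
                            )
    return out


def infection_rate(matches: Iterable[SpacerMatch], spacers: Iterable[Spacer], genomes: Set[str]) -> Dict[str, float]:
    """Fraction of host genomes with at least one retained spacer-vOTU link.

    ``rate_percent`` is truncated toward zero to match the convention of
    reporting whole percentages (92 of 136 -> 67); ``rate_exact`` carries the
    untruncated value.
    """
    if not genomes:
        raise ValueError("genome set is empty")
    spacer_host = {s.id: s.host_genome for s in spacers}
    linked = {spacer_host[m.spacer_id] for m in matches if m.spacer_id in spacer_host}
    linked &= genomes
    exact = len(linked) / len(genomes) * 100.0
    return {
        "linked_genomes": len(linked),
        "total_genomes": len(genomes),
        "rate_percent": int(exact),
        "rate_exact": exact,
    }


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances with per-sample site metadata."""

    abundances: pd.DataFrame                  # samples x taxa, >= 0
    sample_wwtp: Dict[str, str]
    sample_continent: Dict[str, str]

    def __post_init__(self) -> None:
        if (self.abundances.values < 0).any():
            raise ValueError("abundances must be >= 0")
        if not np.isfinite(self.abundances.values).all():
            raise ValueError("abundances must be finite")
        for s in self.abundances.index:
            if s not in self.sample_wwtp or s not in self.sample_continent:
                raise ValueError(f"sample {s}: missing wwtp/continent metadata")

    @property
    def samples(self) -> List[str]:
        return list(self.abundances.index)

    @property
    def taxa(self) -> List[str]:
        return list(self.abundances.columns)

    @classmethod
    def from_tsv(cls, table_path: str, metadata_path: str) -> "AbundanceTable":
        ab = pd.read_csv(table_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(ab, meta["wwtp"].to_dict(), meta["continent"].to_dict())

    def to_tsv(self, table_path: str, metadata_path: str) -> None:
        self.abundances.to_csv(table_path, sep="\t")
        with open(metadata_path, "w") as fh:
            fh.write("sample\twwtp\tcontinent\n")
            for s in self.samples:
                fh.write(f"{s}\t{self.sample_wwtp[s]}\t{self.sample_continent[s]}\n")


def bray_curtis(a: Sequence[float], b: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b); two all-zero profiles
    are defined as identical (0) with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("abundances must be non-negative")
    if a.sum() + b.sum() == 0:
        warnings.warn("Bray-Curtis of two all-zero profiles defined as 0")
        return 0.0
    return float(_scipy_braycurtis(a, b))


def select_representative_samples(table: AbundanceTable) -> Dict[str, str]:
    """One sample per treatment plant: the one nearest (Bray-Curtis) to the
    arithmetic-mean profile of that plant's samples; ties and degenerate
    all-zero plants resolve to the lexicographically smallest sample id."""
    by_wwtp: Dict[str, List[str]] = {}
    for s in table.samples:
        by_wwtp.setdefault(table.sample_wwtp[s], []).append(s)
    out: Dict[str, str] = {}
    for wwtp, samples in by_wwtp.items():
        samples = sorted(samples)
        if len(samples) == 1:
            out[wwtp] = samples[0]
            continue
        profiles = table.abundances.loc[samples]
        centroid = profiles.mean(axis=0).values
        if centroid.sum() == 0:
            warnings.warn(f"wwtp {wwtp}: all-zero profiles; keeping first sample by id")
            out[wwtp] = samples[0]
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dists = [bray_curtis(profiles.loc[s].values, centroid) for s in samples]
        best = min(range(len(samples)), key=lambda i: (dists[i], samples[i]))
        out[wwtp] = samples[best]
    return out


def continent_proportions(table: AbundanceTable, grouping: Mapping[str, str]) -> pd.DataFrame:
    """Per continent, each clade's share of the summed focal abundance.

    ``grouping`` maps taxon -> clade over the focal taxa; rows sum to 1
    wherever the continental total is non-zero (zero-total continents give
    all-zero rows, flagged with a warning).
    """
    focal = [t for t in table.taxa if t in grouping]
    if not focal:
        raise ValueError("grouping covers no taxon in the table")
    clades = sorted(set(grouping[t] for t in focal))
    continents = sorted(set(table.sample_continent.values()))
    out = pd.DataFrame(0.0, index=continents, columns=clades)
    for cont in continents:
        samples = [s for s in table.samples if table.sample_continent[s] == cont]
        sums = table.abundances.loc[samples, focal].sum(axis=0)
        total = sums.sum()
        if total <= 0:
            warnings.warn(f"continent {cont}: zero total focal abundance")
            continue
        for taxon in focal:
            out.loc[cont, grouping[taxon]] += sums[taxon] / total
    return out


# ---------------------------------------------------------------------------
# co-occurrence network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkEdge:
    taxon_a: str
    taxon_b: str
    spearman_rho: float
    p_value: float
    q_value: float


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Exact permutation two-sided p for Spearman's rho with mid-rank ties
    (used for small n where the t approximation is poor)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    rx_c = rx - rx.mean()
    denom_x = (rx_c ** 2).sum()
    count = 0
    total = 0
    chunk: List[Tuple[int, ...]] = []

    def flush(chunk: List[Tuple[int, ...]]) -> int:
        perm = np.array(chunk)
        ry_perm = ry[perm]
        ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt(denom_x * (ry_c ** 2).sum(axis=1))
        rhos = (ry_c @ rx_c) / denom
        return int(np.sum(np.abs(rhos) >= abs(rho) - 1e-12))

    for p_idx in itertools.permutations(range(n)):
        chunk.append(p_idx)
        total += 1
        if len(chunk) >= 100_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return rho, count / total


def _spearman(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    n = len(x)
    if n <= 10:
        return _spearman_exact_p(x, y)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def correlation_network(
    table: AbundanceTable,
    rho_min: float = 0.3,
    q_max: float = 0.05,
    focal: Optional[str] = None,
) -> Tuple[List[NetworkEdge], List[str]]:
    """All-pairs Spearman co-occurrence network across samples.

    Pairs involving a constant-abundance taxon are skipped (rank correlation
    undefined). Benjamini-Hochberg adjustment is applied across all tested
    pairs; edges with |rho| > rho_min and q < q_max are retained. When
    ``focal`` is given, taxa with a retained positive correlation to it are
    returned as the second element.
    """
    if len(table.samples) < 8:
        raise ValueError("need at least 8 samples for rank correlation")
    taxa = table.taxa
    X = table.abundances.values
    tested: List[Tuple[str, str, float, float]] = []
    skipped: List[Tuple[str, str, str]] = []
    for i, j in itertools.combinations(range(len(taxa)), 2):
        xi, xj = X[:, i], X[:, j]
        if np.all(xi == xi[0]) or np.all(xj == xj[0]):
            skipped.append((taxa[i], taxa[j], "constant abundance"))
            continue
        rho, p = _spearman(xi, xj)
        tested.append((taxa[i], taxa[j], rho, p))
    if not tested:
        return [], []
    pvals = np.array([t[3] for t in tested])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    edges = [
        NetworkEdge(a, b, rho, p, q)
        for (a, b, rho, p), q in zip(tested, qvals)
        if abs(rho) > rho_min and q < q_max
    ]
    focal_positive: List[str] = []
    if focal is not None:
        for e in edges:
            if e.spearman_rho > 0:
                if e.taxon_a == focal:
                    focal_positive.append(e.taxon_b)
                elif e.taxon_b == focal:
                    focal_positive.append(e.taxon_a)
    return edges, sorted(focal_positive)


def edges_to_tsv(edges: Iterable[NetworkEdge], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("taxon_a\ttaxon_b\tspearman_rho\tp_value\tq_value\n")
        for e in edges:
            fh.write(f"{e.taxon_a}\t{e.taxon_b}\t{e.spearman_rho:.6g}\t{e.p_value:.6g}\t{e.q_value:.6g}\n")


def ds_size_correlation(ds_counts: Mapping[str, int], genome_sizes: Mapping[str, float]) -> Tuple[float, float]:
    """Spearman correlation of per-genome defense-system counts with genome
    size (bp). Returns (rho, p)."""
    if set(ds_counts) != set(genome_sizes):
        raise ValueError("ds_counts and genome_sizes must cover the same genomes")
    if len(ds_counts) < 3:
        raise ValueError("need at least 3 genomes")
    genomes = sorted(ds_counts)
    x = np.array([ds_counts[g] for g in genomes], dtype=float)
    y = np.array([genome_sizes[g] for g in genomes], dtype=float)
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# FASTA / TSV plumbing
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def matches_to_tsv(matches: Iterable[SpacerMatch], path: str) -> None:
    """BLAST outfmt-6-like table for retained spacer-vOTU matches."""
    with open(path, "w") as fh:
        fh.write("qseqid\tsseqid\tpident\tcoverage\tmismatch\tsstart\tsend\tstrand\n")
        for m in matches:
            fh.write(
                f"{m.spacer_id}\t{m.votu_id}\t{m.identity:.2f}\t{m.coverage:.2f}\t"
                f"{m.mismatches}\t{m.start}\t{m.end}\t{m.strand}\n"
            )
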