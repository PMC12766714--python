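"""Spacer-matching, infection-rate, Bray-Curtis and co-occurrence tests.

The spacer matcher is checked against an independent brute-force scan written
here (per-position loops, no vectorization), and the Benjamini-Hochberg
adjustment against a hand-computed step-up example.
"""

import numpy as np
import pandas as pd
import pytest

from ebpr_gem.ecology_links import (
    AbundanceTable,
    Spacer,
    bray_curtis,
    continent_proportions,
    correlation_network,
    ds_size_correlation,
    infection_rate,
    match_spacers,
    read_fasta,
    select_representative_samples,
    write_fasta,
)
from ebpr_gem.synthetic_data import make_abundance_fixture, make_spacer_fixture

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMP)[::-1]


def brute_force_scan(spacers, votus, min_identity=97.0, min_coverage=90.0, max_mismatch=1):
    """Independent oracle: plain double loop over every offset and strand,
    full-containment windows only (the fixtures plant interior hits)."""
    hits = set()
    for spacer in spacers:
        L = len(spacer.sequence)
        for vid, vseq in votus.items():
            for strand, seq in (("+", spacer.sequence), ("-", revcomp(spacer.sequence))):
                for off in range(len(vseq) - L + 1):
                    window = vseq[off : off + L]
                    mm = sum(1 for a, b in zip(seq, window) if a != b)
                    identity = (L - mm) / L * 100.0
                    if mm <= max_mismatch and identity >= min_identity and 100.0 >= min_coverage:
                        hits.add((spacer.id, vid, strand, off))
    return hits


class TestSpacerMatching:
    def test_34nt_one_mismatch_clears_thresholds(self):
        rng = np.random.default_rng(0)
        target = "".join(rng.choice(list("ACGT"), 34))
        votu = "A" * 500 + target + "C" * 500
        spacer_seq = target[:10] + ("A" if target[10] != "A" else "C") + target[11:]
        matches = match_spacers([Spacer("s1", "g1", spacer_seq)], {"v1": votu})
        assert len(matches) == 1
        m = matches[0]
        assert m.identity == pytest.approx(33 / 34 * 100, abs=0.01)   # 97.06%
        assert m.coverage == pytest.approx(100.0)
        assert m.mismatches == 1
        assert (m.start, m.end) == (500, 534)

    def test_30nt_one_mismatch_fails_identity(self):
        rng = np.random.default_rng(1)
        target = "".join(rng.choice(list("ACGT"), 30))
        votu = "G" * 300 + target + "T" * 300
        spacer_seq = target[:5] + ("A" if target[5] != "A" else "C") + target[6:]
        # 29/30 = 96.67% < 97: rejected despite only one mismatch
        assert match_spacers([Spacer("s1", "g1", spacer_seq)], {"v1": votu}) == []

    def test_two_mismatches_rejected(self):
        spacers, votus, truth = make_spacer_fixture(planted=((2, "+"),), n_decoys=0, seed=2)
        assert match_spacers(spacers, votus) == []

    def test_agrees_with_brute_force_scan(self):
        spacers, votus, _ = make_spacer_fixture(
            n_spacers=20, votu_length=20_000,
            planted=((0, "+"), (1, "+"), (1, "-"), (2, "+"), (0, "-")),
            n_decoys=45, seed=13,
        )
        mine = {(m.spacer_id, m.votu_id, m.strand, m.start) for m in match_spacers(spacers, votus)}
        oracle = brute_force_scan(spacers, votus)
        assert mine == oracle
        assert len(mine) == 4      # the 2-mismatch plant is excluded

    def test_strand_symmetry_under_reverse_complement(self):
        spacers, votus, _ = make_spacer_fixture(planted=((0, "+"), (1, "-")), n_decoys=5, seed=4)
        fwd = match_spacers(spacers, votus)
        rc = match_spacers(spacers, {k: revcomp(v) for k, v in votus.items()})
        flip = {"+": "-", "-": "+"}
        assert {(m.spacer_id, m.votu_id, flip[m.strand]) for m in fwd} == {
            (m.spacer_id, m.votu_id, m.strand) for m in rc
        }

    def test_ambiguous_base_counts_as_mismatch(self):
        votu = "ACGT" * 20
        spacer = Spacer("s", "g", "ACGTACGTACGTACGTACGTACGTACGTACGNAC")
        matches = match_spacers([spacer], {"v": votu + votu})
        assert all(m.mismatches >= 1 for m in matches)

    def test_empty_spacer_rejected(self):
        with pytest.raises(ValueError):
            Spacer("s", "g", "")

    def test_fasta_round_trip(self, tmp_path):
        records = {"a": "ACGT" * 30, "b": "TTTT"}
        path = tmp_path / "x.fasta"
        write_fasta(records, str(path))
        assert read_fasta(str(path)) == records


class TestInfectionRate:
    def test_published_worked_example(self):
        # 92 of 136 genomes linked -> 67% (truncated, as printed)
        genomes = {f"MAG_{i:03d}" for i in range(136)}
        spacers = [Spacer(f"s{i}", f"MAG_{i:03d}", "ACGT" * 9) for i in range(92)]
        matches = [
            type("M", (), {"spacer_id": f"s{i}"})() for i in range(92)
        ]
        out = infection_rate(matches, spacers, genomes)
        assert out["linked_genomes"] == 92
        assert out["rate_percent"] == 67
        assert out["rate_exact"] == pytest.approx(92 / 136 * 100)

    def test_no_matches_gives_zero(self):
        spacers = [Spacer("s0", "g0", "ACGT" * 8)]
        assert infection_rate([], spacers, {"g0", "g1"})["rate_percent"] == 0

    def test_full_linkage_gives_hundred(self):
        spacers = [Spacer(f"s{i}", f"g{i}", "ACGT" * 8) for i in range(3)]
        matches = [type("M", (), {"spacer_id": f"s{i}"})() for i in range(3)]
        assert infection_rate(matches, spacers, {"g0", "g1", "g2"})["rate_percent"] == 100

    def test_empty_genome_set_rejected(self):
        with pytest.raises(ValueError):
            infection_rate([], [], set())


class TestBrayCurtis:
    def test_identical_profiles(self):
        assert bray_curtis([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert bray_curtis([2.0, 1.0], [1.0, 1.0]) == pytest.approx(0.2)

    def test_disjoint_supports(self):
        assert bray_curtis([1.0, 0.0], [0.0, 2.0]) == pytest.approx(1.0)

    def test_all_zero_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert bray_curtis([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([-1.0], [1.0])


def small_table(rows, wwtps=None, continents=None):
    df = pd.DataFrame(rows).T
    samples = list(df.index)
    wwtps = wwtps or {s: "w1" for s in samples}
    continents = continents or {s: "Asia" for s in samples}
    return AbundanceTable(df, wwtps, continents)


class TestRepresentativeSamples:
    def test_single_sample_wwtp_returns_it(self):
        t = small_table({"s1": {"t1": 1.0, "t2": 2.0}})
        assert select_representative_samples(t) == {"w1": "s1"}

    def test_duplicated_profile_pair_wins(self):
        # two identical profiles pull the centroid toward themselves; hand
        # Bray-Curtis on the 3x4 table: centroid (2/3,2/3,1/3,1/3), distance
        # 1/3 for the pair members vs 2/3 for the outlier
        t = small_table({
            "s1": {"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0},
            "s2": {"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0},
            "s3": {"a": 0.0, "b": 0.0, "c": 1.0, "d": 1.0},
        })
        assert select_representative_samples(t)["w1"] in {"s1", "s2"}

    def test_one_representative_per_wwtp(self):
        table, _ = make_abundance_fixture(n_wwtps=10, samples_per_wwtp=3, seed=6)
        reps = select_representative_samples(table)
        assert len(reps) == 10
        for wwtp, sample in reps.items():
            assert table.sample_wwtp[sample] == wwtp

    def test_zero_jitter_ties_break_lexicographically(self):
        table, _ = make_abundance_fixture(n_wwtps=2, samples_per_wwtp=3, replicate_jitter=0.0, seed=6)
        reps = select_representative_samples(table)
        for wwtp, sample in reps.items():
            assert sample == sorted(s for s in table.samples if table.sample_wwtp[s] == wwtp)[0]


class TestContinentProportions:
    def test_single_clade_gets_everything(self):
        t = small_table({"s1": {"t1": 3.0}})
        out = continent_proportions(t, {"t1": "IIA"})
        assert out.loc["Asia", "IIA"] == pytest.approx(1.0)

    def test_three_to_one_split(self):
        t = small_table({"s1": {"t1": 3.0, "t2": 1.0}})
        out = continent_proportions(t, {"t1": "IIA", "t2": "IIC"})
        assert out.loc["Asia", "IIA"] == pytest.approx(0.75)
        assert out.loc["Asia", "IIC"] == pytest.approx(0.25)

    def test_rows_sum_to_one(self):
        table, _ = make_abundance_fixture(n_wwtps=9, samples_per_wwtp=2, seed=8)
        grouping = {t: ("cladeA" if i % 2 else "cladeB") for i, t in enumerate(table.taxa)}
        out = continent_proportions(table, grouping)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_uncovered_taxa_rejected(self):
        t = small_table({"s1": {"t1": 1.0}})
        with pytest.raises(ValueError):
            continent_proportions(t, {"other": "x"})


class TestCorrelationNetwork:
    def test_perfect_monotone_pair_retained(self):
        n = 20
        x = np.arange(1.0, n + 1)
        rows = {f"s{i}": {"t1": x[i], "t2": x[i] ** 2, "t3": float((i * 7) % 5)} for i in range(n)}
        t = small_table(rows)
        edges, _ = correlation_network(t)
        pairs = {frozenset((e.taxon_a, e.taxon_b)): e for e in edges}
        assert frozenset(("t1", "t2")) in pairs
        assert pairs[frozenset(("t1", "t2"))].spearman_rho == pytest.approx(1.0)

    def test_independent_pair_not_retained(self):
        rng = np.random.default_rng(99)
        n = 1000
        rows = {f"s{i:04d}": {"t1": float(a), "t2": float(b)}
                for i, (a, b) in enumerate(zip(rng.random(n), rng.random(n)))}
        t = small_table(rows)
        edges, _ = correlation_network(t)
        assert edges == []

    def test_constant_taxon_skipped(self):
        n = 12
        rows = {f"s{i}": {"t1": float(i), "t2": 5.0, "t3": float(n - i)} for i in range(n)}
        t = small_table(rows)
        edges, _ = correlation_network(t)
        taxa_in_edges = {x for e in edges for x in (e.taxon_a, e.taxon_b)}
        assert "t2" not in taxa_in_edges

    def test_focal_positive_partners_reported(self):
        table, truth = make_abundance_fixture(
            n_wwtps=60, samples_per_wwtp=1,
            planted_correlations=((0, 1, 0.95),), seed=21,
        )
        edges, partners = correlation_network(table, focal="taxon_00")
        assert "taxon_01" in partners

    def test_too_few_samples_rejected(self):
        rows = {f"s{i}": {"t1": float(i), "t2": float(i)} for i in range(5)}
        with pytest.raises(ValueError):
            correlation_network(small_table(rows))

    def test_exact_permutation_p_for_small_n(self):
        # n = 8, perfectly monotone: only the identity and reversal achieve
        # |rho| = 1, so the exact two-sided p is 2/8!
        from ebpr_gem.ecology_links import _spearman_exact_p

        x = np.arange(8.0)
        rho, p = _spearman_exact_p(x, x * 3.0 + 1.0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 40320)

    def test_bh_adjustment_matches_hand_computation(self):
        # textbook step-up on six p-values: q_i = min over j>=i of p_(j)*m/j
        from statsmodels.stats.multitest import multipletests

        pvals = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06])
        expected = np.array([0.006, 0.024, 0.0504, 0.0504, 0.0504, 0.06])
        _, q, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(q, expected, atol=1e-12)


class TestDsSizeCorrelation:
    def test_monotone_counts_give_rho_one(self):
        ds = {f"g{i}": i + 1 for i in range(10)}
        size = {f"g{i}": 2e6 + i * 1e5 for i in range(10)}
        rho, p = ds_size_correlation(ds, size)
        assert rho == pytest.approx(1.0)
        assert p < 0.001

    def test_shuffled_counts_weakly_correlated(self):
        rng = np.random.default_rng(5)
        sizes = {f"g{i:03d}": 2e6 + i * 1e4 for i in range(136)}
        counts = rng.permutation(np.arange(136))
        ds = {f"g{i:03d}": int(counts[i]) for i in range(136)}
        rho, _ = ds_size_correlation(ds, sizes)
        assert abs(rho) < 0.3

    def test_mismatched_keys_rejected(self):
        with pytest.raises(ValueError):
            ds_size_correlation({"a": 1}, {"b": 2.0})

    def test_too_few_genomes_rejected(self):
        with pytest.raises(ValueError):
            ds_size_correlation({"a": 1, "b": 2}, {"a": 1.0, "b": 2.0})
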