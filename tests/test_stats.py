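import itertools
import math

import numpy as np
import pytest

from triads import (
    Genome,
    GenomicInterval,
    LabeledTrack,
    chisq_state_test,
    cis_trans_label,
    cis_trans_shift_test,
    common_specific_split,
    compartment_density,
    cross_experiment_consistency,
    fisher_specificity,
    format_percent,
    jaccard_rna_similarity,
    pr_fold_change,
    scaling_weights,
    split_by_median_p,
    state_counts,
    state_distribution,
)
from triads.stats import geometric_bin_edges

from conftest import make_contact
from test_builder import _toy_triad


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def exact_signed_rank_p(diffs):
    """Two-sided exact signed-rank p by enumerating all sign assignments
    (tie-free |differences| assumed)."""
    d = [x for x in diffs if x != 0]
    if not d:
        return 1.0
    mags = sorted(abs(x) for x in d)
    ranks = {m: i + 1 for i, m in enumerate(mags)}
    w_obs = sum(ranks[abs(x)] for x in d if x > 0)
    n = len(d)
    total = n * (n + 1) // 2
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(sorted(ranks.values()), signs) if s)
        if w <= lo or w >= hi:
            count += 1
    return min(1.0, count / 2**n)


def exact_fisher_p(table):
    """Two-sided Fisher exact p by hypergeometric enumeration: sum the
    probabilities of all tables with the observed margins that are no
    more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


class TestCisTransLabel:
    def test_labels(self):
        assert cis_trans_label(make_contact(rna_chrom="chr1", dna_chrom="chr1")) == "cis"
        assert cis_trans_label(make_contact(rna_chrom="chr1", dna_chrom="chr2")) == "trans"


class TestCisTransShiftTest:
    def _pairs(self, fracs_before, fracs_after):
        """Contacts/triads realising given per-RNA trans fractions out of 10."""
        before, after = [], []
        for i, (fb, fa) in enumerate(zip(fracs_before, fracs_after)):
            rna = f"RNA{i}"
            for j in range(10):
                trans = j < round(fb * 10)
                before.append(make_contact(
                    rna=rna, dna_chrom="chr2" if trans else "chr1",
                    dna_start=10_000 * (j + 1), dna_end=10_000 * (j + 1) + 300))
            for j in range(10):
                trans = j < round(fa * 10)
                after.append(_toy_triad(make_contact(
                    rna=rna, dna_chrom="chr2" if trans else "chr1",
                    dna_start=10_000 * (j + 1), dna_end=10_000 * (j + 1) + 300)))
        return before, after

    def test_identical_gives_p_one(self):
        before, after = self._pairs([0.5, 0.3], [0.5, 0.3])
        _, p, table = cis_trans_shift_test(before, after)
        assert p == 1.0
        assert set(table["rna_id"]) == {"RNA0", "RNA1"}

    def test_all_higher_n6_exact(self):
        """Six RNAs, every trans fraction strictly higher after: the
        exact two-sided signed-rank p is 2/64."""
        fb = [0.0, 0.1, 0.2, 0.3, 0.1, 0.2]
        fa = [0.1, 0.3, 0.5, 0.7, 0.6, 0.8]  # distinct positive differences
        before, after = self._pairs(fb, fa)
        _, p, _ = cis_trans_shift_test(before, after)
        assert p == pytest.approx(2 / 64)

    def test_single_nonzero_pair(self):
        before, after = self._pairs([0.2], [0.5])
        _, p, _ = cis_trans_shift_test(before, after)
        assert p == 1.0

    def test_no_shared_rna_raises(self):
        before = [make_contact(rna="RNA1")]
        after = [_toy_triad(make_contact(rna="RNA2"))]
        with pytest.raises(ValueError):
            cis_trans_shift_test(before, after)

    def test_matches_enumeration_oracle(self, rng):
        """Agreement with full sign-flip enumeration for n <= 10."""
        for trial in range(8):
            n = int(rng.integers(2, 11))
            mags = rng.permutation(np.arange(1, n + 1)) / 10.0
            signs = rng.choice([-1, 1], size=n)
            diffs = (mags * signs).tolist()
            from scipy.stats import wilcoxon

            p_scipy = wilcoxon(diffs, alternative="two-sided", method="exact").pvalue
            assert p_scipy == pytest.approx(exact_signed_rank_p(diffs))


class TestScalingWeights:
    def test_weight_plugin(self):
        """5 of 50 contacts in a 1 kb bin gives weight 1e5."""
        gene = GenomicInterval("chr1", 100_000, 120_000, "+")
        edges = [0, 1000, 2000]
        contacts = (
            [make_contact(dna_start=120_500, dna_end=120_600) for _ in range(5)]
            + [make_contact(dna_start=121_500, dna_end=121_600) for _ in range(45)]
        )
        bins = scaling_weights(contacts, gene, edges)
        assert bins[0].n_contacts == 5 and bins[1].n_contacts == 45
        assert bins[0].weight == pytest.approx(5 / (1000 * 50) * 1e9)
        assert bins[0].weight == pytest.approx(1e5)

    def test_single_bin_normalisation_limit(self):
        gene = GenomicInterval("chr1", 100_000, 120_000, "+")
        edges = [0, 4000]
        contacts = [make_contact(dna_start=121_000, dna_end=121_100)] * 7
        [b] = scaling_weights(contacts, gene, edges)
        assert b.weight == pytest.approx(1e9 / 4000)

    def test_conservation_identity(self, rng):
        """Sum over bins of weight * bin length is always 1e9."""
        gene = GenomicInterval("chr1", 500_000, 550_000, "+")
        for _ in range(5):
            contacts = [
                make_contact(dna_start=int(s), dna_end=int(s) + 200)
                for s in rng.integers(0, 1_900_000, size=int(rng.integers(5, 200)))
            ]
            bins = scaling_weights(contacts, gene)
            assert sum(b.weight * b.length for b in bins) == pytest.approx(1e9)

    def test_inside_gene_distance_zero(self):
        gene = GenomicInterval("chr1", 100_000, 120_000, "+")
        bins = scaling_weights([make_contact(dna_start=110_000, dna_end=110_200)], gene)
        assert bins[0].n_contacts == 1 and bins[0].lo == 0

    def test_trans_contact_rejected(self):
        gene = GenomicInterval("chr1", 100_000, 120_000, "+")
        with pytest.raises(ValueError):
            scaling_weights([make_contact(dna_chrom="chr2")], gene)

    def test_geometric_edges_cover_range(self):
        edges = geometric_bin_edges()
        assert edges[0] == 0 and edges[1] == 1000
        assert edges[-1] >= 100_000_000
        assert all(b > a for a, b in zip(edges, edges[1:]))


class TestStateDistribution:
    def _states(self):
        return LabeledTrack([
            (GenomicInterval("chr1", 0, 1_000_000), "Promoter"),
            (GenomicInterval("chr1", 1_000_000, 2_000_000), "Repressed"),
        ])

    def test_uniform_tiling_density_one(self, genome):
        states = self._states()
        parts = [GenomicInterval("chr1", s, s + 1000) for s in range(0, 2_000_000, 10_000)]
        dist = state_distribution(parts, states, genome)
        for s in dist.labels:
            assert dist.normalized_density[s] == pytest.approx(1.0)

    def test_all_parts_in_one_state(self, genome):
        dist = state_distribution(
            [GenomicInterval("chr1", 100, 600)], self._states(), genome)
        assert dist.fractions()["Promoter"] == 1.0
        assert dist.fractions()["Repressed"] == 0.0

    def test_duplication_invariance(self, genome):
        parts = [GenomicInterval("chr1", 100, 600), GenomicInterval("chr1", 1_500_000, 1_500_400)]
        d1 = state_distribution(parts, self._states(), genome)
        d2 = state_distribution(parts * 2, self._states(), genome)
        assert d1.normalized_density == pytest.approx(d2.normalized_density)

    def test_state_counts_by_midpoint(self):
        counts = state_counts(
            [GenomicInterval("chr1", 100, 600), GenomicInterval("chr1", 999_900, 1_000_200)],
            self._states())
        assert counts == {"Promoter": 1, "Repressed": 1}


class TestChisqStateTest:
    def test_proportional_gives_zero(self):
        chi2, p = chisq_state_test({"a": 50, "b": 50}, {"a": 0.5, "b": 0.5})
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_known_value(self):
        chi2, p = chisq_state_test({"a": 90, "b": 10}, {"a": 0.5, "b": 0.5})
        assert chi2 == pytest.approx(64.0)
        assert p == pytest.approx(1.2443e-15, rel=1e-3)

    def test_small_expected_merged(self):
        # expected counts: a=90, b=9, c=0.9 and d=0.1 merged into "other"
        chi2, p = chisq_state_test(
            {"a": 90, "b": 9, "c": 1, "d": 0},
            {"a": 0.90, "b": 0.09, "c": 0.009, "d": 0.001})
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_too_few_categories(self):
        with pytest.raises(ValueError):
            chisq_state_test({"a": 100}, {"a": 1.0})


class TestProteinGrouping:
    def test_split_by_median(self):
        assoc, other = split_by_median_p({"p1": 0.1, "p2": 0.2, "p3": 0.3, "p4": 0.4})
        assert assoc == ["p1", "p2"] and other == ["p3", "p4"]

    def test_all_equal_goes_to_other(self):
        assoc, other = split_by_median_p({"p1": 0.5, "p2": 0.5, "p3": 0.5})
        assert assoc == [] and len(other) == 3

    def test_minimum_always_associated(self):
        assoc, _ = split_by_median_p({"p1": 1e-10, "p2": 0.9, "p3": 0.8})
        assert "p1" in assoc


class TestCommonSpecificSplit:
    def test_threshold_boundary(self):
        """An RNA contacting exactly 20 proteins is common; 19 is not."""
        triads = []
        for i in range(20):
            triads.append(_toy_triad(make_contact(rna="RNA_common"), protein=f"P{i}"))
        for i in range(19):
            triads.append(_toy_triad(make_contact(rna="RNA_specific"), protein=f"P{i}"))
        common, specific = common_specific_split(triads)
        assert common == {"RNA_common"} and specific == {"RNA_specific"}

    def test_empty(self):
        assert common_specific_split([]) == (set(), set())


class TestFisherSpecificity:
    def _run_table(self, table):
        """Build contacts/loci realising a given 2x2 table."""
        contacts, loci = [], []
        common = {"RNA_common"}
        pos = 10_000
        (a, b), (c, d) = table
        for n, rna, overlap in ((a, "RNA_spec", True), (b, "RNA_spec", False),
                                (c, "RNA_common", True), (d, "RNA_common", False)):
            for _ in range(n):
                contacts.append(make_contact(rna=rna, dna_start=pos, dna_end=pos + 300))
                if overlap:
                    loci.append(GenomicInterval("chr1", pos, pos + 300))
                pos += 1000
        # rows are (specific, common) x columns (overlap, no overlap)
        return fisher_specificity(contacts, loci, common)

    def test_perfect_association(self):
        odds, p, table = self._run_table([[10, 0], [0, 10]])
        assert table.tolist() == [[10, 0], [0, 10]]
        assert p == pytest.approx(2 / 184756)

    def test_no_association(self):
        _, p, _ = self._run_table([[5, 5], [5, 5]])
        assert p == 1.0

    def test_degenerate_margin(self):
        _, p, table = self._run_table([[0, 0], [5, 5]])
        assert p == 1.0

    def test_matches_hypergeometric_enumeration(self, rng):
        """scipy's two-sided Fisher agrees with full enumeration for
        random tables with n <= 40."""
        from scipy.stats import fisher_exact

        for _ in range(20):
            t = rng.integers(0, 11, size=(2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            _, p = fisher_exact(t, alternative="two-sided")
            assert p == pytest.approx(exact_fisher_p(t.tolist()), rel=1e-9)


class TestJaccard:
    def test_matrix(self):
        m = jaccard_rna_similarity({
            "d1": {"A", "B", "C"},
            "d2": {"B", "C", "D"},
            "d3": set(),
        })
        assert m.loc["d1", "d1"] == 1.0
        assert m.loc["d1", "d2"] == pytest.approx(0.5)
        assert m.loc["d1", "d3"] == 0.0
        assert m.loc["d3", "d3"] == 1.0  # diagonal by convention
        assert (m.values == m.values.T).all()


class TestCompartmentDensity:
    def test_counts_per_bp(self, genome, ab_track):
        parts = [GenomicInterval("chr1", 1000 * i + 5, 1000 * i + 105) for i in range(10)]
        dens = compartment_density(parts, ab_track, genome)
        assert dens["A"] == pytest.approx(10 / 2_000_000)
        assert dens["B"] == 0.0

    def test_equal_counts_length_ratio(self, genome):
        track = LabeledTrack([
            (GenomicInterval("chr1", 0, 1_000_000), "A"),
            (GenomicInterval("chr1", 1_000_000, 1_500_000), "B"),
        ])
        parts = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 1_100_000, 1_100_100)]
        dens = compartment_density(parts, track, genome)
        assert dens["A"] == pytest.approx(dens["B"] / 2)


class TestFoldChange:
    def test_plugin(self):
        fc = pr_fold_change({"g": 2, "h": 98}, {"g": 1, "h": 99})
        assert fc["g"] == pytest.approx(0.03 / 0.02)

    def test_identical_replicates(self):
        counts = {"a": 10, "b": 30, "c": 60}
        fc = pr_fold_change(counts, dict(counts))
        assert all(v == pytest.approx(1.0) for v in fc.values())

    def test_absent_gene(self):
        fc = pr_fold_change({"a": 10, "b": 0}, {"a": 10, "b": 0})
        assert fc["b"] == pytest.approx(1.0)  # 0.01 / 0.01


class TestPercentFormatting:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (910, 23_981, "3.79"),
            (910, 4_144, "21.96"),
            (46, 1_585, "2.9"),
            (46, 169, "27.22"),
            (4_348, 236_673, "1.84"),
            (4_348, 227_292, "1.91"),
            (1, 1, "100"),
            (1, 3, "33.33"),
        ],
    )
    def test_trimmed_two_decimals(self, num, den, expected):
        assert format_percent(num, den) == expected


class TestCrossExperimentConsistency:
    def test_self_comparison_fully_consistent(self, genome):
        triads = [
            _toy_triad(make_contact(dna_start=s, dna_end=s + 300))
            for s in range(100_000, 1_800_000, 150_000)
        ]
        res = cross_experiment_consistency(triads, list(triads), genome,
                                           ext=50_000, bin_size=10_000)
        assert res.pct_a == "100" and res.pct_b == "100"
        assert res.n_consistent == len(triads)

    def test_disjoint_chromosomes(self, genome):
        a = [_toy_triad(make_contact(dna_chrom="chr1", dna_start=s, dna_end=s + 300))
             for s in range(100_000, 500_000, 50_000)]
        b = [_toy_triad(make_contact(dna_chrom="chr2", dna_start=s, dna_end=s + 300))
             for s in range(100_000, 500_000, 50_000)]
        res = cross_experiment_consistency(a, b, genome, ext=50_000, bin_size=10_000)
        assert res.n_consistent == 0

    def test_empty_set_rejected(self, genome):
        with pytest.raises(ValueError):
            cross_experiment_consistency([], [], genome)
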