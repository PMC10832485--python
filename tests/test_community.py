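"""16S profiling: demultiplex, QC, dereplication, OTU clustering, diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from maotofu import community as cm

BC1 = "A" * 16
BC2 = "C" * 16


def read(seq, acc=0.99, rid="r1", sample=None):
    return cm.AmpliconRead(rid, seq, acc, sample_id=sample)


class TestDemultiplex:
    def test_all_reads_carry_one_barcode(self):
        reads = [read(BC1 + "ACGT" * 10, rid=f"r{i}") for i in range(4)]
        by_sample, unassigned = cm.demultiplex(reads, {BC1: "S1", BC2: "S2"})
        assert len(by_sample["S1"]) == 4
        assert unassigned == 0
        assert all(r.sequence == "ACGT" * 10 for r in by_sample["S1"])

    def test_novel_prefix_is_unassigned(self):
        reads = [read("G" * 16 + "ACGT" * 10)]
        _, unassigned = cm.demultiplex(reads, {BC1: "S1"})
        assert unassigned == 1

    def test_three_plus_two_assignment(self):
        reads = [read(BC1 + "AAAA" * 5, rid=f"a{i}") for i in range(3)]
        reads += [read(BC2 + "CCCC" * 5, rid=f"b{i}") for i in range(2)]
        by_sample, _ = cm.demultiplex(reads, {BC1: "S1", BC2: "S2"})
        assert (len(by_sample["S1"]), len(by_sample["S2"])) == (3, 2)

    def test_trailing_reverse_complement_barcode_stripped(self):
        insert = "ACGTACGTACGTACGTACGT"
        tail = cm._revcomp(BC1)
        reads = [read(BC1 + insert + tail)]
        by_sample, _ = cm.demultiplex(reads, {BC1: "S1"})
        assert by_sample["S1"][0].sequence == insert

    def test_wrong_length_barcode_rejected(self):
        with pytest.raises(cm.CommunityError, match="16 bases"):
            cm.demultiplex([], {"ACGT": "S1"})


class TestQCFilter:
    def test_boundaries_inclusive(self):
        reads = [
            read("A" * 1399, 0.95, "short"),
            read("A" * 1400, 0.95, "lo-edge"),
            read("A" * 1800, 0.89, "bad-acc"),
            read("A" * 1650, 0.92, "ok"),
        ]
        passed, stats = cm.qc_filter(reads)
        assert {r.read_id for r in passed} == {"lo-edge", "ok"}
        assert stats.n_fail_short == 1
        assert stats.n_fail_accuracy == 1
        assert stats.n_passed == 2

    def test_empty_input(self):
        passed, stats = cm.qc_filter([])
        assert passed == [] and stats.n_input == 0

    def test_all_perfect_reads_survive(self):
        reads = [read("A" * 1500, 1.0, f"r{i}") for i in range(5)]
        passed, stats = cm.qc_filter(reads)
        assert len(passed) == 5 and stats.n_fail_long == 0

    def test_bad_window_rejected(self):
        with pytest.raises(cm.CommunityError):
            cm.qc_filter([], min_len=200, max_len=100)


class TestDereplicate:
    def test_identical_reads_collapse(self):
        reads = [read("ACGT", rid=f"r{i}", sample="S1") for i in range(5)]
        uniques = cm.dereplicate(reads)
        assert len(uniques) == 1
        assert uniques[0].size == 5
        assert uniques[0].rep_id == "r0"
        assert uniques[0].sample_counts == {"S1": 5}

    def test_all_distinct(self):
        reads = [read("ACGT" * (i + 1), rid=f"r{i}") for i in range(4)]
        assert len(cm.dereplicate(reads)) == 4

    def test_mixed_sizes(self):
        reads = [read("AAA", rid=f"a{i}") for i in range(3)]
        reads += [read("AAT", rid=f"t{i}") for i in range(2)]
        sizes = sorted(u.size for u in cm.dereplicate(reads))
        assert sizes == [2, 3]
        assert sum(sizes) == len(reads)


def brute_force_greedy(sequences_with_sizes, identity):
    """Independent reference: greedy centroid assignment from a full
    pairwise identity matrix, same ordering semantics."""
    ordered = sorted(sequences_with_sizes, key=lambda t: (-t[1], t[0]))
    seqs = [s for s, _ in ordered]
    n = len(seqs)
    ident = [[cm.alignment_identity(seqs[i], seqs[j]) for j in range(n)]
             for i in range(n)]
    centroids: list[int] = []
    assignment = {}
    for i in range(n):
        for c in centroids:
            if ident[i][c] >= identity:
                assignment[i] = c
                break
        else:
            centroids.append(i)
            assignment[i] = i
    clusters = {}
    for i, c in assignment.items():
        clusters.setdefault(seqs[c], set()).add(seqs[i])
    return clusters


class TestClusterOTUs:
    def test_identical_sequences_single_otu(self):
        uniques = cm.dereplicate([read("ACGT" * 30, rid=f"r{i}") for i in range(3)])
        table = cm.cluster_otus(uniques)
        assert len(table.otus) == 1

    def test_divergent_pair_splits_at_97(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), 100))
        # 4 substitutions -> 96 % identity: below threshold, two OTUs
        b = list(a)
        for i in (10, 30, 50, 70):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b)
        assert cm.alignment_identity(a, b) == pytest.approx(0.96)
        uniques = cm.dereplicate([read(a, rid="r1"), read(b, rid="r2")])
        assert len(cm.cluster_otus(uniques, 0.97).otus) == 2
        # 2 substitutions -> 98 %: merged
        c = list(a)
        for i in (10, 30):
            c[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c[i]]
        uniques2 = cm.dereplicate([read(a, rid="r1"), read("".join(c), rid="r2")])
        assert len(cm.cluster_otus(uniques2, 0.97).otus) == 1

    def test_sizes_conserved_and_representative_is_member(self):
        rng = np.random.default_rng(7)
        reads = []
        for i in range(30):
            seq = "".join(rng.choice(list("ACGT"), 60))
            reads.append(read(seq, rid=f"r{i}", sample=f"S{i % 2}"))
        uniques = cm.dereplicate(reads)
        table = cm.cluster_otus(uniques, 0.8)
        assert sum(o.size for o in table.otus) == len(reads)
        for otu in table.otus:
            assert otu.representative in {m.sequence for m in otu.members}

    @pytest.mark.parametrize("seed", range(50))
    def test_agrees_with_brute_force_oracle(self, seed):
        """Greedy clustering matches an exhaustive pairwise-matrix
        reference on random instances of up to 20 short sequences."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        base = "".join(rng.choice(list("ACGT"), 60))
        items = []
        for i in range(n):
            seq = list(base)
            for j in range(int(rng.integers(0, 12))):
                pos = int(rng.integers(60))
                seq[pos] = str(rng.choice(list("ACGT")))
            items.append(("".join(seq), int(rng.integers(1, 10))))
        # deduplicate by sequence, summing sizes, as dereplication would
        merged: dict[str, int] = {}
        for s, size in items:
            merged[s] = merged.get(s, 0) + size
        uniques = [
            cm.UniqueSequence(s, size, f"u{i}")
            for i, (s, size) in enumerate(merged.items())
        ]
        identity = 0.93
        table = cm.cluster_otus(uniques, identity)
        got = {o.representative: {m.sequence for m in o.members} for o in table.otus}
        expected = brute_force_greedy(list(merged.items()), identity)
        assert got == expected

    def test_bad_identity_rejected(self):
        with pytest.raises(cm.CommunityError):
            cm.cluster_otus([], identity=1.5)


class TestAbundance:
    @staticmethod
    def counts():
        return pd.DataFrame(
            {"S1": [80, 20, 0], "S2": [50, 25, 25]},
            index=["tA", "tB", "tC"],
        )

    def test_single_taxon_is_100pct(self):
        rel = cm.relative_abundance(pd.DataFrame({"S1": [42]}, index=["tA"]))
        assert rel.loc["tA", "S1"] == pytest.approx(100.0)

    def test_percentages(self):
        rel = cm.relative_abundance(self.counts())
        assert rel["S1"].tolist() == pytest.approx([80.0, 20.0, 0.0])
        assert rel["S1"].sum() == pytest.approx(100.0, abs=1e-6)
        assert rel.loc["tA", "mean_pct"] == pytest.approx(65.0)

    def test_zero_total_sample_rejected(self):
        bad = pd.DataFrame({"S1": [0, 0]}, index=["tA", "tB"])
        with pytest.raises(cm.CommunityError, match="S1"):
            cm.relative_abundance(bad)

    def test_rank_collapse(self):
        rel = cm.relative_abundance(
            self.counts(), rank_of={"tA": "G1", "tB": "G1", "tC": "G2"}
        )
        assert rel.loc["G1", "S2"] == pytest.approx(75.0)

    def test_dominant_taxa_strict_threshold_and_order(self):
        series = pd.Series({"a": 5.0, "b": 1.0, "c": 0.5, "d": 40.0})
        dominant, cumulative = cm.dominant_taxa(series, 1.0)
        assert dominant.index.tolist() == ["d", "a"]  # 1.0 dropped (strict)
        assert cumulative == pytest.approx(45.0)

    def test_dominant_empty_when_all_below(self):
        dominant, cumulative = cm.dominant_taxa(pd.Series({"a": 0.2}), 1.0)
        assert dominant.empty and cumulative == 0.0


class TestShannon:
    def test_uniform_four_otus(self):
        assert cm.shannon([25, 25, 25, 25]) == pytest.approx(math.log(4))

    def test_single_otu_zero(self):
        assert cm.shannon([100]) == 0.0

    def test_half_quarter_quarter(self):
        assert cm.shannon([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_all_zero_rejected(self):
        with pytest.raises(cm.CommunityError):
            cm.shannon([0, 0])


class TestRarefaction:
    def test_full_depth_recovers_true_richness(self):
        counts = [5, 3, 2]
        curve = cm.rarefaction(counts, depths=[10], n_reps=20, seed=1)
        assert curve["mean_otus"].iloc[0] == pytest.approx(3.0)
        assert curve["sd_otus"].iloc[0] == 0.0

    def test_depth_one_observes_one(self):
        curve = cm.rarefaction([5, 5], depths=[1], n_reps=10, seed=1)
        assert curve["mean_otus"].iloc[0] == pytest.approx(1.0)

    def test_matches_hypergeometric_expectation(self):
        """Mean observed richness equals the multivariate-hypergeometric
        closed form sum_i (1 - C(N-n_i, d)/C(N, d)) within 0.1."""
        counts = np.full(10, 10)
        total = int(counts.sum())
        depth = 5
        expected = sum(1.0 - hypergeom(total, n, depth).pmf(0) for n in counts)
        curve = cm.rarefaction(counts, depths=[depth], n_reps=1000, seed=3)
        assert curve["mean_otus"].iloc[0] == pytest.approx(expected, abs=0.1)

    def test_monotone_in_depth(self):
        curve = cm.rarefaction([40, 30, 20, 10], depths=[5, 20, 60, 100],
                               n_reps=200, seed=4)
        means = curve["mean_otus"].to_numpy()
        assert all(means[i] <= means[i + 1] + 0.05 for i in range(len(means) - 1))

    def test_excess_depth_rejected(self):
        with pytest.raises(cm.CommunityError):
            cm.rarefaction([3], depths=[4], n_reps=5, seed=0)
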