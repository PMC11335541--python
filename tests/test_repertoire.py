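"""Consensus filter accounting, greedy clustering vs oracle, sharing."""

import numpy as np
import pytest

from vlrbkit.align import shorter_identity
from vlrbkit.annotate import VLRBAnnotation
from vlrbkit.config import PipelineConfig, Span
from vlrbkit.repertoire import (
    apply_consensus_filter,
    cluster_size_cdf,
    greedy_cluster,
    shared_sequences,
    threshold_sweep,
)


def make_annotation(sp=21, lrrnt=31, lrr1=18, lrrv=(24, 24), cp=11,
                    ct=30, stalk=87, sample="larva1"):
    """Synthetic annotation with arbitrary subunit lengths."""
    pos = 0
    spans = {}
    for name, n in (("SP", sp), ("LRR-NT", lrrnt), ("LRR1", lrr1)):
        spans[name] = Span(pos, pos + n)
        pos += n
    spans["LRRv"] = []
    for n in lrrv:
        spans["LRRv"].append(Span(pos, pos + n))
        pos += n
    for name, n in (("CP", cp), ("LRR-CT", ct), ("stalk", stalk)):
        spans[name] = Span(pos, pos + n)
        pos += n
    return VLRBAnnotation(protein="A" * pos, sample_id=sample, spans=spans,
                          lrrv_count=len(lrrv))


class TestConsensusFilter:
    def test_canonical_annotation_retained(self, cfg):
        retained, report = apply_consensus_filter([make_annotation()], cfg)
        assert len(retained) == 1
        assert report.retained == 1
        assert sum(report.rejections.values()) == 0

    def test_23aa_lrrv_rejected_at_first_step(self, cfg):
        _, report = apply_consensus_filter(
            [make_annotation(lrrv=(24, 23))], cfg)
        assert report.rejections["lrrv_length"] == 1

    def test_sequential_charging_to_first_failing_step(self, cfg):
        # both LRR-NT (30) and LRRv (23) wrong: charged to LRRv only
        _, report = apply_consensus_filter(
            [make_annotation(lrrnt=30, lrrv=(23,))], cfg)
        assert report.rejections["lrrv_length"] == 1
        assert report.rejections["lrrnt_length"] == 0

    @pytest.mark.parametrize("kwargs,step", [
        ({"lrr1": 17}, "lrr1_length"),
        ({"lrrnt": 32}, "lrrnt_length"),
        ({"stalk": 86}, "stalk_length"),
        ({"sp": 20}, "sp_length"),
        ({"cp": 12}, "cp_length"),
    ])
    def test_each_length_check_fires(self, cfg, kwargs, step):
        _, report = apply_consensus_filter([make_annotation(**kwargs)], cfg)
        assert report.rejections[step] == 1

    def test_count_conservation(self, cfg):
        anns = [make_annotation(), make_annotation(lrrv=(23,)),
                make_annotation(cp=9), make_annotation(stalk=90)]
        retained, report = apply_consensus_filter(anns, cfg)
        assert report.input_count == len(anns)
        assert len(retained) + sum(report.rejections.values()) == len(anns)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------

def oracle_greedy(sequences, threshold):
    """Exhaustive reference: plain greedy over a precomputed identity
    matrix, no shortcuts."""
    order = sorted(range(len(sequences)),
                   key=lambda i: (-len(sequences[i]), sequences[i], i))
    clusters = []  # (rep_index, [members])
    for idx in order:
        for rep, members in clusters:
            if shorter_identity(sequences[idx], sequences[rep]) >= threshold:
                members.append(idx)
                break
        else:
            clusters.append((idx, [idx]))
    return [(sequences[rep], sorted(members)) for rep, members in clusters]


def random_peptides(rng, n, lmin=15, lmax=40, alphabet="ACDEFG"):
    # small alphabet: plenty of near-duplicates at every threshold
    return ["".join(rng.choice(list(alphabet),
                               size=rng.integers(lmin, lmax + 1)))
            for _ in range(n)]


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        cs = greedy_cluster(["PEPTIDE"] * 5, 0.65)
        assert len(cs.clusters) == 1
        assert sorted(cs.clusters[0].member_ids) == list(range(5))

    def test_one_mismatch_in_20_at_095(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "ACDEFGHIKLMNPQRSTVWW"
        assert shorter_identity(a, b) == pytest.approx(0.95)
        assert len(greedy_cluster([a, b], 0.95).clusters) == 1
        assert len(greedy_cluster([a, b], 0.96).clusters) == 2

    def test_threshold_one_counts_distinct_strings_of_equal_length(self):
        seqs = ["AAAA", "AAAC", "AAAA", "CCCC"]
        cs = greedy_cluster(seqs, 1.0)
        assert len(cs.clusters) == 3

    def test_empty_input(self):
        assert greedy_cluster([], 0.9).clusters == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle_byte_for_byte(self, seed):
        rng = np.random.default_rng(1000 + seed)
        seqs = random_peptides(rng, 60)
        for t in (0.65, 0.75, 0.85, 0.95, 1.0):
            cs = greedy_cluster(seqs, t)
            got = [(c.representative, sorted(c.member_ids))
                   for c in cs.clusters]
            assert got == oracle_greedy(seqs, t), (seed, t)


class TestCDF:
    def test_sizes_three_one(self):
        cs = greedy_cluster(["AAAA"] * 3 + ["CCCC"], 1.0)
        assert cluster_size_cdf(cs) == [(1, 0.75), (2, 1.0)]

    def test_all_singletons_diagonal(self):
        seqs = ["AAAA", "CCCC", "GGGG", "KKKK"]
        cdf = cluster_size_cdf(greedy_cluster(seqs, 1.0))
        assert cdf == [(k, k / 4) for k in range(1, 5)]

    def test_final_cumulative_fraction_is_one(self):
        rng = np.random.default_rng(3)
        seqs = random_peptides(rng, 50)
        cdf = cluster_size_cdf(greedy_cluster(seqs, 0.8))
        assert cdf[-1][1] == pytest.approx(1.0)


class TestThresholdSweep:
    def test_single_unique_sequence(self):
        table = threshold_sweep(["PEPTIDE"] * 10, [0.65, 1.0], loci_count=1)
        assert (table["n_clusters"] == 1).all()
        assert (table["pct_in_top_loci"] == 100.0).all()

    def test_noisy_invariant_stalk_covered_at_095(self, cfg):
        # one true stalk with <=2% substitution noise clusters together
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=87))
        seqs = []
        for _ in range(100):
            s = list(base)
            for pos in rng.choice(87, size=rng.integers(0, 2), replace=False):
                s[pos] = "W" if s[pos] != "W" else "Y"
            seqs.append("".join(s))
        table = threshold_sweep(seqs, [0.95], loci_count=1)
        assert table["pct_in_top_loci"].iloc[0] == 100.0

    def test_matches_brute_force_on_50_sequences(self):
        rng = np.random.default_rng(17)
        seqs = random_peptides(rng, 50)
        table = threshold_sweep(seqs, [0.7, 0.9], loci_count=5)
        for _, row in table.iterrows():
            oracle = oracle_greedy(seqs, row["threshold"])
            sizes = sorted((len(m) for _, m in oracle), reverse=True)
            assert row["n_clusters"] == len(sizes)
            assert row["pct_in_top_loci"] == pytest.approx(
                100.0 * sum(sizes[:5]) / 50)


class TestSharing:
    def test_protein_in_all_animals_counted_at_every_k(self):
        per_animal = {f"larva{i}": ["SHARED", f"UNIQ{i}"] for i in range(6)}
        s = shared_sequences(per_animal)
        assert all(s.counts[k] == 1 for k in range(2, 7))

    def test_disjoint_repertoires_zero_counts(self):
        s = shared_sequences({"a": ["P1"], "b": ["P2"], "c": ["P3"]})
        assert all(v == 0 for v in s.counts.values())

    def test_monotone_nonincreasing_in_k(self):
        rng = np.random.default_rng(5)
        pool = [f"P{i}" for i in range(30)]
        per_animal = {f"a{j}": list(rng.choice(pool, size=15, replace=False))
                      for j in range(5)}
        s = shared_sequences(per_animal)
        ks = sorted(s.counts)
        assert all(s.counts[ks[i]] >= s.counts[ks[i + 1]]
                   for i in range(len(ks) - 1))

    def test_duplicates_within_animal_count_once(self):
        s = shared_sequences({"a": ["P", "P"], "b": ["P"]})
        assert s.counts[2] == 1 and s.total_unique == 1

    def test_fewer_than_two_animals_rejected(self):
        with pytest.raises(ValueError):
            shared_sequences({"a": ["P"]})
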