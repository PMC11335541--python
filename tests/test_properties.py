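"""Hydropathy/polarity scores, positional stats, frequency matrices."""

import numpy as np
import pytest

from conftest import make_protein
from vlrbkit import simulate as sim
from vlrbkit.annotate import annotate_protein
from vlrbkit.properties import (
    GRANTHAM_POLARITY,
    KYTE_DOOLITTLE,
    frequency_matrix,
    gravy,
    length_distributions,
    majority_residues,
    polarity,
    positional_subunit_stats,
    split_loops_by_hydropathy,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestScales:
    def test_all_twenty_residues_present(self):
        assert set(KYTE_DOOLITTLE) == set(AA)
        assert set(GRANTHAM_POLARITY) == set(AA)

    def test_kd_scale_matches_biopython(self):
        from Bio.SeqUtils.ProtParamData import kd
        assert KYTE_DOOLITTLE == kd

    def test_poly_leucine_gravy(self):
        assert gravy("LLLL") == pytest.approx(3.80)

    def test_single_residue_returns_table_value(self):
        assert gravy("W") == KYTE_DOOLITTLE["W"]
        assert polarity("G") == GRANTHAM_POLARITY["G"]
        assert polarity("GG") == GRANTHAM_POLARITY["G"]

    def test_concatenation_linearity(self):
        a, b = "ACDK", "WYVLL"
        expect = (gravy(a) * len(a) + gravy(b) * len(b)) / (len(a) + len(b))
        assert gravy(a + b) == pytest.approx(expect)

    def test_against_table_lookup_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            pep = "".join(rng.choice(list(AA),
                                     size=rng.integers(1, 30)))
            assert gravy(pep) == sum(
                KYTE_DOOLITTLE[c] for c in pep) / len(pep)
            assert polarity(pep) == sum(
                GRANTHAM_POLARITY[c] for c in pep) / len(pep)

    def test_unknown_residue_raises(self):
        with pytest.raises(ValueError):
            gravy("ABX")
        with pytest.raises(ValueError):
            gravy("")


class TestPositionalStats:
    def test_identical_units_zero_sd(self, cfg):
        anns = [annotate_protein(make_protein(cfg, k=3), cfg)
                for _ in range(4)]
        df = positional_subunit_stats(anns)
        assert set(df["group"]) == {"LRRv1", "LRRv2", "LRRve"}
        assert (df["hydropathy_sd"] == 0).all()

    def test_single_unit_contributes_only_to_lrrve(self, cfg):
        anns = [annotate_protein(make_protein(cfg, k=1), cfg)]
        df = positional_subunit_stats(anns)
        assert list(df["group"]) == ["LRRve"]

    def test_matches_brute_force_recount(self, cfg):
        scfg = sim.SimConfig(n_animals=1, molecules_per_animal=40,
                             error_rate=0.0, nonfunctional_fraction=0.0,
                             shared_sequence_fraction=0.0)
        lib = sim.build_cassette_library(scfg, seed=51, pipeline_cfg=cfg)
        txs = sim.simulate_repertoire(lib, scfg, seed=52)
        anns = [annotate_protein(t.protein, cfg) for t in txs
                if not sim.has_spurious_motifs(t, cfg)]
        df = positional_subunit_stats(anns).set_index("group")
        # independent recount straight from the spans
        by_group = {}
        for a in anns:
            units = a.spans["LRRv"]
            for i, s in enumerate(units):
                g = "LRRve" if i == len(units) - 1 else f"LRRv{i + 1}"
                by_group.setdefault(g, []).append(
                    a.protein[s.start:s.end])
        for g, seqs in by_group.items():
            vals = [sum(KYTE_DOOLITTLE[c] for c in s) / len(s)
                    for s in seqs]
            assert df.loc[g, "n"] == len(seqs)
            assert df.loc[g, "hydropathy_mean"] == pytest.approx(
                np.mean(vals))
            if len(vals) > 1:
                assert df.loc[g, "hydropathy_sd"] == pytest.approx(
                    np.std(vals, ddof=1))


class TestLoopSplit:
    def test_poly_leucine_high_poly_arginine_low(self):
        high, low = split_loops_by_hydropathy(["L" * 10, "R" * 10], 0.35)
        assert high.loops == ["L" * 10]
        assert low.loops == ["R" * 10]

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        loops = ["".join(rng.choice(list(AA), size=20)) for _ in range(200)]
        high, low = split_loops_by_hydropathy(loops)
        assert len(high.loops) + len(low.loops) == len(loops)
        assert all(gravy(s) >= 0.35 for s in high.loops)
        assert all(gravy(s) < 0.35 for s in low.loops)

    def test_empty_input(self):
        high, low = split_loops_by_hydropathy([])
        assert high.loops == [] and low.loops == []


class TestFrequencyMatrix:
    def test_identical_sequences_unit_columns(self):
        freq = frequency_matrix(["PEPTIDE"] * 4)
        assert ((freq.max(axis=1) == 1.0).all())
        assert majority_residues(freq) == list("PEPTIDE")

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list(AA), size=24)) for _ in range(50)]
        freq = frequency_matrix(seqs)
        assert np.allclose(freq.sum(axis=1), 1.0, atol=1e-12)

    def test_single_divergent_position_splits_half(self):
        freq = frequency_matrix(["AAAA", "AAAC"])
        assert freq.loc[3, "A"] == 0.5 and freq.loc[3, "C"] == 0.5

    def test_simulated_lrrv_conserved_leucines_frequency_one(self, cfg):
        scfg = sim.SimConfig()
        lib = sim.build_cassette_library(scfg, seed=61, pipeline_cfg=cfg)
        freq = frequency_matrix(lib.lrrv)
        for i, aa in cfg.lrrv_conserved:
            assert freq.loc[sim.LRRV_MOTIF_OFFSET + i, aa] == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            frequency_matrix(["AAA", "AAAA"])


class TestLengthDistributions:
    def test_lengths_on_24aa_lattice(self, cfg):
        anns = [annotate_protein(make_protein(cfg, k=k), cfg)
                for k in (1, 2, 3, 4)]
        dist = length_distributions(anns)
        assert dist.lattice_fraction == 1.0
        assert sorted(dist.lrrv_count) == [1, 2, 3, 4]

    def test_single_record_zero_sd(self, cfg):
        dist = length_distributions(
            [annotate_protein(make_protein(cfg, k=2), cfg)])
        assert dist.protein_length_sd == 0.0

    def test_lrrv_histogram_matches_truth(self, cfg):
        scfg = sim.SimConfig(n_animals=1, molecules_per_animal=60,
                             error_rate=0.0, nonfunctional_fraction=0.0,
                             shared_sequence_fraction=0.0)
        lib = sim.build_cassette_library(scfg, seed=71, pipeline_cfg=cfg)
        txs = sim.simulate_repertoire(lib, scfg, seed=72)
        anns = [annotate_protein(t.protein, cfg) for t in txs
                if not sim.has_spurious_motifs(t, cfg)]
        dist = length_distributions(anns)
        from collections import Counter
        truth = Counter(t.lrrv_count for t in txs
                        if not sim.has_spurious_motifs(t, cfg))
        assert dist.lrrv_count == truth
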