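import random
from collections import Counter
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnaclassify.clustering import Cluster
from srnaclassify.io_model import reverse_complement_rna
from srnaclassify.structure import (
    FoldResult,
    dinucleotide_shuffle,
    fold_mfe,
    randfold_test,
    select_fold_strand,
    structure_enrichment_curves,
)

from conftest import make_read

PAIR_E = {frozenset("GC"): -1.0, frozenset("AU"): -0.7, frozenset("GU"): -0.5}


def enumerate_min_energy(seq: str, min_loop: int = 3) -> float:
    """Exponential enumeration of every non-crossing structure (oracle)."""

    def best(i: int, j: int) -> float:
        if j - i < min_loop + 1:
            return 0.0
        options = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            e = PAIR_E.get(frozenset({seq[i], seq[k]}))
            if e is not None:
                options.append(best(i + 1, k - 1) + e + best(k + 1, j))
        return min(options)

    return best(0, len(seq) - 1)


HAIRPIN_ARM = "GCGCGGCAUGCAGCGUGCGC"  # 20 nt, GC-rich
HAIRPIN = HAIRPIN_ARM + "GAAA" + reverse_complement_rna(HAIRPIN_ARM)


class TestFoldMfe:
    def test_homopolymer_is_unstructured(self):
        mfe, structure = fold_mfe("A" * 30, backend="builtin")
        assert mfe == 0.0 and structure == "." * 30

    def test_perfect_gc_hairpin_pairs_fully_under_fallback_engine(self):
        mfe, structure = fold_mfe(HAIRPIN, backend="builtin")
        assert structure.count("(") == 20 and structure.count(")") == 20
        # 16 GC pairs and 4 AU pairs in the stem under the proxy energies
        assert mfe == pytest.approx(16 * -1.0 + 4 * -0.7)

    def test_fallback_matches_enumeration_oracle_on_short_sequences(self):
        rng = random.Random(7)
        for _ in range(25):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(10, 13)))
            mfe, structure = fold_mfe(seq, backend="builtin")
            assert mfe == pytest.approx(enumerate_min_energy(seq))
            assert len(structure) == len(seq)

    def test_deterministic(self):
        assert fold_mfe(HAIRPIN, backend="builtin") == fold_mfe(HAIRPIN, backend="builtin")

    def test_non_acgu_raises(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGUNACGUACGU", backend="builtin")

    def test_mfe_nonpositive_both_backends(self):
        rng = random.Random(1)
        for backend in ("builtin", "vienna"):
            for _ in range(5):
                seq = "".join(rng.choice("ACGU") for _ in range(40))
                mfe, _ = fold_mfe(seq, backend=backend)
                assert mfe <= 0.0

    def test_local_span_caps_pairing_distance(self):
        # complementary arms 60 nt apart cannot pair when the span cap is 40
        seq = HAIRPIN_ARM + "A" * 40 + reverse_complement_rna(HAIRPIN_ARM)
        capped, _ = fold_mfe(seq, local_span=40, backend="builtin")
        free, _ = fold_mfe(seq, local_span=150, backend="builtin")
        assert free < capped


class TestSelectFoldStrand:
    genome = {"s1": "G" * 200 + "GGGGGGGGGGGGCCCCCCCCCCCCAAAAAAAAAAAAAAAAAAAAAAAAAA" + "A" * 200}

    def _cluster(self, strands):
        reads = [
            make_read(scaffold="s1", start=200 + 5 * i, length=20, strand=s)
            for i, s in enumerate(strands)
        ]
        return Cluster("s1", 200, 251, reads)

    def test_single_strand_cluster_folds_that_strand(self):
        strand, _, _ = select_fold_strand(self._cluster("--"), self.genome)
        assert strand == "-"

    def test_mixed_cluster_keeps_lower_mfe_strand(self):
        # plus strand has the GC helix, minus strand the same by symmetry;
        # make an asymmetric span where only one strand can pair GU-rich
        genome = {"s1": "A" * 100 + "GGGGGGGGGGUUUUUUUUUUGGGGGGGGGGAAAAAAAAAAAAAAAAAAAAA" + "A" * 100}
        c = Cluster(
            "s1",
            100,
            151,
            [
                make_read(scaffold="s1", start=100, length=20, strand="+"),
                make_read(scaffold="s1", start=120, length=20, strand="-"),
            ],
        )
        strand, mfe, structure = select_fold_strand(c, genome, backend="builtin")
        plus_mfe, _ = fold_mfe("GGGGGGGGGGUUUUUUUUUUGGGGGGGGGGAAAAAAAAAAAAAAAAAAAAA", backend="builtin")
        assert mfe <= plus_mfe
        assert len(structure) == 51

    def test_palindromic_span_ties_to_plus(self):
        genome = {"s1": "GGGGGGGGGGGGGGGGGGGGGGGGGCCCCCCCCCCCCCCCCCCCCCCCCC"}
        c = Cluster(
            "s1",
            0,
            50,
            [
                make_read(scaffold="s1", start=0, length=20, strand="+"),
                make_read(scaffold="s1", start=20, length=20, strand="-"),
            ],
        )
        strand, _, _ = select_fold_strand(c, genome, backend="builtin")
        assert strand == "+"

    def test_missing_scaffold_raises(self):
        with pytest.raises(KeyError):
            select_fold_strand(self._cluster("+"), {"other": "ACGT" * 100})


class TestDinucleotideShuffle:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_exact_dinucleotide_counts_preserved(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(2, 80)))
        shuffled = dinucleotide_shuffle(seq, seed)
        assert len(shuffled) == len(seq)
        assert Counter(shuffled) == Counter(seq)
        dinucs = lambda s: Counter(s[i : i + 2] for i in range(len(s) - 1))
        assert dinucs(shuffled) == dinucs(seq)

    def test_length_two_sequence_is_identity(self):
        assert dinucleotide_shuffle("AC", 0) == "AC"

    def test_same_seed_same_output(self):
        seq = "ACGUACGGCAUGCUAGGCAUCGAUAGCUAACGU"
        assert dinucleotide_shuffle(seq, 5) == dinucleotide_shuffle(seq, 5)

    def test_different_seeds_usually_differ(self):
        seq = "ACGUACGGCAUGCUAGGCAUCGAUAGCUAACGU"
        outputs = {dinucleotide_shuffle(seq, s) for s in range(10)}
        assert len(outputs) > 1


class TestRandfold:
    def test_homopolymer_p_is_one(self):
        assert randfold_test("A" * 40, n_shuffles=20, backend="builtin") == 1.0

    def test_p_bounded_by_add_one_formula(self):
        rng = random.Random(3)
        for _ in range(5):
            seq = "".join(rng.choice("ACGU") for _ in range(50))
            p = randfold_test(seq, n_shuffles=20, rng_seed=1, backend="builtin")
            assert 1 / 21 <= p <= 1.0

    def test_strong_hairpin_is_significant_at_100_shuffles(self):
        p = randfold_test(HAIRPIN, n_shuffles=100, rng_seed=0, backend="builtin")
        assert p <= 0.02

    def test_single_shuffle_formula(self):
        # the hairpin's shuffle is essentially always less stable: p = 1/2
        p = randfold_test(HAIRPIN, n_shuffles=1, rng_seed=0, backend="builtin")
        assert p == 0.5


class TestEnrichmentCurves:
    def _cluster(self, label, p):
        c = Cluster("s1", 0, 60, [make_read(start=0, length=21)])
        c.label = label
        c.fold = FoldResult("+", -5.0, "." * 60, randfold_p=p)
        return c

    def test_all_p_one_gives_zero_percent_everywhere(self):
        clusters = [self._cluster("piRNA", 1.0) for _ in range(5)]
        curves = structure_enrichment_curves(clusters)
        assert (curves.loc["piRNA"] == 0.0).all()

    def test_four_cutoffs_give_four_values_per_class(self):
        clusters = [self._cluster("endo_siRNA", 0.01)]
        curves = structure_enrichment_curves(clusters)
        assert curves.shape[1] == 4

    def test_structured_class_above_background_at_each_cutoff(self):
        clusters = (
            [self._cluster("endo_siRNA", 0.0099) for _ in range(10)]
            + [self._cluster("piRNA", 0.8) for _ in range(10)]
            + [self._cluster("unclassified", 0.5) for _ in range(10)]
        )
        curves = structure_enrichment_curves(clusters)
        assert (curves.loc["endo_siRNA"] > curves.loc["background"]).all()
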