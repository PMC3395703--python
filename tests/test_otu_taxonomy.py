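"""OTU clustering, k-mer classification and abundance tabulation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from pyrotagger.otu_taxonomy import (AbundanceTable, ClassifierParams,
                                     ClusterParams, KmerClassifier,
                                     classify_read, cluster_otus,
                                     pairwise_distance, singleton_fraction,
                                     tabulate)
from pyrotagger.read_qc import PyroRead
from pyrotagger.synth_community import (ERROR_FREE, build_reference_taxon,
                                        simulate_reads, MockCommunity)


def _random_dna(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, positions):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


class TestClusterOtus:
    def test_identical_reads_one_otu(self, rng):
        s = _random_dna(300, rng)
        reads = [(f"r{i}", s) for i in range(5)]
        assert cluster_otus(reads) == [[f"r{i}" for i in range(5)]]

    def test_two_groups_at_90pct_identity(self, rng):
        a = _random_dna(300, rng)
        b = _mutate(a, rng.choice(300, size=30, replace=False))  # 90%
        reads = [("a1", a), ("a2", a), ("b1", b), ("b2", b)]
        otus = cluster_otus(reads)
        assert sorted(sorted(o) for o in otus) == [["a1", "a2"], ["b1", "b2"]]

    def test_complete_linkage_never_chains(self, rng):
        """A~B and B~C at 97% but A~C at 94%: complete linkage keeps the
        far pair apart; verified against brute force over 3-element
        partitions."""
        base = _random_dna(100, rng)
        pos = rng.choice(100, size=6, replace=False)
        a = _mutate(base, pos[:3])           # A~B: 3 diffs (97%)
        c = _mutate(base, pos[3:])           # B~C: 3 diffs; A~C: 6 diffs (94%)
        reads = [("A", a), ("B", base), ("C", c)]
        d = {(x, y): pairwise_distance(sx, sy)
             for (x, sx), (y, sy) in itertools.combinations(reads, 2)}
        assert d[("A", "B")] == pytest.approx(0.03)
        assert d[("B", "C")] == pytest.approx(0.03)
        assert d[("A", "C")] == pytest.approx(0.06)
        otus = cluster_otus(reads, ClusterParams(otu_identity=0.97,
                                                 linkage="complete"))
        sizes = sorted(len(o) for o in otus)
        assert sizes == [1, 2]
        # brute force: valid complete-linkage cuts at 0.03 are exactly the
        # partitions where every within-cluster pair has distance <= 0.03
        merged = next(o for o in otus if len(o) == 2)
        assert "B" in merged  # B is compatible with either neighbour, never A+C

    @pytest.mark.parametrize("seed", range(5))
    def test_refinement_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        base = _random_dna(200, rng)
        reads = []
        for i in range(8):
            k = int(rng.integers(0, 12))
            reads.append((f"r{i}", _mutate(base, rng.choice(200, size=k, replace=False))))
        n_loose = len(cluster_otus(reads, ClusterParams(otu_identity=0.90)))
        n_tight = len(cluster_otus(reads, ClusterParams(otu_identity=0.97)))
        assert n_tight >= n_loose


class TestSingletonFraction:
    def test_limits_and_count(self):
        assert singleton_fraction([["a", "b"], ["c", "d"]]) == 0.0
        assert singleton_fraction([["a"], ["b"]]) == 1.0
        partition = [["s1"], ["s2"], ["s3"]] + [[f"x{i}", f"y{i}"] for i in range(7)]
        assert singleton_fraction(partition) == pytest.approx(0.3)


def _reference_set():
    lineages = [
        ("Bacteria", "P1", "C1", "O1", "F1", "GenA"),
        ("Bacteria", "P1", "C1", "O1", "F1", "GenB"),   # same family as GenA
        ("Bacteria", "P2", "C2", "O2", "F2", "GenC"),
        ("Bacteria", "P3", "C3", "O3", "F3", "GenD"),
    ]
    return [build_reference_taxon(f"t{i}", lin, seed=100 + i)
            for i, lin in enumerate(lineages)]


class TestClassifier:
    def test_exact_substring_hits_its_genus_with_full_confidence(self):
        refs = _reference_set()
        read = PyroRead("r", refs[2].sequence[:350], np.full(350, 35),
                        orientation="forward")
        c = classify_read(read, refs, seed=1)
        assert c.lineage[-1] == "GenC"
        assert c.confidences["genus"] == pytest.approx(1.0, abs=0.02)

    def test_random_dna_truncates_above_genus(self, rng):
        refs = _reference_set()
        read = PyroRead("r", _random_dna(350, rng), np.full(350, 35),
                        orientation="forward")
        c = classify_read(read, refs, seed=2)
        assert len(c.lineage) < 6  # never confidently placed in a genus

    def test_chimera_between_same_family_genera_truncates_at_family(self):
        refs = _reference_set()
        half = 230
        chimera = refs[0].sequence[:half] + refs[1].sequence[half:460]
        read = PyroRead("r", chimera, np.full(len(chimera), 35),
                        orientation="forward")
        hits_at_genus = 0
        for seed in range(20):
            c = classify_read(read, refs, seed=seed)
            if len(c.lineage) == 6:
                hits_at_genus += 1
            if c.lineage[:5]:
                # whatever depth survives agrees with the shared family
                assert c.lineage[:2] == ("Bacteria", "P1")
        assert hits_at_genus == 0  # bootstrap splits GenA/GenB below 80%

    def test_threshold_zero_full_depth_threshold_above_one_unclassified(self):
        refs = _reference_set()
        read = PyroRead("r", refs[3].sequence[:300], np.full(300, 35),
                        orientation="forward")
        full = classify_read(read, refs, ClassifierParams(confidence_threshold=0.0), seed=3)
        assert len(full.lineage) == 6
        none = classify_read(read, refs, ClassifierParams(confidence_threshold=1.01), seed=3)
        assert none.lineage == ()
        assert none.at("genus") == "unclassified"

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            KmerClassifier([])

    def test_genus_table_recovers_template_fractions(self, mid):
        """Error-free libraries tabulated at genus level reproduce the
        template fractions within multinomial 3 sigma."""
        refs = _reference_set()
        fracs = np.array([0.4, 0.3, 0.2, 0.1])
        pool = MockCommunity(refs, fracs)
        depth = 2000
        reads = simulate_reads(pool, depth, mid, model=ERROR_FREE, seed=9)
        from pyrotagger.read_qc import run_qc
        retained, _, _ = run_qc(reads, {"L": mid})
        clf = KmerClassifier(refs)
        cls = clf.classify_reads(retained["L"], seed=4)
        table = tabulate({"L": list(cls.values())}, rank="genus")
        rel = table.relative()["L"] / 100.0
        n = len(retained["L"])
        for taxon, frac in zip(refs, fracs):
            got = rel.get(taxon.genus, 0.0)
            sigma = np.sqrt(frac * (1 - frac) / n)
            assert abs(got - frac) < 3 * sigma + 0.01


class TestTabulate:
    def test_counts_to_percent(self):
        table = tabulate({"L": ["X"] * 80 + ["Y"] * 20})
        rel = table.relative()
        assert rel.loc["X", "L"] == pytest.approx(80.0)
        assert rel.loc["Y", "L"] == pytest.approx(20.0)

    def test_columns_sum_to_hundred(self):
        table = tabulate({"L1": ["a", "b", "c"], "L2": ["a", "a", "d", "e"]})
        assert np.allclose(table.relative().sum(axis=0), 100.0)

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError):
            tabulate({"L": []})

    def test_unknown_rank_rejected(self):
        from pyrotagger.otu_taxonomy import Classification
        c = Classification(("Bacteria",), {"domain": 1.0}, "g")
        with pytest.raises(ValueError):
            tabulate({"L": [c]}, rank="kingdom")
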