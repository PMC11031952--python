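"""Seed extraction, chaining, overlap merging, PPM building and MEME I/O."""

import itertools

import numpy as np
import pytest

from motifgat import (
    SequenceRecord,
    TrainConfig,
    best_alignment_correlation,
    build_motifs,
    collect_attention,
    find_kmer_seeds,
    generate_ppm,
    merge_overlaps,
    merge_seeds,
    read_meme,
    train,
    write_meme,
)
from motifgat.hetgraph import CoexistStats, build_graph
from motifgat.motifs import (
    KmerSeed,
    LabelSplitAttention,
    TFBSInstance,
    empirical_background,
    information_content,
    write_bed,
)


# ---------------------------------------------------------------------------
# attention collection and denoising

@pytest.fixture(scope="module")
def trained(small_graph):
    params, _ = train(small_graph, TrainConfig(epochs=5, d_k=6, rng_seed=0))
    return params, small_graph


class TestCollectAttention:

    def test_backgrounds_are_edge_entry_means(self, trained):
        params, graph = trained
        att = collect_attention(params, graph)
        # oracle: average the negative rows entry-by-entry over edges
        vals_sim, vals_co = [], []
        neg_rows = [i for i, r in enumerate(
            [r for r in graph.sequences if r.label == 0])]
        for i in range(att.B0_sim.shape[0]):
            for j in range(att.B0_sim.shape[1]):
                if att.M0[i, j]:
                    vals_sim.append(att.B0_sim[i, j])
                    vals_co.append(att.B0_co[i, j])
        assert att.background_sim == pytest.approx(np.mean(vals_sim))
        assert att.background_co == pytest.approx(np.mean(vals_co))

    def test_denoised_is_subtraction_on_edges(self, trained):
        params, graph = trained
        att = collect_attention(params, graph)
        i, j = np.argwhere(att.M1)[0]
        assert att.dnB1_sim[i, j] == pytest.approx(att.B1_sim[i, j] - att.background_sim)
        assert np.isnan(att.dnB1_sim[~att.M1]).all()

    def test_rows_partition_by_label(self, trained):
        params, graph = trained
        att = collect_attention(params, graph)
        n_pos = sum(r.label for r in graph.sequences)
        assert att.B1_sim.shape[0] == n_pos
        assert att.B0_sim.shape[0] == len(graph.sequences) - n_pos

    def test_no_negatives_is_error(self):
        recs = [SequenceRecord(f"p{i}", "ACGTACGTAC", 1) for i in range(4)]
        graph = build_graph(recs, lenk=3)
        params, _ = train(graph, TrainConfig(epochs=1, d_k=4, rng_seed=0))
        with pytest.raises(ValueError, match="negative"):
            collect_attention(params, graph)


def _attention_fixture(B1_sim, B1_co, records):
    """LabelSplitAttention with zero background (negative rows all zero on edges)."""
    n_pos, m = B1_sim.shape
    M1 = np.zeros((n_pos, m), dtype=bool)
    for i, rec in enumerate(records):
        for kid, _ in rec.kmer_occurrences:
            M1[i, kid] = True
    M0 = np.ones((1, m), dtype=bool)
    zero = np.zeros((1, m))
    return LabelSplitAttention(
        B1_sim=B1_sim, B1_co=B1_co, B0_sim=zero, B0_co=zero,
        M1=M1, M0=M0, positive_records=list(records),
    )


class _FakeGraph:
    def __init__(self, records):
        self.sequences = list(records)


class TestFindKmerSeeds:
    def _records(self):
        from motifgat.hetgraph import KmerVocabulary
        from motifgat import split_kmers

        vocab = KmerVocabulary(lenk=3)
        recs = [split_kmers(SequenceRecord(f"p{i}", s, 1), 3, vocab)
                for i, s in enumerate(["ACGTA", "CGTAC", "TACGT"])]
        return recs, vocab

    def test_or_rule_emits_on_single_positive_side(self):
        recs, vocab = self._records()
        m = len(vocab)
        B1_sim = np.full((3, m), 0.1)
        B1_co = np.full((3, m), -0.2)
        att = _attention_fixture(B1_sim, B1_co, recs)
        seeds = find_kmer_seeds(att, _FakeGraph(recs))
        # every occurrence passes: dn_sim = 0.1 > 0
        assert len(seeds) == sum(len(r.kmer_occurrences) for r in recs)

    def test_strict_inequality_excludes_zero(self):
        recs, vocab = self._records()
        m = len(vocab)
        att = _attention_fixture(np.zeros((3, m)), np.zeros((3, m)), recs)
        assert find_kmer_seeds(att, _FakeGraph(recs)) == []

    def test_equals_exhaustive_enumeration(self, rng):
        recs, vocab = self._records()
        m = len(vocab)
        B1_sim = rng.normal(scale=0.1, size=(3, m))
        B1_co = rng.normal(scale=0.1, size=(3, m))
        att = _attention_fixture(B1_sim, B1_co, recs)
        seeds = find_kmer_seeds(att, _FakeGraph(recs))
        got = {(s.sequence_id, s.kmer_id, s.offset) for s in seeds}
        expected = set()
        for i, rec in enumerate(recs):
            for kid, off in rec.kmer_occurrences:
                if B1_sim[i, kid] > 0 or B1_co[i, kid] > 0:
                    expected.add((rec.id, kid, off))
        assert got == expected

    def test_repeated_kmer_gives_one_seed_per_occurrence(self):
        from motifgat.hetgraph import KmerVocabulary
        from motifgat import split_kmers

        vocab = KmerVocabulary(lenk=2)
        rec = split_kmers(SequenceRecord("p0", "AAAA", 1), 2, vocab)
        att = _attention_fixture(np.full((1, 1), 0.3), np.full((1, 1), 0.3), [rec])
        seeds = find_kmer_seeds(att, _FakeGraph([rec]))
        assert [s.offset for s in seeds] == [0, 1, 2]


# ---------------------------------------------------------------------------
# chaining and overlap merging

def _stats(pairs, counts):
    return CoexistStats(pair_counts=dict(pairs), kmer_counts=dict(counts), n_pos=10)


class TestMergeSeeds:
    LENK = 5

    def _seed(self, kid, off, seq_id="s0"):
        return KmerSeed(kid, seq_id, off, 0.1, 0.1)

    def test_adjacent_pair_above_threshold_chains(self):
        rec = SequenceRecord("s0", "ACGTACGTACGTACG", 1)
        seeds = [self._seed(0, 3), self._seed(1, 4)]
        stats = _stats({(0, 1): 9}, {0: 10, 1: 10})
        out = merge_seeds(seeds, stats, {"s0": rec}, lenk=self.LENK, theta_co=0.5)
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (3, 4 + self.LENK)
        assert out[0].subsequence == rec.sequence[3:9]

    def test_low_probability_breaks_chain(self):
        rec = SequenceRecord("s0", "ACGTACGTACGTACG", 1)
        seeds = [self._seed(0, 3), self._seed(1, 4)]
        stats = _stats({(0, 1): 1}, {0: 10, 1: 10})
        out = merge_seeds(seeds, stats, {"s0": rec}, lenk=self.LENK, theta_co=0.5)
        assert [(t.start, t.end) for t in out] == [(3, 8), (4, 9)]

    def test_offset_gap_breaks_chain_regardless_of_probability(self):
        rec = SequenceRecord("s0", "ACGTACGTACGTACG", 1)
        seeds = [self._seed(0, 3), self._seed(1, 5)]
        stats = _stats({(0, 1): 10}, {0: 10, 1: 10})
        out = merge_seeds(seeds, stats, {"s0": rec}, lenk=self.LENK, theta_co=0.5)
        assert len(out) == 2

    def test_equals_brute_force_chain_enumeration(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        rec = SequenceRecord("s0", seq, 1)
        offsets = [2, 3, 4, 8, 9, 15]
        kids = list(range(6))
        seeds = [self._seed(k, o) for k, o in zip(kids, offsets)]
        # adjacency allowed between (2,3) and (8,9) only
        stats = _stats({(0, 1): 8, (1, 2): 2, (3, 4): 8}, {k: 10 for k in kids})
        out = merge_seeds(seeds, stats, {"s0": rec}, lenk=self.LENK, theta_co=0.5)
        # brute force: walk the sorted offsets joining iff offset+1 and p >= 0.5
        expected = []
        chain = [seeds[0]]
        for s in seeds[1:]:
            prv = chain[-1]
            p = stats.pair_counts.get((prv.kmer_id, s.kmer_id), 0) / 10
            if s.offset == prv.offset + 1 and p >= 0.5:
                chain.append(s)
            else:
                expected.append((chain[0].offset, chain[-1].offset + self.LENK))
                chain = [s]
        expected.append((chain[0].offset, chain[-1].offset + self.LENK))
        assert [(t.start, t.end) for t in out] == expected
        for t in out:
            assert t.subsequence == seq[t.start:t.end]


class TestMergeOverlaps:
    def _inst(self, start, end, seq="ACGTACGTACGTACGTACGT", seq_id="s0"):
        return TFBSInstance(seq_id, start, end, seq[start:end])

    def test_overlapping_intervals_union(self):
        out = merge_overlaps([self._inst(3, 8), self._inst(6, 11)])
        assert [(t.start, t.end) for t in out] == [(3, 11)]
        assert out[0].subsequence == "ACGTACGTACGTACGTACGT"[3:11]

    def test_disjoint_and_abutting_stay_separate(self):
        out = merge_overlaps([self._inst(0, 4), self._inst(4, 8), self._inst(12, 15)])
        assert [(t.start, t.end) for t in out] == [(0, 4), (4, 8), (12, 15)]

    def test_equals_brute_force_component_union(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        items = []
        for _ in range(10):
            s = int(rng.integers(0, 50))
            items.append(self._inst(s, s + int(rng.integers(3, 9)), seq=seq))
        out = merge_overlaps(items)
        # oracle: connected components under pairwise overlap
        n = len(items)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            a, b = items[i], items[j]
            if a.start < b.end and b.start < a.end:
                parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(items[i])
        expected = sorted(
            (min(t.start for t in grp), max(t.end for t in grp)) for grp in comps.values()
        )
        assert sorted((t.start, t.end) for t in out) == expected
        # outputs pairwise disjoint and slices match
        for a, b in itertools.combinations(out, 2):
            assert a.end <= b.start or b.end <= a.start
        for t in out:
            assert t.subsequence == seq[t.start:t.end]


# ---------------------------------------------------------------------------
# PPMs

class TestBuildMotifs:
    def _inst(self, sub, seq_id="s0"):
        return TFBSInstance(seq_id, 0, len(sub), sub)

    def test_column_frequencies(self):
        motifs = build_motifs([self._inst("AAA"), self._inst("AAC")],
                              min_support=2, pseudocount=0.0)
        assert len(motifs) == 1
        mo = motifs[0]
        assert mo.width == 3 and mo.support == 2
        assert mo.ppm[:, 2] == pytest.approx([0.5, 0.5, 0.0, 0.0])
        assert np.allclose(mo.ppm.sum(axis=0), 1.0, atol=1e-9)

    def test_below_support_dropped(self):
        assert build_motifs([self._inst("ACGTA")], min_support=2) == []

    def test_monte_carlo_ppm_recovery(self):
        rng = np.random.default_rng(5)
        source = generate_ppm(6, 1.2, rng)
        bases = np.array(list("ACGT"))
        insts = [
            self._inst("".join(bases[rng.choice(4, p=source[:, j])] for j in range(6)))
            for _ in range(20)
        ]
        motifs = build_motifs(insts, min_support=5, pseudocount=0.0)
        dev = np.abs(motifs[0].ppm - source).mean()
        assert dev <= 0.15

    def test_pseudocount_strictly_positive_probabilities(self):
        motifs = build_motifs([self._inst("AAAA")] * 5, min_support=5, pseudocount=0.01)
        assert np.all(motifs[0].ppm > 0)
        assert np.allclose(motifs[0].ppm.sum(axis=0), 1.0, atol=1e-9)


class TestPpmUtilities:
    def test_information_content_limits(self):
        flat = np.full((4, 3), 0.25)
        assert np.allclose(information_content(flat), 0.0, atol=1e-9)
        sharp = np.zeros((4, 2))
        sharp[0] = 1.0
        assert np.allclose(information_content(sharp), 2.0, atol=1e-6)

    def test_best_alignment_identity_and_shift(self):
        rng = np.random.default_rng(8)
        ppm = generate_ppm(8, 1.5, rng)
        assert best_alignment_correlation(ppm, ppm) == pytest.approx(1.0)
        sub = ppm[:, 2:8]  # 6-wide slice should align at its true offset
        assert best_alignment_correlation(sub, ppm) > 0.99

    def test_unrelated_ppms_correlate_poorly(self):
        rng = np.random.default_rng(9)
        a, b = generate_ppm(8, 1.8, rng), generate_ppm(8, 1.8, rng)
        assert best_alignment_correlation(a, b) < 0.9

    def test_empirical_background_sums_to_one(self):
        recs = [SequenceRecord("a", "AACC", 1), SequenceRecord("b", "GGTT", 1)]
        bg = empirical_background(recs)
        assert bg == pytest.approx([0.25, 0.25, 0.25, 0.25])


class TestMemeIO:
    def _motifs(self):
        rng = np.random.default_rng(2)
        insts = [TFBSInstance("s", 0, 3, s) for s in ("ACG", "ACG", "ACT", "CCG", "ACG")]
        return build_motifs(insts, min_support=5, pseudocount=0.01)

    def test_file_structure(self, tmp_path):
        p = tmp_path / "m.meme"
        write_meme(self._motifs(), p)
        text = p.read_text()
        assert "MEME version 4" in text
        assert "w= 3" in text
        assert text.count("letter-probability matrix") == 1

    def test_round_trip_at_printed_precision(self, tmp_path):
        motifs = self._motifs()
        p = tmp_path / "m.meme"
        write_meme(motifs, p)
        back = read_meme(p)
        assert len(back) == len(motifs)
        for a, b in zip(motifs, back):
            assert b.width == a.width and b.support == a.support
            assert np.allclose(b.ppm, np.round(a.ppm, 6), atol=1e-9)

    def test_empty_list_is_error_and_writes_nothing(self, tmp_path):
        p = tmp_path / "none.meme"
        with pytest.raises(ValueError):
            write_meme([], p)
        assert not p.exists()

    def test_bed_export(self, tmp_path):
        insts = [TFBSInstance("pos_00001", 10, 18, "ACGTACGT")]
        p = tmp_path / "sites.bed"
        write_bed(insts, p)
        fields = p.read_text().strip().split("\t")
        assert fields[:3] == ["pos_00001", "10", "18"]
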