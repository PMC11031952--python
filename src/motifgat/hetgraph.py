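"""Heterogeneous k-mer/sequence graph construction.

The model operates on a heterogeneous graph with two node types — the m
unique k-mers of a dataset and its n sequences — and three edge types,
kept as separate subgraphs:

* **similarity** (k-mer/k-mer): edges between near-identical k-mers,
  weighted by their positional identity fraction ``(lenk - d_H) / lenk``
  for Hamming distance ``d_H`` up to a cutoff (default 1 mismatch).  These
  edges let the first attention layer pool single-mutation motif variants.
* **coexisting** (k-mer/k-mer): edges weighted by the fraction of positive
  sequences containing both k-mers.  Negatives are per-sequence shuffles,
  so by default they are excluded from this statistic.
* **inclusive** (k-mer/sequence): edges weighted by the number of
  occurrences of the k-mer in the sequence.

All weight matrices are held sparse (CSR).  ``CoexistStats`` additionally
records immediate-adjacency counts — in how many positive sequences one
k-mer starts exactly one base after another — from which the coexisting
probability used for seed chaining is computed as a conditional frequency.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .datasets import ALPHABET, SequenceRecord, split_kmers, write_fasta, read_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "KmerVocabulary",
    "CoexistStats",
    "HeterogeneousGraph",
    "build_vocab",
    "build_similarity_matrix",
    "build_coexisting_matrix",
    "build_inclusive_matrix",
    "build_coexist_stats",
    "coexist_probability",
    "build_graph",
    "save_graph",
    "load_graph",
]


@dataclass
class KmerVocabulary:
    """Ordered set of unique k-mers with a string ↔ id bijection.

    Ids are assigned by first appearance, so re-splitting the same records
    in the same order reproduces identical ids.
    """

    lenk: int
    kmers: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def add(self, kmer: str) -> int:
        if len(kmer) != self.lenk:
            raise ValueError(f"k-mer {kmer!r} has length {len(kmer)}, expected {self.lenk}")
        kid = self.index.get(kmer)
        if kid is None:
            kid = len(self.kmers)
            self.index[kmer] = kid
            self.kmers.append(kmer)
        return kid

    def __len__(self) -> int:
        return len(self.kmers)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.index

    def __getitem__(self, kid: int) -> str:
        return self.kmers[kid]


def build_vocab(records: Sequence[SequenceRecord], lenk: int) -> KmerVocabulary:
    """Build the k-mer vocabulary across all records, populating their occurrence lists."""
    if not records:
        raise ValueError("cannot build a vocabulary from an empty record set")
    vocab = KmerVocabulary(lenk=lenk)
    for rec in records:
        split_kmers(rec, lenk, vocab)
    return vocab


def _hamming_variants(kmer: str, max_mismatch: int):
    """All strings within Hamming distance 1..max_mismatch of ``kmer``, with their distance."""
    L = len(kmer)
    for d in range(1, max_mismatch + 1):
        for positions in itertools.combinations(range(L), d):
            alternatives = [[b for b in ALPHABET if b != kmer[p]] for p in positions]
            for subst in itertools.product(*alternatives):
                var = list(kmer)
                for p, b in zip(positions, subst):
                    var[p] = b
                yield "".join(var), d


def build_similarity_matrix(vocab: KmerVocabulary, sim_max_mismatch: int = 1) -> sp.csr_matrix:
    """Similarity subgraph weights: identity fraction under a mismatch cutoff.

    ``W_sim(x, y) = (lenk - d_H(x, y)) / lenk`` when ``0 < d_H <=
    sim_max_mismatch``, else 0.  Symmetric with a zero diagonal.
    """
    if len(vocab) == 0:
        raise ValueError("empty vocabulary")
    rows, cols, data = [], [], []
    lenk = vocab.lenk
    for x, kmer in enumerate(vocab.kmers):
        for variant, d in _hamming_variants(kmer, sim_max_mismatch):
            y = vocab.index.get(variant)
            if y is not None:
                rows.append(x)
                cols.append(y)
                data.append((lenk - d) / lenk)
    m = len(vocab)
    return sp.csr_matrix((data, (rows, cols)), shape=(m, m))


def _occurrence_ids(rec: SequenceRecord) -> list[int]:
    if rec.kmer_occurrences is None:
        raise ValueError(f"record {rec.id!r} has no k-mer occurrences; split it first")
    return [kid for kid, _ in rec.kmer_occurrences]


def build_coexisting_matrix(
    vocab: KmerVocabulary,
    records: Sequence[SequenceRecord],
    positive_only: bool = True,
    min_z: float = 3.0,
) -> sp.csr_matrix:
    """Coexisting subgraph weights: above-chance co-occurrence across (positive) sequences.

    ``W_co(x, y)`` is the number of counted sequences containing both x and
    y, divided by the number of counted sequences — kept only for pairs
    whose co-occurrence count exceeds the independence expectation
    ``N * p_x * p_y`` by more than ``min_z`` binomial standard deviations.
    Without the significance filter (``min_z=0``, the plain frequency rule)
    the subgraph is near-complete on realistic data — almost every k-mer
    pair co-occurs somewhere — and attention over it is uninformative;
    thresholding keeps exactly the pairs that travel together, which for
    motif-bearing data are the k-mer windows of the shared motif.
    Symmetric, zero diagonal.
    """
    counted = [r for r in records if r.label == 1] if positive_only else list(records)
    if not counted:
        raise ValueError("no sequences to count co-occurrence over")
    m = len(vocab)
    N = len(counted)
    incidence = np.zeros((N, m), dtype=np.float64)
    for i, rec in enumerate(counted):
        incidence[i, list(set(_occurrence_ids(rec)))] = 1.0
    co = incidence.T @ incidence
    np.fill_diagonal(co, 0.0)
    if min_z > 0:
        p = incidence.mean(axis=0)
        p_pair = np.outer(p, p)
        var = N * p_pair * (1.0 - p_pair)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (co - N * p_pair) / np.sqrt(np.where(var > 0, var, np.nan))
        co = np.where(np.nan_to_num(z, nan=-np.inf) > min_z, co, 0.0)
    co /= N
    return sp.csr_matrix(co)


def build_inclusive_matrix(vocab: KmerVocabulary, records: Sequence[SequenceRecord]) -> sp.csr_matrix:
    """Inclusive subgraph weights (m×n): occurrence counts of k-mer x in sequence z."""
    rows, cols, data = [], [], []
    for z, rec in enumerate(records):
        counts: dict[int, int] = {}
        for kid in _occurrence_ids(rec):
            counts[kid] = counts.get(kid, 0) + 1
        for kid, c in counts.items():
            rows.append(kid)
            cols.append(z)
            data.append(float(c))
    return sp.csr_matrix((data, (rows, cols)), shape=(len(vocab), len(records)))


@dataclass
class CoexistStats:
    """Immediate-adjacency statistics over positive sequences.

    ``pair_counts[(x, y)]`` — positive sequences in which some occurrence of
    y starts exactly one base after an occurrence of x; ``kmer_counts[x]`` —
    positive sequences containing x at all.
    """

    pair_counts: dict[tuple[int, int], int] = field(default_factory=dict)
    kmer_counts: dict[int, int] = field(default_factory=dict)
    n_pos: int = 0


def build_coexist_stats(positive_records: Sequence[SequenceRecord]) -> CoexistStats:
    stats = CoexistStats(n_pos=len(positive_records))
    for rec in positive_records:
        if rec.label != 1:
            raise ValueError("coexist statistics are defined over positive sequences")
        occ = rec.kmer_occurrences
        if occ is None:
            raise ValueError(f"record {rec.id!r} has no k-mer occurrences")
        for kid in {k for k, _ in occ}:
            stats.kmer_counts[kid] = stats.kmer_counts.get(kid, 0) + 1
        by_offset = dict((off, kid) for kid, off in occ)
        pairs = {
            (kid, by_offset[off + 1]) for off, kid in by_offset.items() if off + 1 in by_offset
        }
        for pair in pairs:
            stats.pair_counts[pair] = stats.pair_counts.get(pair, 0) + 1
    return stats


def coexist_probability(stats: CoexistStats, x: int, y: int) -> float:
    """P(an occurrence of y directly follows x | a positive sequence contains x)."""
    nx = stats.kmer_counts.get(x, 0)
    if nx == 0:
        raise ValueError(f"k-mer id {x} never occurs in a positive sequence")
    return stats.pair_counts.get((x, y), 0) / nx


@dataclass
class HeterogeneousGraph:
    """The assembled graph: vocabulary, sequences, three weight matrices, adjacency stats."""

    vocab: KmerVocabulary
    sequences: list[SequenceRecord]
    W_sim: sp.csr_matrix
    W_co: sp.csr_matrix
    W_inclu: sp.csr_matrix
    coexist: CoexistStats
    sim_max_mismatch: int = 1
    co_positive_only: bool = True

    @property
    def m(self) -> int:
        return len(self.vocab)

    @property
    def n(self) -> int:
        return len(self.sequences)

    def neighbors_sim(self, x: int) -> set[int]:
        return set(self.W_sim[x].indices)

    def neighbors_co(self, x: int) -> set[int]:
        return set(self.W_co[x].indices)

    def neighbors_inclu(self, z: int) -> set[int]:
        return set(self.W_inclu[:, z].tocsc().indices)


def build_graph(
    records: Sequence[SequenceRecord],
    lenk: int = 5,
    sim_max_mismatch: int = 1,
    co_positive_only: bool = True,
) -> HeterogeneousGraph:
    """Build the full heterogeneous graph from labelled records."""
    vocab = build_vocab(records, lenk)
    positives = [r for r in records if r.label == 1]
    graph = HeterogeneousGraph(
        vocab=vocab,
        sequences=list(records),
        W_sim=build_similarity_matrix(vocab, sim_max_mismatch),
        W_co=build_coexisting_matrix(vocab, records, positive_only=co_positive_only),
        W_inclu=build_inclusive_matrix(vocab, records),
        coexist=build_coexist_stats(positives),
        sim_max_mismatch=sim_max_mismatch,
        co_positive_only=co_positive_only,
    )
    logger.info(
        "built graph: m=%d k-mers, n=%d sequences, %d sim edges, %d co edges",
        graph.m, graph.n, graph.W_sim.nnz, graph.W_co.nnz,
    )
    return graph


def _write_triplets(mat: sp.csr_matrix, path: Path) -> None:
    coo = mat.tocoo()
    with open(path, "w") as fh:
        fh.write("row\tcol\tweight\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}\t{c}\t{float(v)!r}\n")


def _read_triplets(path: Path, shape: tuple[int, int]) -> sp.csr_matrix:
    rows, cols, data = [], [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            r, c, v = line.split("\t")
            rows.append(int(r))
            cols.append(int(c))
            data.append(float(v))
    return sp.csr_matrix((data, (rows, cols)), shape=shape)


def save_graph(graph: HeterogeneousGraph, out_dir: str | Path) -> None:
    """Serialize to sparse triplet TSVs plus a JSON manifest and a FASTA of sequences."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_triplets(graph.W_sim, out / "W_sim.tsv")
    _write_triplets(graph.W_co, out / "W_co.tsv")
    _write_triplets(graph.W_inclu, out / "W_inclu.tsv")
    write_fasta(graph.sequences, out / "sequences.fasta")
    manifest = {
        "m": graph.m,
        "n": graph.n,
        "lenk": graph.vocab.lenk,
        "kmers": graph.vocab.kmers,
        "sim_max_mismatch": graph.sim_max_mismatch,
        "co_positive_only": graph.co_positive_only,
    }
    (out / "manifest.json").write_text(json.dumps(manifest))


def load_graph(in_dir: str | Path) -> HeterogeneousGraph:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    vocab = KmerVocabulary(lenk=manifest["lenk"])
    for kmer in manifest["kmers"]:
        vocab.add(kmer)
    records = read_fasta(src / "sequences.fasta")
    for rec in records:
        split_kmers(rec, manifest["lenk"], vocab)
    m, n = manifest["m"], manifest["n"]
    positives = [r for r in records if r.label == 1]
    return HeterogeneousGraph(
        vocab=vocab,
        sequences=records,
        W_sim=_read_triplets(src / "W_sim.tsv", (m, m)),
        W_co=_read_triplets(src / "W_co.tsv", (m, m)),
        W_inclu=_read_triplets(src / "W_inclu.tsv", (m, n)),
        coexist=build_coexist_stats(positives),
        sim_max_mismatch=manifest["sim_max_mismatch"],
        co_positive_only=manifest["co_positive_only"],
    )
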