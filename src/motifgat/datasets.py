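"""Sequence I/O, preprocessing and synthetic planted-motif benchmarks.

The experimental unit throughout the package is a fixed-length DNA window
(101 bp by default) cut from an accessible-chromatin footprint and labelled
positive, paired with a nucleotide-shuffled negative of identical base
composition.  This module reads and writes those windows in standard
formats (FASTA, BED), performs the preprocessing steps the model expects
(window extraction, negative generation, sliding-window k-mer splitting,
stratified train/validation/test splits) and generates synthetic datasets
in which motif instances drawn from a known position probability matrix
(PPM) are planted at recorded offsets — the ground truth used by the test
suite and the acceptance study.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from pyfaidx import Fasta

if TYPE_CHECKING:  # pragma: no cover
    from .hetgraph import KmerVocabulary

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "SequenceRecord",
    "DatasetSplit",
    "PlantedMotifSpec",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "cut_windows",
    "shuffle_negative",
    "split_kmers",
    "make_split",
    "generate_ppm",
    "generate_synthetic",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass
class SequenceRecord:
    """One labelled fixed-length DNA sequence.

    ``kmer_occurrences`` is the ordered list of ``(kmer_id, offset)`` pairs
    produced by :func:`split_kmers`; it is ``None`` until a vocabulary has
    assigned integer ids.
    """

    id: str
    sequence: str
    label: int
    kmer_occurrences: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DatasetSplit:
    """Stratified partition of a record set into train/validation/test."""

    train: list[SequenceRecord]
    validation: list[SequenceRecord]
    test: list[SequenceRecord]
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    rng_seed: int = 0

    @property
    def n_total(self) -> int:
        return len(self.train) + len(self.validation) + len(self.test)


def _check_alphabet(seq: str) -> bool:
    return all(c in BASE_INDEX for c in seq)


def read_fasta(
    path: str | Path,
    label_sep: str = "|",
    on_invalid: str = "drop",
) -> list[SequenceRecord]:
    """Read labelled sequences from FASTA.

    Labels are encoded in the header as ``id<label_sep>label`` with label
    ``1`` (positive) or ``0`` (negative).  Sequences are uppercased; records
    containing symbols outside A/C/G/T are dropped with a logged count
    (``on_invalid="drop"``, the default) or raise (``on_invalid="error"``).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: malformed FASTA, line {lineno} is not a header: "
                        f"{line.strip()[:40]!r}"
                    )
                break

    records: list[SequenceRecord] = []
    n_invalid = 0
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.id
        if label_sep not in header:
            raise ValueError(
                f"{path}: header {header!r} carries no {label_sep!r}-separated label"
            )
        name, _, tag = header.rpartition(label_sep)
        if tag not in ("0", "1"):
            raise ValueError(f"{path}: unknown label tag {tag!r} in header {header!r}")
        seq = str(entry.seq).upper()
        if not _check_alphabet(seq):
            if on_invalid == "error":
                raise ValueError(f"{path}: sequence {name!r} has non-ACGT symbols")
            n_invalid += 1
            continue
        records.append(SequenceRecord(id=name, sequence=seq, label=int(tag)))
    if n_invalid:
        logger.info("read_fasta: dropped %d record(s) with non-ACGT symbols", n_invalid)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, label_sep: str = "|") -> None:
    """Write records as FASTA with ``id|label`` headers (the paired reader's convention)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}{label_sep}{rec.label}\n{rec.sequence}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED intervals (0-based half-open); returns (chrom, start, end, name)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            intervals.append((chrom, start, end, name))
    return intervals


def cut_windows(
    bed_intervals: str | Path | Sequence[tuple],
    reference_fasta: str | Path,
    window_len: int = 101,
) -> list[SequenceRecord]:
    """Cut fixed-length windows centred on footprint intervals.

    Each interval (0-based half-open) yields a positive record of exactly
    ``window_len`` bases centred at ``floor((start + end) / 2)``; for the
    default 101 bp this is ``center - 50 .. center + 51``.  Windows that run
    off the chromosome, and windows containing non-ACGT symbols, are skipped
    with a logged count.  An interval on a chromosome absent from the
    reference is an error.
    """
    if isinstance(bed_intervals, (str, Path)):
        bed_intervals = read_bed(bed_intervals)
    ref = Fasta(str(reference_fasta))
    half = window_len // 2
    records: list[SequenceRecord] = []
    n_oob = n_invalid = 0
    for iv in bed_intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if chrom not in ref:
            raise KeyError(f"chromosome {chrom!r} absent from {reference_fasta}")
        center = (start + end) // 2
        wstart = center - half
        wend = wstart + window_len
        if wstart < 0 or wend > len(ref[chrom]):
            n_oob += 1
            continue
        seq = str(ref[chrom][wstart:wend]).upper()
        if not _check_alphabet(seq):
            n_invalid += 1
            continue
        records.append(
            SequenceRecord(id=f"{chrom}:{wstart}-{wend}", sequence=seq, label=1)
        )
    if n_oob:
        logger.info("cut_windows: skipped %d interval(s) exceeding chromosome bounds", n_oob)
    if n_invalid:
        logger.info("cut_windows: skipped %d window(s) with non-ACGT symbols", n_invalid)
    return records


def shuffle_negative(record: SequenceRecord, rng: np.random.Generator) -> SequenceRecord:
    """Mononucleotide shuffle of a positive sequence.

    Returns a label-0 record whose sequence is a uniform random permutation
    of the input's nucleotides: the per-sequence base composition is
    preserved exactly while any positional motif signal is destroyed.
    """
    if record.label != 1:
        raise ValueError(f"shuffle_negative expects a positive record, got label {record.label}")
    perm = rng.permutation(len(record.sequence))
    shuffled = "".join(record.sequence[i] for i in perm)
    return SequenceRecord(id=f"{record.id}_shuf", sequence=shuffled, label=0)


def dinucleotide_shuffle(record: SequenceRecord, rng: np.random.Generator) -> SequenceRecord:
    """Optional dinucleotide-preserving shuffle (Altschul–Erickson style Eulerian walk).

    Preserves the dinucleotide multiset of the input; not the default
    negative-generation scheme (see :func:`shuffle_negative`).
    """
    if record.label != 1:
        raise ValueError("dinucleotide_shuffle expects a positive record")
    seq = record.sequence
    if len(seq) < 3:
        return SequenceRecord(id=f"{record.id}_dishuf", sequence=seq, label=0)
    # edge lists of the dinucleotide multigraph, shuffled except the last
    # edge out of each vertex, which must close an Eulerian path to the
    # original terminal base (Altschul & Erickson 1985).
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    for a, succ in edges.items():
        if a == last and all(b == a for b in succ):
            rng.shuffle(succ)
            continue
        # pick a terminal edge that can reach `last`, keep it final, shuffle the rest
        idx = list(range(len(succ)))
        rng.shuffle(idx)
        succ[:] = [succ[i] for i in idx]
    # rebuild by walking; retry until every edge is consumed (walk can stall
    # early when the shuffled order strands edges)
    for _ in range(200):
        trial = {a: list(b) for a, b in edges.items()}
        out = [seq[0]]
        cur = seq[0]
        ok = True
        while any(trial.values()):
            succ = trial.get(cur)
            if not succ:
                ok = False
                break
            nxt = succ.pop(rng.integers(len(succ)))
            out.append(nxt)
            cur = nxt
        if ok:
            return SequenceRecord(id=f"{record.id}_dishuf", sequence="".join(out), label=0)
        for a in edges:
            rng.shuffle(edges[a])
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian walk")


def split_kmers(record: SequenceRecord, lenk: int, vocab: "KmerVocabulary | None" = None) -> SequenceRecord:
    """Split a sequence into overlapping k-mers with a sliding window of step 1.

    Populates ``record.kmer_occurrences`` with ``(kmer_id, offset)`` pairs,
    one per window position: exactly ``L - lenk + 1`` occurrences.  Ids are
    assigned by ``vocab`` (created fresh, in first-appearance order, when not
    supplied); passing a shared vocabulary across records yields consistent
    ids for the whole dataset.
    """
    L = len(record.sequence)
    if lenk < 1 or lenk > L:
        raise ValueError(f"lenk={lenk} outside [1, {L}]")
    if vocab is None:
        from .hetgraph import KmerVocabulary

        vocab = KmerVocabulary(lenk=lenk)
    record.kmer_occurrences = [
        (vocab.add(record.sequence[i : i + lenk]), i) for i in range(L - lenk + 1)
    ]
    return record


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [f * n for f in fractions]
    base = [math.floor(e) for e in exact]
    short = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base


def make_split(
    records: Sequence[SequenceRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
) -> DatasetSplit:
    """Deterministic stratified train/validation/test split.

    Positives and negatives are shuffled and partitioned separately so every
    part keeps the overall class ratio to within one record; counts follow
    the fractions by largest-remainder rounding.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if len(records) < 10:
        raise ValueError(
            f"need at least 10 records to honor a {fractions} split, got {len(records)}"
        )
    rng = np.random.default_rng(rng_seed)
    parts: list[list[SequenceRecord]] = [[], [], []]
    for cls in (1, 0):
        group = [r for r in records if r.label == cls]
        if not group:
            continue
        order = rng.permutation(len(group))
        counts = _largest_remainder_counts(len(group), fractions)
        pos = 0
        for part, c in zip(parts, counts):
            part.extend(group[i] for i in order[pos : pos + c])
            pos += c
    return DatasetSplit(
        train=parts[0], validation=parts[1], test=parts[2],
        split_fractions=tuple(fractions), rng_seed=rng_seed,
    )


@dataclass
class PlantedMotifSpec:
    """Specification of a synthetic planted motif.

    ``ppm`` is a 4×w column-stochastic matrix (rows A, C, G, T); each
    positive sequence receives, with probability ``occurrence_rate``, one
    instance sampled column-wise from the PPM and planted at an offset drawn
    uniformly over valid positions.  Background bases are i.i.d. with
    frequencies ``background`` (uniform by default).
    """

    ppm: np.ndarray
    occurrence_rate: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.ppm.shape[0] != 4:
            raise ValueError("ppm must have 4 rows (A, C, G, T)")
        if not np.allclose(self.ppm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("ppm columns must each sum to 1")
        if not 0.0 < self.occurrence_rate <= 1.0:
            raise ValueError("occurrence_rate must lie in (0, 1]")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.ppm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.ppm.argmax(axis=0))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ppm": self.ppm.tolist(),
            "occurrence_rate": self.occurrence_rate,
            "background": self.background.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedMotifSpec":
        payload = json.loads(Path(path).read_text())
        return cls(
            ppm=np.asarray(payload["ppm"]),
            occurrence_rate=payload["occurrence_rate"],
            background=np.asarray(payload["background"]),
        )


def _column_entropy(p_major: float) -> float:
    q = (1.0 - p_major) / 3.0
    h = 0.0
    for p in (p_major, q, q, q):
        if p > 0:
            h -= p * math.log2(p)
    return h


def generate_ppm(
    width: int, bits_per_column: float = 1.5, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random PPM with a target per-column information content.

    Each column puts probability ``p`` on one dominant base (chosen at
    random) and ``(1 - p)/3`` on the others, with ``p`` solved by bisection
    so the column's information content (2 − entropy, in bits) matches
    ``bits_per_column``.
    """
    if not 0.0 <= bits_per_column <= 2.0:
        raise ValueError("bits_per_column must lie in [0, 2]")
    rng = np.random.default_rng() if rng is None else rng
    target_h = 2.0 - bits_per_column
    lo, hi = 0.25, 1.0 - 1e-12
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _column_entropy(mid) > target_h:
            lo = mid
        else:
            hi = mid
    p = 0.5 * (lo + hi)
    q = (1.0 - p) / 3.0
    ppm = np.full((4, width), q)
    for j in range(width):
        ppm[rng.integers(4), j] = p
    return ppm / ppm.sum(axis=0, keepdims=True)


def generate_synthetic(
    spec: PlantedMotifSpec,
    n_pos: int,
    seq_len: int = 101,
    lenk: int | None = 5,
    rng_seed: int = 0,
) -> tuple[list[SequenceRecord], list[tuple[str, int, str]]]:
    """Generate a planted-motif dataset of ``n_pos`` positives and ``n_pos`` negatives.

    Positives are background sequences with a motif instance planted at a
    recorded offset; negatives are mononucleotide shuffles of the positives.
    Returns the records (positives first) and the ground truth as
    ``(sequence_id, offset, instance)`` triples.  When ``lenk`` is given the
    records' k-mer occurrence lists are populated with first-appearance ids,
    matching what graph construction would later assign.  Fixed
    ``rng_seed`` makes the output bit-reproducible.
    """
    if n_pos < 1:
        raise ValueError("n_pos must be >= 1")
    w = spec.width
    if w >= seq_len:
        raise ValueError(f"motif width {w} must be < sequence length {seq_len}")
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list(ALPHABET))
    positives: list[SequenceRecord] = []
    ground_truth: list[tuple[str, int, str]] = []
    for i in range(n_pos):
        seq = rng.choice(bases, size=seq_len, p=spec.background)
        rec_id = f"pos_{i:05d}"
        if rng.random() < spec.occurrence_rate:
            offset = int(rng.integers(0, seq_len - w + 1))
            instance = "".join(
                bases[rng.choice(4, p=spec.ppm[:, j])] for j in range(w)
            )
            seq[offset : offset + w] = list(instance)
            ground_truth.append((rec_id, offset, instance))
        positives.append(SequenceRecord(id=rec_id, sequence="".join(seq), label=1))
    negatives = []
    for i, rec in enumerate(positives):
        neg = shuffle_negative(rec, rng)
        neg.id = f"neg_{i:05d}"
        negatives.append(neg)
    records = positives + negatives
    if lenk is not None:
        from .hetgraph import KmerVocabulary

        vocab = KmerVocabulary(lenk=lenk)
        for rec in records:
            split_kmers(rec, lenk, vocab)
    return records, ground_truth


def write_ground_truth(ground_truth: Iterable[tuple[str, int, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\toffset\tinstance\n")
        for seq_id, offset, instance in ground_truth:
            fh.write(f"{seq_id}\t{offset}\t{instance}\n")


def read_ground_truth(path: str | Path) -> list[tuple[str, int, str]]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            seq_id, offset, instance = line.rstrip("\n").split("\t")
            out.append((seq_id, int(offset), instance))
    return out


def records_digest(records: Iterable[SequenceRecord]) -> str:
    """SHA-256 over ids, labels and sequences — provenance for pipeline runs."""
    h = hashlib.sha256()
    for rec in records:
        h.update(f"{rec.id}\t{rec.label}\t{rec.sequence}\n".encode())
    return h.hexdigest()
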