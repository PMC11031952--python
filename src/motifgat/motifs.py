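"""Motif extraction from learned inclusive attention coefficients.

After training, every sequence carries two attention rows over its k-mers
(one per k-mer subgraph).  The rows of negative sequences — shuffles with
no binding signal — define a scalar background level per subgraph; the
positive rows minus that background are the denoised coefficients.  A
k-mer occurrence on a positive sequence becomes a *seed* when either of
its denoised coefficients is strictly positive.  Seeds at consecutive
offsets are chained when the coexisting probability of the adjacent k-mer
pair clears a threshold, chains become candidate binding sites, candidates
overlapping within a sequence are unioned, and the resulting instances are
grouped by width into position probability matrices exportable in MEME
minimal format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .datasets import ALPHABET, BASE_INDEX, SequenceRecord
from .gatnet import GraphTensors, ModelParameters, forward
from .hetgraph import CoexistStats, HeterogeneousGraph, coexist_probability

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSplitAttention",
    "KmerSeed",
    "TFBSInstance",
    "MotifModel",
    "collect_attention",
    "find_kmer_seeds",
    "merge_seeds",
    "merge_overlaps",
    "build_motifs",
    "write_meme",
    "read_meme",
    "write_bed",
    "information_content",
    "best_alignment_correlation",
    "empirical_background",
]


@dataclass
class LabelSplitAttention:
    """Inclusive attention coefficients split by sequence label.

    ``B1_*`` (positives) and ``B0_*`` (negatives) are dense arrays whose
    non-edge cells carry no data — the masks say which cells are real.
    Backgrounds are means of the negative matrices over edge cells only,
    and ``dnB1_* = B1_* - background_*`` on edge cells (NaN elsewhere).
    """

    B1_sim: np.ndarray
    B1_co: np.ndarray
    B0_sim: np.ndarray
    B0_co: np.ndarray
    M1: np.ndarray  # edge mask for positives (n_pos, m)
    M0: np.ndarray  # edge mask for negatives (n_neg, m)
    positive_records: list[SequenceRecord]
    background_sim: float = field(init=False)
    background_co: float = field(init=False)
    dnB1_sim: np.ndarray = field(init=False)
    dnB1_co: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.M0.sum() == 0:
            raise ValueError("background undefined: no negative edge entries")
        self.background_sim = float(self.B0_sim[self.M0].mean())
        self.background_co = float(self.B0_co[self.M0].mean())
        self.dnB1_sim = np.where(self.M1, self.B1_sim - self.background_sim, np.nan)
        self.dnB1_co = np.where(self.M1, self.B1_co - self.background_co, np.nan)


@dataclass
class KmerSeed:
    """One k-mer occurrence on a positive sequence passing the denoised-attention rule."""

    kmer_id: int
    sequence_id: str
    offset: int
    dn_sim: float
    dn_co: float


@dataclass
class TFBSInstance:
    """A candidate or final binding site: a half-open slice of one sequence."""

    sequence_id: str
    start: int
    end: int
    subsequence: str
    constituent_seeds: list[KmerSeed] = field(default_factory=list)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class MotifModel:
    """Aligned equal-width instances summarized as a PPM (rows A, C, G, T)."""

    name: str
    width: int
    instances: list[TFBSInstance]
    ppm: np.ndarray
    support: int


def collect_attention(
    params: ModelParameters,
    graph: HeterogeneousGraph,
    gt: GraphTensors | None = None,
) -> LabelSplitAttention:
    """Evaluate the trained model and split its beta rows by sequence label."""
    gt = GraphTensors.from_graph(graph) if gt is None else gt
    cache = forward(params, gt)
    labels = gt.labels
    pos = labels == 1
    neg = labels == 0
    if not neg.any():
        raise ValueError("no negative sequences: background noise is undefined")
    if not pos.any():
        raise ValueError("no positive sequences to mine seeds from")
    return LabelSplitAttention(
        B1_sim=cache["sim"]["beta"][pos],
        B1_co=cache["co"]["beta"][pos],
        B0_sim=cache["sim"]["beta"][neg],
        B0_co=cache["co"]["beta"][neg],
        M1=gt.M[pos],
        M0=gt.M[neg],
        positive_records=[r for r in graph.sequences if r.label == 1],
    )


def find_kmer_seeds(att: LabelSplitAttention, graph: HeterogeneousGraph) -> list[KmerSeed]:
    """Seeds: occurrences with dnB1_sim > 0 OR dnB1_co > 0 (strict).

    The denoised rule is per (sequence, k-mer); a k-mer occurring at several
    offsets of one sequence yields one seed per occurrence, because the
    merging step downstream is positional.
    """
    seeds: list[KmerSeed] = []
    for row, rec in enumerate(att.positive_records):
        if rec.kmer_occurrences is None:
            raise ValueError(f"record {rec.id!r} has no k-mer occurrences")
        for kid, offset in rec.kmer_occurrences:
            dn_s = att.dnB1_sim[row, kid]
            dn_c = att.dnB1_co[row, kid]
            if dn_s > 0 or dn_c > 0:
                seeds.append(KmerSeed(kid, rec.id, offset, float(dn_s), float(dn_c)))
    logger.info("found %d k-mer seeds over %d positive sequences",
                len(seeds), len(att.positive_records))
    return seeds


def merge_seeds(
    seeds: Sequence[KmerSeed],
    coexist_stats: CoexistStats,
    records_by_id: dict[str, SequenceRecord],
    lenk: int,
    theta_co: float = 0.5,
) -> list[TFBSInstance]:
    """Chain adjacent seeds into candidate binding sites.

    Within a sequence, seeds sorted by offset are joined left-to-right when
    their offsets differ by exactly 1 and the coexisting probability of the
    (left, right) k-mer pair reaches ``theta_co``; each maximal chain spans
    from its first offset to its last offset + lenk.  Singleton chains give
    lenk-wide candidates.
    """
    by_seq: dict[str, dict[int, KmerSeed]] = {}
    for seed in seeds:
        by_seq.setdefault(seed.sequence_id, {})[seed.offset] = seed
    candidates: list[TFBSInstance] = []
    for seq_id, offset_map in by_seq.items():
        seq = records_by_id[seq_id].sequence
        offsets = sorted(offset_map)
        chain = [offset_map[offsets[0]]]
        for off in offsets[1:]:
            nxt = offset_map[off]
            prv = chain[-1]
            joined = False
            if off == prv.offset + 1:
                try:
                    p = coexist_probability(coexist_stats, prv.kmer_id, nxt.kmer_id)
                except ValueError:
                    p = 0.0
                joined = p >= theta_co
            if joined:
                chain.append(nxt)
            else:
                candidates.append(_chain_to_instance(chain, seq, lenk))
                chain = [nxt]
        candidates.append(_chain_to_instance(chain, seq, lenk))
    return candidates


def _chain_to_instance(chain: list[KmerSeed], seq: str, lenk: int) -> TFBSInstance:
    start = chain[0].offset
    end = chain[-1].offset + lenk
    return TFBSInstance(
        sequence_id=chain[0].sequence_id,
        start=start,
        end=end,
        subsequence=seq[start:end],
        constituent_seeds=list(chain),
    )


def merge_overlaps(candidates: Sequence[TFBSInstance]) -> list[TFBSInstance]:
    """Union overlapping candidates (sharing >= 1 base) within each sequence.

    Output instances are pairwise disjoint per sequence and cover exactly
    the union of the input intervals; abutting intervals stay separate.
    """
    by_seq: dict[str, list[TFBSInstance]] = {}
    for cand in candidates:
        by_seq.setdefault(cand.sequence_id, []).append(cand)
    final: list[TFBSInstance] = []
    for seq_id, items in by_seq.items():
        items = sorted(items, key=lambda t: (t.start, t.end))
        cur = items[0]
        merged = TFBSInstance(seq_id, cur.start, cur.end, cur.subsequence,
                              list(cur.constituent_seeds))
        for nxt in items[1:]:
            if nxt.start < merged.end:  # overlap: share at least one base
                if nxt.end > merged.end:
                    merged.subsequence += nxt.subsequence[merged.end - nxt.start:]
                    merged.end = nxt.end
                merged.constituent_seeds.extend(nxt.constituent_seeds)
            else:
                final.append(merged)
                merged = TFBSInstance(seq_id, nxt.start, nxt.end, nxt.subsequence,
                                      list(nxt.constituent_seeds))
        final.append(merged)
    return final


def build_motifs(
    instances: Sequence[TFBSInstance],
    min_support: int = 5,
    pseudocount: float = 0.01,
) -> list[MotifModel]:
    """Group instances by exact width into PPMs.

    Width groups with fewer than ``min_support`` instances are dropped (with
    a log entry).  The PPM is the per-column base frequency with an additive
    pseudocount; columns sum to 1.  Motifs are returned by decreasing
    support.
    """
    by_width: dict[int, list[TFBSInstance]] = {}
    for inst in instances:
        by_width.setdefault(inst.width, []).append(inst)
    motifs: list[MotifModel] = []
    n_dropped = 0
    for width in sorted(by_width):
        group = by_width[width]
        if len(group) < min_support:
            n_dropped += 1
            continue
        counts = np.zeros((4, width))
        for inst in group:
            for j, base in enumerate(inst.subsequence):
                counts[BASE_INDEX[base], j] += 1
        ppm = (counts + pseudocount) / (len(group) + 4 * pseudocount)
        motifs.append(MotifModel(
            name=f"motif_w{width}", width=width, instances=group,
            ppm=ppm, support=len(group),
        ))
    if n_dropped:
        logger.info("dropped %d width group(s) below support %d", n_dropped, min_support)
    motifs.sort(key=lambda mo: -mo.support)
    return motifs


# ---------------------------------------------------------------------------
# PPM utilities

def information_content(ppm: np.ndarray) -> np.ndarray:
    """Per-column information content in bits (2 - entropy), uniform background."""
    p = np.clip(np.asarray(ppm, dtype=float), 1e-12, 1.0)
    return 2.0 + (p * np.log2(p)).sum(axis=0)


def _column_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        return 1.0 if np.allclose(a, b, atol=1e-9) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def best_alignment_correlation(ppm_a: np.ndarray, ppm_b: np.ndarray) -> float:
    """Best-offset mean per-column Pearson correlation between two PPMs.

    The narrower PPM slides fully inside the wider one; at each offset the
    correlation of the aligned 4-probability columns is averaged, and the
    maximum over offsets is returned.
    """
    a, b = np.asarray(ppm_a), np.asarray(ppm_b)
    if a.shape[1] > b.shape[1]:
        a, b = b, a
    w = a.shape[1]
    best = -np.inf
    for off in range(b.shape[1] - w + 1):
        cols = [_column_pearson(a[:, j], b[:, off + j]) for j in range(w)]
        best = max(best, float(np.mean(cols)))
    return best


def empirical_background(records: Sequence[SequenceRecord]) -> np.ndarray:
    """Mononucleotide frequencies over (positive) records, for MEME headers."""
    counts = np.zeros(4)
    for rec in records:
        for base in rec.sequence:
            counts[BASE_INDEX[base]] += 1
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


# ---------------------------------------------------------------------------
# I/O

def write_meme(
    motifs: Sequence[MotifModel],
    path: str | Path,
    background_freqs: np.ndarray | None = None,
) -> None:
    """Write motifs in MEME minimal motif format (version 4).

    Probabilities print with 6 decimals and round-trip bit-identically at
    that precision through :func:`read_meme`.  An empty motif list is an
    error and writes nothing.
    """
    if not motifs:
        raise ValueError("no motifs to write")
    bg = np.full(4, 0.25) if background_freqs is None else np.asarray(background_freqs)
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        " ".join(f"{b} {f:.6f}" for b, f in zip(ALPHABET, bg)),
        "",
    ]
    for mo in motifs:
        lines.append(f"MOTIF {mo.name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {mo.width} "
            f"nsites= {mo.support} E= 0"
        )
        for j in range(mo.width):
            lines.append(" " + " ".join(f"{mo.ppm[i, j]:.6f}" for i in range(4)))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_meme(path: str | Path) -> list[MotifModel]:
    """Read MEME minimal format back into width/PPM/support summaries (no instances)."""
    motifs: list[MotifModel] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            header = lines[i].strip()
            if not header.startswith("letter-probability matrix"):
                raise ValueError(f"{path}: expected matrix header after MOTIF {name}")
            fields = header.replace("=", " = ").split()
            width = int(fields[fields.index("w") + 2])
            nsites = int(fields[fields.index("nsites") + 2]) if "nsites" in fields else 0
            rows = []
            for j in range(width):
                i += 1
                rows.append([float(v) for v in lines[i].split()])
            ppm = np.asarray(rows).T
            motifs.append(MotifModel(name=name, width=width, instances=[],
                                     ppm=ppm, support=nsites))
        i += 1
    return motifs


def write_bed(instances: Sequence[TFBSInstance], path: str | Path) -> None:
    """BED6 export of binding-site instances (0-based half-open)."""
    with open(path, "w") as fh:
        for k, inst in enumerate(instances):
            fh.write(
                f"{inst.sequence_id}\t{inst.start}\t{inst.end}\t"
                f"site_{k}_w{inst.width}\t0\t+\n"
            )
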