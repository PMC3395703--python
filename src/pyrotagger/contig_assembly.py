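"""Greedy consensus assembly of quality-filtered pyrotag reads.

Forward and (reverse-complemented) reverse reads of one amplicon pool are
merged into contigs whenever they overlap a growing consensus by at least
``min_overlap_bp`` at ``min_identity`` or better.  Contigs backed by fewer
than 20 reads, or lacking at least one read of each orientation, are
excluded from downstream fingerprint work.

The greedy order is deterministic: seeds and joiners are processed longest
first with read-id ties broken lexicographically, and the consensus is
recomputed by per-column majority vote (ties: higher summed quality, then
alphabetical) after every merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import OverlapAlignment, overlap_align
from .read_qc import PyroRead, oriented_sequence

_BASE2IDX = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class AssemblyParams:
    min_identity: float = 0.98
    min_overlap_bp: int = 50
    min_reads_per_contig: int = 20
    require_both_orientations: bool = True
    #: merge contigs whose consensi satisfy the same thresholds after the
    #: read pass; majority-vote consensi are far cleaner than single reads,
    #: so this reunites fragments split by early borderline comparisons
    merge_contigs: bool = True

    def __post_init__(self):
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")


@dataclass
class Contig:
    contig_id: str
    consensus: str
    member_reads: list[str]
    n_forward: int
    n_reverse: int

    @property
    def n_reads(self) -> int:
        return len(self.member_reads)


def overlap_identity(a: str, b: str) -> tuple[int, float]:
    """Best free-end-gap overlap of two oriented sequences.

    Returns ``(overlap_columns, identity)`` where identity counts internal
    gaps as mismatches.
    """
    aln = overlap_align(a, b)
    return aln.columns, aln.identity


_PREFILTER_K = 20


def kmer_set(seq: str, k: int = _PREFILTER_K) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def shares_kmers(a_kmers: set[str], b_kmers: set[str], n: int = 3) -> bool:
    """Cheap screen before alignment: two sequences overlapping >=50 bp at
    >=97% identity must share many k-mers; fewer than ``n`` shared 20-mers
    rules the pair out without running the quadratic DP."""
    return len(a_kmers & b_kmers) >= n


class _ContigBuilder:
    """Column-wise base/quality tallies supporting left/right extension."""

    def __init__(self, contig_id: str):
        self.contig_id = contig_id
        self.counts = np.zeros((4, 0), dtype=np.int32)
        self.quals = np.zeros((4, 0), dtype=np.float64)
        self.members: list[str] = []
        self.n_forward = 0
        self.n_reverse = 0

    def absorb(self, other: "_ContigBuilder", offset: int) -> None:
        """Fold another builder's columns in at the given offset."""
        if offset < 0:
            pad = -offset
            self.counts = np.pad(self.counts, ((0, 0), (pad, 0)))
            self.quals = np.pad(self.quals, ((0, 0), (pad, 0)))
            offset = 0
        end = offset + other.counts.shape[1]
        if end > self.counts.shape[1]:
            pad = end - self.counts.shape[1]
            self.counts = np.pad(self.counts, ((0, 0), (0, pad)))
            self.quals = np.pad(self.quals, ((0, 0), (0, pad)))
        self.counts[:, offset:end] += other.counts
        self.quals[:, offset:end] += other.quals
        self.members.extend(other.members)
        self.n_forward += other.n_forward
        self.n_reverse += other.n_reverse

    def add(self, read: PyroRead, offset: int) -> None:
        seq = oriented_sequence(read)
        q = read.qualities if len(read.qualities) == len(seq) else np.full(len(seq), 30)
        if read.orientation == "reverse":
            q = q[::-1]
        if offset < 0:
            pad = -offset
            self.counts = np.pad(self.counts, ((0, 0), (pad, 0)))
            self.quals = np.pad(self.quals, ((0, 0), (pad, 0)))
            offset = 0
        end = offset + len(seq)
        if end > self.counts.shape[1]:
            pad = end - self.counts.shape[1]
            self.counts = np.pad(self.counts, ((0, 0), (0, pad)))
            self.quals = np.pad(self.quals, ((0, 0), (0, pad)))
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        idx = np.array([_BASE2IDX.get(b, -1) for b in arr])
        valid = idx >= 0
        cols = np.arange(offset, end)[valid]
        rows = idx[valid]
        np.add.at(self.counts, (rows, cols), 1)
        np.add.at(self.quals, (rows, cols), np.asarray(q, dtype=float)[valid])
        self.members.append(read.read_id)
        if read.orientation == "reverse":
            self.n_reverse += 1
        else:
            self.n_forward += 1

    def consensus(self) -> str:
        covered = self.counts.sum(axis=0) > 0
        # majority count, then summed quality, then alphabetical (lowest index)
        key = (self.counts * 1e9 + self.quals
               - np.arange(4)[:, None] * 1e-3)
        winner = np.argmax(key, axis=0)
        bases = _IDX2BASE[winner]
        return bases[covered].tobytes().decode("ascii")

    def finalize(self) -> Contig:
        return Contig(self.contig_id, self.consensus(), list(self.members),
                      self.n_forward, self.n_reverse)


def _sort_key(read: PyroRead):
    return (-len(read.sequence), read.read_id)


def assemble(reads, params: AssemblyParams | None = None):
    """Greedy seeded assembly.

    Reads (quality-filtered, orientation known) are processed by descending
    length.  Each read joins the best-matching existing contig — highest
    identity, then longest overlap, then earliest contig — when the overlap
    passes the thresholds against the current consensus; otherwise it seeds
    a new contig.  Contigs left with a single member are returned as the
    unassembled pool.

    Returns ``(contigs: list[Contig], unassembled: list[PyroRead])``.
    """
    params = params or AssemblyParams()
    builders: list[_ContigBuilder] = []
    consensi: list[str] = []
    kmers: list[set[str]] = []
    by_id: dict[str, PyroRead] = {r.read_id: r for r in reads}
    singles: dict[str, PyroRead] = {}
    for read in sorted(reads, key=_sort_key):
        seq = oriented_sequence(read)
        seq_kmers = kmer_set(seq)
        best: tuple[float, int, int, OverlapAlignment] | None = None
        for ci, cons in enumerate(consensi):
            if not shares_kmers(seq_kmers, kmers[ci]):
                continue
            aln = overlap_align(cons, seq)
            if (aln.columns >= params.min_overlap_bp
                    and aln.identity >= params.min_identity):
                cand = (aln.identity, aln.columns, -ci, aln)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        if best is None:
            builder = _ContigBuilder(f"contig{len(builders):04d}")
            builder.add(read, 0)
            builders.append(builder)
            consensi.append(seq)
            kmers.append(seq_kmers)
            singles[builder.contig_id] = read
        else:
            ci = -best[2]
            builders[ci].add(read, best[3].offset)
            consensi[ci] = builders[ci].consensus()
            kmers[ci] = kmer_set(consensi[ci])
            singles.pop(builders[ci].contig_id, None)
    if params.merge_contigs:
        builders = _merge_pass(builders, params)
    contigs: list[Contig] = []
    unassembled: list[PyroRead] = []
    for b in builders:
        if len(b.members) == 1:
            unassembled.append(by_id[b.members[0]])
        else:
            contigs.append(b.finalize())
    return contigs, unassembled


def _merge_pass(builders: list["_ContigBuilder"],
                params: AssemblyParams) -> list["_ContigBuilder"]:
    """Merge contigs whose consensi pass the overlap thresholds.

    Repeats until no further pair qualifies; pairs are merged best-first
    (identity, then overlap, then earliest indices) so the result is
    deterministic."""
    builders = list(builders)
    merged = True
    while merged and len(builders) > 1:
        merged = False
        consensi = [b.consensus() for b in builders]
        ksets = [kmer_set(c) for c in consensi]
        best = None
        for i in range(len(builders)):
            for j in range(i + 1, len(builders)):
                if not shares_kmers(ksets[i], ksets[j]):
                    continue
                aln = overlap_align(consensi[i], consensi[j])
                if (aln.columns >= params.min_overlap_bp
                        and aln.identity >= params.min_identity):
                    cand = (aln.identity, aln.columns, -i, -j, aln)
                    if best is None or cand[:4] > best[:4]:
                        best = cand
        if best is not None:
            i, j, aln = -best[2], -best[3], best[4]
            builders[i].absorb(builders[j], aln.offset)
            del builders[j]
            merged = True
    return builders


def filter_contigs(contigs, params: AssemblyParams | None = None) -> list[Contig]:
    """Retain contigs with enough reads and (optionally) both orientations."""
    params = params or AssemblyParams()
    kept = []
    for c in contigs:
        if c.n_reads < params.min_reads_per_contig:
            continue
        if params.require_both_orientations and (c.n_forward < 1 or c.n_reverse < 1):
            continue
        kept.append(c)
    return kept


def write_contigs_fasta(contigs, path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig_id} reads={c.n_reads} fwd={c.n_forward} "
                     f"rev={c.n_reverse}\n{c.consensus}\n")


def write_membership(contigs, path) -> None:
    import pandas as pd

    rows = [(c.contig_id, rid) for c in contigs for rid in c.member_reads]
    pd.DataFrame(rows, columns=["contig_id", "read_id"]).to_csv(
        path, sep="\t", index=False)
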