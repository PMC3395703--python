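"""Demultiplexing, quality trimming and read filtering for pyrotag libraries.

Raw 454 reads carry a multiplex identifier (MID) barcode followed by one of
the two amplification primers, Ba27f (forward) or Ba519r (reverse).  Reads
are assigned to libraries by exact (or near-exact) MID prefix match, 3'
quality-trimmed with a sliding-window mean-Phred rule, and then discarded
when shorter than 250 bp after trimming or when the expected primer cannot
be found at the start of the read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

# IUPAC nucleotide codes -> set of concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DegeneratePrimer:
    """An amplification primer, possibly with IUPAC-degenerate positions."""

    name: str
    sequence: str  # uppercase IUPAC

    def __post_init__(self):
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"non-IUPAC characters in primer: {bad}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


#: the bidirectional 16S primer pair used throughout
BA27F = DegeneratePrimer("Ba27f", "AGAGTTTGATCMTGGCTCAG")
BA519R = DegeneratePrimer("Ba519r", "TATTACCGCGGCKGCTG")


@dataclass
class PyroRead:
    """One pyrosequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # int array, same length as sequence
    library_id: str | None = None
    orientation: str | None = None  # "forward" | "reverse"
    mid: str | None = None
    true_taxon: str | None = None  # simulator ground truth, if known

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


def oriented_sequence(read: PyroRead) -> str:
    """Read sequence on the forward strand of the amplicon."""
    if read.orientation == "reverse":
        return revcomp(read.sequence)
    return read.sequence


@dataclass
class QCParams:
    min_length_bp: int = 250
    trim_window: int = 10
    trim_mean_phred: int = 20
    mid_mismatches_allowed: int = 0
    primer_mismatches_allowed: int = 0

    def __post_init__(self):
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")


def iupac_mismatches(observed: str, pattern: str) -> int:
    """Count positions of ``observed`` incompatible with IUPAC ``pattern``."""
    return sum(o not in IUPAC.get(p, "") for o, p in zip(observed, pattern))


def match_primer(sequence: str, primer: DegeneratePrimer,
                 allowed_mismatches: int = 0) -> int | None:
    """Leftmost position where the primer matches within the mismatch budget.

    Returns ``None`` when no qualifying position exists.  Comparison is
    IUPAC-aware on the primer side (M matches A or C, K matches G or T, ...).
    """
    p = primer.sequence
    for start in range(len(sequence) - len(p) + 1):
        if iupac_mismatches(sequence[start:start + len(p)], p) <= allowed_mismatches:
            return start
    return None


def demultiplex(reads, mapping: dict[str, str], params: QCParams | None = None):
    """Assign reads to libraries by MID prefix; strip the MID.

    ``mapping`` is library_id -> MID sequence.  A read is assigned iff its
    prefix matches exactly one MID within ``mid_mismatches_allowed``;
    ambiguous or unmatched reads go to the unassigned pool.
    Returns ``(per_library: dict[str, list[PyroRead]], unassigned: list)``.
    """
    params = params or QCParams()
    mids = list(mapping.values())
    if len(set(mids)) != len(mids):
        raise ValueError("duplicate MID in mapping")
    per_library: dict[str, list[PyroRead]] = {lib: [] for lib in mapping}
    unassigned: list[PyroRead] = []
    for read in reads:
        hits = [
            lib for lib, mid in mapping.items()
            if len(read.sequence) >= len(mid)
            and sum(a != b for a, b in zip(read.sequence[:len(mid)], mid))
            <= params.mid_mismatches_allowed
        ]
        if len(hits) == 1:
            lib = hits[0]
            mid = mapping[lib]
            stripped = replace(
                read,
                sequence=read.sequence[len(mid):],
                qualities=read.qualities[len(mid):],
                library_id=lib,
                mid=mid,
            )
            per_library[lib].append(stripped)
        else:
            unassigned.append(read)
    return per_library, unassigned


def trim_read(read: PyroRead, params: QCParams | None = None) -> PyroRead:
    """3'-truncate at the last position whose sliding-window mean Phred
    passes the threshold.  Never lengthens a read; trimming is idempotent.
    """
    params = params or QCParams()
    w = params.trim_window
    q = read.qualities
    n = len(q)
    if n == 0:
        return read
    if n < w:
        keep = n if q.mean() >= params.trim_mean_phred else 0
    else:
        means = np.convolve(q, np.ones(w) / w, mode="valid")  # window starting at i
        ok = np.nonzero(means >= params.trim_mean_phred - 1e-9)[0]
        keep = int(ok[-1]) + w if len(ok) else 0
    if keep >= n:
        return read
    return replace(read, sequence=read.sequence[:keep], qualities=q[:keep])


def filter_reads(reads, params: QCParams | None = None,
                 forward_primer: DegeneratePrimer = BA27F,
                 reverse_primer: DegeneratePrimer = BA519R):
    """Length and primer filter; reads must already be trimmed and MID-free.

    A read is retained iff one of the two primers matches at position 0
    (within ``primer_mismatches_allowed``) and its post-trim length is at
    least ``min_length_bp``.  Orientation is recorded on retained reads.
    Returns ``(retained: list[PyroRead], tally: Counter)`` where the tally
    partitions rejected reads into reasons ``"primer"`` and ``"length"``.
    """
    params = params or QCParams()
    retained: list[PyroRead] = []
    tally: Counter = Counter()
    for read in reads:
        orientation = None
        for primer, name in ((forward_primer, "forward"), (reverse_primer, "reverse")):
            window = read.sequence[: len(primer)]
            if (len(window) == len(primer)
                    and iupac_mismatches(window, primer.sequence)
                    <= params.primer_mismatches_allowed):
                orientation = name
                break
        if orientation is None:
            tally["primer"] += 1
            continue
        if len(read) < params.min_length_bp:
            tally["length"] += 1
            continue
        read.orientation = orientation
        retained.append(read)
    return retained, tally


def run_qc(raw_reads, mapping: dict[str, str], params: QCParams | None = None):
    """Demultiplex, trim and filter; returns per-library retained reads plus
    a per-library rejection tally and the unassigned count."""
    params = params or QCParams()
    per_library, unassigned = demultiplex(raw_reads, mapping, params)
    retained: dict[str, list[PyroRead]] = {}
    tallies: dict[str, Counter] = {}
    for lib, reads in per_library.items():
        trimmed = [trim_read(r, params) for r in reads]
        retained[lib], tallies[lib] = filter_reads(trimmed, params)
    return retained, tallies, len(unassigned)
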