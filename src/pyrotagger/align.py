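"""Semi-global pairwise alignment with free end gaps.

Amplicon reads are anchored at one of the two primers, so two reads (or a
read and a contig consensus) overlap in a suffix/prefix fashion.  The
aligner scores match +1, mismatch -1, internal gap -1, with end gaps free
on both sequences, and reports identity over the aligned overlap columns
(internal gaps count as mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MATCH = 1
_MISMATCH = -1
_GAP = -1


@dataclass(frozen=True)
class OverlapAlignment:
    """Result of a free-end-gap alignment of ``a`` against ``b``."""

    score: int
    columns: int          # aligned overlap columns (incl. internal gaps)
    matches: int
    a_start: int
    a_end: int            # exclusive
    b_start: int
    b_end: int            # exclusive

    @property
    def identity(self) -> float:
        if self.columns == 0:
            return 0.0
        return self.matches / self.columns

    @property
    def offset(self) -> int:
        """Ungapped placement of b's start in a's coordinates."""
        return self.a_start - self.b_start


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def overlap_align(a: str, b: str) -> OverlapAlignment:
    """Align two sequences allowing free terminal gaps.

    Returns the highest-scoring overlap placement; ties are resolved
    deterministically (first maximum scanning the final row then the final
    column, diagonal moves preferred in traceback).
    """
    if not a or not b:
        raise ValueError("overlap_align requires two non-empty sequences")
    av, bv = _encode(a), _encode(b)
    na, nb = len(av), len(bv)
    H = np.zeros((na + 1, nb + 1), dtype=np.int32)
    jidx = np.arange(nb + 1, dtype=np.int32)
    g = -_GAP  # positive gap cost
    cand = np.empty(nb + 1, dtype=np.int32)
    for i in range(1, na + 1):
        prev = H[i - 1]
        s = np.where(bv == av[i - 1], _MATCH, _MISMATCH).astype(np.int32)
        cand[0] = 0  # free gap down the first column
        np.maximum(prev[:-1] + s, prev[1:] + _GAP, out=cand[1:])
        # fold in left-gap chains: H[i,j] = max_{k<=j} cand[k] - g*(j-k)
        H[i] = np.maximum.accumulate(cand + g * jidx) - g * jidx
    # best end on the last row or last column
    last_row = H[na, :]
    last_col = H[:, nb]
    if last_row.max() >= last_col.max():
        j = int(np.argmax(last_row))
        i = na
    else:
        i = int(np.argmax(last_col))
        j = nb
    a_end, b_end = i, j
    matches = columns = 0
    while i > 0 and j > 0:
        diag = H[i - 1, j - 1] + (_MATCH if av[i - 1] == bv[j - 1] else _MISMATCH)
        if H[i, j] == diag:
            matches += int(av[i - 1] == bv[j - 1])
            columns += 1
            i -= 1
            j -= 1
        elif H[i, j] == H[i - 1, j] + _GAP:
            columns += 1
            i -= 1
        else:
            columns += 1
            j -= 1
    return OverlapAlignment(
        score=int(H[a_end, b_end]),
        columns=columns,
        matches=matches,
        a_start=i,
        a_end=a_end,
        b_start=j,
        b_end=b_end,
    )
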