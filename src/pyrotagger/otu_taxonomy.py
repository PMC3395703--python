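"""OTU clustering and naive-Bayes k-mer taxonomy assignment.

Reads are clustered into operational taxonomic units at 97% pairwise
identity (hierarchical linkage on 1 - gapped identity, complete linkage by
default), and classified with a bootstrap-confidence k-mer classifier in
the style of the RDP classifier: multinomial-free naive Bayes over 8-mer
presence with word-specific priors, 100 bootstrap resamples of ``L/k``
words, and the reported lineage truncated at the deepest rank whose
bootstrap agreement reaches the confidence threshold (default 80%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .align import overlap_align
from .read_qc import PyroRead, oriented_sequence
from .synth_community import RANKS, ReferenceTaxon

UNCLASSIFIED = "unclassified"

#: pairs closer than this overlap are treated as non-comparable (distance 1);
#: guards against tiny spurious end-overlaps collapsing unrelated reads
MIN_COMPARABLE_OVERLAP = 30


@dataclass
class ClusterParams:
    otu_identity: float = 0.97
    linkage: str = "complete"

    def __post_init__(self):
        if not 0 < self.otu_identity <= 1:
            raise ValueError("otu_identity must lie in (0, 1]")
        if self.linkage not in ("complete", "average", "single"):
            raise ValueError("linkage must be complete, average or single")


@dataclass
class ClassifierParams:
    kmer_size: int = 8
    n_bootstrap: int = 100
    confidence_threshold: float = 0.80

    def __post_init__(self):
        # 0 forces full-depth lineages, >1 forces "unclassified"; both are
        # useful degenerate probes, so only negatives are rejected
        if self.confidence_threshold < 0:
            raise ValueError("confidence_threshold must be non-negative")


def pairwise_distance(a: str, b: str) -> float:
    """1 - gapped identity over the mutual overlap of two oriented reads."""
    if a == b:
        return 0.0
    aln = overlap_align(a, b)
    if aln.columns < MIN_COMPARABLE_OVERLAP:
        return 1.0
    return 1.0 - aln.identity


def cluster_otus(reads, params: ClusterParams | None = None) -> list[list[str]]:
    """Partition reads into OTUs; returns lists of read ids per OTU.

    Accepts PyroRead objects or (read_id, sequence) pairs; reverse reads
    are put on the forward strand first.
    """
    params = params or ClusterParams()
    ids, seqs = [], []
    for r in reads:
        if isinstance(r, PyroRead):
            ids.append(r.read_id)
            seqs.append(oriented_sequence(r))
        else:
            ids.append(r[0])
            seqs.append(r[1])
    n = len(ids)
    if n == 0:
        return []
    if n == 1:
        return [[ids[0]]]
    # deduplicate identical sequences before the quadratic alignment pass
    uniq: dict[str, int] = {}
    rep = np.empty(n, dtype=int)
    for i, s in enumerate(seqs):
        rep[i] = uniq.setdefault(s, len(uniq))
    useqs = list(uniq)
    m = len(useqs)
    if m == 1:
        return [list(ids)]
    from .contig_assembly import kmer_set, shares_kmers
    ksets = [kmer_set(s) for s in useqs]
    dm = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            # pairs sharing almost no 20-mers cannot be >=97% similar:
            # skip the quadratic alignment, call them maximally distant
            if shares_kmers(ksets[i], ksets[j]):
                d = pairwise_distance(useqs[i], useqs[j])
            else:
                d = 1.0
            dm[i, j] = dm[j, i] = d
    Z = linkage(squareform(dm, checks=False), method=params.linkage)
    labels = fcluster(Z, t=1.0 - params.otu_identity, criterion="distance")
    otus: dict[int, list[str]] = {}
    for i, rid in enumerate(ids):
        otus.setdefault(int(labels[rep[i]]), []).append(rid)
    return [otus[k] for k in sorted(otus)]


def singleton_fraction(partition: list[list[str]]) -> float:
    """Fraction of OTUs represented by exactly one read."""
    if not partition:
        return 0.0
    return sum(len(o) == 1 for o in partition) / len(partition)


@dataclass
class Classification:
    lineage: tuple[str, ...]          # truncated at the supported rank
    confidences: dict[str, float]     # rank -> bootstrap agreement
    best_genus: str

    @property
    def rank(self) -> str | None:
        return RANKS[len(self.lineage) - 1] if self.lineage else None

    def at(self, rank: str) -> str:
        """Name at ``rank`` or 'unclassified' when truncated above it."""
        i = RANKS.index(rank)
        return self.lineage[i] if i < len(self.lineage) else UNCLASSIFIED


class KmerClassifier:
    """RDP-style naive-Bayes classifier over k-mer presence.

    Genera are the classification units; reads are assigned the lineage of
    the maximum-posterior genus and the bootstrap agreement at every rank
    is the fraction of resamples whose winning genus shares that ancestor.
    """

    def __init__(self, reference: list[ReferenceTaxon],
                 params: ClassifierParams | None = None):
        if not reference:
            raise ValueError("empty reference set")
        self.params = params or ClassifierParams()
        k = self.params.kmer_size
        genera: dict[str, list[str]] = {}
        lineages: dict[str, tuple[str, ...]] = {}
        for t in reference:
            genera.setdefault(t.genus, []).append(t.sequence)
            lineages[t.genus] = t.lineage
        self.genus_names = sorted(genera)
        self.lineage_arr = np.array(
            [lineages[g] for g in self.genus_names], dtype=object)
        # integer codes per rank for fast bootstrap agreement
        self.rank_codes = np.empty((len(self.genus_names), len(RANKS)), dtype=int)
        for ri in range(len(RANKS)):
            _, codes = np.unique(self.lineage_arr[:, ri].astype(str),
                                 return_inverse=True)
            self.rank_codes[:, ri] = codes
        vocab: dict[str, int] = {}
        per_seq_words: list[tuple[int, set[int]]] = []  # (genus index, word ids)
        n_seqs = 0
        for gi, g in enumerate(self.genus_names):
            for seq in genera[g]:
                words = {vocab.setdefault(seq[i:i + k], len(vocab))
                         for i in range(len(seq) - k + 1)}
                per_seq_words.append((gi, words))
                n_seqs += 1
        self.vocab = vocab
        V, G = len(vocab), len(self.genus_names)
        n_w = np.zeros(V)            # sequences containing word w
        m = np.zeros((G, V))         # per-genus sequences containing w
        M = np.zeros(G)              # sequences per genus
        for gi, words in per_seq_words:
            idx = np.fromiter(words, dtype=int)
            n_w[idx] += 1
            m[gi, idx] += 1
            M[gi] += 1
        prior = (n_w + 0.5) / (n_seqs + 1.0)
        self.logp = np.log((m + prior[None, :]) / (M[:, None] + 1.0)).astype(np.float64)

    def _word_ids(self, seq: str) -> np.ndarray:
        k = self.params.kmer_size
        vocab = self.vocab
        ids = {vocab[w] for i in range(len(seq) - k + 1)
               if (w := seq[i:i + k]) in vocab}
        return np.fromiter(ids, dtype=int) if ids else np.empty(0, dtype=int)

    def classify(self, sequence: str,
                 rng: np.random.Generator | None = None) -> Classification:
        """Classify one oriented read sequence."""
        rng = rng or np.random.default_rng(0)
        p = self.params
        idx = self._word_ids(sequence)
        G = len(self.genus_names)
        if len(idx) == 0:
            return Classification((), {r: 0.0 for r in RANKS}, UNCLASSIFIED)
        scores_full = self.logp[:, idx].sum(axis=1)
        jitter = rng.uniform(0, 1e-9, size=G)  # random tie-break
        best = int(np.argmax(scores_full + jitter))
        s = max(1, len(sequence) // p.kmer_size)
        sel = rng.integers(0, len(idx), size=(p.n_bootstrap, s))
        sub = self.logp[:, idx]                       # (G, m)
        boot = sub[:, sel].sum(axis=2)                # (G, n_bootstrap)
        boot = boot + rng.uniform(0, 1e-9, size=boot.shape)
        winners = np.argmax(boot, axis=0)
        best_lineage = self.lineage_arr[best]
        confidences: dict[str, float] = {}
        lineage: list[str] = []
        supported = True
        for ri, rank in enumerate(RANKS):
            agree = float(np.mean(
                self.rank_codes[winners, ri] == self.rank_codes[best, ri]))
            confidences[rank] = agree
            if supported and agree >= p.confidence_threshold:
                lineage.append(best_lineage[ri])
            else:
                supported = False
        return Classification(tuple(lineage), confidences,
                              self.genus_names[best])

    def classify_reads(self, reads, seed: int = 0) -> dict[str, Classification]:
        """Classify a batch of PyroReads (oriented first); deterministic."""
        rng = np.random.default_rng(seed)
        return {r.read_id: self.classify(oriented_sequence(r), rng)
                for r in reads}


def classify_read(read: PyroRead, reference: list[ReferenceTaxon],
                  params: ClassifierParams | None = None,
                  seed: int = 0) -> Classification:
    """Convenience one-shot wrapper; builds a classifier per call."""
    clf = KmerClassifier(reference, params)
    return clf.classify(oriented_sequence(read), np.random.default_rng(seed))


class AbundanceTable:
    """Taxon-or-OTU x library table of read counts with derived percentages."""

    def __init__(self, counts: pd.DataFrame):
        if (counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        if (counts.sum(axis=0) == 0).any():
            raise ValueError("empty library column in abundance table")
        self.counts = counts.astype(int)

    def relative(self) -> pd.DataFrame:
        """Relative abundance in percent; columns sum to 100."""
        return 100.0 * self.counts / self.counts.sum(axis=0)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)


def tabulate(per_library, rank: str | None = None) -> AbundanceTable:
    """Aggregate classifications (or OTU partitions) into an AbundanceTable.

    ``per_library`` maps library id to either a list of Classification
    objects (aggregated at ``rank``) or a list of arbitrary labels
    (e.g. OTU ids), in which case ``rank`` is ignored.
    """
    if rank is not None and rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    columns = {}
    for lib, items in per_library.items():
        if len(items) == 0:
            raise ValueError(f"library {lib!r} has no reads to tabulate")
        labels = []
        for it in items:
            if isinstance(it, Classification):
                if rank is None:
                    raise ValueError("rank required for classifications")
                labels.append(it.at(rank))
            else:
                labels.append(it)
        columns[lib] = pd.Series(labels).value_counts()
    counts = pd.DataFrame(columns).fillna(0).astype(int)
    counts = counts.sort_index()
    return AbundanceTable(counts)
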