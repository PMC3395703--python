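"""Synthetic mock communities and 454-style bidirectional pyrotag reads.

Emulates the sequencing substrate of a tar-oil-contaminated-aquifer survey:
a community of a few dominant lineages (each below ~15% template share)
with a long rare tail, amplified with the Ba27f/Ba519r primer pair, MID
barcoded, read in both orientations, and corrupted with homopolymer-biased
pyrosequencing noise.  Every read carries its true source taxon so each
downstream stage can be scored against ground truth.

Reference sequences are random DNA with the two primer sites spliced in at
the amplicon ends.  Taxonomic signal for the k-mer classifier is created by
seeding each genus with two shared 60-nt signature blocks, one near each
amplicon end so that both forward and reverse reads observe one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .read_qc import (
    BA27F,
    BA519R,
    IUPAC,
    PyroRead,
    match_primer,
    revcomp,
)

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: lineages typical of a hydrocarbon-degrading aquifer community, ordered so
#: that the most abundant ranks of a sorted community fall mostly into one
#: dominant phylum (Proteobacteria), as at the field site being emulated.
AQUIFER_LINEAGES = (
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfobacterales", "Desulfobulbaceae", "Desulfobulbus"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Peptococcaceae", "Desulfosporosinus"),
    ("Bacteria", "Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Spirochaeta"),
    ("Bacteria", "Proteobacteria", "Deltaproteobacteria", "Desulfuromonadales", "Geobacteraceae", "Geobacter"),
    ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prolixibacteraceae", "Draconibacterium"),
    ("Bacteria", "Chloroflexi", "Anaerolineae", "Anaerolineales", "Anaerolineaceae", "Anaerolinea"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Desulfitobacteriaceae", "Desulfitobacterium"),
    ("Bacteria", "Actinobacteria", "Actinomycetia", "Micrococcales", "Microbacteriaceae", "Microbacterium"),
    ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae", "Rhodoferax"),
    ("Bacteria", "Acidobacteria", "Acidobacteriia", "Acidobacteriales", "Acidobacteriaceae", "Acidobacterium"),
    ("Bacteria", "Nitrospirae", "Nitrospira", "Nitrospirales", "Nitrospiraceae", "Nitrospira"),
    ("Bacteria", "Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Sulfurimonadaceae", "Sulfurimonas"),
)

SPIKE_LINEAGE = ("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                 "Vibrionales", "Vibrionaceae", "Aliivibrio")

#: standard Roche GS FLX multiplex identifiers (MID1..MID10)
ROCHE_MIDS = (
    "ACGAGTGCGT", "ACGCTCGACA", "AGACGCACTC", "AGCACTGTAG", "ATCAGACACG",
    "ATATCGCGAG", "CGTGTCTCTA", "CTCGCGTGTC", "TAGTATCAGC", "TCTCTATGCG",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SIG_LEN = 60
_SITE = "CCGG"


def _stable_seed(*parts) -> int:
    h = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii")


def _resolve_degenerate(pattern: str, rng: np.random.Generator) -> str:
    return "".join(b if b in "ACGT" else rng.choice(list(IUPAC[b])) for b in pattern)


def _scrub_site(seq: str, protected: list[tuple[int, int]]) -> str:
    """Mutate one unprotected base of every recognition-site occurrence."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        pos = text.find(_SITE)
        while pos >= 0:
            for off in range(len(_SITE)):
                p = pos + off
                if not any(a <= p < b for a, b in protected):
                    s[p] = "A" if s[p] != "A" else "T"
                    changed = True
                    break
            pos = text.find(_SITE, pos + 1)
            if changed:
                break
    return "".join(s)


@dataclass(frozen=True)
class ReferenceTaxon:
    """A full-length amplicon reference with its taxonomy."""

    taxon_id: str
    lineage: tuple[str, ...]  # (domain, phylum, class, order, family, genus)
    sequence: str

    def __post_init__(self):
        if len(self.lineage) != len(RANKS):
            raise ValueError(f"lineage must have ranks {RANKS}")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference sequence must be concrete ACGT")

    @property
    def genus(self) -> str:
        return self.lineage[-1]

    @property
    def phylum(self) -> str:
        return self.lineage[1]


@dataclass
class MockCommunity:
    """Ground-truth template pool: taxa plus their template fractions."""

    taxa: list[ReferenceTaxon]
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.taxa) != len(self.fractions):
            raise ValueError("taxa/fractions length mismatch")
        if (self.fractions < 0).any():
            raise ValueError("fractions must be non-negative")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return [t.taxon_id for t in self.taxa]

    def fraction_of(self, taxon_id: str) -> float:
        return float(self.fractions[self.taxon_ids.index(taxon_id)])


@dataclass
class SpikeDesign:
    """Template-amendment layout: one external taxon at defined fractions."""

    spike_taxon: ReferenceTaxon
    amendment_fractions: tuple[float, ...] = (0.0, 0.002, 0.02, 0.20)
    replicate_seeds: tuple[int, ...] = (1, 2)

    def __post_init__(self):
        if any(not (0 <= f < 1) for f in self.amendment_fractions):
            raise ValueError("amendment fractions must lie in [0, 1)")


@dataclass
class QualityProfile:
    """Mean Phred by relative position, with linear 3' decay."""

    q_start: float = 37.0
    q_end: float = 27.0
    noise_sd: float = 2.0

    def means(self, length: int) -> np.ndarray:
        if length <= 1:
            return np.full(length, self.q_start)
        return np.linspace(self.q_start, self.q_end, length)


@dataclass
class ErrorModel:
    """454-like noise: rare substitutions, indels enriched in homopolymers."""

    substitution_rate: float = 5e-4
    indel_rate: float = 1e-3
    homopolymer_multiplier: float = 4.0
    quality_profile: QualityProfile = field(default_factory=QualityProfile)

    def __post_init__(self):
        for r in (self.substitution_rate, self.indel_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.homopolymer_multiplier < 1:
            raise ValueError("homopolymer multiplier must be >= 1")


ERROR_FREE = ErrorModel(substitution_rate=0.0, indel_rate=0.0,
                        homopolymer_multiplier=1.0)


def _genus_signature(genus: str, which: str, rng_cls=np.random.default_rng) -> str:
    """Deterministic 60-nt signature shared by all members of a genus."""
    rng = rng_cls(_stable_seed("signature", genus, which))
    sig = _random_dna(_SIG_LEN, rng)
    return _scrub_site(sig, [])


def build_reference_taxon(taxon_id: str, lineage: tuple[str, ...], seed: int,
                          length: int | None = None,
                          with_site: bool = True) -> ReferenceTaxon:
    """Construct one reference amplicon.

    Layout (coordinates from the Ba27f 5' end): forward primer, 10-nt pad,
    genus 5' signature, variable core, genus 3' signature, 30-nt pad,
    reverse-primer site.  ``with_site`` controls whether an internal MspI
    site is guaranteed (True) or scrubbed out entirely (False).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(20):
        L = length if length is not None else int(rng.integers(450, 551))
        fwd = _resolve_degenerate(BA27F.sequence, rng)
        rev_site = revcomp(_resolve_degenerate(BA519R.sequence, rng))
        genus = lineage[-1]
        sig5 = _genus_signature(genus, "5p")
        sig3 = _genus_signature(genus, "3p")
        head = fwd + _random_dna(10, rng) + sig5
        tail = sig3 + _random_dna(30, rng) + rev_site
        core_len = L - len(head) - len(tail)
        if core_len < 40:
            raise ValueError("amplicon too short for the fixed layout")
        core = _random_dna(core_len, rng)
        seq = head + core + tail
        protected = [(0, len(fwd)),
                     (len(head) - _SIG_LEN, len(head)),
                     (len(head) + core_len, len(head) + core_len + _SIG_LEN),
                     (L - len(rev_site), L)]
        if with_site:
            if _SITE not in seq[len(fwd):L - len(rev_site)]:
                pos = int(rng.integers(len(head), len(head) + core_len - len(_SITE)))
                seq = seq[:pos] + _SITE + seq[pos + len(_SITE):]
        else:
            seq = _scrub_site(seq, protected)
        # invariant: exactly one match per primer site
        if (_count_matches(seq, BA27F.sequence) == 1
                and _count_matches(seq, revcomp(BA519R.sequence)) == 1):
            return ReferenceTaxon(taxon_id, tuple(lineage), seq)
        rng = np.random.default_rng(_stable_seed(seed, "retry", attempt))
    raise RuntimeError("could not satisfy primer-site uniqueness")


def _count_matches(seq: str, pattern: str) -> int:
    n = 0
    for start in range(len(seq) - len(pattern) + 1):
        if all(b in IUPAC.get(p, "") for b, p in zip(seq[start:start + len(pattern)], pattern)):
            n += 1
    return n


def build_mock_community(n_taxa: int, dominance: float = 1.5,
                         seed: int = 0) -> MockCommunity:
    """Dirichlet community with fractions sorted descending.

    ``dominance`` is the symmetric Dirichlet concentration: small values
    give strongly uneven communities, ``inf`` gives a perfectly even one.
    ~90% of taxa carry at least one internal MspI site.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng(seed)
    if np.isinf(dominance):
        fractions = np.full(n_taxa, 1.0 / n_taxa)
    else:
        fractions = np.sort(rng.dirichlet([dominance] * n_taxa))[::-1]
        fractions = fractions / fractions.sum()
    taxa = []
    for i in range(n_taxa):
        lineage = AQUIFER_LINEAGES[i % len(AQUIFER_LINEAGES)]
        with_site = bool(rng.random() < 0.9)
        taxa.append(build_reference_taxon(
            f"{lineage[-1]}_{i:02d}", lineage,
            seed=_stable_seed(seed, "taxon", i), with_site=with_site))
    return MockCommunity(taxa, fractions)


def make_spike_taxon(seed: int = 0) -> ReferenceTaxon:
    """The external *Aliivibrio fisheri*-like amendment template."""
    return build_reference_taxon("Aliivibrio_fisheri", SPIKE_LINEAGE,
                                 seed=_stable_seed(seed, "spike"))


def spike_pool(base: MockCommunity, design: SpikeDesign,
               fraction: float) -> MockCommunity:
    """Amend the base pool with the spike taxon at exactly ``fraction``."""
    if fraction not in design.amendment_fractions:
        raise ValueError("fraction not part of the spike design")
    if design.spike_taxon.taxon_id in base.taxon_ids:
        raise ValueError("spike taxon already present in base community")
    if fraction == 0:
        return MockCommunity(list(base.taxa), base.fractions.copy())
    fractions = np.append(base.fractions * (1.0 - fraction), fraction)
    return MockCommunity(list(base.taxa) + [design.spike_taxon], fractions)


def _run_lengths(arr: np.ndarray) -> np.ndarray:
    change = np.r_[True, arr[1:] != arr[:-1]]
    run_id = np.cumsum(change) - 1
    counts = np.bincount(run_id)
    return counts[run_id]


def _corrupt(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    n = len(arr)
    if model.substitution_rate > 0:
        mask = rng.random(n) < model.substitution_rate
        for p in np.nonzero(mask)[0]:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)
    if model.indel_rate > 0:
        runlen = _run_lengths(arr)
        rate = np.where(runlen >= 3,
                        min(1.0, model.indel_rate * model.homopolymer_multiplier),
                        model.indel_rate)
        events = np.nonzero(rng.random(n) < rate)[0]
        if len(events):
            out = []
            prev = 0
            for p in events:
                out.append(arr[prev:p])
                if rng.random() < 0.5:  # over-call: duplicate the base
                    out.append(arr[p:p + 1])
                    out.append(arr[p:p + 1])
                # else under-call: drop the base
                prev = p + 1
            out.append(arr[prev:])
            arr = np.concatenate(out)
    return arr.tobytes().decode("ascii")


def simulate_reads(pool: MockCommunity, depth: int, mid: str,
                   model: ErrorModel | None = None, seed: int = 0,
                   library_id: str = "lib", short_read_prob: float = 0.01,
                   mean_length: float = 400.0, sd_length: float = 60.0,
                   min_length: int = 150) -> list[PyroRead]:
    """Draw ``depth`` barcoded bidirectional reads from a template pool.

    Each read samples a taxon multinomially, an orientation uniformly, and
    a post-primer template length from a truncated Gaussian; with
    probability ``short_read_prob`` the read is instead a short product
    (uniform 150..249 nt post-primer), the knob used to emulate 2-step-PCR
    libraries which carry ~5x more sub-250-bp reads.  Deterministic for a
    fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(pool.taxa) == 0:
        raise ValueError("empty template pool")
    if model is None:
        model = ErrorModel()
    rng = np.random.default_rng(seed)
    taxa_idx = rng.choice(len(pool.taxa), size=depth, p=pool.fractions)
    forward = rng.random(depth) < 0.5
    reads: list[PyroRead] = []
    profile = model.quality_profile
    for i in range(depth):
        taxon = pool.taxa[taxa_idx[i]]
        template = taxon.sequence if forward[i] else revcomp(taxon.sequence)
        primer_len = len(BA27F) if forward[i] else len(BA519R)
        max_core = len(template) - primer_len
        if rng.random() < short_read_prob:
            core = int(rng.integers(min_length, 250))
        else:
            core = int(round(rng.normal(mean_length, sd_length)))
        core = max(min_length, min(core, max_core))
        raw = template[: primer_len + core]
        noisy = _corrupt(raw, model, rng)
        seq = mid + noisy
        quals = np.full(len(seq), profile.q_start, dtype=float)
        body = profile.means(len(noisy))
        if profile.noise_sd > 0:
            body = body + rng.normal(0.0, profile.noise_sd, size=len(noisy))
        quals[len(mid):] = body
        quals = np.clip(np.round(quals), 2, 40).astype(np.int64)
        reads.append(PyroRead(
            read_id=f"{library_id}_r{i:06d}",
            sequence=seq,
            qualities=quals,
            library_id=None,
            orientation="forward" if forward[i] else "reverse",
            mid=None,
            true_taxon=taxon.taxon_id,
        ))
    return reads


# ---------------------------------------------------------------------------
# plain-text outputs

def write_fastq(reads, path) -> None:
    """Sanger Phred+33 FASTQ, one record per read, insertion order."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path) -> list[PyroRead]:
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(PyroRead(
            read_id=rec.id,
            sequence=str(rec.seq),
            qualities=np.asarray(rec.letter_annotations["phred_quality"]),
        ))
    return reads


def write_truth_table(pool: MockCommunity, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "taxon_id": pool.taxon_ids,
        "lineage": [";".join(t.lineage) for t in pool.taxa],
        "true_fraction": pool.fractions,
    }).to_csv(path, sep="\t", index=False)


def write_mapping(mapping: dict[str, str], path, groups: dict[str, str] | None = None) -> None:
    import pandas as pd

    groups = groups or {}
    pd.DataFrame({
        "library_id": list(mapping),
        "mid": [mapping[k] for k in mapping],
        "replicate_group": [groups.get(k, "") for k in mapping],
    }).to_csv(path, sep="\t", index=False)
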