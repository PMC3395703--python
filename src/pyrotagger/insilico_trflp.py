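"""In-silico T-RFLP: digestion, fingerprint prediction and matching.

A terminal restriction fragment (T-RF) is the stretch from the 5' base of
the labelled forward primer to the first restriction cut; its length is the
community-profiling signal read off a capillary electropherogram.  Partial
digestion additionally produces "pseudo-T-RFs" ending at secondary sites
downstream of the primary one — observable in vivo but never predicted by
a complete in-silico digest, which is why the matcher flags them
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contig_assembly import Contig


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str = "MspI"
    recognition_site: str = "CCGG"
    cut_offset: int = 1  # C^CGG on the labelled strand

    def __post_init__(self):
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError("cut_offset must lie within the recognition site")


MSPI = RestrictionEnzyme()


@dataclass
class TRF:
    length_bp: int
    abundance: float = 0.0      # relative share (%) or signal height (RFU)
    pseudo: bool = False
    origin: str = "in_silico"   # "in_silico" | "in_vivo"
    parent_length_bp: int | None = None  # primary T-RF a pseudo fragment belongs to

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")


@dataclass
class Fingerprint:
    sample_id: str
    trfs: list[TRF]
    rfu_threshold: float = 100.0

    def thresholded(self) -> list[TRF]:
        """T-RFs whose signal passes the electropherogram threshold."""
        return [t for t in self.trfs if t.abundance >= self.rfu_threshold]

    def primary(self) -> list[TRF]:
        return [t for t in self.trfs if not t.pseudo]

    def lengths(self) -> list[int]:
        return [t.length_bp for t in self.trfs]


@dataclass
class ElectrophoresisParams:
    drift_bp: int = 3            # fragment sizes slide by up to this many bp
    signal_per_read: float = 100.0
    noise_sd: float = 5.0
    partial_digest_fraction: float = 0.0  # pseudo-T-RF signal vs parent

    def __post_init__(self):
        if self.drift_bp < 0:
            raise ValueError("drift_bp must be non-negative")


def _site_positions(sequence: str, site: str) -> list[int]:
    pos, out = sequence.find(site), []
    while pos >= 0:
        out.append(pos)
        pos = sequence.find(site, pos + 1)
    return out


def digest(sequence: str, enzyme: RestrictionEnzyme = MSPI,
           include_pseudo: bool = True) -> list[TRF]:
    """Terminal fragments of one labelled amplicon.

    ``sequence`` must start at the 5' base of the labelled primer.  The
    first recognition site yields the primary T-RF (site index plus
    ``cut_offset``); each later site yields a pseudo-T-RF at the analogous
    coordinate.  A sequence without any site gives one uncut full-length
    fragment.
    """
    if not sequence:
        raise ValueError("empty sequence")
    sites = _site_positions(sequence.upper(), enzyme.recognition_site)
    if not sites:
        return [TRF(length_bp=len(sequence))]
    primary = TRF(length_bp=sites[0] + enzyme.cut_offset)
    out = [primary]
    if include_pseudo:
        out.extend(TRF(length_bp=p + enzyme.cut_offset, pseudo=True,
                       parent_length_bp=primary.length_bp)
                   for p in sites[1:])
    return out


def predict_fingerprint(contigs: list[Contig],
                        enzyme: RestrictionEnzyme = MSPI,
                        sample_id: str = "in_silico",
                        include_pseudo: bool = True) -> Fingerprint:
    """Read-count-weighted in-silico fingerprint of retained contigs.

    Primary T-RFs of equal length are merged by summing read counts and the
    merged abundances are normalised to 100%.  Secondary sites are carried
    along as zero-abundance pseudo-T-RF records so the matcher can
    recognise partial-digestion artefacts.  Contigs that do not begin at
    the labelled primer are skipped (counted in ``skipped``).
    """
    from .read_qc import BA27F, iupac_mismatches

    primary: dict[int, float] = {}
    pseudo: dict[int, int] = {}  # pseudo length -> parent length
    skipped = 0
    for c in contigs:
        head = c.consensus[: len(BA27F)]
        if len(head) < len(BA27F) or iupac_mismatches(head, BA27F.sequence) > 2:
            skipped += 1
            continue
        frags = digest(c.consensus, enzyme, include_pseudo=include_pseudo)
        primary[frags[0].length_bp] = primary.get(frags[0].length_bp, 0.0) + c.n_reads
        for f in frags[1:]:
            pseudo.setdefault(f.length_bp, f.parent_length_bp)
    total = sum(primary.values())
    trfs = [TRF(length_bp=l, abundance=100.0 * w / total)
            for l, w in sorted(primary.items())] if total else []
    trfs += [TRF(length_bp=l, abundance=0.0, pseudo=True, parent_length_bp=par)
             for l, par in sorted(pseudo.items())]
    fp = Fingerprint(sample_id, trfs, rfu_threshold=0.0)
    fp.skipped = skipped
    return fp


def emulate_electropherogram(truth: Fingerprint,
                             params: ElectrophoresisParams | None = None,
                             seed: int = 0,
                             rfu_threshold: float = 100.0) -> Fingerprint:
    """Turn a predicted fingerprint into a synthetic in-vivo one.

    Fragment sizes drift by a uniform integer within ±drift_bp, abundances
    are scaled to signal units with Gaussian noise, and peaks below the RFU
    threshold vanish.  With ``partial_digest_fraction > 0`` each pseudo-T-RF
    record is emitted at that fraction of its parent's signal, emulating
    incomplete digestion.
    """
    params = params or ElectrophoresisParams()
    rng = np.random.default_rng(seed)
    parent_signal = {t.length_bp: t.abundance * params.signal_per_read
                     for t in truth.trfs if not t.pseudo}
    peaks: dict[int, float] = {}
    for t in truth.trfs:
        if t.pseudo:
            if params.partial_digest_fraction <= 0:
                continue
            signal = parent_signal.get(t.parent_length_bp, 0.0) \
                * params.partial_digest_fraction
        else:
            signal = t.abundance * params.signal_per_read
        drift = int(rng.integers(-params.drift_bp, params.drift_bp + 1)) \
            if params.drift_bp else 0
        if params.noise_sd > 0:
            signal += rng.normal(0.0, params.noise_sd)
        length = max(1, t.length_bp + drift)
        peaks[length] = peaks.get(length, 0.0) + max(0.0, signal)
    trfs = [TRF(length_bp=l, abundance=s, origin="in_vivo")
            for l, s in sorted(peaks.items()) if s >= rfu_threshold]
    return Fingerprint(truth.sample_id, trfs, rfu_threshold=rfu_threshold)


@dataclass
class MatchResult:
    pairs: list[tuple[TRF, TRF, int]]          # (observed, predicted, delta bp)
    unmatched_observed: list[TRF]
    unmatched_predicted: list[TRF]
    pseudo_flags: list[tuple[TRF, int]]        # (observed, parent primary length)


def match_fingerprints(observed: Fingerprint, predicted: Fingerprint,
                       tolerance_bp: int = 3) -> MatchResult:
    """One-to-one pairing of observed vs predicted primary T-RFs.

    Greedy nearest-size pairing (ties toward the smaller fragment), subject
    to |Δbp| <= tolerance.  Observed fragments left unmatched are flagged as
    pseudo-T-RF candidates when they sit within tolerance of a predicted
    secondary (pseudo) fragment; the flag names the parent primary T-RF.
    """
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be non-negative")
    obs = sorted(observed.primary(), key=lambda t: t.length_bp)
    pred = sorted(predicted.primary(), key=lambda t: t.length_bp)
    candidates = sorted(
        (abs(o.length_bp - p.length_bp), o.length_bp, p.length_bp, oi, pi)
        for oi, o in enumerate(obs) for pi, p in enumerate(pred)
        if abs(o.length_bp - p.length_bp) <= tolerance_bp)
    used_o: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for d, _, _, oi, pi in candidates:
        if oi in used_o or pi in used_p:
            continue
        pairs.append((obs[oi], pred[pi], obs[oi].length_bp - pred[pi].length_bp))
        used_o.add(oi)
        used_p.add(pi)
    unmatched_o = [o for i, o in enumerate(obs) if i not in used_o]
    unmatched_p = [p for i, p in enumerate(pred) if i not in used_p]
    pseudo_sites = [(t.length_bp, t.parent_length_bp)
                    for t in predicted.trfs if t.pseudo]
    flags = []
    for o in unmatched_o:
        hits = sorted((abs(o.length_bp - l), par) for l, par in pseudo_sites
                      if abs(o.length_bp - l) <= tolerance_bp)
        if hits:
            flags.append((o, hits[0][1]))
    return MatchResult(pairs, unmatched_o, unmatched_p, flags)


def write_fingerprint(fp: Fingerprint, path) -> None:
    import pandas as pd

    pd.DataFrame({
        "length_bp": [t.length_bp for t in fp.trfs],
        "signal": [t.abundance for t in fp.trfs],
        "pseudo_flag": [int(t.pseudo) for t in fp.trfs],
        "origin": [t.origin for t in fp.trfs],
    }).to_csv(path, sep="\t", index=False)


def read_fingerprint(path, sample_id: str | None = None,
                     rfu_threshold: float = 100.0) -> Fingerprint:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    trfs = [TRF(length_bp=int(r.length_bp), abundance=float(r.signal),
                pseudo=bool(r.pseudo_flag), origin=str(r.origin))
            for r in df.itertuples()]
    return Fingerprint(sample_id or str(path), trfs, rfu_threshold)
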