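"""End-to-end orchestration: simulate -> qc -> assemble -> classify ->
digest -> stats, with one config, derived per-stage seeds and a checksummed
run manifest.

Every stage reads its inputs from and writes its outputs to the run
directory, so stages can be re-run selectively; a missing upstream artifact
raises :class:`DependencyError` naming the stage.  A single global seed
deterministically derives per-stage/per-library sub-seeds by stable
hashing, so a rerun with the same config reproduces identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community_stats as cstats
from .contig_assembly import (AssemblyParams, assemble, filter_contigs,
                              write_contigs_fasta, write_membership)
from .insilico_trflp import (ElectrophoresisParams, RestrictionEnzyme, MSPI,
                             emulate_electropherogram, match_fingerprints,
                             predict_fingerprint, read_fingerprint,
                             write_fingerprint)
from .otu_taxonomy import (ClassifierParams, ClusterParams, KmerClassifier,
                           cluster_otus, singleton_fraction, tabulate)
from .read_qc import PyroRead, QCParams, run_qc
from .synth_community import (ROCHE_MIDS, ErrorModel, MockCommunity,
                              ReferenceTaxon, SpikeDesign, _stable_seed,
                              build_mock_community, build_reference_taxon,
                              make_spike_taxon, read_fastq, simulate_reads,
                              spike_pool, write_fastq, write_mapping,
                              write_truth_table)

STAGES = ("simulate", "qc", "assemble", "classify", "digest", "stats")


class DependencyError(RuntimeError):
    """An upstream stage artifact is missing."""


@dataclass
class SimulationParams:
    n_taxa: int = 8
    dominance: float = 2.0
    depth: int = 300
    n_libraries: int = 3
    short_read_prob: float = 0.01
    error: ErrorModel = field(default_factory=ErrorModel)


@dataclass
class PipelineConfig:
    """All tunables of the workflow, preloaded with the study thresholds:
    250 bp length filter, 98% / 50 bp / 20-read assembly, 97% OTUs, 80%
    classifier confidence, 100 RFU, 20% Pareto-Lorenz point, ±3 bp T-RF
    match tolerance."""

    seed: int = 0
    outdir: str = "run"
    simulation: SimulationParams = field(default_factory=SimulationParams)
    qc: QCParams = field(default_factory=QCParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    electrophoresis: ElectrophoresisParams = field(default_factory=ElectrophoresisParams)
    enzyme: RestrictionEnzyme = field(default_factory=RestrictionEnzyme)
    rfu_threshold: float = 100.0
    fo_top_fraction: float = 0.2
    trf_tolerance_bp: int = 3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        err = sim.pop("error", {})
        qp = err.pop("quality_profile", {}) if err else {}
        from .synth_community import QualityProfile
        error = ErrorModel(**err, quality_profile=QualityProfile(**qp)) \
            if err else ErrorModel()
        return cls(
            simulation=SimulationParams(**sim, error=error),
            qc=QCParams(**d.pop("qc", {})),
            assembly=AssemblyParams(**d.pop("assembly", {})),
            cluster=ClusterParams(**d.pop("cluster", {})),
            classifier=ClassifierParams(**d.pop("classifier", {})),
            electrophoresis=ElectrophoresisParams(**d.pop("electrophoresis", {})),
            enzyme=RestrictionEnzyme(**d.pop("enzyme", {})),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(seed: int, *names) -> int:
    """Derived, independent sub-seed for a stage (and optional library)."""
    return _stable_seed(seed, *names)


# ---------------------------------------------------------------------------
# reference round-trip

def write_reference_fasta(taxa: list[ReferenceTaxon], path) -> None:
    with open(path, "w") as fh:
        for t in taxa:
            fh.write(f">{t.taxon_id} {';'.join(t.lineage)}\n{t.sequence}\n")


def read_reference_fasta(path) -> list[ReferenceTaxon]:
    taxa = []
    with open(path) as fh:
        header, seq = None, []
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header:
                    tid, lin = header.split(" ", 1)
                    taxa.append(ReferenceTaxon(tid, tuple(lin.split(";")), "".join(seq)))
                header, seq = line[1:], []
            elif line:
                seq.append(line)
        if header:
            tid, lin = header.split(" ", 1)
            taxa.append(ReferenceTaxon(tid, tuple(lin.split(";")), "".join(seq)))
    return taxa


def _oriented_reads_from_fastq(path) -> list[PyroRead]:
    reads = read_fastq(path)
    for r in reads:
        rid, orientation = r.read_id.rsplit("|", 1)
        r.read_id = rid
        r.orientation = orientation
    return reads


def _write_oriented_fastq(reads, path) -> None:
    tagged = []
    for r in reads:
        t = dataclasses.replace(r, read_id=f"{r.read_id}|{r.orientation}")
        tagged.append(t)
    write_fastq(tagged, path)


# ---------------------------------------------------------------------------
# stages

def _libraries(config: PipelineConfig) -> list[str]:
    return [f"lib{i + 1:02d}" for i in range(config.simulation.n_libraries)]


def _require(out: Path, stage: str, *paths: str) -> None:
    for p in paths:
        if not (out / p).exists():
            raise DependencyError(
                f"stage '{stage}' requires missing artifact '{p}' "
                f"(run the upstream stage first)")


def _stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    sim = config.simulation
    pool = build_mock_community(sim.n_taxa, sim.dominance,
                                seed=stage_seed(config.seed, "community"))
    libs = _libraries(config)
    mapping = {lib: ROCHE_MIDS[i % len(ROCHE_MIDS)] for i, lib in enumerate(libs)}
    all_reads = []
    for lib in libs:
        all_reads += simulate_reads(
            pool, sim.depth, mapping[lib], sim.error,
            seed=stage_seed(config.seed, "simulate", lib),
            library_id=lib, short_read_prob=sim.short_read_prob)
    files = [out / "raw.fastq", out / "mapping.tsv", out / "truth.tsv",
             out / "reference.fasta"]
    write_fastq(all_reads, files[0])
    write_mapping(mapping, files[1])
    write_truth_table(pool, files[2])
    write_reference_fasta(pool.taxa, files[3])
    return files


def _stage_qc(config: PipelineConfig, out: Path) -> list[Path]:
    _require(out, "qc", "raw.fastq", "mapping.tsv")
    mapping = dict(pd.read_csv(out / "mapping.tsv", sep="\t")
                   [["library_id", "mid"]].values)
    raw = read_fastq(out / "raw.fastq")
    retained, tallies, n_unassigned = run_qc(raw, mapping, config.qc)
    files = []
    for lib, reads in retained.items():
        f = out / f"qc_{lib}.fastq"
        _write_oriented_fastq(reads, f)
        files.append(f)
    rows = [{"library_id": lib, "retained": len(retained[lib]),
             **{f"rejected_{k}": v for k, v in tallies[lib].items()}}
            for lib in retained]
    tally = out / "qc_tally.tsv"
    pd.DataFrame(rows).fillna(0).to_csv(tally, sep="\t", index=False)
    (out / "qc_unassigned.txt").write_text(f"{n_unassigned}\n")
    return files + [tally, out / "qc_unassigned.txt"]


def _stage_assemble(config: PipelineConfig, out: Path) -> list[Path]:
    libs = _libraries(config)
    _require(out, "assemble", *[f"qc_{lib}.fastq" for lib in libs])
    files = []
    for lib in libs:
        reads = _oriented_reads_from_fastq(out / f"qc_{lib}.fastq")
        contigs, _ = assemble(reads, config.assembly)
        kept = filter_contigs(contigs, config.assembly)
        fa = out / f"contigs_{lib}.fasta"
        tsv = out / f"contigs_{lib}.tsv"
        write_contigs_fasta(kept, fa)
        write_membership(kept, tsv)
        files += [fa, tsv]
    return files


def _stage_classify(config: PipelineConfig, out: Path) -> list[Path]:
    libs = _libraries(config)
    _require(out, "classify", "reference.fasta",
             *[f"qc_{lib}.fastq" for lib in libs])
    reference = read_reference_fasta(out / "reference.fasta")
    clf = KmerClassifier(reference, config.classifier)
    per_lib_cls = {}
    files = []
    for lib in libs:
        reads = _oriented_reads_from_fastq(out / f"qc_{lib}.fastq")
        cls = clf.classify_reads(reads, seed=stage_seed(config.seed, "classify", lib))
        per_lib_cls[lib] = list(cls.values())
        rows = [{"read_id": rid, "lineage": ";".join(c.lineage),
                 **{f"conf_{r}": c.confidences[r] for r in c.confidences}}
                for rid, c in cls.items()]
        f = out / f"taxonomy_{lib}.tsv"
        pd.DataFrame(rows).to_csv(f, sep="\t", index=False)
        files.append(f)
        otus = cluster_otus(reads, config.cluster)
        f2 = out / f"otus_{lib}.tsv"
        pd.DataFrame([(f"otu{k:04d}", rid) for k, otu in enumerate(otus)
                      for rid in otu],
                     columns=["otu_id", "read_id"]).to_csv(f2, sep="\t", index=False)
        files.append(f2)
    for rank in ("phylum", "genus"):
        tab = tabulate(per_lib_cls, rank=rank)
        f = out / f"abundance_{rank}.tsv"
        tab.counts.to_csv(f, sep="\t")
        files.append(f)
    return files


def _stage_digest(config: PipelineConfig, out: Path) -> list[Path]:
    libs = _libraries(config)
    _require(out, "digest", *[f"contigs_{lib}.fasta" for lib in libs])
    from .contig_assembly import Contig
    files = []
    for lib in libs:
        contigs = []
        with open(out / f"contigs_{lib}.fasta") as fh:
            header, seq = None, []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if header:
                        contigs.append(_contig_from_header(header, "".join(seq)))
                    header, seq = line[1:], []
                elif line:
                    seq.append(line)
            if header:
                contigs.append(_contig_from_header(header, "".join(seq)))
        predicted = predict_fingerprint(contigs, config.enzyme, sample_id=lib)
        observed = emulate_electropherogram(
            predicted, config.electrophoresis,
            seed=stage_seed(config.seed, "digest", lib),
            rfu_threshold=config.rfu_threshold)
        f1, f2 = out / f"fingerprint_insilico_{lib}.tsv", out / f"fingerprint_invivo_{lib}.tsv"
        write_fingerprint(predicted, f1)
        write_fingerprint(observed, f2)
        match = match_fingerprints(observed, predicted, config.trf_tolerance_bp)
        rows = [{"observed_bp": o.length_bp, "predicted_bp": p.length_bp,
                 "delta_bp": d} for o, p, d in match.pairs]
        rows += [{"observed_bp": o.length_bp, "predicted_bp": "",
                  "delta_bp": "", "pseudo_parent": par}
                 for o, par in match.pseudo_flags]
        f3 = out / f"trf_match_{lib}.tsv"
        pd.DataFrame(rows).to_csv(f3, sep="\t", index=False)
        files += [f1, f2, f3]
    return files


def _contig_from_header(header: str, seq: str):
    from .contig_assembly import Contig
    parts = dict(p.split("=") for p in header.split()[1:])
    n = int(parts.get("reads", 1))
    return Contig(header.split()[0], seq, [f"m{i}" for i in range(n)],
                  int(parts.get("fwd", n)), int(parts.get("rev", 0)))


def _stage_stats(config: PipelineConfig, out: Path) -> list[Path]:
    libs = _libraries(config)
    _require(out, "stats", "abundance_phylum.tsv", "abundance_genus.tsv",
             *[f"fingerprint_invivo_{lib}.tsv" for lib in libs])
    from .otu_taxonomy import AbundanceTable
    genus = AbundanceTable(pd.read_csv(out / "abundance_genus.tsv",
                                       sep="\t", index_col=0))
    phylum = AbundanceTable(pd.read_csv(out / "abundance_phylum.tsv",
                                        sep="\t", index_col=0))
    rows = []
    for lib in libs:
        counts = genus.counts[lib]
        h = cstats.shannon(counts[counts > 0], sample_id=lib)
        fp_obs = read_fingerprint(out / f"fingerprint_invivo_{lib}.tsv",
                                  sample_id=lib, rfu_threshold=config.rfu_threshold)
        fp_pred = read_fingerprint(out / f"fingerprint_insilico_{lib}.tsv",
                                   sample_id=lib, rfu_threshold=0.0)
        obs_ab = [t.abundance for t in fp_obs.thresholded()]
        pred_ab = [t.abundance for t in fp_pred.trfs
                   if not t.pseudo and t.abundance > 0]
        fo_vivo = (cstats.pareto_lorenz_fo(obs_ab, lib, config.fo_top_fraction).fo
                   if len(obs_ab) >= 2 else float("nan"))
        fo_silico = (cstats.pareto_lorenz_fo(pred_ab, lib, config.fo_top_fraction).fo
                     if len(pred_ab) >= 2 else float("nan"))
        rows.append({"library_id": lib, "shannon_h": h.shannon_h,
                     "richness": h.richness, "fo_in_vivo": fo_vivo,
                     "fo_in_silico": fo_silico})
    f1 = out / "summary_stats.tsv"
    pd.DataFrame(rows).to_csv(f1, sep="\t", index=False)
    _, sd_summary = cstats.replicate_sd(phylum)
    f2 = out / "replicate_sd_phylum.tsv"
    sd_summary.to_csv(f2, sep="\t", index=False)
    # incidence overlap between replicate libraries at genus level
    sets = {lib: set(genus.counts.index[genus.counts[lib] > 0]) for lib in libs}
    pairs = [{"a": a, "b": b, "sorensen": cstats.sorensen(sets[a], sets[b])}
             for i, a in enumerate(libs) for b in libs[i + 1:]]
    f3 = out / "sorensen_pairs.tsv"
    pd.DataFrame(pairs).to_csv(f3, sep="\t", index=False)
    return [f1, f2, f3]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "assemble": _stage_assemble,
    "classify": _stage_classify,
    "digest": _stage_digest,
    "stats": _stage_stats,
}


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the selected stages in order; returns the run manifest.

    The manifest records, per stage, every output file with a sha256
    content checksum plus the full parameter echo; it is also written to
    ``<outdir>/manifest.tsv`` and ``<outdir>/config.yaml``.
    """
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"params": config.to_dict(), "stages": {}}
    for stage in stages:
        files = _STAGE_FN[stage](config, out)
        manifest["stages"][stage] = {
            str(f.relative_to(out)): _checksum(f) for f in files}
    rows = [{"stage": s, "file": f, "sha256": c}
            for s, fs in manifest["stages"].items() for f, c in fs.items()]
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    config.to_yaml(out / "config.yaml")
    return manifest


# ---------------------------------------------------------------------------
# demo fixtures

SCENARIOS = ("replicates", "spiking", "pseudo_trf", "two_step")


def make_fixtures(scenario: str, seed: int, outdir, depth: int = 8000) -> dict:
    """Write an on-disk demo dataset for one of the study's experiments.

    ``replicates``: 3 biological-style + 3 technical-style libraries from
    one aquifer-like pool.  ``spiking``: 4 amendment levels x 2 replicate
    series.  ``pseudo_trf``: a pool whose Spirochaeta-like member carries
    MspI sites at 208/285 bp.  ``two_step``: paired libraries differing
    only in the short-read ratio knob (5x).  Byte-identical for a fixed
    seed.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    info: dict = {"scenario": scenario, "seed": seed, "depth": depth,
                  "libraries": {}}
    if scenario == "replicates":
        pool = build_mock_community(24, seed=stage_seed(seed, "pool"))
        write_truth_table(pool, out / "truth.tsv")
        write_reference_fasta(pool.taxa, out / "reference.fasta")
        mapping, groups = {}, {}
        for i in range(3):  # technical: same template pool, new sequencing run
            lib = f"tech_{chr(97 + i)}"
            mapping[lib] = ROCHE_MIDS[i]
            groups[lib] = "technical"
            reads = simulate_reads(pool, depth, mapping[lib],
                                   seed=stage_seed(seed, "tech", i),
                                   library_id=lib)
            write_fastq(reads, out / f"{lib}.fastq")
            info["libraries"][lib] = len(reads)
        for i in range(3):  # biological: jittered template fractions
            lib = f"bio_{chr(97 + i)}"
            mapping[lib] = ROCHE_MIDS[3 + i]
            groups[lib] = "biological"
            rng = np.random.default_rng(stage_seed(seed, "biofrac", i))
            frac = pool.fractions * np.exp(rng.normal(0.0, 0.25, len(pool.taxa)))
            bio = MockCommunity(list(pool.taxa), frac / frac.sum())
            reads = simulate_reads(bio, depth, mapping[lib],
                                   seed=stage_seed(seed, "bio", i),
                                   library_id=lib)
            write_fastq(reads, out / f"{lib}.fastq")
            info["libraries"][lib] = len(reads)
        write_mapping(mapping, out / "mapping.tsv", groups)
        info["expected"] = {"max_phylum_sd_technical_pct": 2.0,
                            "max_phylum_sd_biological_pct": 5.0}
    elif scenario == "spiking":
        base = build_mock_community(20, seed=stage_seed(seed, "pool"))
        design = SpikeDesign(make_spike_taxon(stage_seed(seed, "spiketaxon")))
        write_reference_fasta(base.taxa + [design.spike_taxon],
                              out / "reference.fasta")
        mapping, groups = {}, {}
        k = 0
        for rep in range(len(design.replicate_seeds)):
            for level in design.amendment_fractions:
                lib = f"spike{int(level * 1000):03d}_r{rep + 1}"
                mapping[lib] = ROCHE_MIDS[k % len(ROCHE_MIDS)]
                groups[lib] = f"level_{level}"
                pool = spike_pool(base, design, level)
                reads = simulate_reads(
                    pool, depth, mapping[lib],
                    seed=stage_seed(seed, "spike", rep, level), library_id=lib)
                write_fastq(reads, out / f"{lib}.fastq")
                write_truth_table(pool, out / f"truth_{lib}.tsv")
                info["libraries"][lib] = len(reads)
                k += 1
        write_mapping(mapping, out / "mapping.tsv", groups)
        info["expected"] = {"slope": [0.9, 1.1], "r_squared_min": 0.99,
                            "levels": list(design.amendment_fractions)}
    elif scenario == "pseudo_trf":
        pool = _pseudo_trf_pool(seed)
        write_truth_table(pool, out / "truth.tsv")
        write_reference_fasta(pool.taxa, out / "reference.fasta")
        mapping = {"pseudo": ROCHE_MIDS[0]}
        reads = simulate_reads(pool, depth, mapping["pseudo"],
                               seed=stage_seed(seed, "pseudo"),
                               library_id="pseudo")
        write_fastq(reads, out / "pseudo.fastq")
        write_mapping(mapping, out / "mapping.tsv")
        info["libraries"]["pseudo"] = len(reads)
        info["expected"] = {"primary_bp": 208, "secondary_bp": 285,
                            "partial_digest_fraction": 0.3}
    else:  # two_step
        pool = build_mock_community(20, seed=stage_seed(seed, "pool"))
        write_truth_table(pool, out / "truth.tsv")
        write_reference_fasta(pool.taxa, out / "reference.fasta")
        mapping = {"one_step": ROCHE_MIDS[0], "two_step": ROCHE_MIDS[1]}
        for lib, p_short in (("one_step", 0.01), ("two_step", 0.05)):
            reads = simulate_reads(pool, depth, mapping[lib],
                                   seed=stage_seed(seed, lib),
                                   library_id=lib, short_read_prob=p_short)
            write_fastq(reads, out / f"{lib}.fastq")
            info["libraries"][lib] = len(reads)
        write_mapping(mapping, out / "mapping.tsv")
        info["expected"] = {"short_read_ratio": 5.0}
    with open(out / "fixture.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
    return info


def _pseudo_trf_pool(seed: int) -> MockCommunity:
    """A small pool whose Spirochaeta member has MspI sites at 208/285 bp."""
    from .synth_community import AQUIFER_LINEAGES, _SITE, _scrub_site
    pool = build_mock_community(6, dominance=2.0, seed=stage_seed(seed, "pool"))
    spiro_lineage = AQUIFER_LINEAGES[2]  # Spirochaeta
    base = build_reference_taxon("Spirochaeta_px", spiro_lineage,
                                 seed=stage_seed(seed, "spiro"),
                                 length=520, with_site=False)
    seq = base.sequence
    seq = seq[:207] + _SITE + seq[211:284] + _SITE + seq[288:]
    spiro = ReferenceTaxon(base.taxon_id, base.lineage, seq)
    taxa = list(pool.taxa[:-1]) + [spiro]
    return MockCommunity(taxa, pool.fractions)
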