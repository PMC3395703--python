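# pyrotagger

Simulation and analysis toolkit for **bidirectional 16S rRNA pyrotag
sequencing cross-validated against T-RFLP fingerprinting**.

Barcoded amplicon pyrosequencing ("pyrotags") and terminal restriction
fragment length polymorphism (T-RFLP) profile the same PCR amplicon pool of
a microbial community through two very different read-outs: relative read
abundance of classified sequences vs. peak heights of fluorescently
labelled terminal restriction fragments (T-RFs). `pyrotagger` implements,
as tested and reproducible code, the complete workflow needed to ask
whether the two agree and how far amplicon sequencing can be trusted
quantitatively:

- a **synthetic-data generator** emulating an aquifer-like mock community
  (a few dominant lineages each below ~15% template share, long rare tail)
  read with 454-style homopolymer-biased noise, bidirectional
  Ba27f/Ba519r primers and Roche MID barcodes, including quantified
  spike-in template amendments (0.2 / 2 / 20%);
- **quality control**: MID demultiplexing, sliding-window mean-Phred
  trimming, the ≥250 bp length filter and IUPAC-aware primer check;
- **greedy contig assembly** of forward+reverse reads at ≥98% identity
  over ≥50 bp overlaps, with the 20-reads-and-both-orientations contig
  filter;
- **OTU clustering** (complete linkage at 97% identity) and an RDP-style
  **naive-Bayes k-mer classifier** (k=8, 100 bootstraps, 80% confidence);
- **in-silico T-RFLP**: MspI digestion of contigs measured from the
  labelled primer, pseudo-T-RF bookkeeping for partial digestion, a
  synthetic electropherogram emulator (±3 bp drift, 100 RFU threshold) and
  a size-tolerant fingerprint matcher;
- the **community statistics** that tie it together.

## Statistics

For a library with taxon/OTU/T-RF proportions $p_1,\dots,p_S$:

- Shannon diversity $H' = -\sum_i p_i \ln p_i$;
- Sørensen incidence similarity $C_s = 2|A\cap B| / (|A|+|B|)$ between two
  OTU sets;
- functional organisation $F_o$: the cumulative relative abundance of the
  most abundant 20% of OTUs on the Pareto-Lorenz curve ($F_o=0.2$ for a
  perfectly even community, $\to 1$ under strong dominance);
- across-replicate standard deviation of relative abundance, summarised in
  abundance bins (>10%, <10%, <2%, <0.3%);
- spike recovery: ordinary least squares of recovered vs. nominal spike
  fraction over all amendment levels, reported as slope, intercept, $R^2$.

## Worked example

```python
from pyrotagger import (build_mock_community, make_spike_taxon, SpikeDesign,
                        spike_pool, simulate_reads, run_qc, KmerClassifier,
                        tabulate, shannon, pareto_lorenz_fo)
from pyrotagger.synth_community import ROCHE_MIDS

base = build_mock_community(n_taxa=20, seed=42)
design = SpikeDesign(make_spike_taxon(42))
pool = spike_pool(base, design, fraction=0.02)   # 2% template amendment

mid = ROCHE_MIDS[0]
reads = simulate_reads(pool, depth=4000, mid=mid, seed=7, library_id="demo")
retained, tally, _ = run_qc(reads, {"demo": mid})
print(f"retained {len(retained['demo'])} of {len(reads)} reads "
      f"(rejected: {dict(tally['demo'])})")

clf = KmerClassifier(list(base.taxa) + [design.spike_taxon])
calls = clf.classify_reads(retained["demo"], seed=1)
table = tabulate({"demo": list(calls.values())}, rank="genus")
rel = table.relative()["demo"]
print(f"recovered spike fraction: {rel.get('Aliivibrio', 0.0):.2f}% (nominal 2.00%)")
h = shannon(table.counts["demo"][table.counts["demo"] > 0])
fo = pareto_lorenz_fo(rel[rel > 0])
print(f"Shannon H' = {h.shannon_h:.2f} over {h.richness} genera, Fo = {fo.fo:.2f}")
```

prints

```
retained 3837 of 4000 reads (rejected: {'primer': 128, 'length': 35})
recovered spike fraction: 2.06% (nominal 2.00%)
Shannon H' = 2.47 over 13 genera, Fo = 0.31
```

The 2% *Aliivibrio* template amendment comes back at 2.06% read abundance
after quality filtering and 80%-confidence classification; the remaining
numbers summarise the community structure of the retained reads.

## Command line

```bash
pyrotagger run --seed 5 --outdir run        # simulate → qc → assemble →
                                            # classify → digest → stats
pyrotagger fixtures spiking --seed 1 --outdir demo --depth 2000
pyrotagger digest-seq $(python -c "print('A'*207+'CCGG'+'A'*100)")
```

Every run writes a `manifest.tsv` with sha256 checksums of all outputs;
reruns with the same config and seed reproduce identical checksums.

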