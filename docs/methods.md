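# Methods

This note documents the models, conventions and numerical choices behind
`pyrotagger`, in the spirit of a methods section: what each component
assumes, which knobs matter, and what the synthetic data can and cannot
tell you about real sequencing runs.

## The synthetic community and read simulator

`synth_community` is first-class, tested code — it defines the study
conditions every downstream module is validated under.

**Reference amplicons.** Each taxon is a random ACGT sequence of 450–550 nt
laid out as: Ba27f forward-primer realisation (degenerate M resolved per
taxon), a 10-nt pad, a 60-nt genus signature, a variable core, a second
60-nt genus signature, a 30-nt pad and the reverse-complemented Ba519r
site. Every sequence is checked to contain exactly one IUPAC-compatible
match per primer. The two signature blocks are deterministic functions of
the genus name and are shared by all members of a genus; placing one near
each amplicon end guarantees that both forward reads (which cover a prefix)
and reverse reads (which cover a suffix) observe a full signature, so the
classifier has a learnable genus signal in either orientation. Signatures
are generated MspI-free; ~90% of taxa carry at least one internal CCGG
site (inserted when absent), the remainder are scrubbed free of sites so
uncut full-length T-RFs occur.

**Taxonomy.** Lineages come from a built-in table of twelve
hydrocarbon-aquifer genera (Desulfobulbus, Geobacter, Desulfosporosinus,
Rhodoferax, Spirochaeta, …) cycled over the taxa. The table is ordered so
that, once Dirichlet fractions are sorted descending, Proteobacteria
accumulates roughly a third of the template pool — the "dominant phylum
near 30%" structure typical of such sites. Template fractions are
symmetric-Dirichlet draws (concentration `dominance`, default 1.5–2;
`inf` gives a perfectly even pool), sorted descending and renormalised.

**Reads.** Each read draws a taxon multinomially, an orientation with
probability 0.5, and a post-primer template length from a Gaussian
(mean 400 nt, sd 60, truncated to [150, full amplicon]) — chosen so a small
tail of reads fails the 250-bp filter and QC has real work. With
probability `short_read_prob` (default 0.01) the read is instead a short
product of 150–249 nt; the two-step-PCR scenario multiplies this knob by 5,
which is the only aspect of two-step amplification that is modelled. Reads
are `MID + primer + template prefix`. Noise is 454-like: substitutions at
5×10⁻⁴ per base, indels at 10⁻³ per base multiplied by 4 inside
homopolymer runs ≥3 (insertions duplicate the base, deletions drop it).
Quality strings decay linearly from Phred 37 to 27 with Gaussian jitter
(sd 2); error placement is independent of the quality values — a
simplification, since real base-calling confidence correlates with error
probability. The MID itself is copied error-free; demultiplexing therefore
defaults to 0 allowed mismatches.

**What this does not emulate:** chimera formation, MID-specific
amplification bias, flow-space valley filtering, true 454 quality-score
statistics, and template-molecule bottlenecks in emulsion PCR (reads are
sampled directly from template fractions; per-library molecule counts are
not modelled). Passing tests therefore demonstrate correctness of the
analysis pipeline under multinomial sampling with realistic noise levels,
not robustness to PCR chemistry artefacts.

## Quality control

Trimming is 3'-only: the read is truncated at the end of the last
sliding window (size 10) whose mean Phred is ≥ 20. The exact trimming
algorithm of legacy pipelines is not documented anywhere; a windowed
mean-confidence rule is the standard reading of "quality trimming based on
base-calling confidence scores", and the window/threshold are exposed as
parameters. Trimming is idempotent by construction. The length filter is
inclusive ("shorter than 250 bp" are excluded, a 250-bp read is retained)
and is applied post-trim with the primer included in the length; whether
the historical pipelines counted the primer is unknowable, so it is noted
here as the package's convention. The primer check requires an exact
IUPAC-aware match at position 0 of the MID-stripped read by default.
Rejection tallies partition all discarded reads (primer checked before
length), so `retained + rejected == input` always holds.

## Contig assembly

Overlap scoring is a free-end-gap semi-global alignment (match +1,
mismatch −1, internal gap −1) written against a brute-force oracle;
identity = matches / aligned overlap columns, internal gaps counting as
mismatches. "Sequence similarity" thresholds from amplicon-assembly
practice are interpreted as this gapped identity against the *current
consensus* (not read-vs-read), which is how interactive assemblers behave.

Greedy order: reads processed longest-first (id-lexicographic ties); a
read joins the best contig (identity, then overlap length, then earliest
contig) whose consensus it overlaps by ≥50 bp at ≥98%; otherwise it seeds
a new contig. The consensus is recomputed by per-column majority after
every merge, with ties broken by higher summed quality, then
alphabetically. Reads are stacked at the ungapped offset implied by the
alignment start; internal indels are tolerated as column mismatches — at
the simulator's indel rates (≤0.4% effective) this costs well under 0.5%
consensus identity, as the tests verify.

After the read pass, contigs whose consensi themselves satisfy the same
overlap thresholds are merged (best-first, deterministic;
`AssemblyParams.merge_contigs=True` by default). This pass is necessary
for a clean statement of the "one template → one contig" behaviour: two
reads that each carry ~1% errors differ by ~2% — exactly at the 98%
boundary — so a single greedy pass occasionally leaves a second contig
seeded by an unlucky early comparison, and non-overlapping tile positions
can likewise split a template. Majority-vote consensi are far cleaner
than single reads, so the merge is safe: templates ≥5% divergent never
merge. Set `merge_contigs=False` for strict single-pass behaviour.

A k-mer prescreen (pairs must share ≥3 20-mers) skips the quadratic DP for
sequence pairs that cannot possibly reach 97–98% identity over ≥50 bp;
at 90% identity a pair still shares hundreds of 20-mers, so the screen is
conservative for every threshold the workflow uses.

## OTU clustering and classification

OTU distances are 1 − gapped identity over the mutual overlap (pairs
overlapping <30 columns are treated as non-comparable, distance 1, to stop
tiny spurious end-overlaps from collapsing unrelated reads). Clustering is
scipy hierarchical linkage — complete by default, the conservative choice
for "linkage clustering" when the historical default is ambiguous — cut at
distance 0.03.

The classifier is a naive Bayes over 8-mer presence with RDP-style
word priors: for word $w$, $P(w\mid g) = (m_g(w) + P_w)/(M_g + 1)$ with
$P_w = (n(w)+0.5)/(N+1)$, genera as classification units and uniform genus
priors. Confidence is bootstrap agreement: 100 resamples of ⌊L/8⌋ of the
read's reference-vocabulary words, each scored and arg-maxed (ties broken
by a vanishing random jitter, so uninformative reads split their votes
and fall to "unclassified"); a rank is reported if the winning genus's
ancestor at that rank agrees in ≥80% of resamples, and the lineage is
truncated at the deepest such rank. Reverse reads are reverse-complemented
before classification. Threshold 0 forces full-depth lineages and >1
forces "unclassified"; both degenerate probes are permitted deliberately.

## In-silico T-RFLP

T-RF lengths are counted from the labelled (Ba27f) primer's first base;
with MspI (C^CGG, `cut_offset=1`) a site starting at 0-based index $i$
yields a fragment of $i+1$ bp, so a site at index 207 gives the 208-bp
primary T-RF and a downstream site at 284 the 285-bp secondary. TRiFLe's
exact coordinate convention is not published; `cut_offset` is exposed for
calibration against a known standard. Fragments from sites after the first
are *pseudo-T-RFs* — products of incomplete digestion — carried through
prediction with zero abundance so the matcher can recognise them.

Fingerprint prediction weights each retained contig's primary T-RF by its
member-read count, merges equal lengths and normalises to 100%. The
electropherogram emulator shifts each fragment by a uniform integer within
±3 bp (capillary drift), scales to RFU, adds Gaussian noise, optionally
emits pseudo-T-RFs at `partial_digest_fraction` of their parent's signal,
and applies the 100-RFU detection threshold. Matching is greedy
nearest-Δ one-to-one pairing within ±3 bp (ties toward the smaller
fragment — optimal for non-crossing 1-D assignments); unmatched observed
peaks within tolerance of a predicted secondary site are flagged as
pseudo-T-RF candidates with their parent's length.

The in-vivo protocol this emulates used a longer amplicon (reverse primer
907r) than the pyrotag pool (Ba519r); restriction sites beyond the Ba519r
site are invisible to contigs. This caveat is documented rather than
modelled: digestion operates on whatever sequence is supplied.

## Statistics

Shannon H′ uses natural log by default (`base` exposed) on renormalised
proportions with zeros dropped. Sørensen similarity is incidence-based.
Fo is read off the Lorenz polyline at the 20%-of-OTUs point with linear
interpolation at non-integer ranks; only T-RFs ≥100 RFU (in vivo) or
contigs ≥20 reads (in silico) enter. Replicate SDs are sample SDs (ddof 1)
of relative abundance in percentage points, computed for taxa averaging
≥1 read, binned right-open at 0.3 / 2 / 10%. Spike recovery is OLS of
recovered on nominal proportion over all libraries including the 0% level;
a response with zero variance is defined to have R² = 0.

## Pipeline

Six stages (simulate, qc, assemble, classify, digest, stats); OTU
clustering runs inside the classify stage and electropherogram emulation +
matching inside digest. A single global seed derives per-stage/per-library
sub-seeds by stable SHA-256 hashing of the stage and library names, so
streams are independent but fully reproducible; every output file is
checksummed into the manifest, and identical configs reproduce identical
checksums. Since per-library OTU labels are not comparable across
libraries without a joint clustering, the stats stage computes Sørensen
overlap on genus-level incidence.

## Problem sizes

The bundled demo configuration runs 3 libraries × 300 reads over 8 taxa,
and the validation suite exercises the spiking scenario at 8 × 8,000 reads
and the replicate scenario at 3 × 10,000 reads — the library sizes the
workflow is designed around. The quadratic OTU clustering is the one
component that does not scale past a few hundred reads per library in this
implementation; the demo depth reflects that, and deeper libraries should
subsample before clustering.

## Known limitations

- Error placement ignores quality values; trimming therefore removes the
  low-quality 3′ tail but not the errors themselves.
- Assembly stacks reads ungapped relative to the consensus; at indel rates
  far above the 454-like defaults, consensus columns would smear.
- The classifier's training set is the simulation's own reference pool;
  nothing is claimed about transfer to a full 16S database.
- Pseudo-T-RF flagging requires the secondary site to be carried in the
  predicted fingerprint; a partial digest of a taxon absent from the
  retained contigs cannot be attributed.
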