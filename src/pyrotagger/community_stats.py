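"""Diversity, similarity, evenness, reproducibility and spike-recovery
statistics for pyrotag libraries and T-RFLP fingerprints.

Implements the statistics used to compare amplicon-sequencing community
profiles with fingerprinting: Shannon H' (natural log by default),
incidence-based Sørensen similarity, the Pareto-Lorenz functional
organisation Fo (cumulative share of the most abundant 20% of OTUs),
across-replicate standard deviations binned by mean abundance, and the
linear-recovery fit for quantified template spike-ins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .otu_taxonomy import AbundanceTable


@dataclass
class DiversityResult:
    sample_id: str
    shannon_h: float
    richness: int


@dataclass
class FunctionalOrganisation:
    sample_id: str
    fo: float


@dataclass
class ReplicateSummary:
    taxon: str
    mean_abundance: float  # percent
    sd_abundance: float    # percentage points
    abundance_bin: str


@dataclass
class SpikeRecoveryFit:
    slope: float
    intercept: float
    r_squared: float
    per_level: pd.DataFrame  # nominal_pct, mean_recovered_pct, sd_recovered_pct


def shannon(abundances, sample_id: str = "", base: float | None = None) -> DiversityResult:
    """Shannon diversity H' = -sum p_i log p_i over renormalised proportions.

    Zeros are dropped; ``base=None`` means natural log (nats).
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("at least one positive abundance required")
    h = float(stats.entropy(p / p.sum(), base=base))
    return DiversityResult(sample_id, h, int(p.size))


def sorensen(set_a, set_b) -> float:
    """Incidence-based Sørensen similarity 2|A∩B| / (|A| + |B|)."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 0.0  # convention for two empty communities
    return 2.0 * len(a & b) / (len(a) + len(b))


def pareto_lorenz_fo(abundances, sample_id: str = "",
                     top_fraction: float = 0.2) -> FunctionalOrganisation:
    """Functional organisation from the Pareto-Lorenz curve.

    OTUs are ranked by decreasing abundance; Fo is the cumulative relative
    abundance at the ``top_fraction`` point of the OTU axis, linearly
    interpolated on the Lorenz polyline when 0.2·n falls between ranks.
    0.2 marks a perfectly even community, values near 1 a strongly
    organised (uneven) one.
    """
    p = np.sort(np.asarray(abundances, dtype=float))[::-1]
    p = p[p > 0]
    if p.size < 2:
        raise ValueError("Fo needs at least 2 OTUs with positive abundance")
    n = p.size
    x = np.arange(n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(p) / p.sum()])
    return FunctionalOrganisation(sample_id, float(np.interp(top_fraction, x, y)))


DEFAULT_SD_BINS = (0.3, 2.0, 10.0)


def _bin_label(mean_pct: float, edges) -> str:
    for e in edges:
        if mean_pct < e:
            return f"<{e:g}%"
    return f">{edges[-1]:g}%"


def replicate_sd(table: AbundanceTable, bins=DEFAULT_SD_BINS,
                 min_mean_reads: float = 1.0):
    """Across-replicate SD of relative abundance, binned by mean abundance.

    Columns of ``table`` are replicate libraries.  Taxa averaging fewer
    than ``min_mean_reads`` reads over the replicates are excluded.
    Returns ``(per_taxon: list[ReplicateSummary], summary: DataFrame)``
    where the summary reports mean and maximum SD per abundance bin.
    """
    if table.counts.shape[1] < 2:
        raise ValueError("replicate SD needs at least 2 replicate libraries")
    keep = table.counts.mean(axis=1) >= min_mean_reads
    rel = table.relative().loc[keep]
    means = rel.mean(axis=1)
    sds = rel.std(axis=1, ddof=1)
    per_taxon = [
        ReplicateSummary(taxon=t, mean_abundance=float(means[t]),
                         sd_abundance=float(sds[t]),
                         abundance_bin=_bin_label(float(means[t]), bins))
        for t in rel.index
    ]
    df = pd.DataFrame({
        "bin": [r.abundance_bin for r in per_taxon],
        "sd": [r.sd_abundance for r in per_taxon],
    })
    summary = df.groupby("bin")["sd"].agg(["mean", "max", "count"]).reset_index()
    summary.columns = ["abundance_bin", "mean_sd", "max_sd", "n_taxa"]
    return per_taxon, summary


def spike_recovery(levels, spike_reads, total_reads) -> SpikeRecoveryFit:
    """Ordinary-least-squares fit of recovered vs nominal spike fraction.

    ``levels`` are nominal template fractions per library; ``spike_reads``
    and ``total_reads`` the spike-assigned and total retained read counts.
    The fit is on the proportion scale over all libraries, zero-amendment
    libraries included; per-level means and SDs are reported in percent.
    """
    levels = np.asarray(levels, dtype=float)
    spike_reads = np.asarray(spike_reads, dtype=float)
    total_reads = np.asarray(total_reads, dtype=float)
    if len({len(levels), len(spike_reads), len(total_reads)}) != 1:
        raise ValueError("inputs must have equal length")
    if np.unique(levels).size < 3:
        raise ValueError("need at least 3 distinct amendment levels")
    if (total_reads <= 0).any():
        raise ValueError("every library needs a positive total read count")
    recovered = spike_reads / total_reads
    if np.allclose(recovered, recovered[0]):
        # zero response variance: no association by definition
        from types import SimpleNamespace
        fit = SimpleNamespace(slope=0.0, intercept=float(recovered.mean()),
                              rvalue=0.0)
    else:
        fit = stats.linregress(levels, recovered)
    rows = []
    for lv in sorted(np.unique(levels), reverse=True):
        r = 100.0 * recovered[levels == lv]
        rows.append({
            "nominal_pct": 100.0 * lv,
            "mean_recovered_pct": float(r.mean()),
            "sd_recovered_pct": float(r.std(ddof=1)) if r.size > 1 else 0.0,
        })
    return SpikeRecoveryFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        per_level=pd.DataFrame(rows),
    )
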