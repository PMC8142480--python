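"""Per-sample read-depth quality control.

Genotyping success tracks sequencing depth at the target SNPs: samples whose
median per-SNP mapped-read count falls below about ten reads typically
genotype poorly.  This module summarizes per-SNP depth distributions per
sample and flags low-median samples.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .io import DepthTable
from .panel import PanelError

__all__ = ["DepthSummary", "depth_distribution", "flag_low_depth_samples", "DEFAULT_MIN_MEDIAN"]

#: Median mapped reads per SNP below which a sample is considered at risk of
#: poor genotyping success.
DEFAULT_MIN_MEDIAN = 10.0


class DepthSummary(NamedTuple):
    min: float
    q1: float
    median: float
    q3: float
    max: float
    mean: float


def depth_distribution(depth: DepthTable, sample_id: str) -> DepthSummary:
    """Five-number summary + mean of per-SNP mapped-read counts for a sample.

    Every panel locus contributes; loci absent from the depth file count as
    zero reads — the absence of reads is exactly the signal of interest.
    Quantiles use linear interpolation on the sorted values (numpy default,
    "type 7"), stated explicitly because quantile conventions differ.
    """
    if sample_id not in depth.sample_ids:
        raise PanelError(f"sample not in depth table: {sample_id!r}")
    counts = depth.sample_depths(sample_id)
    q1, med, q3 = np.percentile(counts, [25, 50, 75])
    return DepthSummary(
        float(counts.min()), float(q1), float(med), float(q3),
        float(counts.max()), float(counts.mean()),
    )


def flag_low_depth_samples(depth: DepthTable, min_median: float = DEFAULT_MIN_MEDIAN) -> set[str]:
    """Samples whose median per-SNP depth is below ``min_median``."""
    if min_median < 0:
        raise ValueError("min_median must be >= 0")
    return {
        s for s in depth.sample_ids if depth_distribution(depth, s).median < min_median
    }


def depth_boxplot(depth: DepthTable, path, min_median: float = DEFAULT_MIN_MEDIAN):
    """Render per-sample depth boxplots with the median threshold line (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    samples = depth.sample_ids
    data = [depth.sample_depths(s) for s in samples]
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(samples)), 4))
    ax.boxplot(data, tick_labels=samples, showfliers=False)
    ax.axhline(min_median, color="red", lw=1)
    ax.set_ylabel("mapped reads per SNP")
    ax.tick_params(axis="x", rotation=90, labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
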