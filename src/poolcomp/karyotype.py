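"""Aneuploidy and segmental-amplification calling from per-base depth.

Per-chromosome copy ratio = median chromosome depth / median genome
depth, rounded to the nearest 0.5 (ratio 1.0 is euploid, 1.5 a trisomy on
a diploid, 0.5 a monosomy). Samples with genome median depth of 6 or less
are ineligible. Segmental events are maximal runs of 1-kb bins whose
normalised depth deviates from the chromosome baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoverageProfile", "KaryotypeCall", "call_karyotype", "call_segments",
           "coverage_profile", "round_to_half"]

#: contigs excluded from the genome-median computation (organelle /
#: episome depth does not track nuclear ploidy)
DEFAULT_EXCLUDE = frozenset({"chrM", "chrMT", "MT", "2-micron", "plasmid"})


def round_to_half(x: float) -> float:
    """Round to the nearest multiple of 0.5, half-way values away from zero
    (1.25 -> 1.5)."""
    return math.floor(2.0 * x + 0.5) / 2.0 if x >= 0 else -round_to_half(-x)


@dataclass
class CoverageProfile:
    """Median depths and binned means for one sample."""

    chrom_median: dict[str, float]
    genome_median: float
    bin_means: pd.DataFrame = field(repr=False)  # chrom, start(0-based), end, mean_depth
    bin_size: int = 1000
    sample: str = ""


def coverage_profile(
    depth_table: pd.DataFrame,
    bin_size: int = 1000,
    sample: str = "",
    exclude: frozenset = DEFAULT_EXCLUDE,
) -> CoverageProfile:
    """Summarise a samtools-depth style table (chrom, pos 1-based, depth).

    Every position of each chromosome must be present in order (the
    ``-a`` dialect); gaps or disorder raise with the first offending
    position. The genome median excludes organelle/episome contigs. The
    last partial bin is averaged over its actual length.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    cols = list(depth_table.columns[:3])
    df = depth_table.rename(columns=dict(zip(cols, ["chrom", "pos", "depth"])))
    chrom_median: dict[str, float] = {}
    bins = []
    nuclear_depths = []
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        expected = np.arange(1, len(pos) + 1)
        if len(pos) == 0:
            raise ValueError(f"chromosome {chrom!r} has no positions")
        bad = np.nonzero(pos != expected)[0]
        if bad.size:
            raise ValueError(
                f"depth table not sorted/complete: {chrom}:{int(pos[bad[0]])} "
                f"where position {int(expected[bad[0]])} was expected")
        depth = grp["depth"].to_numpy(float)
        chrom_median[chrom] = float(np.median(depth))
        if chrom not in exclude:
            nuclear_depths.append(depth)
        idx = (pos - 1) // bin_size
        sums = np.bincount(idx, weights=depth)
        lens = np.bincount(idx)
        starts = np.arange(len(sums)) * bin_size
        bins.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + bin_size, len(pos)),
            "mean_depth": sums / lens,
        }))
    if not nuclear_depths:
        raise ValueError("no non-excluded chromosomes in depth table")
    return CoverageProfile(
        chrom_median=chrom_median,
        genome_median=float(np.median(np.concatenate(nuclear_depths))),
        bin_means=pd.concat(bins, ignore_index=True),
        bin_size=bin_size,
        sample=sample,
    )


@dataclass
class KaryotypeCall:
    eligible: bool
    ratios: dict[str, float]  # chrom -> copy ratio, multiples of 0.5
    genome_median: float
    segments: pd.DataFrame | None = None

    def aneuploid_chromosomes(self) -> dict[str, float]:
        return {c: r for c, r in self.ratios.items() if r != 1.0}


def call_karyotype(
    profile: CoverageProfile,
    min_median: float = 6.0,
    exclude: frozenset = DEFAULT_EXCLUDE,
) -> KaryotypeCall:
    """Per-chromosome copy ratios rounded to the nearest 0.5.

    Requires genome median strictly greater than ``min_median``;
    otherwise the sample is ineligible and no ratios are reported.
    """
    if profile.genome_median <= min_median:
        return KaryotypeCall(False, {}, profile.genome_median)
    ratios = {
        c: round_to_half(m / profile.genome_median)
        for c, m in profile.chrom_median.items()
        if c not in exclude
    }
    return KaryotypeCall(True, ratios, profile.genome_median)


def call_segments(
    profile: CoverageProfile,
    baseline_ratio: dict[str, float],
    min_bins: int = 20,
    delta: float = 0.4,
    exclude: frozenset = DEFAULT_EXCLUDE,
) -> pd.DataFrame:
    """Sub-chromosomal amplifications/deletions as bin runs.

    Reports maximal runs of >= ``min_bins`` consecutive bins whose
    normalised depth deviates from the chromosome's whole-chromosome
    baseline by >= ``delta``, as BED-style 0-based half-open intervals
    with the run's mean copy ratio.
    """
    rows = []
    for chrom, grp in profile.bin_means.groupby("chrom", sort=False):
        if chrom in exclude or chrom not in baseline_ratio:
            continue
        ratio = grp["mean_depth"].to_numpy(float) / profile.genome_median
        dev = np.abs(ratio - baseline_ratio[chrom]) >= delta
        i = 0
        while i < len(dev):
            if not dev[i]:
                i += 1
                continue
            j = i
            while j < len(dev) and dev[j]:
                j += 1
            if j - i >= min_bins:
                rows.append({
                    "chrom": chrom,
                    "start": int(grp["start"].iloc[i]),
                    "end": int(grp["end"].iloc[j - 1]),
                    "ratio": float(ratio[i:j].mean()),
                    "n_bins": j - i,
                })
            i = j
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio", "n_bins"])
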