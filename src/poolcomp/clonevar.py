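"""Evolved-clone variant filtering and classification.

Input is a multi-sample variant table (ancestor + evolved clones from the
same strain background) flattened to one row per site with
``<sample>.GT/.AD/.DP/.GQ`` columns, read from a VCF or a tab-delimited
export. Filtering removes multiallelic sites, sites uncertain in the
ancestor, low/high-depth sites (< 5 or more than double the sample
median), low genotype quality (< 99), and blacklisted regions
(mitochondria, telomeres, rDNA, and similar repeat-rich intervals).
Surviving sites are classified per focal clone from allele-depth
fractions: de novo heterozygous or homozygous mutations require every
other sample to sit outside (0.2, 0.8); loss of heterozygosity (LOH)
requires the ancestor and all other clones to sit strictly inside it
while the focal clone has gone homozygous.

Boundary conventions (the focal side of the het interval is closed,
[0.2, 0.8]; the LOH background interval is open) are recorded in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "allele_fraction",
    "classify_variants",
    "classify_variant",
    "compare_loh_direction",
    "filter_variants",
    "read_blacklist_bed",
    "read_variant_table",
    "read_vcf",
    "samples_in",
    "tally_parallel_genes",
]

HET_LO, HET_HI = 0.2, 0.8
_RULES = ("multiallelic", "ancestor_uncertain", "depth_low", "depth_high", "gq", "blacklist")


def samples_in(variants: pd.DataFrame) -> list[str]:
    return [c[:-3] for c in variants.columns if c.endswith(".GT")]


def allele_fraction(variants: pd.DataFrame, sample: str) -> np.ndarray:
    """Alt-allele fraction from the AD field (not the genotype call);
    NaN where the site has zero allele depth."""
    ad = variants[f"{sample}.AD"].astype(str).str.split(",", expand=True).astype(float)
    total = ad.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = ad.iloc[:, 1] / total
    return np.where(total > 0, af, np.nan)


def read_variant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"CHROM": str})


def read_vcf(path) -> pd.DataFrame:
    """Flatten a VCF into the per-sample column layout used here."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    for v in vcf:
        row = {"CHROM": v.CHROM, "POS": v.POS, "REF": v.REF, "ALT": ",".join(v.ALT)}
        ad = v.format("AD")
        dp = v.format("DP")
        for i, s in enumerate(samples):
            alleles = [a for a in v.genotypes[i][:-1]]
            row[f"{s}.GT"] = "/".join("." if a < 0 else str(a) for a in alleles)
            row[f"{s}.AD"] = ",".join(str(int(x)) for x in np.atleast_1d(ad[i])) if ad is not None else "0,0"
            row[f"{s}.DP"] = int(np.atleast_1d(dp[i])[0]) if dp is not None else 0
            row[f"{s}.GQ"] = float(v.gt_quals[i])
        rows.append(row)
    return pd.DataFrame(rows)


def read_blacklist_bed(path) -> list[tuple[str, int, int]]:
    """BED intervals (0-based half-open) as (chrom, start, end) tuples."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"],
                      dtype={"chrom": str})
    return list(bed.itertuples(index=False, name=None))


@dataclass
class FilterReport:
    removed: dict[str, int] = field(default_factory=lambda: dict.fromkeys(_RULES, 0))
    surviving: int = 0

    @property
    def total(self) -> int:
        return self.surviving + sum(self.removed.values())


def _in_blacklist(chrom, pos, blacklist) -> bool:
    # variant POS is 1-based; BED intervals are 0-based half-open
    p0 = pos - 1
    return any(c == chrom and s <= p0 < e for c, s, e in blacklist)


def filter_variants(
    variants: pd.DataFrame,
    ancestor: str,
    sample_median_depth: dict[str, float],
    blacklist: list[tuple[str, int, int]] | None = None,
    focal: str | None = None,
    min_depth: int = 5,
    min_gq: float = 99.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the removal rules in order with first-matching attribution.

    Depth rule: keep iff ``min_depth <= DP <= 2 * median`` (exactly double
    is kept — the rule removes strictly-more-than-double). GQ rule: keep
    iff ``GQ >= min_gq``. ``ancestor_uncertain`` applies the same two
    rules (plus a missing genotype check) to the ancestor sample. The
    depth and GQ rules are checked in the focal clone when ``focal`` is
    given, else in every non-ancestor sample.
    """
    for m in sample_median_depth.values():
        if m <= 0:
            raise ValueError("sample median depths must be > 0")
    blacklist = blacklist or []
    check = [focal] if focal else [s for s in samples_in(variants) if s != ancestor]
    report = FilterReport()
    keep_rows = []
    for i, row in variants.iterrows():
        if {"CHROM", "POS", "REF", "ALT"} - set(row.index) or pd.isna(row["POS"]):
            raise ValueError(f"malformed variant row at index {i}")
        rule = None
        if "," in str(row["ALT"]):
            rule = "multiallelic"
        elif ("." in str(row[f"{ancestor}.GT"])
              or row[f"{ancestor}.GQ"] < min_gq
              or row[f"{ancestor}.DP"] < min_depth
              or row[f"{ancestor}.DP"] > 2 * sample_median_depth[ancestor]):
            rule = "ancestor_uncertain"
        else:
            for s in check:
                if row[f"{s}.DP"] < min_depth:
                    rule = "depth_low"
                    break
                if row[f"{s}.DP"] > 2 * sample_median_depth[s]:
                    rule = "depth_high"
                    break
            if rule is None and any(row[f"{s}.GQ"] < min_gq for s in check):
                rule = "gq"
            if rule is None and _in_blacklist(row["CHROM"], int(row["POS"]), blacklist):
                rule = "blacklist"
        if rule is None:
            keep_rows.append(i)
        else:
            report.removed[rule] += 1
    surviving = variants.loc[keep_rows].copy()
    report.surviving = len(surviving)
    return surviving, report


def _category(a_focal: float, a_background: np.ndarray) -> str:
    if np.isnan(a_focal) or np.isnan(a_background).any():
        return "none"
    outside = ((a_background < HET_LO) | (a_background > HET_HI)).all()
    strictly_inside = ((a_background > HET_LO) & (a_background < HET_HI)).all()
    if HET_LO <= a_focal <= HET_HI and outside:
        return "de_novo_het"
    if ((a_focal > HET_HI and (a_background < HET_LO).all())
            or (a_focal < HET_LO and (a_background > HET_HI).all())):
        return "de_novo_hom"
    if (a_focal < HET_LO or a_focal > HET_HI) and strictly_inside:
        return "LOH"
    return "none"


def classify_variants(
    variants: pd.DataFrame,
    focal: str,
    ancestor: str,
    others: list[str] | None = None,
) -> pd.DataFrame:
    """Classify every surviving row for one focal clone.

    Returns the input plus ``clone``, ``category`` (de_novo_het |
    de_novo_hom | LOH | none), ``focal_af`` and ``ancestor_af``. The
    categories partition the rows: each row gets exactly one.
    """
    if focal == ancestor:
        raise ValueError("focal clone must differ from the ancestor")
    if others is None:
        others = [s for s in samples_in(variants) if s not in (focal, ancestor)]
    a_focal = allele_fraction(variants, focal)
    background = np.column_stack(
        [allele_fraction(variants, s) for s in [ancestor] + list(others)])
    cats = [_category(a_focal[i], background[i]) for i in range(len(variants))]
    out = variants.copy()
    out["clone"] = focal
    out["category"] = cats
    out["focal_af"] = a_focal
    out["ancestor_af"] = background[:, 0]
    out.attrs["boundary_convention"] = (
        f"de_novo_het focal interval closed [{HET_LO}, {HET_HI}]; "
        f"LOH background interval open ({HET_LO}, {HET_HI})")
    return out


def classify_variant(row: pd.Series, focal: str, ancestor: str,
                     others: list[str]) -> str:
    """Single-row category; see :func:`classify_variants`."""
    df = row.to_frame().T.reset_index(drop=True)
    return classify_variants(df, focal, ancestor, others)["category"].iloc[0]


def tally_parallel_genes(
    classified: pd.DataFrame,
    impact_filter: set[str] = frozenset({"frameshift", "nonsense"}),
) -> tuple[pd.DataFrame, dict]:
    """Gene-level parallelism among high-impact de novo variants.

    ``classified`` must carry ``gene``, ``impact``, ``clone`` and group
    columns ``ancestor_strain`` and ``environment``. Counts distinct
    clones (not variants) with >= 1 qualifying variant per gene per
    (strain, environment) group; genes hit in >= 2 groups are flagged
    cross-group, and genes hit in >= 2 ancestor backgrounds
    cross-background (the strongest form of parallelism).
    """
    df = classified[classified["category"] != "none"].copy()
    missing = df["gene"].isna() | df["impact"].isna()
    skipped = int(missing.sum())
    df = df[~missing]
    df = df[df["impact"].isin(impact_filter)]
    if df.empty:
        return pd.DataFrame(), {"skipped_missing_annotation": skipped,
                                "cross_group": set(), "cross_background": set()}
    counts = (df.groupby(["gene", "ancestor_strain", "environment"])["clone"]
              .nunique().unstack(["ancestor_strain", "environment"], fill_value=0))
    hit = counts > 0
    cross_group = set(counts.index[hit.sum(axis=1) >= 2])
    backgrounds = hit.T.groupby(level="ancestor_strain").any().T
    cross_background = set(counts.index[backgrounds.sum(axis=1) >= 2])
    return counts, {"skipped_missing_annotation": skipped,
                    "cross_group": cross_group,
                    "cross_background": cross_background}


def compare_loh_direction(
    classified: pd.DataFrame,
    locus: tuple[str, int],
    group_a: list[str],
    group_b: list[str],
) -> str:
    """Did coincident LOH events resolve to the same allele?

    For each clone with an LOH call at ``locus`` the resolved allele is
    the homozygous state reached (0 = reference, 1 = alternate). Returns
    ``convergent`` when every clone in both groups resolved identically,
    ``divergent`` when each group is internally consistent but the groups
    differ, ``mixed`` when a group disagrees internally, and
    ``insufficient`` when either group has no LOH call at the locus.
    """
    chrom, pos = locus
    loh = classified[(classified["category"] == "LOH")
                     & (classified["CHROM"] == chrom)
                     & (classified["POS"] == pos)]
    resolved = {}
    for _, row in loh.iterrows():
        resolved[row["clone"]] = 1 if row["focal_af"] > HET_HI else 0
    alleles_a = {resolved[c] for c in group_a if c in resolved}
    alleles_b = {resolved[c] for c in group_b if c in resolved}
    if not alleles_a or not alleles_b:
        return "insufficient"
    if len(alleles_a) > 1 or len(alleles_b) > 1:
        return "mixed"
    return "convergent" if alleles_a == alleles_b else "divergent"
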