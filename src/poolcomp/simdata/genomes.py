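"""Synthetic evolved-clone genomes.

Generates an ancestor plus evolved clones as a multi-sample variant table
(GT/AD/DP/GQ per sample) and per-base depth tables, with injected events:
de novo heterozygous / homozygous SNVs, loss-of-heterozygosity tracts
over ancestrally heterozygous sites, whole-chromosome aneuploidies, and
segmental amplifications. Expected depth scales with copies / base
ploidy; a truth log records every injected event for recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import spawn_rng

_BASES = "ACGT"


@dataclass(frozen=True)
class Event:
    clone: str
    kind: str  # het_snv | hom_snv | loh_tract | aneuploidy | segmental_amp
    chrom: str
    start: int  # 1-based, inclusive (snvs: position)
    end: int  # inclusive; snvs: == start
    allele: int | None = None  # LOH target allele (0=ref, 1=alt)
    copies: int | None = None  # aneuploidy / segmental_amp
    sites: tuple = ()  # positions actually affected (filled in)


@dataclass
class CloneGenomeSpec:
    """Design of the synthetic genomes.

    ``chrom_sizes`` in bp; ``n_het_sites`` ancestrally heterozygous sites
    spread uniformly over the genome; ``base_ploidy`` 2 (diploid) or 3
    (triploid, ancestral het allele fraction 1/3 or 2/3); ``mean_depth``
    expected coverage of a 1-copy-ratio base; ``depth_noise`` "none" for
    exact expectations or "poisson".
    """

    chrom_sizes: dict[str, int]
    n_het_sites: int = 200
    base_ploidy: int = 2
    mean_depth: float = 30.0
    depth_noise: str = "poisson"
    gq: int = 99
    events: list[Event] = field(default_factory=list)


def _check_bounds(spec: CloneGenomeSpec) -> None:
    for ev in spec.events:
        size = spec.chrom_sizes.get(ev.chrom)
        if size is None:
            raise ValueError(f"event on unknown chromosome {ev.chrom!r}")
        if not (1 <= ev.start <= ev.end <= size):
            raise ValueError(
                f"event {ev.kind} {ev.chrom}:{ev.start}-{ev.end} outside chromosome bounds"
            )


def _copy_ratio_track(spec: CloneGenomeSpec, clone_events: list[Event]) -> dict[str, np.ndarray]:
    """Per-base expected copy ratio (1.0 = euploid) for one clone."""
    track = {c: np.ones(n) for c, n in spec.chrom_sizes.items()}
    for ev in clone_events:
        if ev.kind == "aneuploidy":
            track[ev.chrom][:] = ev.copies / spec.base_ploidy
        elif ev.kind == "segmental_amp":
            track[ev.chrom][ev.start - 1 : ev.end] = ev.copies / spec.base_ploidy
    return track


def _sample_fields(gt: str, af: float, depth_mean: float, noisy: bool,
                   gq: int, rng) -> tuple[str, str, int, int]:
    if noisy:
        dp = int(rng.poisson(depth_mean))
        alt = int(rng.binomial(dp, af)) if dp > 0 else 0
    else:
        dp = int(round(depth_mean))
        alt = int(round(dp * af))
    return gt, f"{dp - alt},{alt}", dp, gq


def make_clone_genomes(
    spec: CloneGenomeSpec,
    n_clones: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], list[Event]]:
    """Build ancestor + ``n_clones`` genomes.

    Returns ``(variants, depth_tables, truth_log)``: a multi-sample
    variant table with columns CHROM, POS, REF, ALT and
    ``<sample>.GT/.AD/.DP/.GQ`` for the ancestor and each clone; per-clone
    per-base depth tables (chrom, pos, depth, 1-based); and the truth log
    with realised site lists. Events in ``spec.events`` with clone ids not
    among ``clone1..cloneN`` are ignored. LOH tracts spanning no ancestral
    het site raise a warning and are skipped.
    """
    _check_bounds(spec)
    rng = spawn_rng(seed, "genomes")
    noisy = spec.depth_noise == "poisson"
    clones = [f"clone{i + 1}" for i in range(n_clones)]
    ploidy = spec.base_ploidy

    # ancestral heterozygous sites, uniform over the genome
    chroms = list(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], float)
    site_chrom_idx = rng.choice(len(chroms), size=spec.n_het_sites, p=sizes / sizes.sum())
    sites: set[tuple[str, int]] = set()
    for ci in site_chrom_idx:
        c = chroms[ci]
        while True:
            pos = int(rng.integers(1, spec.chrom_sizes[c] + 1))
            if (c, pos) not in sites:
                sites.add((c, pos))
                break
    het_sites = sorted(sites)
    # triploid ancestors carry the alt on 1 of 3 (or 2 of 3) copies
    if ploidy == 2:
        anc_af = {s: 0.5 for s in het_sites}
        anc_gt = {s: "0/1" for s in het_sites}
    else:
        anc_af, anc_gt = {}, {}
        for s in het_sites:
            k = int(rng.integers(1, ploidy))
            anc_af[s] = k / ploidy
            anc_gt[s] = "/".join(["1"] * k + ["0"] * (ploidy - k))

    by_clone = {c: [ev for ev in spec.events if ev.clone == c] for c in clones}
    truth: list[Event] = []

    # genotype state per site per sample: (gt_string, alt allele fraction)
    state: dict[tuple[str, int], dict[str, tuple[str, float]]] = {
        s: {"ancestor": (anc_gt[s], anc_af[s])} for s in het_sites
    }
    for s in het_sites:
        for c in clones:
            state[s][c] = state[s]["ancestor"]

    for clone in clones:
        for ev in by_clone[clone]:
            if ev.kind == "loh_tract":
                hit = [s for s in het_sites
                       if s[0] == ev.chrom and ev.start <= s[1] <= ev.end]
                if not hit:
                    warnings.warn(
                        f"LOH tract {ev.chrom}:{ev.start}-{ev.end} in {clone} spans no "
                        "ancestral het site; event skipped")
                    continue
                hom = ("1/1", 1.0) if ev.allele == 1 else ("0/0", 0.0)
                if ploidy == 3:
                    hom = ("1/1/1", 1.0) if ev.allele == 1 else ("0/0/0", 0.0)
                for s in hit:
                    state[s][clone] = hom
                truth.append(Event(clone, ev.kind, ev.chrom, ev.start, ev.end,
                                   allele=ev.allele, sites=tuple(p for _, p in hit)))
            elif ev.kind in ("het_snv", "hom_snv"):
                s = (ev.chrom, ev.start)
                if s not in state:
                    state[s] = {"ancestor": ("0/0" if ploidy == 2 else "0/0/0", 0.0)}
                    for c in clones:
                        state[s][c] = state[s]["ancestor"]
                if ev.kind == "het_snv":
                    state[s][clone] = ("0/1" if ploidy == 2 else "0/0/1",
                                       0.5 if ploidy == 2 else 1 / 3)
                else:
                    state[s][clone] = ("1/1" if ploidy == 2 else "1/1/1", 1.0)
                truth.append(Event(clone, ev.kind, ev.chrom, ev.start, ev.end,
                                   sites=(ev.start,)))
            elif ev.kind in ("aneuploidy", "segmental_amp"):
                truth.append(Event(clone, ev.kind, ev.chrom, ev.start, ev.end,
                                   copies=ev.copies))
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")

    ratio_tracks = {c: _copy_ratio_track(spec, by_clone[c]) for c in clones}

    rows = []
    for (chrom, pos) in sorted(state):
        ref = _BASES[rng.integers(4)]
        alt = _BASES[(_BASES.index(ref) + 1 + rng.integers(3)) % 4]
        row: dict = {"CHROM": chrom, "POS": pos, "REF": ref, "ALT": alt}
        for sample in ["ancestor"] + clones:
            gt, af = state[(chrom, pos)][sample]
            ratio = 1.0 if sample == "ancestor" else ratio_tracks[sample][chrom][pos - 1]
            g, ad, dp, gq = _sample_fields(gt, af, spec.mean_depth * ratio, noisy,
                                           spec.gq, rng)
            row[f"{sample}.GT"] = g
            row[f"{sample}.AD"] = ad
            row[f"{sample}.DP"] = dp
            row[f"{sample}.GQ"] = gq
        rows.append(row)
    variants = pd.DataFrame(rows)

    depth_tables: dict[str, pd.DataFrame] = {}
    for clone in clones:
        parts = []
        for chrom in chroms:
            mean = spec.mean_depth * ratio_tracks[clone][chrom]
            depth = rng.poisson(mean) if noisy else np.round(mean).astype(int)
            parts.append(pd.DataFrame({
                "chrom": chrom,
                "pos": np.arange(1, spec.chrom_sizes[chrom] + 1),
                "depth": depth,
            }))
        depth_tables[clone] = pd.concat(parts, ignore_index=True)

    return variants, depth_tables, truth
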