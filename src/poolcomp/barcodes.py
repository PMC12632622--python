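"""Barcode extraction, demultiplexing, and counting from merged amplicon reads.

A read is matched against a fixed-layout template (constant regions with a
per-segment mismatch tolerance, two sample-index slots, one barcode slot),
the index pair demultiplexes it into a (replicate, timepoint) sample, and
the barcode is assigned to a strain by unique nearest Levenshtein match
against the catalog. Ties are never guessed: an observed barcode
equidistant from two catalog entries is left unassigned, since a wrong
assignment is worse than a lost read. Degenerate bases (N) count as
mismatches.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

REJECT_REASONS = ("constant_mismatch", "length", "ambiguous_anchor", "unknown_sample", "no_barcode_match")


@dataclass(frozen=True)
class Segment:
    kind: str  # "const" | "index_f" | "index_r" | "barcode"
    seq: str | None = None  # constants only
    length: int = 0
    tolerance: int = 0  # constants only

    def __post_init__(self):
        if self.kind == "const":
            if not self.seq:
                raise ValueError("constant regions must be non-empty")
            object.__setattr__(self, "length", len(self.seq))
        elif self.kind in ("index_f", "index_r", "barcode"):
            if self.length < 1:
                raise ValueError(f"{self.kind} slot needs a positive length")
        else:
            raise ValueError(f"unknown segment kind {self.kind!r}")


class ReadTemplate:
    """Fixed-layout merged-read template.

    ``segments`` is an ordered list of :class:`Segment`. Exactly one
    barcode slot is required; index slots are optional (0, 1 or 2 — a pair
    is the usual dual-index design).
    """

    def __init__(self, segments: list[Segment]):
        kinds = [s.kind for s in segments]
        if kinds.count("barcode") != 1:
            raise ValueError("template must contain exactly one barcode slot")
        self.segments = list(segments)
        self.length = sum(s.length for s in segments)
        offsets = np.cumsum([0] + [s.length for s in segments])
        self._offsets = {i: int(offsets[i]) for i in range(len(segments))}

    @property
    def barcode_length(self) -> int:
        return next(s.length for s in self.segments if s.kind == "barcode")

    def render(self, index_pair: tuple[str, str] | None, barcode: str) -> str:
        """Fill the template slots to produce an error-free read."""
        out = []
        pair = list(index_pair) if index_pair else []
        for seg in self.segments:
            if seg.kind == "const":
                out.append(seg.seq)
            elif seg.kind == "index_f":
                out.append(pair[0])
            elif seg.kind == "index_r":
                out.append(pair[1])
            else:
                out.append(barcode)
        return "".join(out)

    def parse(self, read: str):
        """Extract ((index_f, index_r), barcode) or a rejection reason.

        Constant regions are compared positionally (Hamming) with each
        segment's own mismatch tolerance; slots are cut out by position.
        Returns ``(("idxF","idxR"), "BARCODE")`` on success, else a string
        from :data:`REJECT_REASONS`.
        """
        if not read:
            raise ValueError("read must be non-empty")
        if len(read) < self.length:
            return "length"
        idx_f = idx_r = None
        barcode = None
        for i, seg in enumerate(self.segments):
            start = self._offsets[i]
            chunk = read[start : start + seg.length]
            if seg.kind == "const":
                mm = sum(a != b for a, b in zip(chunk, seg.seq))
                if mm > seg.tolerance:
                    return "constant_mismatch"
            elif seg.kind == "index_f":
                idx_f = chunk
            elif seg.kind == "index_r":
                idx_r = chunk
            else:
                barcode = chunk
        return (idx_f, idx_r), barcode


@dataclass
class BarcodeCatalog:
    """Map from known barcode sequence to strain id."""

    barcode_to_strain: dict[str, str]

    def __post_init__(self):
        lengths = {len(b) for b in self.barcode_to_strain}
        if len(lengths) > 1:
            raise ValueError("catalog barcodes must all be the same length")
        strains = list(self.barcode_to_strain.values())
        if len(set(strains)) != len(strains):
            raise ValueError("catalog strain ids must be unique")
        self.length = lengths.pop() if lengths else 0

    @classmethod
    def from_pool(cls, pool) -> "BarcodeCatalog":
        return cls({bc: sid for sid, bc in pool.barcode_map.items()})

    @classmethod
    def from_tsv(cls, path) -> "BarcodeCatalog":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["barcode"], df["strain_id"])))

    def min_pairwise_distance(self) -> int:
        """Smallest Levenshtein distance between any two catalog barcodes."""
        best = self.length
        for a, b in itertools.combinations(self.barcode_to_strain, 2):
            d = edlib.align(a, b, task="distance")["editDistance"]
            best = min(best, d)
            if best == 0:
                break
        return best


def assign_barcode(observed: str, catalog: BarcodeCatalog, max_dist: int = 1) -> str | None:
    """Unique nearest-catalog-entry assignment within ``max_dist`` edits.

    Returns the strain id, or None when no entry is close enough, the
    observed length differs from the catalog length, or two entries tie at
    the minimum distance.
    """
    if len(observed) != catalog.length:
        return None
    hit = catalog.barcode_to_strain.get(observed)
    if hit is not None:
        return hit
    if max_dist == 0:
        return None
    best_d, best_id, tied = max_dist + 1, None, False
    for bc, sid in catalog.barcode_to_strain.items():
        d = edlib.align(observed, bc, task="distance", k=max_dist)["editDistance"]
        if d < 0:  # beyond k
            continue
        if d < best_d:
            best_d, best_id, tied = d, sid, False
        elif d == best_d:
            tied = True
    return None if tied or best_id is None else best_id


@dataclass
class BarcodeCountTable:
    """Per-strain read counts with per-sample accounting.

    ``counts`` is strain x sample; a sample is a (replicate, timepoint)
    pair. ``assigned + unassigned == total`` per sample, always.
    """

    counts: pd.DataFrame = field(repr=False)
    unassigned: pd.Series = field(repr=False)
    totals: pd.Series = field(repr=False)
    reject_reasons: pd.DataFrame = field(repr=False)

    @property
    def assigned(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def qc_summary(self) -> pd.DataFrame:
        out = pd.DataFrame({"total": self.totals, "assigned": self.assigned,
                            "unassigned": self.unassigned})
        return out.join(self.reject_reasons)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def _iter_reads(reads):
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for i, rec in enumerate(SeqIO.parse(fh, "fastq")):
                yield rec.id, str(rec.seq)
        return
    for item in reads:
        yield item


def count_barcodes(
    reads,
    template: ReadTemplate,
    catalog: BarcodeCatalog,
    sample_map: dict[tuple[str, str], tuple],
    max_dist: int = 1,
) -> BarcodeCountTable:
    """One-pass demultiplex + assign + count.

    ``reads`` is a FASTQ path (optionally .gz) or an iterable of
    ``(read_id, sequence)``. ``sample_map`` maps (index_f, index_r) to a
    sample label. Reads whose index pair is absent from ``sample_map`` are
    rejected with reason ``unknown_sample``; template or assignment
    failures are tallied per sample (or globally when the sample is
    unknowable).
    """
    samples = list(dict.fromkeys(sample_map.values()))
    strains = sorted(set(catalog.barcode_to_strain.values()))
    counts = {s: dict.fromkeys(strains, 0) for s in samples}
    totals = dict.fromkeys(samples, 0)
    unassigned = dict.fromkeys(samples, 0)
    reasons = {s: dict.fromkeys(REJECT_REASONS, 0) for s in samples + ["<no_sample>"]}
    totals["<no_sample>"] = 0
    unassigned["<no_sample>"] = 0

    for i, (rid, seq) in enumerate(_iter_reads(reads)):
        if not seq:
            raise ValueError(f"unreadable FASTQ record at position {i} ({rid})")
        parsed = template.parse(seq)
        if isinstance(parsed, str):  # rejection before the sample is known
            totals["<no_sample>"] += 1
            unassigned["<no_sample>"] += 1
            reasons["<no_sample>"][parsed] += 1
            continue
        idx_pair, barcode = parsed
        sample = sample_map.get(idx_pair)
        if sample is None:
            totals["<no_sample>"] += 1
            unassigned["<no_sample>"] += 1
            reasons["<no_sample>"]["unknown_sample"] += 1
            continue
        totals[sample] += 1
        strain = assign_barcode(barcode, catalog, max_dist=max_dist)
        if strain is None:
            unassigned[sample] += 1
            reasons[sample]["no_barcode_match"] += 1
        else:
            counts[sample][strain] += 1

    all_samples = samples + ["<no_sample>"]
    count_df = pd.DataFrame({s: counts.get(s, dict.fromkeys(strains, 0)) for s in all_samples})
    count_df.index.name = "strain_id"
    return BarcodeCountTable(
        counts=count_df,
        unassigned=pd.Series({s: unassigned[s] for s in all_samples}),
        totals=pd.Series({s: totals[s] for s in all_samples}),
        reject_reasons=pd.DataFrame(reasons).T.loc[all_samples],
    )
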