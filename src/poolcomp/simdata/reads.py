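"""Sequencing-read simulation: overdispersed counts and amplicon FASTQ.

Read counts are modelled as negative binomial with mean f*R and variance
kappa*f*R via the Gamma-Poisson construction; kappa = 1 degenerates to
Poisson. The amplicon generator then turns a count table into merged
reads (constant regions + sample index pair + barcode) with optional
uniform substitution error, providing a full round-trip fixture for the
barcode-counting stage.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .._rng import spawn_rng
from ..barcodes import ReadTemplate
from .competition import TrueTrajectory

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass
class SimulatedCounts:
    """Barcode x timepoint read counts plus the sampling parameters used."""

    counts: pd.DataFrame = field(repr=False)  # strain x timepoint, ints
    depth: np.ndarray  # R_t requested per timepoint
    dispersion: np.ndarray  # kappa_t per timepoint

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")


def _negbin_draws(mean: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """NB(mean, var = kappa*mean) via Gamma-Poisson; kappa=1 is Poisson."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if kappa == 1.0:
        out[pos] = rng.poisson(mean[pos])
    else:
        shape = mean[pos] / (kappa - 1.0)
        lam = rng.gamma(shape, kappa - 1.0)
        out[pos] = rng.poisson(lam)
    return out


def sample_reads(
    traj: TrueTrajectory | pd.DataFrame,
    depth,
    dispersion=1.0,
    conditional: bool = False,
    seed: int = 0,
) -> SimulatedCounts:
    """Draw read counts for every barcode at every timepoint.

    ``depth`` and ``dispersion`` are scalars or per-timepoint arrays. With
    ``conditional=True`` the per-timepoint total is fixed exactly at R_t
    (multinomial over Gamma-perturbed weights); the default draws counts
    independently, so column totals fluctuate around R_t.
    """
    freq = traj.barcode_frequencies() if isinstance(traj, TrueTrajectory) else traj
    n_t = freq.shape[1]
    depth = np.broadcast_to(np.asarray(depth, float), (n_t,)).copy()
    kappa = np.broadcast_to(np.asarray(dispersion, float), (n_t,)).copy()
    if (depth < 0).any():
        raise ValueError("depth must be non-negative")
    if (kappa < 1).any():
        raise ValueError("dispersion must be >= 1")
    rng = spawn_rng(seed, "reads")
    f = freq.to_numpy(float)
    counts = np.zeros(f.shape, dtype=np.int64)
    for t in range(n_t):
        mean = f[:, t] * depth[t]
        if conditional:
            if kappa[t] == 1.0:
                w = f[:, t]
            else:
                w = np.zeros_like(mean)
                pos = mean > 0
                w[pos] = rng.gamma(mean[pos] / (kappa[t] - 1.0), kappa[t] - 1.0)
                if w.sum() == 0:
                    w = f[:, t]
            counts[:, t] = rng.multinomial(int(depth[t]), w / w.sum())
        else:
            counts[:, t] = _negbin_draws(mean, float(kappa[t]), rng)
    return SimulatedCounts(
        counts=pd.DataFrame(counts, index=freq.index, columns=freq.columns),
        depth=depth,
        dispersion=kappa,
    )


def _mutate(seq: str, per_base_error: float, rng: np.random.Generator) -> str:
    hits = np.nonzero(rng.random(len(seq)) < per_base_error)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        chars[i] = _OTHER.get(chars[i], _BASES)[rng.integers(3)]
    return "".join(chars)


def simulate_amplicon_reads(
    counts: SimulatedCounts | pd.DataFrame,
    template: ReadTemplate,
    barcode_map: dict[str, str],
    sample_indices: dict[object, tuple[str, str]],
    per_base_error: float = 0.0,
    seed: int = 0,
    path: str | Path | None = None,
):
    """Emit one merged read per count unit.

    ``sample_indices`` maps each count-table column (a sample: timepoint
    or (replicate, timepoint) label) to its (forward, reverse) index pair.
    Returns a list of ``(read_id, sequence)`` pairs, or writes a Phred+33
    FASTQ when ``path`` is given (constant quality 'I'; gzip if the name
    ends in .gz).
    """
    if not 0 <= per_base_error <= 0.1:
        raise ValueError("per_base_error must be in [0, 0.1]")
    table = counts.counts if isinstance(counts, SimulatedCounts) else counts
    for strain, bc in barcode_map.items():
        if len(bc) != template.barcode_length:
            raise ValueError(
                f"barcode for {strain} is {len(bc)} bp; template slot is "
                f"{template.barcode_length} bp"
            )
    rng = spawn_rng(seed, "amplicon")
    records: list[tuple[str, str]] = []
    n = 0
    for col in table.columns:
        idx_pair = sample_indices[col]
        for strain in table.index:
            c = int(table.loc[strain, col])
            if c == 0:
                continue
            clean = template.render(index_pair=idx_pair, barcode=barcode_map[strain])
            for _ in range(c):
                seq = _mutate(clean, per_base_error, rng) if per_base_error > 0 else clean
                records.append((f"read{n}", seq))
                n += 1
    # shuffle so samples are interleaved as on a real lane
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    if path is None:
        return records
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path
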