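"""Serial-dilution competition simulator.

Each 48-h cycle is summarised as deterministic exponential selection over
``g`` generations followed by an optional finite-cell bottleneck
(multinomial resampling of the transfer volume) and optional beneficial
mutation. Sublineages founded by mutations are tracked internally but the
observable output is always aggregated by founding barcode, because the
barcode — not the mutation — is what amplicon sequencing reads out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import spawn_rng
from .pool import StrainPool

#: generations per 1:250 transfer: round(log2(250)) = 8
GENERATIONS_PER_TRANSFER = round(math.log2(250))


@dataclass
class MutationEvent:
    transfer: int
    parent_lineage: int
    increment: float


@dataclass
class TrueTrajectory:
    """Ground-truth lineage trajectories from a simulated competition.

    ``freq`` is lineages x (n_transfers + 1); column t is the state at the
    start of transfer t (column 0 is the inoculum). ``founder`` maps each
    lineage (row) to the index of its founding strain in ``strain_ids``.
    """

    freq: np.ndarray = field(repr=False)
    founder: np.ndarray = field(repr=False)
    lineage_fitness: np.ndarray = field(repr=False)
    strain_ids: list[str]
    mutation_log: list[MutationEvent]
    g: float
    bottleneck: int | None

    @property
    def n_timepoints(self) -> int:
        return self.freq.shape[1]

    def barcode_frequencies(self) -> pd.DataFrame:
        """Observable strain x timepoint frequencies (sublineages summed
        into their founding barcode)."""
        n_strains = len(self.strain_ids)
        agg = np.zeros((n_strains, self.freq.shape[1]))
        np.add.at(agg, self.founder, self.freq)
        return pd.DataFrame(agg, index=pd.Index(self.strain_ids, name="strain_id"),
                            columns=range(self.freq.shape[1]))


def simulate_competition(
    pool: StrainPool,
    n_transfers: int,
    g: float = GENERATIONS_PER_TRANSFER,
    bottleneck: int | None = 100_000,
    mutation_rate: float = 0.0,
    dfe_mean: float = 0.05,
    seed: int = 0,
) -> TrueTrajectory:
    """Run ``n_transfers`` growth/dilution cycles.

    Per cycle: frequencies are multiplied by exp(g * s) and renormalised;
    if ``mutation_rate`` > 0, each lineage spawns Poisson(mutation_rate *
    f * bottleneck) new sublineages (a per-cell, per-transfer beneficial
    rate) whose fitness is the parent's plus an exponential increment of
    mean ``dfe_mean``; if ``bottleneck`` is finite, the next cycle starts
    from a multinomial sample of that many cells. ``bottleneck=None``
    means deterministic (infinite-population) transfer.
    """
    if n_transfers < 1:
        raise ValueError("n_transfers must be >= 1")
    if g <= 0:
        raise ValueError("g must be > 0")
    if bottleneck is not None and bottleneck < 1:
        raise ValueError("bottleneck must be >= 1 (or None for infinite)")
    if mutation_rate < 0:
        raise ValueError("mutation_rate must be >= 0")
    if mutation_rate > 0 and bottleneck is None:
        raise ValueError("mutation requires a finite bottleneck (founding frequency 1/N)")

    rng = spawn_rng(seed, "competition")
    freq = [pool.init_freq.copy()]
    founder = list(range(len(pool.strain_ids)))
    fitness = list(pool.fitness)
    mutation_log: list[MutationEvent] = []
    columns = [freq[0]]

    f = freq[0].copy()
    for transfer in range(1, n_transfers + 1):
        s = np.asarray(fitness)
        # deterministic selection over g generations
        w = f * np.exp(g * (s - s.max()))  # shift for overflow safety
        f = w / w.sum()
        # beneficial mutation: new sublineages at frequency 1/N
        if mutation_rate > 0:
            n_new = rng.poisson(mutation_rate * f * bottleneck)
            for parent in np.nonzero(n_new)[0]:
                for _ in range(int(n_new[parent])):
                    inc = rng.exponential(dfe_mean)
                    mutation_log.append(MutationEvent(transfer, int(parent), inc))
                    founder.append(founder[parent])
                    fitness.append(fitness[parent] + inc)
                    f = np.append(f, 1.0 / bottleneck)
                    f[parent] = max(f[parent] - 1.0 / bottleneck, 0.0)
            f = f / f.sum()
        # bottleneck: multinomial resampling of transferred cells
        if bottleneck is not None:
            counts = rng.multinomial(bottleneck, f)
            f = counts / bottleneck
        columns.append(f.copy())

    n_lineages = len(founder)
    mat = np.zeros((n_lineages, n_transfers + 1))
    for t, col in enumerate(columns):
        mat[: len(col), t] = col
    return TrueTrajectory(
        freq=mat,
        founder=np.asarray(founder),
        lineage_fitness=np.asarray(fitness),
        strain_ids=pool.strain_ids,
        mutation_log=mutation_log,
        g=g,
        bottleneck=bottleneck,
    )
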