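"""Construction of barcoded strain pools.

A pool mixes wild isolates (drawn fitnesses and starting frequencies) with
a set of neutral reference barcodes that share a fixed total mass — the
9:1 wild:reference mixing used in pooled competition assays. Reference
barcodes define the zero of the per-generation fitness scale and are later
used to calibrate measurement noise and the population mean fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .._rng import spawn_rng

_BASES = np.array(list("ACGT"))

#: Default wild-fitness distribution: a normal bulk plus an exponential
#: right tail, covering both flat-tailed and spike-tailed environments.
DEFAULT_FITNESS_SPEC = {
    "name": "normal_exp_mix",
    "mu": 0.0,
    "sigma": 0.02,
    "tail_frac": 0.05,
    "tail_mean": 0.05,
}

#: Default starting-frequency distribution (before renormalisation):
#: lognormal spread around an even pool, mimicking pipetting variation.
DEFAULT_FREQ_SPEC = {"name": "lognormal", "sigma": 0.5}


@dataclass
class StrainPool:
    """A barcoded pool: one row per strain.

    ``table`` columns: strain_id, barcode, true_fitness (per-generation
    natural-log selection coefficient, reference == 0), init_freq,
    is_reference. init_freq sums to 1.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if not np.isclose(t["init_freq"].sum(), 1.0, atol=1e-9):
            raise ValueError("init_freq must sum to 1 over the pool")
        if t["barcode"].duplicated().any():
            raise ValueError("barcodes must be unique")
        if t["strain_id"].duplicated().any():
            raise ValueError("strain ids must be unique")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.table["strain_id"])

    @property
    def reference_ids(self) -> set[str]:
        return set(self.table.loc[self.table["is_reference"], "strain_id"])

    @property
    def barcode_map(self) -> dict[str, str]:
        """strain_id -> barcode sequence."""
        return dict(zip(self.table["strain_id"], self.table["barcode"]))

    @property
    def fitness(self) -> np.ndarray:
        return self.table["true_fitness"].to_numpy(float)

    @property
    def init_freq(self) -> np.ndarray:
        return self.table["init_freq"].to_numpy(float)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StrainPool":
        return cls(pd.read_csv(path, sep="\t"))


def _draw_fitness(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    spec = {**DEFAULT_FITNESS_SPEC, **(spec or {})}
    name = spec["name"]
    if name == "normal_exp_mix":
        sigma, tail_frac, tail_mean = spec["sigma"], spec["tail_frac"], spec["tail_mean"]
        if sigma < 0:
            raise ValueError("fitness_spec parameter 'sigma' must be >= 0")
        if not 0 <= tail_frac <= 1:
            raise ValueError("fitness_spec parameter 'tail_frac' must be in [0, 1]")
        if tail_mean < 0:
            raise ValueError("fitness_spec parameter 'tail_mean' must be >= 0")
        s = rng.normal(spec["mu"], sigma, size=n)
        tail = rng.random(n) < tail_frac
        s[tail] += rng.exponential(tail_mean, size=int(tail.sum()))
        return s
    if name == "uniform":
        lo, hi = spec["low"], spec["high"]
        if hi < lo:
            raise ValueError("fitness_spec parameter 'high' must be >= 'low'")
        return rng.uniform(lo, hi, size=n)
    if name == "constant":
        return np.full(n, float(spec["value"]))
    raise ValueError(f"fitness_spec parameter 'name' unknown: {name!r}")


def _draw_freq(spec: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    spec = {**DEFAULT_FREQ_SPEC, **(spec or {})}
    name = spec["name"]
    if name == "lognormal":
        sigma = spec["sigma"]
        if sigma < 0:
            raise ValueError("freq_spec parameter 'sigma' must be >= 0")
        w = rng.lognormal(0.0, sigma, size=n)
    elif name == "uniform":
        w = np.ones(n)
    elif name == "dirichlet":
        alpha = spec["alpha"]
        if alpha <= 0:
            raise ValueError("freq_spec parameter 'alpha' must be > 0")
        w = rng.dirichlet(np.full(n, float(alpha)))
    else:
        raise ValueError(f"freq_spec parameter 'name' unknown: {name!r}")
    return w / w.sum()


def random_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Draw ``n`` distinct random nucleotide barcodes of ``length`` bp."""
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(_BASES, size=length))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def make_pool(
    n_wild: int,
    fitness_spec: dict | None = None,
    freq_spec: dict | None = None,
    n_reference: int = 6,
    reference_mass: float = 0.1,
    barcode_length: int = 20,
    seed: int = 0,
) -> StrainPool:
    """Assemble a wild + reference pool.

    Wild strains get fitnesses from ``fitness_spec`` and starting
    frequencies from ``freq_spec`` renormalised to ``1 - reference_mass``;
    the ``n_reference`` reference barcodes split ``reference_mass`` equally
    and have fitness exactly 0.
    """
    if n_wild < 1:
        raise ValueError("n_wild must be >= 1")
    if n_reference < 1:
        raise ValueError("n_reference must be >= 1")
    if not 0 < reference_mass < 1:
        raise ValueError("reference_mass must be in (0, 1)")
    rng = spawn_rng(seed, "pool")
    s_wild = _draw_fitness(fitness_spec or {}, n_wild, rng)
    f_wild = _draw_freq(freq_spec or {}, n_wild, rng) * (1.0 - reference_mass)
    ids = [f"W{i:04d}" for i in range(n_wild)] + [f"REF{i}" for i in range(n_reference)]
    barcodes = random_barcodes(n_wild + n_reference, barcode_length, rng)
    table = pd.DataFrame(
        {
            "strain_id": ids,
            "barcode": barcodes,
            "true_fitness": np.concatenate([s_wild, np.zeros(n_reference)]),
            "init_freq": np.concatenate(
                [f_wild, np.full(n_reference, reference_mass / n_reference)]
            ),
            "is_reference": [False] * n_wild + [True] * n_reference,
        }
    )
    return StrainPool(table)
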