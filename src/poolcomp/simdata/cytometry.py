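"""Synthetic flow-cytometry event tables for GFP competition assays.

Events mix a dark (unlabelled) and a GFP fluorescence component, each
log-normal on the fluorescence channel, over a forward-scatter model in
which singlets have an area/height ratio near 1 and doublets fall outside
the 0.9-1.03 singlet gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .._rng import spawn_rng


@dataclass
class ChannelModel:
    """Log10-space fluorescence components and scatter parameters."""

    dark_mean: float = 2.0
    dark_sigma: float = 0.15
    gfp_mean: float = 4.0
    gfp_sigma: float = 0.15
    fsc_height_mean: float = 5e4
    fsc_height_cv: float = 0.2
    singlet_ratio_range: tuple[float, float] = (0.92, 1.01)
    doublet_ratio_range: tuple[float, float] = (1.5, 2.1)


def make_cytometry_events(
    frac_dark: float,
    n_events: int,
    doublet_frac: float = 0.0,
    channel_model: ChannelModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an event table (fsc_a, fsc_h, ssc_a, fl columns).

    ``frac_dark`` of singlet events come from the dark component; doublets
    (a ``doublet_frac`` share of all events) have area/height ratios
    outside the singlet gate and fluorescence from either component.
    """
    if not 0 <= frac_dark <= 1:
        raise ValueError("frac_dark must be in [0, 1]")
    if not 0 <= doublet_frac <= 1:
        raise ValueError("doublet_frac must be in [0, 1]")
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    m = channel_model or ChannelModel()
    rng = spawn_rng(seed, "cytometry")
    is_doublet = rng.random(n_events) < doublet_frac
    is_dark = rng.random(n_events) < frac_dark
    height = rng.normal(m.fsc_height_mean, m.fsc_height_cv * m.fsc_height_mean, n_events)
    height = np.clip(height, 1.0, None)
    ratio = np.where(
        is_doublet,
        rng.uniform(*m.doublet_ratio_range, n_events),
        rng.uniform(*m.singlet_ratio_range, n_events),
    )
    log_fl = np.where(
        is_dark,
        rng.normal(m.dark_mean, m.dark_sigma, n_events),
        rng.normal(m.gfp_mean, m.gfp_sigma, n_events),
    )
    return pd.DataFrame({
        "fsc_a": height * ratio,
        "fsc_h": height,
        "ssc_a": np.clip(rng.normal(3e4, 6e3, n_events), 1.0, None),
        "fl": 10.0 ** log_fl,
    })
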