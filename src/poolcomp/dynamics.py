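"""Trajectory analytics for pooled competitions.

Works on frequency tables laid out as strain x timepoint DataFrames, one
per replicate (a ``dict`` replicate -> DataFrame). Covers diversity decay
(N99), dominant-strain tracking, cross-replicate variability, finalist
calling at the 1% last-timepoint threshold, and top-fitness-percentile
membership.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "call_finalists",
    "n99",
    "n99_series",
    "replicate_cv",
    "top_percentile_set",
    "top_strain_frequency",
]


def n99(freq_column, mass: float = 0.99) -> int:
    """Minimal number of strains whose summed frequencies reach ``mass``.

    The diversity summary behind "how many strains make up 99% of the
    pool". The column must sum to ~1.
    """
    if not 0 < mass <= 1:
        raise ValueError("mass must be in (0, 1]")
    f = np.sort(np.asarray(freq_column, float))[::-1]
    total = f.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"frequency column sums to {total:.6g}, not 1")
    cum = np.cumsum(f)
    # tolerate float round-off at exact-boundary cases (e.g. uniform pools)
    return int(np.searchsorted(cum, mass - 1e-9) + 1)


def n99_series(freq: dict[str, pd.DataFrame], mass: float = 0.99) -> pd.DataFrame:
    """Per-replicate N99 at every timepoint plus the cross-replicate
    median and interquartile range."""
    per_rep = pd.DataFrame({
        rep: {t: n99(df[t], mass) for t in df.columns} for rep, df in freq.items()
    })
    per_rep.index.name = "timepoint"
    q1, q3 = per_rep.quantile(0.25, axis=1), per_rep.quantile(0.75, axis=1)
    summary = pd.DataFrame({"median": per_rep.median(axis=1), "iqr_low": q1, "iqr_high": q3})
    return per_rep.join(summary)


def top_strain_frequency(freq: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Frequency of the most abundant strain per timepoint per replicate,
    with the cross-replicate mean and (sample) standard deviation."""
    if not freq:
        raise ValueError("need at least one replicate")
    per_rep = pd.DataFrame({rep: df.max(axis=0) for rep, df in freq.items()})
    per_rep.index.name = "timepoint"
    out = per_rep.copy()
    out["mean"] = per_rep.mean(axis=1)
    out["sd"] = per_rep.std(axis=1, ddof=1) if per_rep.shape[1] > 1 else 0.0
    return out


def replicate_cv(freq: dict[str, pd.DataFrame], strain_id: str) -> pd.Series:
    """Coefficient of variation (sample sd / mean) of one strain's
    frequency across replicates, per timepoint; NaN where the mean is 0."""
    if len(freq) < 2:
        raise ValueError("need >=2 replicates for a coefficient of variation")
    rows = {}
    for rep, df in freq.items():
        if strain_id not in df.index:
            raise KeyError(f"strain {strain_id!r} not in replicate {rep!r}")
        rows[rep] = df.loc[strain_id]
    mat = pd.DataFrame(rows)
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd / mean
    cv[mean == 0] = np.nan
    cv.name = strain_id
    return cv


def call_finalists(
    freq: dict[str, pd.DataFrame],
    last_timepoints: dict[str, object] | None = None,
    threshold: float = 0.01,
    environment: str = "",
) -> pd.DataFrame:
    """Strains at >= ``threshold`` frequency in >= 1 replicate at that
    replicate's own last timepoint (replicates may end at different
    transfers). The boundary is inclusive: exactly 1% qualifies.
    """
    if last_timepoints is None:
        last_timepoints = {rep: df.columns[-1] for rep, df in freq.items()}
    final = {}
    for rep, df in freq.items():
        t_last = last_timepoints[rep]
        if t_last not in df.columns:
            raise ValueError(f"replicate {rep!r} has no timepoint {t_last!r}")
        final[rep] = df[t_last]
    mat = pd.DataFrame(final)
    hit = mat.ge(threshold)
    keep = hit.any(axis=1)
    out = pd.DataFrame({
        "environment": environment,
        "strain_id": mat.index[keep],
        "max_final_freq": mat.loc[keep].max(axis=1),
        "n_replicates_above": hit.loc[keep].sum(axis=1),
        "threshold": threshold,
    }).reset_index(drop=True)
    return out.sort_values("max_final_freq", ascending=False).reset_index(drop=True)


def top_percentile_set(
    estimates: pd.DataFrame, q: float = 0.95, finalists=None
) -> pd.DataFrame:
    """Strains at or above the q-quantile of fitness estimates.

    The quantile uses linear interpolation between order statistics.
    Returns per-strain percentile ranks and membership; when a finalist
    list is supplied a ``finalist_in_set`` containment check column is
    attached for reporting.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    s = estimates["s_hat"].dropna()
    if len(s) < 2:
        raise ValueError("need >=2 defined fitness estimates")
    cutoff = float(np.quantile(s, q))
    rank = s.rank(pct=True)
    out = pd.DataFrame({
        "s_hat": s,
        "percentile": 100.0 * rank,
        "in_top_set": s >= cutoff,
    })
    out.attrs["cutoff"] = cutoff
    out.attrs["quantile_method"] = "linear"
    if finalists is not None:
        ids = set(finalists["strain_id"]) if isinstance(finalists, pd.DataFrame) else set(finalists)
        out["is_finalist"] = out.index.isin(ids)
        out.attrs["finalists_contained"] = bool(
            out.loc[out["is_finalist"], "in_top_set"].all())
    return out
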