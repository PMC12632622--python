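"""Maximum-likelihood fitness inference from barcode count trajectories.

Model
-----
A barcode with selection coefficient ``s`` (per-generation natural-log
units, reference strain == 0) and initial frequency ``f0`` follows

    f(t_k) = f0 * exp( g * sum_{j<k} (s - xbar_j) * (t_{j+1} - t_j) )

where ``g`` is generations per transfer and ``xbar_j`` the population mean
fitness over inter-transfer interval ``j``, estimated from the decline of
the neutral reference barcodes. The observed read count at timepoint t is
negative binomial with mean ``f(t) * R_t`` and variance ``kappa_t`` times
the mean; the dispersion ``kappa_t`` is calibrated from the scatter of the
reference barcodes, which share a common true trajectory. Maximising the
resulting likelihood over (s, f0) per barcode gives the fitness estimate;
the standard error comes from the observed information at the optimum.

Anchoring the mean fitness on the references (rather than iterating over
all lineages) breaks the model's gauge freedom: adding a constant to every
fitness and to every xbar leaves the likelihood unchanged, so only
reference-relative values are identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "FitnessEstimate",
    "MeanFitnessTrack",
    "NoiseModel",
    "combine_replicate_estimates",
    "estimate_dispersion",
    "estimate_mean_fitness",
    "frequencies",
    "infer_fitness",
    "interval_fitness",
    "negbin_loglik",
]

_MEAN_FLOOR_FRAC = 1e-12  # predicted mean clipped below at this fraction of R_t


def frequencies(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Pseudocounted frequencies: f = (r + a) / (R + a*B), per column.

    With ``pseudocount`` 0, zeros propagate. Raises on an all-zero sample.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total reads")
    b = counts.shape[0]
    return (counts + pseudocount) / (totals + pseudocount * b)


@dataclass
class MeanFitnessTrack:
    """Population mean fitness per inter-transfer interval (per-generation
    log units), from the decline of the summed reference frequency."""

    timepoints: np.ndarray  # transfer indices, len K
    xbar: np.ndarray  # len K-1; NaN where undefined
    g: float

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.xbar)

    def cumulative_generations(self) -> np.ndarray:
        """g * (t_k - t_0) for each timepoint."""
        return self.g * (self.timepoints - self.timepoints[0]).astype(float)


def estimate_mean_fitness(
    freq: pd.DataFrame,
    reference_ids: set,
    g: float = 8.0,
    floor: float = 0.0,
) -> MeanFitnessTrack:
    """xbar over (t_k, t_{k+1}) = ln(F_ref(t_k)/F_ref(t_{k+1})) / (g * dt).

    F_ref is the summed reference-barcode frequency; the references are
    neutral by construction, so their decline measures how fast the rest
    of the pool gains fitness. Intervals where F_ref does not exceed
    ``floor`` at both ends are NaN (undefined).
    """
    refs = [r for r in reference_ids if r in freq.index]
    if not refs:
        raise ValueError("no reference barcodes present in the table")
    tp = np.asarray(list(freq.columns), dtype=float)
    f_ref = freq.loc[refs].sum(axis=0).to_numpy(float)
    xbar = np.full(len(tp) - 1, np.nan)
    for k in range(len(tp) - 1):
        if f_ref[k] > floor and f_ref[k + 1] > floor:
            xbar[k] = np.log(f_ref[k] / f_ref[k + 1]) / (g * (tp[k + 1] - tp[k]))
    return MeanFitnessTrack(timepoints=tp, xbar=xbar, g=g)


@dataclass
class NoiseModel:
    """Count overdispersion calibrated from reference barcodes.

    ``kappa`` is the pooled variance-to-mean ratio (>= 1, the Poisson
    floor); ``kappa_interval`` the per-interval estimates it is the median
    of."""

    kappa: float
    kappa_interval: np.ndarray = field(repr=False)
    n_reference: int = 0


def estimate_dispersion(counts: pd.DataFrame, reference_ids: set) -> NoiseModel:
    """Dispersion from reference-barcode log-frequency-change scatter.

    All references share a true trajectory, so after removing the common
    (median) log change per interval, the residual variance of
    d_i = ln(f_i(t+1)/f_i(t)) is kappa * mean(1/r_i(t) + 1/r_i(t+1)) to
    first order. The ratio, floored at 1, estimates kappa per interval;
    the pooled value accumulates squared deviations and expected Poisson
    variance over all intervals before taking the ratio, which keeps its
    sampling noise small even with a handful of reference barcodes.
    """
    refs = [r for r in reference_ids if r in counts.index]
    freq = frequencies(counts, pseudocount=0.0)
    tp = list(counts.columns)
    kappas = []
    ss_total = 0.0
    expected_total = 0.0
    for k in range(len(tp) - 1):
        r0 = counts.loc[refs, tp[k]].to_numpy(float)
        r1 = counts.loc[refs, tp[k + 1]].to_numpy(float)
        ok = (r0 > 0) & (r1 > 0)
        if ok.sum() < 3:
            raise ValueError(
                f"need >=3 reference barcodes with nonzero counts on interval "
                f"({tp[k]}, {tp[k + 1]}); have {int(ok.sum())}")
        d = np.log(freq.loc[refs, tp[k + 1]].to_numpy(float)[ok]
                   / freq.loc[refs, tp[k]].to_numpy(float)[ok])
        d = d - np.median(d)
        expected = np.mean(1.0 / r0[ok] + 1.0 / r1[ok])
        var = float(np.var(d, ddof=1))
        kappas.append(max(var / expected, 1.0))
        ss_total += float((d ** 2).sum())
        expected_total += (ok.sum() - 1) * expected
    kappa_interval = np.asarray(kappas)
    return NoiseModel(kappa=max(ss_total / expected_total, 1.0),
                      kappa_interval=kappa_interval, n_reference=len(refs))


def _predicted_freq(s, f0, xbar: MeanFitnessTrack):
    """Model trajectory f(t_k); NaN xbar intervals truncate the window."""
    tp = xbar.timepoints
    dt = np.diff(tp)
    incr = xbar.g * (s - xbar.xbar) * dt
    cum = np.concatenate([[0.0], np.cumsum(incr)])
    return f0 * np.exp(cum)


def negbin_loglik(
    s: float,
    f0: float,
    counts_row: np.ndarray,
    depths: np.ndarray,
    xbar: MeanFitnessTrack,
    kappa: float | np.ndarray = 1.0,
    g: float | None = None,
) -> float:
    """Log-likelihood of one barcode trajectory under the NB model.

    Timepoints whose leading mean-fitness interval is undefined are
    excluded (the predicted frequency is unknown past a gap). ``g`` is
    taken from ``xbar`` when omitted. Public so optimisers can be checked
    against grid search.
    """
    if not 0 < f0 < 1:
        return -np.inf
    if g is not None and g != xbar.g:
        xbar = MeanFitnessTrack(xbar.timepoints, xbar.xbar * (xbar.g / g), g)
    counts_row = np.asarray(counts_row, float)
    depths = np.asarray(depths, float)
    kappa_t = np.broadcast_to(np.asarray(kappa, float), counts_row.shape)
    pred = _predicted_freq(s, f0, xbar)
    usable = np.isfinite(pred)
    mean = np.clip(pred[usable] * depths[usable],
                   _MEAN_FLOOR_FRAC * depths[usable], None)
    k = counts_row[usable]
    kap = kappa_t[usable]
    ll = np.where(
        kap <= 1.0 + 1e-9,
        k * np.log(mean) - mean - gammaln(k + 1),
        _nb_logpmf(k, mean, kap),
    )
    return float(ll.sum())


def _nb_logpmf(k, mean, kappa):
    # var = kappa * mean  =>  size r = mean/(kappa-1), success p = 1/kappa
    with np.errstate(divide="ignore", invalid="ignore"):
        r = mean / (kappa - 1.0)
        return (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
                + r * np.log(1.0 / kappa) + k * np.log(1.0 - 1.0 / kappa))


@dataclass
class FitnessEstimate:
    strain_id: str
    s_hat: float
    f0_hat: float
    se: float
    loglik: float
    n_timepoints: int
    flags: str = ""


def _init_guess(counts_row, depths, xbar: MeanFitnessTrack, pseudocount=0.5):
    """Closed-form start: regress ln f~(t) + g*cum(xbar) on cumulative
    generations; slope = s, intercept = ln f0."""
    tp = xbar.timepoints
    f = (counts_row + pseudocount) / (depths + pseudocount)
    dt = np.diff(tp)
    cum_xbar = np.concatenate([[0.0], np.cumsum(np.nan_to_num(xbar.xbar) * dt)]) * xbar.g
    x = xbar.cumulative_generations()
    y = np.log(f) + cum_xbar
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return 0.0, max(f[0], 1e-9)
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    return float(slope), float(np.clip(np.exp(intercept), 1e-12, 0.5))


def infer_fitness(
    counts: pd.DataFrame,
    reference_ids: set,
    g: float = 8.0,
    window=None,
    pseudocount: float = 0.5,
    s_bounds: tuple[float, float] = (-2.0, 2.0),
) -> pd.DataFrame:
    """Per-barcode ML fitness from a strain x timepoint count table.

    ``window`` restricts to a list of timepoint columns (default: all).
    Mean fitness and dispersion are calibrated from ``reference_ids``
    within the window; each barcode's (s, f0) is then optimised by
    bounded quasi-Newton from the regression start, with the standard
    error from the observed-information diagonal. Barcodes with all-zero
    counts in the window are flagged ``extinct`` and left NaN.
    """
    if window is not None:
        counts = counts[list(window)]
    if counts.shape[1] < 3:
        raise ValueError("need >=3 timepoints in the fit window")
    depths = counts.sum(axis=0).to_numpy(float)
    freq_pc = frequencies(counts, pseudocount=pseudocount if pseudocount > 0 else 0.5)
    xbar = estimate_mean_fitness(freq_pc, reference_ids, g=g)
    noise = estimate_dispersion(counts, reference_ids)
    if not xbar.defined.sum() >= 2:
        raise ValueError("fit window has fewer than 3 timepoints with defined mean fitness")

    # Mean-fitness scale noise, shared by every barcode: the reference
    # pool shrinks over the competition, so late xbar intervals are
    # estimated from few reads. Propagate kappa/r_ref(t) through the
    # slope weights of the trajectory regression and add it to each
    # barcode's observed-information variance.
    refs = [r for r in reference_ids if r in counts.index]
    r_ref = counts.loc[refs].sum(axis=0).to_numpy(float)
    x = xbar.cumulative_generations()
    w = (x - x.mean()) / ((x - x.mean()) ** 2).sum()
    with np.errstate(divide="ignore"):
        shared_var = float(np.sum(w ** 2 * noise.kappa / np.clip(r_ref, 1.0, None)))

    lo = np.log(1e-12)
    hi = np.log(0.999)
    rows = []
    for strain in counts.index:
        row = counts.loc[strain].to_numpy(float)
        if row.sum() == 0:
            rows.append(FitnessEstimate(strain, np.nan, np.nan, np.nan, np.nan,
                                        0, "extinct"))
            continue
        s0, f00 = _init_guess(row, depths, xbar, pseudocount=max(pseudocount, 0.5))
        s0 = float(np.clip(s0, s_bounds[0] + 1e-6, s_bounds[1] - 1e-6))

        def nll(theta):
            return -negbin_loglik(theta[0], np.exp(theta[1]), row, depths, xbar,
                                  kappa=noise.kappa)

        res = minimize(nll, x0=[s0, np.log(f00)], method="L-BFGS-B",
                       bounds=[s_bounds, (lo, hi)],
                       options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500})
        flags = []
        if not res.success:
            # near-noiseless data makes the likelihood extremely sharp and
            # L-BFGS-B can stop in its line search; a simplex polish from
            # the same point settles it
            polish = minimize(nll, res.x, method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12})
            if polish.fun <= res.fun:
                res = polish
            if not polish.success:
                flags.append("no_convergence")
        s_hat, lnf0 = res.x
        if abs(s_hat - s_bounds[0]) < 1e-9 or abs(s_hat - s_bounds[1]) < 1e-9:
            flags.append("boundary")
        se = _observed_se(res.x, nll)
        if np.isfinite(se):
            se = float(np.sqrt(se ** 2 + shared_var))
        rows.append(FitnessEstimate(strain, float(s_hat), float(np.exp(lnf0)),
                                    se, -float(res.fun),
                                    int(np.isfinite(_predicted_freq(0, 0.5, xbar)).sum()),
                                    ";".join(flags)))
    out = pd.DataFrame([vars(r) for r in rows]).set_index("strain_id")
    out.attrs["kappa"] = noise.kappa
    out.attrs["g"] = g
    return out


def _observed_se(theta, nll, step=(1e-5, 1e-4)) -> float:
    """SE of s from the 2x2 observed information (central differences)."""
    h = np.zeros((2, 2))
    f0 = nll(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * step[i]
            ej = np.eye(2)[j] * step[j]
            if i == j:
                h[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / step[i] ** 2
            else:
                h[i, j] = h[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)
                ) / (4 * step[i] * step[j])
    try:
        cov = np.linalg.inv(h)
        var = cov[0, 0]
        return float(np.sqrt(var)) if var > 0 else np.nan
    except np.linalg.LinAlgError:
        return np.nan


def interval_fitness(
    freq: pd.DataFrame, t1, t2, g: float = 8.0
) -> pd.DataFrame:
    """Log fold change of each strain between two timepoints.

    Returns both the raw ``log_fold_change`` ln(f(t2)/f(t1)) and the
    ``per_generation`` rate (divided by g*(t2-t1)), reflecting fitness
    relative to the population mean over the interval. Strains at zero
    frequency at either endpoint are NaN (extinct conditioning).
    """
    if t2 == t1:
        raise ValueError("t1 and t2 must differ")
    if t2 < t1:
        t1, t2 = t2, t1
    f1 = freq[t1].to_numpy(float)
    f2 = freq[t2].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.where((f1 > 0) & (f2 > 0), np.log(f2 / f1), np.nan)
    return pd.DataFrame(
        {"log_fold_change": lfc, "per_generation": lfc / (g * (float(t2) - float(t1)))},
        index=freq.index,
    )


def combine_replicate_estimates(per_replicate: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance-weighted combination across replicates.

    Returns one row per strain with the pooled ``s_hat``/``se`` plus the
    simple mean and the per-replicate estimate count, so both views of
    replicate combination are available.
    """
    frames = []
    for rep, df in per_replicate.items():
        sub = df[["s_hat", "se"]].copy()
        sub["replicate"] = rep
        frames.append(sub.reset_index())
    longf = pd.concat(frames, ignore_index=True).dropna(subset=["s_hat", "se"])
    longf = longf[longf["se"] > 0]

    def _combine(grp):
        w = 1.0 / grp["se"] ** 2
        return pd.Series({
            "s_hat": float(np.average(grp["s_hat"], weights=w)),
            "se": float(np.sqrt(1.0 / w.sum())),
            "s_mean_unweighted": float(grp["s_hat"].mean()),
            "n_replicates": int(len(grp)),
        })

    return longf.groupby("strain_id").apply(_combine, include_groups=False)
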