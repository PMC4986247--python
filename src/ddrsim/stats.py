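"""Statistical utilities: chi-square agreement tests, one-at-a-time
parameter sensitivity, and half-life estimation from decay time courses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

HOUR = 3600.0


@dataclass
class CountTable:
    """Observed (experiment) vs expected (simulation) counts by category."""

    categories: list
    observed: np.ndarray
    expected: np.ndarray

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.expected = np.asarray(self.expected, dtype=float)
        if self.observed.shape != self.expected.shape:
            raise ValueError("count vectors differ in shape")
        if len(self.categories) != len(self.observed):
            raise ValueError("category labels do not match counts")
        if np.any(self.observed < 0) or np.any(self.expected < 0):
            raise ValueError("negative counts")

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        return cls(list(df["category"]), df["observed"].to_numpy(),
                   df["expected"].to_numpy())


def chi2_compare(table: CountTable, alpha=0.05, pool_threshold=1.0):
    """Two-sample chi-square homogeneity test on two count vectors.

    Rows are the two samples (experiment, simulation), columns the
    categories.  Categories whose pooled expected count would fall below
    ``pool_threshold`` are merged into their neighbour before testing.
    Returns ``(statistic, p_value, verdict)`` where the verdict is True
    when the null hypothesis (no difference) is *not* rejected at
    ``alpha``.
    """
    obs = np.vstack([table.observed, table.expected])
    if obs.sum() == 0:
        raise ValueError("all-zero table")
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    # pool sparse categories left-to-right
    cols = []
    carry = np.zeros(2)
    for j in range(obs.shape[1]):
        carry += obs[:, j]
        row_tot = obs.sum(axis=1)
        n_tot = obs.sum()
        exp_lo = min(row_tot[0] * carry.sum() / n_tot,
                     row_tot[1] * carry.sum() / n_tot)
        if exp_lo >= pool_threshold:
            cols.append(carry.copy())
            carry = np.zeros(2)
    if carry.sum() > 0:
        if cols:
            cols[-1] += carry
        else:
            cols.append(carry.copy())
    obs = np.array(cols).T
    if obs.shape[1] < 2:
        return 0.0, 1.0, True
    stat, p, _, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), float(p), bool(p > alpha)


def fit_half_life(times_h, levels):
    """Log-linear least-squares exponential decay fit.

    Returns ``(rate_per_s, t_half_h, r_squared)``.  A non-decreasing
    series yields a warning flag through a non-positive rate and
    ``t_half = inf``.
    """
    times_h = np.asarray(times_h, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if len(times_h) < 3:
        raise ValueError("need at least 3 time points")
    if np.any(levels <= 0):
        raise ValueError("levels must be positive for a log-linear fit")
    ln = np.log(levels)
    slope, intercept = np.polyfit(times_h, ln, 1)
    resid = ln - (slope * times_h + intercept)
    ss_tot = np.sum((ln - ln.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    k_per_h = -slope
    if abs(k_per_h) < 1e-12:             # numerically flat series
        k_per_h = 0.0
    k_per_s = k_per_h / HOUR
    t_half_h = np.log(2) / k_per_h if k_per_h > 0 else np.inf
    return float(k_per_s), float(t_half_h), float(r2)


@dataclass
class SensitivityRow:
    parameter: str
    s_plus: float
    s_minus: float
    mc_error: float
    inconclusive: bool = False


def sensitivity_analysis(spec, protocol, *, parameters=None, perturbation=0.2,
                         n=200, master_seed=1, cfg=None, thresholds=None,
                         outputs=("apoptotic_pct_48h", "survival_pct"),
                         n_error_seeds=2):
    """One-at-a-time relative sensitivity of fate outputs to parameters.

    For each parameter p and each output Y:
    ``S = (dY / Y) / (dp / p)`` for a +/- ``perturbation`` relative change,
    computed with common random numbers (the same per-cell seed stream for
    baseline and perturbed runs) to suppress Monte-Carlo variance.  The
    Monte-Carlo error bar is the spread of the baseline output over
    ``n_error_seeds`` replicate seed streams; rows whose signal is below
    that noise are flagged inconclusive rather than reported as zero.

    Returns a DataFrame with one row per (parameter, output).
    """
    import pandas as pd

    from .population import run_population

    parameters = list(parameters if parameters is not None else spec.fitted)

    def measure(sv, seed):
        res = run_population(sv, protocol, n, seed, cfg=cfg,
                             thresholds=thresholds)
        fr = res.apoptotic_fractions(((0, 24), (24, 48)))
        vals = {"apoptotic_pct_24h": 100 * fr[0],
                "apoptotic_pct_48h": 100 * (fr[0] + fr[1]),
                "survival_pct": 100 * res.survival()}
        return {k: vals[k] for k in outputs}

    base = measure(spec, master_seed)
    reps = [measure(spec, master_seed + 7919 * (r + 1))
            for r in range(n_error_seeds)]
    mc_err = {k: float(np.std([base[k]] + [r[k] for r in reps], ddof=1))
              for k in outputs}

    rows = []
    for p in parameters:
        if p not in spec.parameters:
            raise KeyError(f"unknown parameter {p!r}")
        vals = {}
        for sign, tag in ((+1, "plus"), (-1, "minus")):
            sv = spec.copy()
            sv.parameters[p] = spec.parameters[p] * (1 + sign * perturbation)
            vals[tag] = measure(sv, master_seed)
        for out in outputs:
            y0 = base[out]
            if y0 == 0:
                s_plus = s_minus = 0.0 if vals["plus"][out] == 0 else np.inf
            else:
                s_plus = ((vals["plus"][out] - y0) / y0) / perturbation
                s_minus = ((vals["minus"][out] - y0) / y0) / (-perturbation)
            signal = max(abs(vals["plus"][out] - y0),
                         abs(vals["minus"][out] - y0))
            rows.append({
                "parameter": p, "output": out,
                "S_plus": s_plus, "S_minus": s_minus,
                "delta_plus": vals["plus"][out] - y0,
                "delta_minus": vals["minus"][out] - y0,
                "baseline": y0, "mc_error": mc_err[out],
                "inconclusive": bool(signal <= 2 * mc_err[out]),
            })
    df = pd.DataFrame(rows)
    return df.sort_values("S_plus", key=np.abs,
                          ascending=False).reset_index(drop=True)
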