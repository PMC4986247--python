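"""Small synthetic networks with known closed-form behaviour.

These fixtures exercise the hybrid engine and the statistics utilities
without the full DDR model: a linear birth-death process (stationary
Poisson), a two-allele gene toggle (binomial stationary occupancy), exact
exponential decay series for the half-life fitter, and a time-compressed
variant of the full model for fast population-level property tests.
None of them is a biological claim; they validate machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genes import GeneDef
from .model import (DsbChannel, ModelSpec, Reaction, ReceptorChannel,
                    Species)
from .protocols import Protocol


@dataclass
class ToyModel:
    name: str
    spec: ModelSpec
    analytic: dict = field(default_factory=dict)


def _channel_params(k_syn=0.0, k_deg=1.0, linear=True):
    """DSB-channel parameters for a birth-death process on the DSB counter.

    With ``km`` far above any reachable count the saturating repair law
    ``vmax*d/(km+d)`` reduces to first-order decay ``k_deg*d``.
    """
    km = 1.0e9
    return {
        "dsb_per_gy": 0.0,
        "k_dsb_bg": k_syn,
        "vmax_repair": k_deg * km if linear else k_deg,
        "km_repair": km,
        "n_receptors": 0.0,
        "k_rec_on": 0.0,
        "k_rec_off": 0.0,
    }


def make_birth_death(k_syn, k_deg) -> ToyModel:
    """Linear birth-death process, stationary Poisson(k_syn / k_deg).

    The stochastic count rides the engine's DSB event channel (constant
    birth propensity, first-order death).  The continuous twin species
    ``x_c`` obeys the matching ODE, so the deterministic limit of the same
    model has steady state ``k_syn / k_deg``.
    """
    if k_syn <= 0 or k_deg <= 0:
        raise ValueError("rates must be positive")
    pars = {"k_syn": k_syn, "k_deg": k_deg, **_channel_params(k_syn, k_deg)}
    spec = ModelSpec(
        species=[Species("tnf_e", "extracellular"),
                 Species("x_c", "cytoplasm")],
        parameters=pars,
        reactions=[
            Reaction("birth", "const", "k_syn", stoich=(("x_c", 1),)),
            Reaction("death", "lin", "k_deg", s1="x_c",
                     stoich=(("x_c", -1),)),
        ],
        genes=[],
        param_kinds={k: "rate" for k in pars},
    )
    lam = k_syn / k_deg
    return ToyModel(
        "birth_death", spec,
        analytic={"stationary_mean": lam, "stationary_var": lam,
                  "stationary_pmf": lambda k: np.exp(
                      k * np.log(lam) - lam -
                      np.array([np.sum(np.log(np.arange(1, kk + 1)))
                                for kk in np.atleast_1d(k)]))})


def make_gene_toggle(a, d) -> ToyModel:
    """Two-allele gene with constant switching rates.

    Per-allele on-probability p = a/(a+d); stationary occupancy of
    {0, 1, 2} active alleles is binomial: ((1-p)^2, 2p(1-p), p^2), with
    mean allele state 2a/(a+d).
    """
    if a <= 0 or d <= 0:
        raise ValueError("rates must be positive")
    pars = {"q0_toy": a, "d_toy": d, **_channel_params(1e-12, 1.0)}
    spec = ModelSpec(
        species=[Species("tnf_e", "extracellular")],
        parameters=pars,
        reactions=[],
        genes=[GeneDef("toy", basal="q0_toy", deactivation_rate="d_toy")],
        param_kinds={k: "rate" for k in pars},
    )
    p = a / (a + d)
    return ToyModel(
        "gene_toggle", spec,
        analytic={"stationary": np.array([(1 - p) ** 2, 2 * p * (1 - p),
                                          p ** 2]),
                  "mean_state": 2 * p})


#: sampling cadence (hours) of the transcript/protein chase experiments
DECAY_TIMES_H = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0])


def make_decay_series(t_half, noise_cv, n_points=9, seed=0, level0=100.0):
    """Exponential decay sampled at the chase-experiment cadence.

    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (median-unbiased in log space, so the log-linear fitter
    recovers the true rate without bias).
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    times = DECAY_TIMES_H[:n_points]
    levels = level0 * np.exp2(-times / t_half)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        levels = levels * np.exp(rng.normal(0.0, sigma, size=len(times)))
    return times, levels


def fast_scaled_model(factor=60.0):
    """Time-compressed variant of the default DDR model.

    All first-order/propensity rate constants are multiplied by
    ``factor``, compressing every timescale; molecule-count scales and
    Michaelis constants are untouched.  NOT quantitatively faithful to
    the hour-scale biology -- it exists so population-level property
    tests (dose monotonicity, genotype ordering) run at desk scale.
    """
    from .model import build_default_model

    spec = build_default_model()
    fast = spec.copy()
    for p, kind in fast.param_kinds.items():
        if kind == "rate":
            fast.parameters[p] *= factor
    return fast


def fast_scaled_protocol(p: Protocol, factor=60.0) -> Protocol:
    """Compress a protocol to match :func:`fast_scaled_model` timescales.

    The dose rate is scaled up so the delivered dose (hence the expected
    DSB count) is preserved over the compressed delivery window.
    """
    return Protocol(
        name=p.name + "_fast",
        burn_in=p.burn_in / factor,
        ir_dose=p.ir_dose,
        ir_start=p.ir_start / factor,
        ir_dose_rate=p.ir_dose_rate * factor,
        tnf_dose=p.tnf_dose,
        tnf_start=p.tnf_start / factor,
        tnf_duration=p.tnf_duration / factor,
        knockdowns=p.knockdowns,
        horizon=p.horizon / factor,
    )


def fast_scaled_thresholds(th, factor=60.0):
    """Fate thresholds with time windows compressed to match."""
    from .fate import FateThresholds

    return FateThresholds(th.p21_arrest, th.p53_apoptosis,
                          th.bax_apoptosis,
                          max_arrest=th.max_arrest / factor,
                          division_window=th.division_window / factor)
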