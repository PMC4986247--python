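"""Reproductions of the published virtual experiments.

Each function runs the full pipeline (model build, knockdown, protocol,
population simulation, fate classification) and returns the summary
quantity the corresponding figure or text reports.  Population sizes and
the integration cadence are arguments so callers can trade Monte-Carlo
error against runtime; defaults are desk-scale.
"""

from __future__ import annotations

import numpy as np

from .engine import EngineConfig
from .fate import FateThresholds
from .model import build_default_model
from .population import run_population
from .protocols import apply_knockdown, make_protocol

HOUR = 3600.0

#: relaxed integration cadence for population studies (validated by the
#: step-halving convergence test)
POP_CFG = dict(dt=4.0, save_every=600.0)


def _cfg(**kw):
    d = dict(POP_CFG)
    d.update(kw)
    return EngineConfig(**d)


def default_pair(kd_factor=0.25):
    """(wild-type spec, Wip1-RNAi spec) with shared resting calibration."""
    spec = build_default_model()
    kd = apply_knockdown(spec, "wip1", kd_factor)
    return spec, kd


def tnf_after_ir_fractions(seed, n=200, dose=4.0, lag_h=6.0,
                           spec=None, thresholds=None):
    """Apoptotic fractions (%) in (0,24] and (24,48] h for IR + TNF at +6 h.

    The experiment behind the printed 1.3 % / 4.5 % pair: 4 Gy IR with
    TNFa (10 ng/ml, 1 h) added six hours after irradiation.
    """
    spec = spec or build_default_model()
    th = thresholds or FateThresholds.default()
    prot = make_protocol("ir_then_tnf", dose=dose, lag_h=lag_h,
                         horizon_h=48.0)
    res = run_population(spec, prot, n, seed, cfg=_cfg(), thresholds=th)
    f24, f48 = res.apoptotic_fractions(((0, 24), (24, 48)))
    return 100.0 * f24, 100.0 * f48, res


def knockdown_fold(seed, n=100, dose=10.0, window_h=24.0, pair=None,
                   thresholds=None):
    """Median Wip1 protein fold, Ctr-RNAi / Wip1-RNAi, after ``dose`` Gy.

    Medians are taken across cells and across the observation window
    (0-24 h, the immunoblot time-course window).
    """
    spec, kd = pair or default_pair()
    th = thresholds or FateThresholds.default()
    prot = make_protocol("ir_only", dose=dose, horizon_h=window_h)
    lo = {}
    for label, sv in (("ctr", spec), ("kd", kd)):
        res = run_population(sv, prot, n, seed, cfg=_cfg(), thresholds=th,
                             tracked=("wip1_n", "p53a_n", "bax_c", "p21_n"))
        mask = res.t >= 0
        lo[label] = np.median(res.median[mask][:, res.species.index("wip1_n")])
    return lo["ctr"] / lo["kd"]


def clonogenic_grid(seed, n=150, doses=(2.0, 4.0), pair=None,
                    thresholds=None, horizon_h=120.0):
    """Clonogenic survival (relative to each genotype's unirradiated
    control) for Ctr-RNAi and Wip1-RNAi across ``doses``.

    Returns ``{genotype: {dose: relative survival}}`` including dose 0.
    """
    spec, kd = pair or default_pair()
    th = thresholds or FateThresholds.default()
    out = {}
    for gi, (label, sv) in enumerate((("ctr", spec), ("kd", kd))):
        out[label] = {}
        for dj, dose in enumerate((0.0,) + tuple(doses)):
            preset = "ir_only" if dose else "untreated"
            prot = make_protocol(preset, dose=dose, horizon_h=horizon_h)
            res = run_population(
                sv, prot, n, seed + 1009 * gi + 101 * dj, cfg=_cfg(),
                thresholds=th, tracked=("p53a_n", "bax_c", "p21_n"))
            out[label][dose] = res.survival()
        ref = max(out[label][0.0], 1e-9)
        out[label] = {d: s / ref for d, s in out[label].items()}
    return out


def clonogenic_ratios(seed, n=150, doses=(2.0, 4.0), **kw):
    """Ctr/Wip1-RNAi relative-survival ratio at each dose."""
    grid = clonogenic_grid(seed, n=n, doses=doses, **kw)
    return {d: grid["ctr"][d] / max(grid["kd"][d], 1e-9) for d in doses}


def kinetic_landmarks(seed, n=200, dose=10.0, pair=None, thresholds=None,
                      horizon_h=36.0):
    """(Wip1 mRNA peak h, Wip1 protein peak h, max p53 genotype diff h).

    All three are read from median population trajectories after a
    ``dose`` Gy exposure, times in hours post irradiation start.
    """
    spec, kd = pair or default_pair()
    th = thresholds or FateThresholds.default()
    prot = make_protocol("ir_only", dose=dose, horizon_h=horizon_h)
    med = {}
    for label, sv in (("ctr", spec), ("kd", kd)):
        res = run_population(sv, prot, n, seed, cfg=_cfg(), thresholds=th,
                             tracked=("wip1_n", "wip1_mrna_c", "p53a_n"))
        mask = res.t >= 0
        med[label] = {
            name: res.median[mask][:, res.species.index(name)]
            for name in ("wip1_n", "wip1_mrna_c", "p53a_n")}
        t_h = res.t[mask] / HOUR
    mrna_pk = float(t_h[np.argmax(med["ctr"]["wip1_mrna_c"])])
    prot_pk = float(t_h[np.argmax(med["ctr"]["wip1_n"])])
    diff = np.abs(med["kd"]["p53a_n"] - med["ctr"]["p53a_n"])
    diff_pk = float(t_h[np.argmax(diff)])
    return mrna_pk, prot_pk, diff_pk


def apoptosis_dose_course(seed, n=150, doses=(6.0, 8.0, 10.0), spec=None,
                          thresholds=None):
    """Cumulative 48 h apoptotic fraction (%) per dose, wild type."""
    spec = spec or build_default_model()
    th = thresholds or FateThresholds.default()
    out = {}
    for dj, dose in enumerate(doses):
        prot = make_protocol("ir_only", dose=dose, horizon_h=48.0)
        res = run_population(spec, prot, n, seed + 31 * dj, cfg=_cfg(),
                             thresholds=th,
                             tracked=("p53a_n", "bax_c", "p21_n"))
        f24, f48 = res.apoptotic_fractions(((0, 24), (24, 48)))
        out[dose] = 100.0 * (f24 + f48)
    return out


def tnf_timing_course(seed, n=150, dose=4.0, spec=None, thresholds=None):
    """48 h cumulative apoptotic fraction (%) for the three TNF timings:
    TNF only, IR only, TNF 3 h before IR, TNF 6 h after IR."""
    spec = spec or build_default_model()
    th = thresholds or FateThresholds.default()
    protos = {
        "tnf_only": make_protocol("tnf_only", horizon_h=48.0),
        "ir_only": make_protocol("ir_only", dose=dose, horizon_h=48.0),
        "tnf_then_ir": make_protocol("tnf_then_ir", dose=dose,
                                     horizon_h=51.0),
        "ir_then_tnf": make_protocol("ir_then_tnf", dose=dose, lag_h=6.0,
                                     horizon_h=48.0),
    }
    out = {}
    for pj, (name, prot) in enumerate(protos.items()):
        res = run_population(spec, prot, n, seed + 7 * pj, cfg=_cfg(),
                             thresholds=th,
                             tracked=("p53a_n", "bax_c", "p21_n"))
        # windows anchored at the IR exposure (t=0 for IR-first protocols)
        anchor = prot.ir_start / HOUR if prot.ir_dose > 0 else 0.0
        f24, f48 = res.apoptotic_fractions(
            ((anchor, anchor + 24), (anchor + 24, anchor + 48)))
        out[name] = 100.0 * (f24 + f48)
    return out
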