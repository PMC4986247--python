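"""Virtual experiment protocols: burn-in, irradiation, TNFa dosing, RNAi.

A :class:`Protocol` mirrors the wet-lab treatment schedule: cells
equilibrate for a burn-in period, are optionally exposed to a square pulse
of TNFa (medium physically replaced at washout, so the extracellular level
drops to exactly zero), and/or irradiated at a constant dose rate
(default 1 Gy/min, so a D-Gy exposure elevates the DSB induction
propensity for exactly D minutes).  All times are stored in seconds on a
clock whose zero is the start of treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

HOUR = 3600.0


@dataclass(frozen=True)
class Protocol:
    """One virtual experiment."""

    name: str = "custom"
    burn_in: float = 24 * HOUR           # s of pre-treatment equilibration
    ir_dose: float = 0.0                 # Gy
    ir_start: float = 0.0                # s, relative to treatment start
    ir_dose_rate: float = 1.0            # Gy / min
    tnf_dose: float = 0.0                # ng/ml
    tnf_start: float = 0.0               # s
    tnf_duration: float = HOUR           # s
    knockdowns: tuple = ()               # ((target, factor), ...)
    horizon: float = 48 * HOUR           # s of post-treatment simulation

    def __post_init__(self):
        if self.ir_dose < 0 or self.tnf_dose < 0:
            raise ValueError("doses must be non-negative")
        if self.ir_dose_rate <= 0:
            raise ValueError("dose rate must be positive")
        if self.burn_in < 0 or self.horizon <= 0:
            raise ValueError("bad protocol timing")

    @property
    def ir_duration(self) -> float:
        """Dose delivery window in seconds (dose / dose rate)."""
        return self.ir_dose / self.ir_dose_rate * 60.0

    @property
    def tnf_end(self) -> float:
        return self.tnf_start + self.tnf_duration

    def replace(self, **kw):
        d = asdict(self)
        d.update(kw)
        d["knockdowns"] = tuple(tuple(x) for x in d["knockdowns"])
        return Protocol(**d)

    def to_dict(self):
        d = asdict(self)
        d["knockdowns"] = [list(x) for x in self.knockdowns]
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["knockdowns"] = tuple(tuple(x) for x in d.get("knockdowns", ()))
        return cls(**d)


def protocol_segments(p: Protocol):
    """Piecewise-constant (TNF level, dose rate) segmentation.

    Returns ``(bounds, tnf_levels, dose_rates)`` where ``bounds`` has one
    more entry than the level arrays and spans ``[-burn_in, horizon]``.
    Every discontinuity is a segment boundary, hence an integration
    breakpoint for the engine.
    """
    events = {-p.burn_in, p.horizon}
    if p.ir_dose > 0:
        events.add(p.ir_start)
        events.add(p.ir_start + p.ir_duration)
    if p.tnf_dose > 0 and p.tnf_duration > 0:
        events.add(p.tnf_start)
        events.add(p.tnf_end)
    bounds = np.array(sorted(t for t in events
                             if -p.burn_in <= t <= p.horizon))
    tnf = np.zeros(len(bounds) - 1)
    dr = np.zeros(len(bounds) - 1)
    for i in range(len(bounds) - 1):
        mid = 0.5 * (bounds[i] + bounds[i + 1])
        if p.tnf_dose > 0 and p.tnf_start <= mid < p.tnf_end:
            tnf[i] = p.tnf_dose
        if p.ir_dose > 0 and p.ir_start <= mid < p.ir_start + p.ir_duration:
            dr[i] = p.ir_dose_rate / 60.0        # Gy/s
    return bounds, tnf, dr


def delivered_dose(p: Protocol) -> float:
    """Integral of the dose rate over the protocol; equals ir_dose exactly."""
    bounds, _, dr = protocol_segments(p)
    return float(np.sum(dr * np.diff(bounds)))


PRESETS = ("untreated", "tnf_only", "ir_only", "tnf_then_ir", "ir_then_tnf")


def make_protocol(name, dose=0.0, lag_h=6.0, tnf_dose=10.0, horizon_h=48.0,
                  burn_in_h=24.0, **kw):
    """Build one of the documented treatment presets.

    - ``tnf_only``: 10 ng/ml TNFa for 1 h, no irradiation.
    - ``ir_only``: IR at ``dose`` Gy delivered at 1 Gy/min from t = 0.
    - ``tnf_then_ir``: TNFa pulse, 2 h recovery after washout, then IR
      (irradiation starts 3 h after TNFa addition).
    - ``ir_then_tnf``: IR at t = 0, TNFa added ``lag_h`` hours later
      (default 6 h).
    """
    base = dict(burn_in=burn_in_h * HOUR, horizon=horizon_h * HOUR, **kw)
    if name == "untreated":
        return Protocol(name=name, **base)
    if name == "tnf_only":
        return Protocol(name=name, tnf_dose=tnf_dose, tnf_start=0.0, **base)
    if name == "ir_only":
        return Protocol(name=name, ir_dose=dose, ir_start=0.0, **base)
    if name == "tnf_then_ir":
        # TNF window [0, 1 h]; IR starts 2 h after washout, i.e. at +3 h
        return Protocol(name=name, tnf_dose=tnf_dose, tnf_start=0.0,
                        ir_dose=dose, ir_start=3 * HOUR, **base)
    if name == "ir_then_tnf":
        if lag_h < 0:
            raise ValueError("negative lag")
        return Protocol(name=name, ir_dose=dose, ir_start=0.0,
                        tnf_dose=tnf_dose, tnf_start=lag_h * HOUR, **base)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")


# ---------------------------------------------------------------------------
# RNAi knockdown
# ---------------------------------------------------------------------------

def apply_knockdown(spec, target: str, factor: float):
    """Return a copy of ``spec`` with ``target`` expression knocked down.

    shRNA acts on the transcript, so the knockdown is modelled as an added
    first-order mRNA degradation term, calibrated against the wild-type
    resting state so that the steady-state target protein is
    ``factor x`` wild type.  ``factor = 1`` returns an unmodified copy;
    ``factor = 0`` removes the transcript entirely (full knockout limit).
    """
    from .model import Reaction, resting_state

    if not 0.0 <= factor <= 1.0:
        raise ValueError("knockdown factor must be in [0, 1]")
    mrna = f"{target}_mrna_c"
    if mrna not in spec.index:
        raise KeyError(f"unknown knockdown target {target!r}")
    new = spec.copy()
    if factor == 1.0:
        return new

    # total resting degradation flux of the transcript -> effective rate
    y, g, dsb = resting_state(spec)
    from .model import CellState, rhs

    state = CellState(t=0.0, y=y,
                      genes={gd.name: float(gv)
                             for gd, gv in zip(spec.genes, g)},
                      dsb=dsb, receptors_active=0)
    mi = spec.index[mrna]
    deg_flux = 0.0
    from .model import _term_rate
    ylev = {s.name: y[i] for i, s in enumerate(spec.species)}
    for r in spec.reactions:
        for sname, c in r.stoich:
            if sname == mrna and c < 0:
                deg_flux += -c * _term_rate(r, ylev, state.genes, dsb, 0,
                                            spec.parameters)
    level = max(y[mi], 1e-12)
    k_eff = deg_flux / level
    pname = f"k_shrna_{target}"
    prot = f"{target}_n" if f"{target}_n" in spec.index else target
    prot_wt = y[spec.index[prot]] if prot in spec.index else None

    if factor == 0.0:
        # transcript reduced ~100-fold; stronger rates would make the
        # mRNA equation stiff for the fixed-step integrator
        k_extra = 100.0 * k_eff
    else:
        k_extra = k_eff * (1.0 / factor - 1.0)

    new.parameters[pname] = k_extra
    new.param_kinds[pname] = "rate"
    new.reactions.append(Reaction(
        f"shRNA-mediated {target} mRNA degradation", "lin", pname,
        s1=mrna, stoich=((mrna, -1),)))
    new.validate()

    # transcription feedbacks partially compensate the knockdown; iterate
    # the added degradation rate until the resting protein level actually
    # sits at factor x wild type
    if prot_wt is not None and factor > 0.0:
        target_level = factor * prot_wt
        for _ in range(6):
            new._resting = None
            yk, _, _ = resting_state(new)
            got = yk[new.index[prot]]
            if abs(got / target_level - 1.0) < 0.02:
                break
            # protein responds roughly like 1/(k_deg_m + k_extra)
            denom = k_eff + new.parameters[pname]
            new.parameters[pname] = max(
                denom * got / target_level - k_eff, 0.0)
        new._resting = None
    return new
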