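"""Cell-fate classification: arrest, apoptosis and clonogenic viability.

Two-threshold mechanism: a lower threshold on p21 marks cell-cycle arrest;
a higher joint threshold on active p53 AND Bax -- both must be exceeded
*simultaneously* -- marks apoptosis.  A cell is not viable (cannot found a
>= 30-cell colony) if it apoptoses before its first division or if its
cycle is arrested for more than 63.9 h in total.  The model has no explicit
cell-cycle clock, so the first division is placed after one cell-cycle
length of non-arrested time (arrest pauses the cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

HOUR = 3600.0


@dataclass(frozen=True)
class FateThresholds:
    """Threshold configuration (molecules per cell; times in hours)."""

    p21_arrest: float
    p53_apoptosis: float
    bax_apoptosis: float
    max_arrest: float = 63.9            # h of total arrest tolerated
    division_window: float = 27.0       # h of non-arrested time to 1st division

    @classmethod
    def default(cls):
        return cls(p21_arrest=DEFAULT_P21_ARREST,
                   p53_apoptosis=DEFAULT_P53_APOPTOSIS,
                   bax_apoptosis=DEFAULT_BAX_APOPTOSIS)

    def scaled(self, factor):
        return FateThresholds(self.p21_arrest * factor,
                              self.p53_apoptosis * factor,
                              self.bax_apoptosis * factor,
                              self.max_arrest, self.division_window)


# Calibrated against the wild-type resting state and the 2-10 Gy training
# grid: the arrest threshold sits above resting p21 excursions, the
# apoptosis thresholds well above the resting levels of active p53 and Bax
# (the "higher second threshold").
DEFAULT_P21_ARREST = 9.5e3
DEFAULT_P53_APOPTOSIS = 6.5e3
DEFAULT_BAX_APOPTOSIS = 1.9e4


@dataclass
class FateRecord:
    """Per-cell outcome."""

    apoptosis_time: float | None        # s after treatment start, or None
    arrest_intervals: list              # [(start_s, end_s), ...]
    divided_before_death: bool
    viable: bool

    @property
    def arrest_total_s(self):
        return float(sum(b - a for a, b in self.arrest_intervals))


def _intervals_above(t, x, th):
    """Half-open intervals (t[i], t[j]] where x >= th (post-treatment)."""
    above = x >= th
    intervals = []
    start = None
    for i in range(len(t)):
        if t[i] < 0:
            continue
        if above[i] and start is None:
            start = t[i]
        elif not above[i] and start is not None:
            intervals.append((start, t[i]))
            start = None
    if start is not None:
        intervals.append((start, t[-1]))
    return intervals


def classify_cell(traj, th: FateThresholds) -> FateRecord:
    """Classify one trajectory.

    Apoptotic iff active p53 and Bax both exceed their thresholds at the
    same sampled instant; arrested wherever p21 is above its threshold;
    not viable iff apoptotic before first division or total arrest
    exceeds ``max_arrest`` hours.
    """
    for name in ("p53a_n", "bax_c", "p21_n"):
        if name not in traj.species:
            raise KeyError(f"trajectory lacks species {name!r}")
    if th.p21_arrest <= 0 or th.p53_apoptosis <= 0 or th.bax_apoptosis <= 0:
        raise ValueError("thresholds must be positive")

    t = traj.t
    post = t >= 0
    p53a = traj.level("p53a_n")
    bax = traj.level("bax_c")
    p21 = traj.level("p21_n")

    both = (p53a >= th.p53_apoptosis) & (bax >= th.bax_apoptosis) & post
    apop_t = float(t[np.argmax(both)]) if both.any() else None

    intervals = _intervals_above(t, p21, th.p21_arrest)
    arrest_total = sum(b - a for a, b in intervals)

    # first division after one cell cycle of non-arrested time
    div_t = None
    need = th.division_window * HOUR
    acc = 0.0
    for i in range(1, len(t)):
        if t[i] <= 0:
            continue
        dt_i = t[i] - max(t[i - 1], 0.0)
        if p21[i] < th.p21_arrest:
            acc += dt_i
            if acc >= need:
                div_t = t[i]
                break

    divided = (div_t is not None and
               (apop_t is None or div_t <= apop_t))
    dead_before_division = apop_t is not None and not divided
    viable = (not dead_before_division
              and arrest_total <= th.max_arrest * HOUR)
    return FateRecord(apoptosis_time=apop_t,
                      arrest_intervals=intervals,
                      divided_before_death=divided,
                      viable=viable)


def apoptotic_fraction(fates, windows):
    """Fraction of cells whose apoptosis time falls in each (lo, hi] window.

    Windows are hours post-irradiation, ordered and non-overlapping; a cell
    already counted in an earlier window is excluded from later ones
    (each apoptotic cell counts exactly once, in the window containing its
    apoptosis time; boundaries are closed on the right).
    """
    windows = [tuple(w) for w in windows]
    for (a, b) in windows:
        if b <= a:
            raise ValueError("empty window")
    for w1, w2 in zip(windows, windows[1:]):
        if w2[0] < w1[1]:
            raise ValueError("overlapping windows")
    n = len(fates)
    out = []
    for lo, hi in windows:
        c = sum(1 for f in fates
                if f.apoptosis_time is not None
                and lo * HOUR < f.apoptosis_time <= hi * HOUR)
        out.append(c / n if n else 0.0)
    return out


def clonogenic_survival(fates):
    """Fraction of cells able to found a colony (viable verdicts)."""
    if not fates:
        return 0.0
    return sum(1 for f in fates if f.viable) / len(fates)


def fate_table(fates):
    """Per-cell fate report as a DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "cell_id": np.arange(len(fates)),
        "apoptosis_time_h": [
            (f.apoptosis_time / HOUR if f.apoptosis_time is not None
             else np.nan) for f in fates],
        "arrest_hours": [f.arrest_total_s / HOUR for f in fates],
        "divided": [f.divided_before_death for f in fates],
        "viable": [f.viable for f in fates],
    })
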