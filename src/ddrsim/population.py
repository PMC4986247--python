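"""Population orchestration: N-cell runs, quantile trajectories, grids."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import model as _model
from .engine import EngineConfig, simulate_cell
from .fate import (FateThresholds, apoptotic_fraction, classify_cell,
                   clonogenic_survival)

HOUR = 3600.0

#: species kept in population quantile summaries by default
DEFAULT_TRACKED = ("p53a_n", "wip1_n", "wip1_mrna_c", "chk2a_n", "mdm2_n",
                   "p21_n", "bax_c", "nfkb_n")


def cell_seed(master_seed: int, cell_index: int) -> int:
    """Stable per-cell seed stream, independent of execution order."""
    ss = np.random.SeedSequence([int(master_seed), int(cell_index)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFFFFFFFFFF)


@dataclass
class PopulationResult:
    """Per-time-point quantiles plus fate tallies for one protocol."""

    t: np.ndarray                       # s relative to treatment start
    species: list
    median: np.ndarray                  # (n_times, n_tracked)
    q1: np.ndarray
    q3: np.ndarray
    fates: list
    n: int
    meta: dict = field(default_factory=dict)

    def level(self, name, which="median"):
        arr = {"median": self.median, "q1": self.q1, "q3": self.q3}[which]
        return arr[:, self.species.index(name)]

    def peak_time_h(self, name, which="median", after_h=0.0):
        """Time (hours post-treatment) at which the quantile curve peaks."""
        mask = self.t >= after_h * HOUR
        x = self.level(name, which)[mask]
        return float(self.t[mask][np.argmax(x)] / HOUR)

    def apoptotic_fractions(self, windows=((0, 24), (24, 48))):
        return apoptotic_fraction(self.fates, windows)

    def survival(self):
        return clonogenic_survival(self.fates)

    def summary(self, windows=((0, 24), (24, 48))):
        fr = self.apoptotic_fractions(windows)
        return {
            "n": self.n,
            **{f"apoptotic_pct_{int(lo)}_{int(hi)}h": 100.0 * f
               for (lo, hi), f in zip(windows, fr)},
            "survival_pct": 100.0 * self.survival(),
        }


def _quantiles(stack, qs=(0.5, 0.25, 0.75)):
    # nearest-rank for bit-reproducibility across platforms
    return [np.quantile(stack, q, axis=0, method="closest_observation")
            for q in qs]


def run_population(spec, protocol, n, master_seed, *, cfg=None,
                   thresholds=None, tracked=DEFAULT_TRACKED,
                   progress=False) -> PopulationResult:
    """Simulate ``n`` independent cells and aggregate.

    Each cell gets a seed derived from (master_seed, cell index), so the
    result is a pure function of its arguments regardless of execution
    order.  Individual cell failures are recorded; the run aborts if more
    than 1 % of cells fail.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or EngineConfig()
    th = thresholds or FateThresholds.default()
    tracked = [s for s in tracked if s in spec.index]

    traj_stack = None
    t_axis = None
    fates = []
    failures = []
    it = range(n)
    if progress:
        from tqdm import tqdm
        it = tqdm(it, desc=protocol.name)
    for i in it:
        try:
            traj = simulate_cell(spec, protocol, cfg, thresholds=th,
                                 seed=cell_seed(master_seed, i))
        except Exception as e:          # noqa: BLE001 - recorded, re-raised below
            failures.append((i, repr(e)))
            if len(failures) > max(1, 0.01 * n):
                raise RuntimeError(f"{len(failures)} cells failed: "
                                   f"{failures[:3]}") from e
            continue
        if traj_stack is None:
            t_axis = traj.t
            traj_stack = np.empty((n, len(t_axis), len(tracked)))
        for j, name in enumerate(tracked):
            traj_stack[len(fates), :, j] = traj.level(name)
        fates.append(classify_cell(traj, th))
    n_ok = len(fates)
    med, q1, q3 = _quantiles(traj_stack[:n_ok])
    return PopulationResult(
        t=t_axis, species=list(tracked), median=med, q1=q1, q3=q3,
        fates=fates, n=n_ok,
        meta={"master_seed": int(master_seed),
              "spec_hash": spec.spec_hash(),
              "protocol": protocol.to_dict(),
              "failures": failures,
              "dt": cfg.dt})


def run_grid(spec_variants, protocols, n, master_seed, *, cfg=None,
             thresholds=None, windows=((0, 24), (24, 48)), progress=False):
    """Run every (spec variant x protocol) combination.

    ``spec_variants`` maps label -> ModelSpec.  Returns
    (summary DataFrame, dict of PopulationResult keyed by (label, protocol
    name)).  Seeds are derived per grid cell so each combination is
    independent yet reproducible.
    """
    import pandas as pd

    if not spec_variants or not protocols:
        raise ValueError("empty grid")
    rows = []
    results = {}
    for gi, (label, sv) in enumerate(spec_variants.items()):
        for pj, prot in enumerate(protocols):
            seed_ij = cell_seed(master_seed, 100_000 + 1000 * gi + pj)
            res = run_population(sv, prot, n, seed_ij, cfg=cfg,
                                 thresholds=thresholds, progress=progress)
            results[(label, prot.name)] = res
            row = {"genotype": label, "protocol": prot.name,
                   "ir_dose_gy": prot.ir_dose, "tnf_dose": prot.tnf_dose,
                   **res.summary(windows)}
            rows.append(row)
    return pd.DataFrame(rows), results


def write_hdf5(path, results, extra_meta=None):
    """Store a dict of PopulationResult in an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        for (label, pname), res in results.items():
            g = f.create_group(f"{label}/{pname}")
            g.create_dataset("t", data=res.t)
            g.create_dataset("median", data=res.median)
            g.create_dataset("q1", data=res.q1)
            g.create_dataset("q3", data=res.q3)
            g.attrs["species"] = ",".join(res.species)
            g.attrs["n"] = res.n
            g.attrs["spec_hash"] = res.meta.get("spec_hash", "")
            g.attrs["master_seed"] = res.meta.get("master_seed", -1)
        if extra_meta:
            for k, v in extra_meta.items():
                f.attrs[k] = v
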