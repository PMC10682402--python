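"""Synthetic microfluidic aging experiments.

Emulates the statistical structure of a fixed-duration single-cell
replicative-lifespan (RLS) assay: newborn mother cells are trapped at time
zero, each division is logged, and at the end of the run every cell is either
dead (its full division count observed) or still alive, i.e. right-censored
at the number of divisions completed so far.

The generator draws integer lifespans exactly from the Weibull survival law,
gives each cell-cycle a duration near 90 minutes with multiplicative
lognormal noise, inflates the final few cycles to mimic senescent slow-down,
and censors at the experiment duration (72 h by default).  A strain is
simulated as 200 cells pooled from two biological replicates, matching the
standard screen design.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .weibull import WeibullParams, mean_rls, sd_rls, sample_lifespan

__all__ = ["CellRecord", "AgingSimParams", "simulate_cell", "simulate_experiment", "simulate_screen"]

DEAD = "dead"
CENSORED = "censored"


@dataclass(frozen=True)
class CellRecord:
    """One tracked mother cell: observed divisions and end state."""

    strain_id: str
    replicate_id: str
    cell_id: str
    divisions: int
    end_state: str  # "dead" or "censored"
    division_times: tuple[float, ...] | None = None  # minutes from experiment start

    def __post_init__(self) -> None:
        if self.end_state not in (DEAD, CENSORED):
            raise ValueError(f"end_state must be 'dead' or 'censored', got {self.end_state!r}")
        if self.divisions < 0:
            raise ValueError("divisions must be a nonnegative integer")
        if self.division_times is not None:
            if len(self.division_times) != self.divisions:
                raise ValueError("division_times length must equal divisions")
            if any(b <= a for a, b in zip(self.division_times, self.division_times[1:])):
                raise ValueError("division_times must be strictly increasing")


@dataclass(frozen=True)
class AgingSimParams:
    """Design of one simulated aging experiment.

    true_params        -- Weibull law the lifespans are drawn from
    n_cells            -- cells analyzed per strain (default 200)
    n_replicates       -- biological replicates the cells are split across
    duration_h         -- experiment duration in hours (default 72 = 3 days)
    base_cycle_min     -- young-cell cell-cycle duration, minutes
    cycle_cv           -- coefficient of variation of lognormal cycle noise
    elongation_factor  -- relative slow-down reached in the final cycles
    elongation_window  -- number of final cycles over which duration ramps up
    imaging_interval_min -- if > 0, division times snap up to the next frame
    seed               -- master seed; identical seeds give identical data
    """

    true_params: WeibullParams
    n_cells: int = 200
    n_replicates: int = 2
    duration_h: float = 72.0
    base_cycle_min: float = 90.0
    cycle_cv: float = 0.2
    elongation_factor: float = 1.0
    elongation_window: int = 5
    imaging_interval_min: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_replicates < 1:
            raise ValueError("n_cells and n_replicates must be positive")
        if self.duration_h < 0 or self.base_cycle_min <= 0:
            raise ValueError("duration_h must be >= 0 and base_cycle_min > 0")
        if self.cycle_cv < 0 or self.elongation_factor < 0 or self.elongation_window < 0:
            raise ValueError("cycle_cv, elongation_factor and elongation_window must be >= 0")
        if self.imaging_interval_min < 0:
            raise ValueError("imaging_interval_min must be >= 0")


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    # Stream keyed by (seed, cell index) only, so replicate labelling can
    # never perturb the lifespan draws.
    return np.random.default_rng([int(seed), int(cell_index)])


def _age_factor(i: int, lifespan: int, lam: float, window: int) -> float:
    """Senescent elongation: linear ramp over the final ``window`` cycles."""
    if window <= 0 or lam <= 0.0:
        return 1.0
    return 1.0 + lam * max(0.0, (i - (lifespan - window)) / window)


def simulate_cell(
    params: AgingSimParams,
    cell_index: int,
    rng: np.random.Generator | None = None,
    strain_id: str = "strain",
    replicate_id: str = "rep1",
) -> CellRecord:
    """Simulate one mother cell under the experiment design.

    The integer lifespan L is drawn by inverse-CDF sampling; cycle i lasts
    ``base_cycle_min * f_age(i) * eps_i`` minutes with eps lognormal (unit
    median, CV = cycle_cv).  Death happens during the failed attempt at
    division L+1.  A cell whose death falls past the experiment duration is
    censored at however many divisions it completed in time.
    """
    if rng is None:
        rng = _cell_rng(params.seed, cell_index)
    u = rng.random()
    while not (0.0 < u < 1.0):  # guard the measure-zero endpoints
        u = rng.random()
    lifespan = sample_lifespan(params.true_params, u)

    n_cycles = lifespan + 1  # the last one is the failed division attempt
    if params.cycle_cv > 0:
        sigma = math.sqrt(math.log1p(params.cycle_cv**2))
        eps = rng.lognormal(mean=0.0, sigma=sigma, size=n_cycles)
    else:
        eps = np.ones(n_cycles)
    factors = np.array(
        [_age_factor(i, lifespan, params.elongation_factor, params.elongation_window)
         for i in range(1, n_cycles + 1)]
    )
    cycles = params.base_cycle_min * factors * eps
    times = np.cumsum(cycles)
    division_times = times[:lifespan]
    death_time = times[-1]

    if params.imaging_interval_min > 0:
        dt = params.imaging_interval_min
        division_times = np.ceil(division_times / dt) * dt
        # snapping can create ties at a frame; nudge to keep strict ordering
        for j in range(1, len(division_times)):
            if division_times[j] <= division_times[j - 1]:
                division_times[j] = division_times[j - 1] + dt

    duration_min = params.duration_h * 60.0
    observed = int(np.searchsorted(division_times, duration_min, side="right"))
    cell_id = f"{strain_id}.{cell_index:04d}"
    if observed == lifespan and death_time <= duration_min:
        return CellRecord(
            strain_id=strain_id,
            replicate_id=replicate_id,
            cell_id=cell_id,
            divisions=lifespan,
            end_state=DEAD,
            division_times=tuple(float(t) for t in division_times),
        )
    return CellRecord(
        strain_id=strain_id,
        replicate_id=replicate_id,
        cell_id=cell_id,
        divisions=observed,
        end_state=CENSORED,
        division_times=tuple(float(t) for t in division_times[:observed]),
    )


def simulate_experiment(params: AgingSimParams, strain_id: str = "strain") -> list[CellRecord]:
    """Simulate one strain: n_cells records split evenly across replicates."""
    records = []
    for i in range(params.n_cells):
        rep = i * params.n_replicates // params.n_cells
        records.append(
            simulate_cell(
                params,
                cell_index=i,
                strain_id=strain_id,
                replicate_id=f"rep{rep + 1}",
            )
        )
    return records


def strain_seed(master_seed: int, strain_id: str) -> int:
    """Deterministic per-strain seed below 2**31."""
    h = zlib.crc32(strain_id.encode("utf-8"))
    return int((master_seed * 1_000_003 + h) % (2**31))


def simulate_screen(
    strain_specs: Sequence[tuple[str, WeibullParams]],
    shared: AgingSimParams,
) -> tuple[list[CellRecord], pd.DataFrame]:
    """Simulate a deletion-strain screen under a common design.

    Returns the pooled cell records of every strain and a truth table with
    each strain's generating parameters and the closed-form mean/SD they
    imply.  Per-strain seeds derive deterministically from the master seed
    and the strain id.
    """
    ids = [sid for sid, _ in strain_specs]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate strain ids: {dupes}")
    if not strain_specs:
        raise ValueError("at least one strain spec is required")

    records: list[CellRecord] = []
    rows = []
    for sid, wp in strain_specs:
        strain_params = replace(shared, true_params=wp, seed=strain_seed(shared.seed, sid))
        records.extend(simulate_experiment(strain_params, strain_id=sid))
        rows.append(
            {
                "strain": sid,
                "r": wp.r,
                "alpha": wp.alpha,
                "true_mean": mean_rls(wp),
                "true_sd": sd_rls(wp),
            }
        )
    return records, pd.DataFrame(rows)
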