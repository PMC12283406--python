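"""Moran-model simulator of HSPC turnover, chemotherapy and clonal diversity.

The population starts with ``n`` active HSPCs, each its own clone (the
adult clonal pool is assumed established by early childhood). One time
step is 1/n year, so each cell divides about once per year. Per step one
cell dies and one divides; the divider is chosen by fitness-proportionate
selection, Pr(division of cell k) = (1 + i_k s) / Gamma with
Gamma = sum_j (1 + i_j s), where i_k counts the cell's driver mutations
(each division adds a driver with probability ``u``). Death is uniform.

Chemotherapy shrinks the population linearly to ``epsilon * n`` between
``chemo_start_age`` and ``chemo_end_age`` (excess deaths only) and
recovery restores it linearly to ``n`` within ``beta`` years (excess
births only) — the simplest schedule consistent with a stated bottleneck
depth and recovery duration. In the resistant scenario, cells may acquire
a chemotherapy-resistance mutation (probability ``m`` per division,
available before or during chemotherapy only); during chemotherapy a
resistant cell's death weight is ``w`` < 1 versus 1 for sensitive cells.

Fast runs use rejection sampling for the weighted choices, which draws
from exactly the same distribution as the explicit per-cell probability
vectors (kept in :func:`division_probabilities`, :func:`death_probabilities`
and :func:`moran_step` as the small-n reference implementation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .diversity import shannon_index, simpson_index, subsample_diversity

SCENARIOS = ("neutral", "drivers", "chemo", "chemo_resistant")


@dataclass(frozen=True)
class SimulationParams:
    """All Moran-model constants. Defaults are documented, non-authoritative
    working values for a mid-life chemotherapy exposure."""
    n: int = 1000               # active HSPC count (= steps per year)
    s: float = 0.1              # additive fitness gain per driver
    u: float = 1e-5             # driver mutation probability per division
    epsilon: float = 0.3        # bottleneck fraction (population floor / n)
    beta: float = 1.0           # recovery duration, years
    m: float = 1e-6             # resistance mutation probability per division
    w: float = 0.1              # death weight of resistant cells during chemo
    chemo_start_age: float = 35.0
    chemo_end_age: float = 40.0
    t_end: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if not 0 <= self.w < 1:
            raise ValueError("w must lie in [0, 1)")
        if self.s < 0 or not 0 <= self.u <= 1 or not 0 <= self.m <= 1:
            raise ValueError("s >= 0 and u, m in [0, 1] required")
        if self.beta < 0 or self.chemo_end_age < self.chemo_start_age:
            raise ValueError("invalid chemotherapy window")


@dataclass
class PopulationState:
    """Per-cell arrays (active prefix of length ``size``)."""
    clone: np.ndarray           # initial-lineage label per cell
    drivers: np.ndarray         # driver count i_k per cell
    resistant: np.ndarray       # resistance flag per cell
    size: int
    age: float

    @classmethod
    def initial(cls, n: int, age: float = 0.0) -> "PopulationState":
        return cls(clone=np.arange(n, dtype=np.int64),
                   drivers=np.zeros(n, dtype=np.int64),
                   resistant=np.zeros(n, dtype=bool),
                   size=n, age=age)

    def clone_sizes(self) -> np.ndarray:
        counts = np.bincount(self.clone[:self.size])
        return counts[counts > 0]


# ----------------------------------------------------------------------
# per-cell reference probabilities (the explicit model definition)
# ----------------------------------------------------------------------

def division_probabilities(state: PopulationState, s: float) -> np.ndarray:
    """Fitness-proportionate division probabilities (1 + i_k s) / Gamma."""
    fitness = 1.0 + state.drivers[:state.size] * s
    return fitness / fitness.sum()


def death_probabilities(state: PopulationState, during_chemo: bool,
                        w: float = 1.0) -> np.ndarray:
    """Death probabilities: uniform, except resistant cells weight w in chemo."""
    weights = np.ones(state.size)
    if during_chemo:
        weights[state.resistant[:state.size]] = w
    return weights / weights.sum()


def moran_step(state: PopulationState, params: SimulationParams,
               rng: np.random.Generator,
               resistant_deaths: bool = False) -> PopulationState:
    """One explicit death + division step (small-n reference implementation).

    The daughter replaces the dead cell, inheriting clone label, driver
    count and resistance; with probability ``u`` she gains a driver and,
    before or during chemotherapy, with probability ``m`` she gains
    resistance. Population size is unchanged.
    """
    during_chemo = params.chemo_start_age <= state.age < params.chemo_end_age
    victim = rng.choice(state.size,
                        p=death_probabilities(state, during_chemo and resistant_deaths,
                                              params.w))
    parent = rng.choice(state.size, p=division_probabilities(state, params.s))
    state.clone[victim] = state.clone[parent]
    state.drivers[victim] = state.drivers[parent]
    state.resistant[victim] = state.resistant[parent]
    if params.u > 0 and rng.random() < params.u:
        state.drivers[victim] += 1
    if resistant_deaths and params.m > 0 and state.age <= params.chemo_end_age \
            and rng.random() < params.m:
        state.resistant[victim] = True
    state.age += 1.0 / params.n
    return state


# ----------------------------------------------------------------------
# fast path
# ----------------------------------------------------------------------

class _UniformBuffer:
    """Chunked uniform(0,1) draws as plain Python floats."""

    __slots__ = ("rng", "chunk", "buf", "i")

    def __init__(self, rng: np.random.Generator, chunk: int = 1 << 16):
        self.rng = rng
        self.chunk = chunk
        self.buf = rng.random(chunk).tolist()
        self.i = 0

    def u(self) -> float:
        if self.i >= len(self.buf):
            self.buf = self.rng.random(self.chunk).tolist()
            self.i = 0
        v = self.buf[self.i]
        self.i += 1
        return v


def _target_size(t: float, params: SimulationParams, with_chemo: bool) -> int:
    if not with_chemo:
        return params.n
    n, cs, ce = params.n, params.chemo_start_age, params.chemo_end_age
    n_min = max(int(np.ceil(params.epsilon * n)), 1)
    if t < cs or t >= ce + params.beta:
        return n
    if t < ce:
        if ce == cs:
            return n_min
        frac = (t - cs) / (ce - cs)
        return int(round(n - (n - n_min) * frac))
    if params.beta == 0:
        return n
    frac = (t - ce) / params.beta
    return int(round(n_min + (n - n_min) * frac))


def _advance(state: PopulationState, params: SimulationParams, scenario: str,
             t_to: float, rng: np.random.Generator) -> PopulationState:
    """Advance the population to ``t_to`` (fast rejection-sampling stepper)."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    with_chemo = scenario in ("chemo", "chemo_resistant")
    resistant_deaths = scenario == "chemo_resistant"
    s = 0.0 if scenario == "neutral" else params.s
    u = 0.0 if scenario == "neutral" else params.u
    m = params.m if resistant_deaths else 0.0
    w = params.w
    clone, drivers, resistant = state.clone, state.drivers, state.resistant
    size, t = state.size, state.age
    dt = 1.0 / params.n
    ub = _UniformBuffer(rng)
    max_drivers = int(drivers[:size].max()) if size else 0

    def pick_parent() -> int:
        if s == 0.0 or max_drivers == 0:
            return int(ub.u() * size)
        wmax = 1.0 + max_drivers * s
        while True:
            idx = int(ub.u() * size)
            if ub.u() * wmax < 1.0 + drivers[idx] * s:
                return idx

    def pick_victim(during_chemo: bool) -> int:
        if not (during_chemo and resistant_deaths):
            return int(ub.u() * size)
        while True:
            idx = int(ub.u() * size)
            if not resistant[idx] or ub.u() < w:
                return idx

    cs, ce = params.chemo_start_age, params.chemo_end_age
    while t < t_to - 1e-12:
        during_chemo = with_chemo and cs <= t < ce
        # the step spans (t, t + dt]; aim for the schedule at its end so the
        # floor is reached exactly at chemo end and size n exactly at recovery
        target = _target_size(t + dt, params, with_chemo)
        if size > target:           # bottleneck: excess death, no division
            idx = pick_victim(during_chemo)
            size -= 1
            clone[idx] = clone[size]
            drivers[idx] = drivers[size]
            resistant[idx] = resistant[size]
            t += dt
            continue
        if size < target:           # recovery: excess division, no death
            parent = pick_parent()
            child = size
            size += 1
        else:                       # constant-size Moran step
            child = pick_victim(during_chemo)
            parent = pick_parent()
        clone[child] = clone[parent]
        drivers[child] = drivers[parent]
        resistant[child] = resistant[parent]
        if u > 0.0 and ub.u() < u:
            drivers[child] += 1
            if drivers[child] > max_drivers:
                max_drivers = int(drivers[child])
        if m > 0.0 and t <= ce and ub.u() < m:
            resistant[child] = True
        t += dt

    state.size, state.age = size, t
    return state


def apply_chemotherapy(state: PopulationState, params: SimulationParams,
                       rng: np.random.Generator,
                       resistant_deaths: bool = False) -> PopulationState:
    """Run the bottleneck + recovery phase (chemo start to end of recovery)."""
    scenario = "chemo_resistant" if resistant_deaths else "chemo"
    if state.age < params.chemo_start_age:
        raise ValueError("state has not reached chemo_start_age")
    return _advance(state, params, scenario,
                    params.chemo_end_age + params.beta, rng)


# ----------------------------------------------------------------------
# scenario runner
# ----------------------------------------------------------------------

@dataclass
class DiversityTrajectory:
    """Per-replicate diversity over time for one scenario."""
    scenario: str
    params: SimulationParams
    data: pd.DataFrame          # time, replicate, shannon, simpson, population_size

    def mean_at(self, time: float, column: str = "shannon") -> float:
        sel = self.data[np.isclose(self.data["time"], time)]
        return float(sel[column].mean())


def replicate_seeds(master_seed: int, replicates: int) -> list[np.random.Generator]:
    """Independent per-replicate generators via SeedSequence spawning."""
    return [np.random.default_rng(ss)
            for ss in np.random.SeedSequence(master_seed).spawn(replicates)]


def run_scenario(scenario: str, params: SimulationParams, replicates: int,
                 record_every: float = 5.0,
                 subsample_size: Optional[int] = None,
                 subsample_reps: int = 1) -> DiversityTrajectory:
    """Simulate a scenario and record clone-level diversity on a time grid.

    Scenarios: "neutral" (no fitness effects), "drivers" (selection s on
    driver mutations), "chemo" (drivers + bottleneck), "chemo_resistant"
    (chemo + death-resistant mutants). With ``subsample_size`` set, the
    indices are computed on random subsamples of that many cells
    (emulating sequencing a finite number of colonies).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    grid = np.arange(0.0, params.t_end + 1e-9, record_every)
    rows = []
    for rep, rng in enumerate(replicate_seeds(params.seed, replicates)):
        state = PopulationState.initial(params.n)
        for t in grid:
            if t > 0:
                _advance(state, params, scenario, t, rng)
            if subsample_size is not None and subsample_size < state.size:
                sub_seed = int(rng.integers(2 ** 31))
                sh = float(np.mean(subsample_diversity(
                    state.clone[:state.size], subsample_size,
                    subsample_reps, sub_seed, "shannon")))
                si = float(np.mean(subsample_diversity(
                    state.clone[:state.size], subsample_size,
                    subsample_reps, sub_seed + 1, "simpson")))
            else:
                sizes = state.clone_sizes()
                sh = shannon_index(sizes)
                si = simpson_index(sizes)
            rows.append((float(t), rep, sh, si, state.size))
    data = pd.DataFrame(rows, columns=["time", "replicate", "shannon",
                                       "simpson", "population_size"])
    return DiversityTrajectory(scenario, params, data)


# ----------------------------------------------------------------------
# fixation helpers (drift/selection oracles at small n)
# ----------------------------------------------------------------------

def simulate_fixation(n: int, initial_mutants: int, s: float,
                      rng: np.random.Generator,
                      max_steps: Optional[int] = None) -> bool:
    """Run a plain Moran process until the focal lineage fixes or dies out.

    The focal lineage starts with ``initial_mutants`` cells carrying one
    driver (fitness 1 + s); no new mutations occur. Returns True on
    fixation. Under neutrality (s = 0) the fixation probability is the
    initial frequency; with selection it is (1 - 1/r) / (1 - 1/r^n) for
    r = 1 + s.
    """
    k = initial_mutants
    if max_steps is None:
        max_steps = 500 * n * n
    for _ in range(max_steps):
        if k == 0 or k == n:
            return k == n
        # victim uniform; parent weighted: mutant with prob k r / (k r + (n-k))
        r = 1.0 + s
        p_mut_parent = k * r / (k * r + (n - k))
        parent_mut = rng.random() < p_mut_parent
        victim_mut = rng.random() < k / n
        if parent_mut and not victim_mut:
            k += 1
        elif victim_mut and not parent_mut:
            k -= 1
    raise RuntimeError("no absorption within max_steps")
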