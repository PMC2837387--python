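"""Generic delayed stochastic simulation algorithm (delayed SSA).

The delayed SSA extends Gillespie's direct method with a *waitlist*: a
reaction may, in addition to its instantaneous products, schedule *delayed*
products that appear a (possibly random) time after the reaction fires.
Writing ``A -> B + C(tau)`` means B is produced when the reaction fires and
C is released ``tau`` seconds later.  A single reaction may carry any number
of delayed products, each with its own delay distribution.

One iteration of the algorithm:

1. generate a candidate reaction and its firing time ``t + t1`` by the
   standard SSA,
2. if the waitlist is empty or ``t1`` is smaller than the earliest pending
   release, advance to ``t + t1``, apply the reaction, and enqueue its
   delayed products,
3. otherwise advance to the earliest release time and release that entry
   (ties between a reaction and a release go to the waitlist; equal release
   times are served first-in-first-out).

The candidate drawn in step 1 is discarded whenever a release wins; because
exponential clocks are memoryless this does not bias the process.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DelaySpec",
    "Reaction",
    "ReactionSystem",
    "SystemState",
    "EventRecord",
    "SimulationExhausted",
    "sample_delay",
    "propensity",
    "step",
    "run",
]


class SimulationExhausted(Exception):
    """All propensities are zero and the waitlist is empty: nothing can fire."""


@dataclass(frozen=True)
class DelaySpec:
    """Distribution of a delayed-product release time, in seconds.

    kind
        ``"constant"`` (delay = param1), ``"gaussian"`` (mean param1, std
        param2, redrawn until positive) or ``"exponential"`` (mean param1).
    """

    kind: str
    param1: float
    param2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gaussian", "exponential"):
            raise ValueError(f"unknown delay kind {self.kind!r}")
        if not (math.isfinite(self.param1) and math.isfinite(self.param2)):
            raise ValueError("delay parameters must be finite")
        if self.param1 < 0:
            raise ValueError("delay param1 must be >= 0")
        if self.kind == "gaussian" and self.param2 < 0:
            raise ValueError("gaussian delay std must be >= 0")

    @property
    def mean(self) -> float:
        return self.param1


def sample_delay(spec: DelaySpec, rng: np.random.Generator) -> float:
    """Draw one delay from ``spec``.

    Gaussian delays are redrawn until strictly positive; for every
    distribution used here sigma/mu <= 1/3, so the truncation bias is
    negligible.  Exponential and constant delays are clamped away from
    exactly zero so a delayed product never releases at the firing instant.
    """
    if spec.kind == "constant":
        return spec.param1 if spec.param1 > 0 else 5e-324
    if spec.kind == "exponential":
        d = rng.exponential(spec.param1) if spec.param1 > 0 else 0.0
        return d if d > 0 else 5e-324
    # gaussian
    if spec.param2 == 0:
        return spec.param1 if spec.param1 > 0 else 5e-324
    while True:
        d = rng.normal(spec.param1, spec.param2)
        if d > 0:
            return d


@dataclass(frozen=True)
class Reaction:
    """A reaction with optional delayed products.

    ``reactants`` and ``instant_products`` map species name to stoichiometric
    count; ``delayed_products`` is a list of ``(species, DelaySpec)`` pairs,
    one entry per delayed copy produced.
    """

    reactants: Mapping[str, int]
    instant_products: Mapping[str, int]
    rate_constant: float
    delayed_products: Sequence[tuple[str, DelaySpec]] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.rate_constant < 0 or not math.isfinite(self.rate_constant):
            raise ValueError("rate_constant must be finite and >= 0")


@dataclass
class ReactionSystem:
    reactions: list[Reaction]

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for s in r.reactants:
                seen.setdefault(s)
            for s in r.instant_products:
                seen.setdefault(s)
            for s, _ in r.delayed_products:
                seen.setdefault(s)
        return list(seen)


@dataclass
class SystemState:
    """Simulation clock, species counts and the waitlist of pending releases.

    The waitlist is a heap of ``(release_time, insertion_seq, species)``;
    the insertion sequence number makes equal release times FIFO.
    """

    t: float = 0.0
    counts: dict[str, int] = field(default_factory=dict)
    waitlist: list[tuple[float, int, str]] = field(default_factory=list)
    _seq: int = 0

    def push_delayed(self, release_time: float, species: str) -> None:
        heapq.heappush(self.waitlist, (release_time, self._seq, species))
        self._seq += 1


@dataclass(frozen=True)
class EventRecord:
    time: float
    kind: str                 # "reaction" | "release"
    label: str                # reaction name/index or species released


def propensity(reaction: Reaction, counts: Mapping[str, int]) -> float:
    """Stochastic propensity: rate constant times falling-factorial counts.

    For a reactant with stoichiometry m and copy number x the contribution is
    x (x-1) ... (x-m+1) / m!, the number of distinct reactant combinations.
    """
    a = reaction.rate_constant
    for sp, m in reaction.reactants.items():
        x = counts.get(sp, 0)
        if x < m:
            return 0.0
        if m == 1:
            a *= x
        else:
            a *= math.comb(x, m)
    return a


def _apply_reaction(r: Reaction, state: SystemState, rng: np.random.Generator) -> None:
    for sp, m in r.reactants.items():
        state.counts[sp] = state.counts.get(sp, 0) - m
        if state.counts[sp] < 0:  # pragma: no cover - guarded by propensity
            raise RuntimeError(f"negative count for {sp}")
    for sp, m in r.instant_products.items():
        state.counts[sp] = state.counts.get(sp, 0) + m
    for sp, spec in r.delayed_products:
        state.push_delayed(state.t + sample_delay(spec, rng), sp)


def step(
    system: ReactionSystem, state: SystemState, rng: np.random.Generator
) -> EventRecord:
    """Advance the system by one event (one reaction firing or one release).

    Raises :class:`SimulationExhausted` when no reaction can fire and the
    waitlist is empty.
    """
    props = [propensity(r, state.counts) for r in system.reactions]
    a0 = sum(props)

    t1 = math.inf
    if a0 > 0:
        t1 = rng.exponential(1.0 / a0)

    if state.waitlist:
        t_min = state.waitlist[0][0] - state.t
        if t1 >= t_min:  # waitlist wins ties, per the algorithm's step 4
            release_time, _, sp = heapq.heappop(state.waitlist)
            state.t = max(state.t, release_time)
            state.counts[sp] = state.counts.get(sp, 0) + 1
            return EventRecord(state.t, "release", sp)
    elif not math.isfinite(t1):
        raise SimulationExhausted(
            "all propensities are zero and the waitlist is empty"
        )

    # reaction R1 fires at t + t1
    state.t += t1
    u = rng.random() * a0
    acc = 0.0
    idx = len(props) - 1
    for i, p in enumerate(props):
        acc += p
        if u < acc:
            idx = i
            break
    r = system.reactions[idx]
    _apply_reaction(r, state, rng)
    return EventRecord(state.t, "reaction", r.name or str(idx))


def run(
    system: ReactionSystem,
    state: SystemState,
    t_stop: float,
    sample_dt: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    record_species: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, list[EventRecord]]:
    """Run the delayed SSA until the clock passes ``t_stop``.

    Returns the species counts sampled on the regular grid
    ``state.t, state.t + sample_dt, ...`` (as a DataFrame with a ``time``
    column) together with the full event log.  Sampling uses the value held
    *just before* each grid time, i.e. the trajectory is piecewise constant
    between events.
    """
    if t_stop <= state.t:
        raise ValueError("t_stop must exceed the current time")
    if sample_dt <= 0:
        raise ValueError("sample_dt must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    species = list(record_species) if record_species is not None else system.species
    grid = [state.t]
    samples = [[state.counts.get(s, 0) for s in species]]
    next_t = state.t + sample_dt
    log: list[EventRecord] = []

    while state.t < t_stop:
        prev_counts = [state.counts.get(s, 0) for s in species]
        try:
            ev = step(system, state, rng)
        except SimulationExhausted:
            state.t = t_stop
            ev = None
        while next_t <= min(state.t, t_stop):
            grid.append(next_t)
            samples.append(prev_counts)
            next_t += sample_dt
        if ev is None:
            break
        if ev.time <= t_stop:
            log.append(ev)

    ts = pd.DataFrame(samples, columns=species)
    ts.insert(0, "time", grid)
    return ts, log
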