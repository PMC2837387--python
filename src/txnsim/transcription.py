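"""Single-nucleotide transcription model of a bacterial gene.

The model follows an RNA polymerase (RNAP) through initiation (promoter
binding at ``k_init`` followed by the open-complex delay ``tau_oc``),
stepwise elongation over ``N`` nucleotides (move at ``k_move``, nucleotide
activation at ``k_act``; the first ``alpha`` nucleotides activate at the
slower ``k_act_first``), the competing residence pathways (ubiquitous
pausing, arrest, misincorporation and editing, pyrophosphorolysis,
premature termination) and termination (transcript release at ``k_f``).
An RNAP occupies ``2 * delta + 1`` nucleotides; steric hindrance between
footprints produces blocked moves and, against a paused leader, collisions.
Default rate constants are E. coli measurements for the 2445-nt tsr-venus
template.

Sequence-specific long-pause sites (e.g. hairpin-stabilised pauses such as
the his-operon leader pause) are positional: on first arrival at the site
each RNAP enters a long pause with ``occurrence_prob``, stays for an
exponential time of the given mean, and can terminate prematurely on exit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _core
from .engine import DelaySpec

__all__ = [
    "TranscriptionParams",
    "PauseSiteSpec",
    "GeneSystem",
    "build_gene_system",
    "simulate_transcription",
    "apply_collision",
    "expected_initiation_interval",
    "expected_activations_per_pause",
    "expected_traversal_time",
    "expected_on_template_time",
    "effective_elongation_velocity",
    "completion_survival_fraction",
]


@dataclass(frozen=True)
class TranscriptionParams:
    """Rate constants and delays of the transcription model (units: s, 1/s).

    Defaults are the E. coli parameter set for the 2445-nt template:
    28 RNAPs, initiation at 0.0148 1/s, a Gaussian 40 +/- 4 s open-complex
    delay, 150 1/s move and activation rates (75 nt/s effective speed),
    pausing at 0.55 1/s with 3 s mean exponential duration, and the measured
    arrest / editing / misincorporation / pyrophosphorolysis / premature-
    termination constants.
    """

    N: int = 2445
    n_rnap: int = 28
    k_init: float = 0.0148
    tau_oc: DelaySpec = field(default_factory=lambda: DelaySpec("gaussian", 40.0, 4.0))
    k_move: float = 150.0
    k_act: float = 150.0
    alpha: int = 10
    k_act_first: float = 30.0
    delta: int = 12
    k_pause: float = 0.55
    d_pause: float = 3.0
    p_collision_pause: float = 0.2
    k_arrest: float = 0.00027
    d_arrest: float = 100.0
    k_error_correct: float = 0.00875
    d_correct: float = 5.0
    k_mis: float = 0.05
    k_pyro: float = 0.75
    k_prem: float = 0.00019
    k_f: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "k_init", "k_move", "k_act", "k_act_first", "k_pause", "d_pause",
            "p_collision_pause", "k_arrest", "d_arrest", "k_error_correct",
            "d_correct", "k_mis", "k_pyro", "k_prem", "k_f",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0 (got {v})")
        if not 0 <= self.p_collision_pause <= 1:
            raise ValueError("p_collision_pause must be a probability")
        if self.N <= 2 * self.delta + 1:
            raise ValueError("template must be longer than one RNAP footprint")
        if self.alpha >= self.N:
            raise ValueError("alpha must be smaller than the template length")

    def without_alternative_pathways(self) -> "TranscriptionParams":
        """Copy with pausing, arrest, editing, pyrophosphorolysis and
        premature termination switched off (pure stepwise elongation)."""
        return replace(
            self, k_pause=0.0, k_arrest=0.0, k_error_correct=0.0,
            k_mis=0.0, k_pyro=0.0, k_prem=0.0,
        )


@dataclass(frozen=True)
class PauseSiteSpec:
    """A sequence-specific long-pause site (1-based nucleotide position)."""

    position: int
    occurrence_prob: float
    mean_duration: float
    premature_term_prob: float = 0.0
    once_per_rnap: bool = True

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be a 1-based nucleotide index")
        for p in (self.occurrence_prob, self.premature_term_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_duration <= 0:
            raise ValueError("mean_duration must be positive")


class GeneSystem:
    """The reaction system of one gene: per-nucleotide channel table.

    Thin structured description consumed by the simulator core; ``species``
    enumerates the per-nucleotide occupancy states the channels act on.
    """

    def __init__(self, params: TranscriptionParams, pause_sites=()):
        self.params = params
        self.pause_sites = tuple(pause_sites)
        seen = set()
        for s in self.pause_sites:
            if s.position in seen:
                raise ValueError(
                    f"overlapping long-pause sites at nucleotide {s.position}"
                )
            seen.add(s.position)

    @property
    def n_nucleotides(self) -> int:
        return self.params.N

    @property
    def species(self) -> list[str]:
        """Occupancy species: O_n / A_n / U_n per nucleotide plus the pools."""
        out = ["Pro", "RNAP", "RNAP.Pro", "R"]
        for n in range(1, self.params.N + 1):
            out += [f"O_{n}", f"A_{n}", f"U_{n}"]
        return out

    @property
    def has_pausing(self) -> bool:
        return self.params.k_pause > 0 and self.params.d_pause > 0

    def make_unit(self, ep=None, record_events: bool = False) -> _core.GeneUnit:
        return _core.GeneUnit(
            self.params, self.pause_sites, ep=ep, record_events=record_events
        )


def build_gene_system(
    params: TranscriptionParams, pause_sites=()
) -> GeneSystem:
    """Assemble the transcription reaction system for one gene."""
    return GeneSystem(params, pause_sites)


def simulate_transcription(
    params: TranscriptionParams,
    pause_sites=(),
    t_stop: float = 3300.0,
    seed: int | None = None,
    sample_dt: float = 1.0,
    deg_R: float = 0.0,
    record_events: bool = False,
    check_invariants: bool = False,
):
    """Simulate transcription of a single gene (no translation).

    Returns ``(time_series, log)`` where the time series is a DataFrame with
    columns ``time`` and ``rna`` (free RNA count; subject to first-order
    degradation if ``deg_R`` > 0) and ``log`` is the gene's event log with
    the exact completion times and event counters.
    """
    if t_stop <= 0:
        raise ValueError("t_stop must be positive")
    system = build_gene_system(params, pause_sites)
    ep = _DegOnly(deg_R) if deg_R > 0 else None
    unit = system.make_unit(ep=ep, record_events=record_events)
    sim = _core.Simulation([unit], seed=seed, check_invariants=check_invariants)
    res = sim.run(t_stop, sample_dt=sample_dt)
    ts = pd.DataFrame({"time": res["times"], "rna": res["samples"][:, 0]})
    return ts, unit.log


@dataclass(frozen=True)
class _DegOnly:
    """Minimal expression block: RNA degradation only, no translation."""

    deg_R: float
    k_tr: float = 0.0
    n_rib: int = 0
    tau1: float = 0.0
    tau2: float = 0.0
    tau3: DelaySpec = field(default_factory=lambda: DelaySpec("constant", 0.0))
    deg_P: float = 0.0


def apply_collision(gene_unit: _core.GeneUnit, trailing_idx: int, rng) -> str:
    """Resolve a collision between an activated trailing RNAP and its paused
    leader; returns ``"leader_released"`` or ``"trailing_paused"``."""
    u = rng.random() if hasattr(rng, "random") else float(rng)
    return _core.apply_collision(gene_unit, trailing_idx, u)


# ----------------------------------------------------------- expectations

def expected_initiation_interval(params: TranscriptionParams) -> float:
    """Mean time between transcription initiations:
    ``1 / (n_rnap * k_init) + mean(tau_oc)`` (promoter clearance neglected).
    """
    if params.k_init <= 0 or params.n_rnap <= 0:
        return math.inf
    return 1.0 / (params.n_rnap * params.k_init) + params.tau_oc.mean


def effective_elongation_velocity(params: TranscriptionParams) -> float:
    """Mean speed of unobstructed stepwise elongation, nt/s:
    ``(1/k_move + 1/k_act)^-1`` (75 nt/s at defaults)."""
    return 1.0 / (1.0 / params.k_move + 1.0 / params.k_act)


def expected_activations_per_pause(params: TranscriptionParams) -> float:
    """Mean number of activation events between successive pause events.

    The pause hazard acts over the whole residence at a nucleotide, so one
    pause occurs per ``v_eff / k_pause`` activations (~136 at defaults).
    """
    if params.k_pause <= 0:
        return math.inf
    return effective_elongation_velocity(params) / params.k_pause


def expected_traversal_time(params: TranscriptionParams) -> float:
    """Approximate mean time for one RNAP to traverse the template.

    Base dwell ``N (1/k_move + 1/k_act)`` inflated by the expected time
    spent in pauses, arrests and editing halts, plus a small
    pyrophosphorolysis correction (each backward step must be re-traversed).
    Collisions, the slower first-``alpha`` activation and the terminal
    transcript-release wait are not included; see
    :func:`expected_on_template_time` for the full residence expectation.
    """
    if params.N == 0:
        return 0.0
    dwell = 1.0 / params.k_move + 1.0 / params.k_act
    base = params.N * dwell
    load = (
        params.k_pause * params.d_pause
        + params.k_arrest * params.d_arrest
        + params.k_error_correct * params.d_correct
    )
    pyro_extra = params.N * params.k_pyro * dwell * dwell * (1.0 + load)
    return base * (1.0 + load) + pyro_extra


def expected_on_template_time(params: TranscriptionParams) -> float:
    """Mean time from elongation start to transcript release for one
    unobstructed RNAP: traversal plus the slower activation of the first
    ``alpha`` nucleotides and the ``1/k_f`` release wait."""
    first = (
        min(params.alpha, params.N)
        * (1.0 / params.k_act_first - 1.0 / params.k_act)
        if params.k_act_first > 0
        else 0.0
    )
    release = 1.0 / params.k_f if params.k_f > 0 else math.inf
    return expected_traversal_time(params) + first + release


def completion_survival_fraction(params: TranscriptionParams) -> float:
    """Probability that an initiated RNAP completes its transcript, under
    the premature-termination hazard alone: ``exp(-k_prem * N * dwell)``."""
    dwell = 1.0 / params.k_move + 1.0 / params.k_act
    return math.exp(-params.k_prem * params.N * dwell)
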