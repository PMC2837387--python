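"""Shared event loop for the single-nucleotide gene models.

This module implements the delayed-SSA waitlist algorithm (see
:mod:`txnsim.engine`) specialized to the transcription template: instead of
per-nucleotide species counts it tracks each RNA polymerase (RNAP) as a
record carrying its position, kinetic phase and per-molecule flags.  The two
representations are equivalent — RNAPs cannot pass one another, so the
multiset of (position, phase) pairs *is* the species state — but the tracker
makes per-RNAP features (misincorporation flags, once-per-RNAP long-pause
sites, "resume in the sub-state the pause started from") direct, and keeps
the propensity update local to the fired molecule and its two neighbours.

Kinetic scheme per RNAP on the template (positions are 1-based; an RNAP at
position n occupies nucleotides [n - delta, n + delta]):

* occupied ``O_n``: activation at ``k_act`` (``k_act_first`` for the first
  ``alpha`` nucleotides) -> ``A_n``.
* activated ``A_n``: move to ``O_{n+1}`` at ``k_move`` if nucleotide
  ``n + delta + 1`` is not covered by the next RNAP; at the last nucleotide,
  transcript release at ``k_f`` frees the RNAP and emits one RNA.
* residence hazards, active in both ``O`` and ``A``: pause entry
  (``k_pause``), arrest (``k_arrest``, fixed ``d_arrest`` recovery),
  misincorporation (``k_mis``, sets a flag) / editing of a flagged RNAP
  (``k_error_correct``, fixed ``d_correct`` halt), pyrophosphorolysis
  (``k_pyro``, one step backwards if the backward footprint is free) and
  premature termination (``k_prem``, RNAP released without product).
* paused RNAPs exit spontaneously at rate ``1/d_pause`` (exponential
  durations) or through a collision: a trailing activated RNAP whose move is
  blocked by an adjacent paused leader carries a collision channel at
  ``k_move``; with probability ``1 - p_collision_pause`` the leader is
  pushed back into its pre-pause sub-state, otherwise the trailing RNAP
  pauses as well.

The promoter cycles free -> open-complex delay (Gaussian ``tau_oc``) ->
cleared complex -> (elongation start at ``k_move`` once the first
``delta + 1`` nucleotides are free) -> free.  The cellular RNAP pool is a
constant reservoir: ``n_rnap`` polymerases are available for initiation at
all times, so the initiation propensity is ``k_init * n_rnap`` whenever the
promoter is free, independent of how many RNAPs are on the template.  Expression adds translation as
a multi-delayed reaction (RNA sequestered for ``tau1``, ribosome for
``tau2``, protein finished after ``tau3``) and first-order degradation of
free RNA and free protein; the repressilator adds repressor
binding/unbinding and bound-protein degradation on each promoter.
"""

from __future__ import annotations

import heapq
import math
from typing import Sequence

import numpy as np

from .engine import DelaySpec, sample_delay

# RNAP phases
O, A, PAUSED, LONGPAUSED, ARRESTED, EDITING = range(6)
PHASE_NAMES = ("occupied", "activated", "paused", "long_paused", "arrested", "editing")

# promoter states
PROM_FREE, PROM_OC, PROM_CLEAR, PROM_BOUND = range(4)

# waitlist entry codes
W_OC, W_ARREST, W_EDIT, W_R, W_RIB, W_P = range(6)

# per-RNAP channel codes
ACT, MOVE, TERM, PAUSE, UNPAUSE, LP_EXIT, ARREST_GO, MIS, EDIT_GO, PYRO, PREM = range(11)

# collision outcomes
LEADER_RELEASED = "leader_released"
TRAILING_PAUSED = "trailing_paused"


class Rnap:
    """One RNA polymerase on (or headed to) the template."""

    __slots__ = ("pos", "phase", "mis", "prev_phase", "lp_drawn", "pause_t0", "rate")

    def __init__(self, pos: int):
        self.pos = pos
        self.phase = O
        self.mis = False
        self.prev_phase = O
        self.lp_drawn = False
        self.pause_t0 = 0.0
        self.rate = 0.0


class GeneLog:
    """Event log of one gene: completion times, counters, optional records."""

    __slots__ = (
        "completion_times", "initiation_times", "pause_durations", "records",
        "n_init", "n_act", "n_move", "n_pause", "n_unpause", "n_collision",
        "n_collision_paused", "n_arrest", "n_mis", "n_edit", "n_pyro",
        "n_prem", "n_lp", "n_lp_term", "n_completions",
    )

    def __init__(self) -> None:
        self.completion_times: list[float] = []
        self.initiation_times: list[float] = []
        self.pause_durations: list[float] = []
        self.records: list[tuple[float, str, int]] = []
        self.n_init = 0
        self.n_act = 0
        self.n_move = 0
        self.n_pause = 0
        self.n_unpause = 0
        self.n_collision = 0
        self.n_collision_paused = 0
        self.n_arrest = 0
        self.n_mis = 0
        self.n_edit = 0
        self.n_pyro = 0
        self.n_prem = 0
        self.n_lp = 0
        self.n_lp_term = 0
        self.n_completions = 0


class GeneUnit:
    """State and cached propensities of one gene (template + expression)."""

    def __init__(self, tp, pause_sites=(), ep=None, record_events: bool = False):
        self.tp = tp
        self.ep = ep
        self.N = int(tp.N)
        self.delta = int(tp.delta)
        self.excl = 2 * self.delta + 1          # minimum distance between RNAP positions
        self.alpha = int(tp.alpha)
        sites = {}
        for s in pause_sites or ():
            if s.position in sites:
                raise ValueError(f"duplicate long-pause site at nucleotide {s.position}")
            if not (1 <= s.position <= self.N):
                raise ValueError("long-pause site outside the template")
            sites[int(s.position)] = s
        self.sites = sites
        # pause entry is a no-op when the rate or mean duration is zero
        if tp.k_pause > 0 and tp.d_pause > 0:
            self.kp = float(tp.k_pause)
            self.pause_exit = 1.0 / float(tp.d_pause)
        else:
            self.kp = 0.0
            self.pause_exit = 0.0

        self.rnaps: list[Rnap] = []             # leader (largest position) first
        self.prom = PROM_FREE
        self.free_rnap = int(tp.n_rnap)
        self.rnap_sum = 0.0

        self.R_free = 0
        self.P_free = 0
        self.rib_free = int(ep.n_rib) if ep is not None else 0
        self.n_R_waitlisted = 0
        self.n_rib_waitlisted = 0

        # per-event cached non-RNAP channel rates (refreshed every iteration)
        self.c_init = self.c_clear = self.c_tr = 0.0
        self.c_degR = self.c_degP = 0.0
        self.c_bind = self.c_unbind = self.c_bdeg = 0.0
        self.other_total = 0.0

        self.log = GeneLog()
        self.record_events = record_events

    # ------------------------------------------------------------------ rates

    def channels(self, i: int) -> list[tuple[float, int]]:
        """Active kinetic channels of RNAP ``i`` as (rate, code) pairs."""
        rn = self.rnaps[i]
        ph = rn.phase
        if ph == PAUSED:
            return [(self.pause_exit, UNPAUSE)] if self.pause_exit > 0 else []
        if ph == LONGPAUSED:
            site = self.sites[rn.pos]
            return [(1.0 / site.mean_duration, LP_EXIT)]
        if ph == ARRESTED or ph == EDITING:
            return []
        tp = self.tp
        n = rn.pos
        out: list[tuple[float, int]] = []
        if ph == O:
            k = tp.k_act_first if n <= self.alpha else tp.k_act
            if k > 0:
                out.append((k, ACT))
        else:  # activated
            if n == self.N:
                if tp.k_f > 0:
                    out.append((tp.k_f, TERM))
            else:
                ahead = self.rnaps[i - 1] if i > 0 else None
                if ahead is None or ahead.pos - n > self.excl:
                    out.append((tp.k_move, MOVE))
                elif ahead.pos - n == self.excl and (
                    ahead.phase == PAUSED or ahead.phase == LONGPAUSED
                ):
                    out.append((tp.k_move, MOVE))  # resolved as a collision
        if self.kp > 0:
            out.append((self.kp, PAUSE))
        if tp.k_arrest > 0:
            out.append((tp.k_arrest, ARREST_GO))
        if rn.mis:
            if tp.k_error_correct > 0:
                out.append((tp.k_error_correct, EDIT_GO))
        elif tp.k_mis > 0:
            out.append((tp.k_mis, MIS))
        if tp.k_prem > 0:
            out.append((tp.k_prem, PREM))
        if tp.k_pyro > 0 and n > 1:
            behind = self.rnaps[i + 1] if i + 1 < len(self.rnaps) else None
            if behind is None or (n - 1) - behind.pos >= self.excl:
                out.append((tp.k_pyro, PYRO))
        return out

    def rate_of(self, i: int) -> float:
        return sum(r for r, _ in self.channels(i))

    def update_rnap(self, i: int) -> None:
        rn = self.rnaps[i]
        new = self.rate_of(i)
        self.rnap_sum += new - rn.rate
        rn.rate = new

    def update_around(self, i: int) -> None:
        lo = max(0, i - 1)
        hi = min(len(self.rnaps) - 1, i + 1)
        for k in range(lo, hi + 1):
            self.update_rnap(k)

    def resync(self) -> None:
        """Recompute the cached propensity sum (kills floating-point drift)."""
        s = 0.0
        for i, rn in enumerate(self.rnaps):
            rn.rate = self.rate_of(i)
            s += rn.rate
        self.rnap_sum = s

    def clearance_open(self) -> bool:
        """True when nucleotides 1..delta+1 are free for a fresh RNAP."""
        return not self.rnaps or self.rnaps[-1].pos >= self.excl + 1

    # -------------------------------------------------------------- occupancy

    def occupied_intervals(self) -> list[tuple[int, int]]:
        return [
            (max(1, r.pos - self.delta), min(self.N, r.pos + self.delta))
            for r in self.rnaps
        ]

    def check_invariants(self) -> None:
        prev = None
        for r in self.rnaps:
            if prev is not None and prev - r.pos < self.excl:
                raise AssertionError(
                    f"overlapping footprints: positions {prev} and {r.pos}"
                )
            prev = r.pos
        # the initiation reservoir is constant by assumption
        if self.free_rnap != self.tp.n_rnap:
            raise AssertionError("initiation reservoir changed size")
        if self.ep is not None:
            if self.rib_free + self.n_rib_waitlisted != self.ep.n_rib:
                raise AssertionError("ribosome conservation violated")
        if self.R_free < 0 or self.P_free < 0 or self.free_rnap < 0:
            raise AssertionError("negative count")


class Simulation:
    """Delayed-SSA run over one or more gene units, sharing one clock and RNG.

    ``net`` (optional) is a repressilator parameter object adding the
    promoter repression channels; gene ``i`` is then repressed by the protein
    of gene ``i - 1`` (ring topology).
    """

    RESYNC_EVERY = 16384
    _U_BUF = 1 << 15

    def __init__(
        self,
        genes: Sequence[GeneUnit],
        seed: int | None = None,
        rng: np.random.Generator | None = None,
        net=None,
        check_invariants: bool = False,
    ):
        self.genes = list(genes)
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        self.net = net
        self.check = check_invariants
        self.t = 0.0
        self.waitlist: list[tuple[float, int, int, int, Rnap | None]] = []
        self._seq = 0
        self._u = self.rng.random(self._U_BUF)
        self._ui = 0

    # ------------------------------------------------------------------- rng

    def _next_u(self) -> float:
        i = self._ui
        if i >= self._U_BUF:
            self._u = self.rng.random(self._U_BUF)
            i = 0
        self._ui = i + 1
        return self._u[i]

    # --------------------------------------------------------------- waitlist

    def _push(self, when: float, code: int, gi: int, payload: Rnap | None) -> None:
        heapq.heappush(self.waitlist, (when, self._seq, code, gi, payload))
        self._seq += 1

    # ------------------------------------------------------------ run control

    def run(
        self,
        t_stop: float,
        sample_dt: float = 1.0,
        sample: bool = True,
    ) -> dict:
        """Advance until ``t_stop``; return sampled counts and per-gene logs.

        The sampled series are piecewise constant: the value reported at a
        grid time is the state immediately before that instant.
        """
        if t_stop <= self.t:
            raise ValueError("t_stop must exceed the current time")
        if sample_dt <= 0:
            raise ValueError("sample_dt must be positive")

        genes = self.genes
        net = self.net
        ng = len(genes)
        times: list[float] = []
        rows: list[list[int]] = []
        next_sample = self.t if sample else math.inf
        since_resync = 0

        def take_samples(up_to: float) -> None:
            nonlocal next_sample
            while next_sample <= up_to:
                times.append(next_sample)
                row: list[int] = []
                for g in genes:
                    row.append(g.R_free)
                    row.append(g.P_free)
                rows.append(row)
                next_sample += sample_dt

        while self.t < t_stop:
            a0 = 0.0
            for gi in range(ng):
                g = genes[gi]
                tp = g.tp
                c_init = (
                    tp.k_init * g.free_rnap if g.prom == PROM_FREE and g.free_rnap > 0 else 0.0
                )
                c_clear = tp.k_move if g.prom == PROM_CLEAR and g.clearance_open() else 0.0
                other = c_init + c_clear
                ep = g.ep
                if ep is not None:
                    c_tr = ep.k_tr * g.R_free * g.rib_free
                    c_degR = ep.deg_R * g.R_free
                    c_degP = ep.deg_P * g.P_free
                    other += c_tr + c_degR + c_degP
                    g.c_tr, g.c_degR, g.c_degP = c_tr, c_degR, c_degP
                if net is not None:
                    rep = genes[gi - 1]  # protein of the previous gene in the ring
                    c_bind = net.k_r * rep.P_free if g.prom == PROM_FREE else 0.0
                    if g.prom == PROM_BOUND:
                        c_unbind = net.k_u
                        c_bdeg = net.k_dp
                    else:
                        c_unbind = c_bdeg = 0.0
                    other += c_bind + c_unbind + c_bdeg
                    g.c_bind, g.c_unbind, g.c_bdeg = c_bind, c_unbind, c_bdeg
                g.c_init, g.c_clear = c_init, c_clear
                g.other_total = other
                a0 += other + g.rnap_sum

            if a0 > 1e-13:
                u = self._next_u()
                t_next = self.t - math.log(1.0 - u) / a0
            else:
                t_next = math.inf

            wl = self.waitlist
            if wl and wl[0][0] <= t_next:
                when, _, code, gi, payload = heapq.heappop(wl)
                if when > t_stop:
                    heapq.heappush(wl, (when, _, code, gi, payload))
                    take_samples(t_stop)
                    self.t = t_stop
                    break
                take_samples(when)
                self.t = when
                self._apply_release(code, gi, payload)
                if self.check:
                    genes[gi].check_invariants()
                continue

            if not math.isfinite(t_next):
                # nothing can fire and the waitlist is empty: exhausted
                take_samples(t_stop)
                self.t = t_stop
                break

            if t_next > t_stop:
                take_samples(t_stop)
                self.t = t_stop
                break

            take_samples(t_next)
            self.t = t_next

            x = self._next_u() * a0
            gi = ng - 1
            for k in range(ng):
                g = genes[k]
                tot = g.other_total + g.rnap_sum
                if x < tot or k == ng - 1:
                    gi = k
                    break
                x -= tot
            self._dispatch(gi, x)
            if self.check:
                genes[gi].check_invariants()

            since_resync += 1
            if since_resync >= self.RESYNC_EVERY:
                since_resync = 0
                for g in genes:
                    g.resync()

        out: dict = {
            "times": np.asarray(times),
            "samples": np.asarray(rows, dtype=np.int64).reshape(len(times), 2 * ng),
            "logs": [g.log for g in genes],
        }
        return out

    # ------------------------------------------------------------ dispatchers

    def _dispatch(self, gi: int, x: float) -> None:
        g = self.genes[gi]
        if x < g.other_total:
            if x < g.c_init:
                self._fire_initiation(g, gi)
                return
            x -= g.c_init
            if x < g.c_clear:
                self._fire_clearance(g, gi)
                return
            x -= g.c_clear
            if g.ep is not None:
                if x < g.c_tr:
                    self._fire_translation(g, gi)
                    return
                x -= g.c_tr
                if x < g.c_degR:
                    g.R_free -= 1
                    return
                x -= g.c_degR
                if x < g.c_degP:
                    g.P_free -= 1
                    return
                x -= g.c_degP
            if self.net is not None:
                rep = self.genes[gi - 1]
                if x < g.c_bind:
                    rep.P_free -= 1
                    g.prom = PROM_BOUND
                    return
                x -= g.c_bind
                if x < g.c_unbind:
                    rep.P_free += 1
                    g.prom = PROM_FREE
                    return
                x -= g.c_unbind
                # bound-protein degradation frees the promoter
                g.prom = PROM_FREE
                return
            # numerical slack: fall through to the RNAP walk below
            x = 0.0
        else:
            x -= g.other_total

        rnaps = g.rnaps
        if not rnaps:  # numerical slack with an empty template
            return
        idx = len(rnaps) - 1
        for i, rn in enumerate(rnaps):
            if x < rn.rate:
                idx = i
                break
            x -= rn.rate
        self._fire_rnap(g, gi, idx, x)

    def _fire_initiation(self, g: GeneUnit, gi: int) -> None:
        # the cellular RNAP pool is a constant reservoir: binding one to the
        # promoter does not deplete the n_rnap available for initiation
        g.prom = PROM_OC
        g.log.n_init += 1
        g.log.initiation_times.append(self.t)
        self._push(self.t + sample_delay(g.tp.tau_oc, self.rng), W_OC, gi, None)

    def _fire_clearance(self, g: GeneUnit, gi: int) -> None:
        g.prom = PROM_FREE
        rn = Rnap(1)
        g.rnaps.append(rn)
        rn.rate = 0.0
        g.update_around(len(g.rnaps) - 1)
        if g.record_events:
            g.log.records.append((self.t, "elongation_start", 1))
        self._maybe_long_pause(g, len(g.rnaps) - 1)

    def _fire_translation(self, g: GeneUnit, gi: int) -> None:
        ep = g.ep
        g.R_free -= 1
        g.rib_free -= 1
        g.n_R_waitlisted += 1
        g.n_rib_waitlisted += 1
        self._push(self.t + ep.tau1, W_R, gi, None)
        self._push(self.t + ep.tau2, W_RIB, gi, None)
        self._push(self.t + sample_delay(ep.tau3, self.rng), W_P, gi, None)

    def _apply_release(self, code: int, gi: int, payload: Rnap | None) -> None:
        g = self.genes[gi]
        if code == W_OC:
            g.prom = PROM_CLEAR
        elif code == W_R:
            g.R_free += 1
            g.n_R_waitlisted -= 1
        elif code == W_RIB:
            g.rib_free += 1
            g.n_rib_waitlisted -= 1
        elif code == W_P:
            g.P_free += 1
        elif code == W_ARREST or code == W_EDIT:
            rn = payload
            if rn not in g.rnaps:  # pragma: no cover - defensive
                return
            rn.phase = rn.prev_phase
            if code == W_EDIT:
                rn.mis = False
                g.log.n_edit += 1
            g.update_around(g.rnaps.index(rn))

    # ------------------------------------------------------------ RNAP events

    def _fire_rnap(self, g: GeneUnit, gi: int, i: int, x: float) -> None:
        ch = g.channels(i)
        if not ch:  # pragma: no cover - numerical slack
            return
        code = ch[-1][1]
        for r, c in ch:
            if x < r:
                code = c
                break
            x -= r
        rn = g.rnaps[i]
        log = g.log
        t = self.t

        if code == ACT:
            rn.phase = A
            log.n_act += 1
            g.update_rnap(i)
        elif code == MOVE:
            ahead = g.rnaps[i - 1] if i > 0 else None
            if ahead is not None and ahead.pos - rn.pos == g.excl:
                self._fire_collision(g, gi, i)
            else:
                rn.pos += 1
                rn.phase = O
                log.n_move += 1
                g.update_around(i)
                self._maybe_long_pause(g, i)
        elif code == TERM:
            log.n_completions += 1
            log.completion_times.append(t)
            g.R_free += 1
            self._remove_rnap(g, i)
        elif code == PAUSE:
            rn.prev_phase = rn.phase
            rn.phase = PAUSED
            rn.pause_t0 = t
            log.n_pause += 1
            if g.record_events:
                log.records.append((t, "pause_start", rn.pos))
            g.update_around(i)
        elif code == UNPAUSE:
            self._end_pause(g, i, collision=False)
        elif code == LP_EXIT:
            self._end_long_pause(g, gi, i)
        elif code == ARREST_GO:
            rn.prev_phase = rn.phase
            rn.phase = ARRESTED
            log.n_arrest += 1
            if g.record_events:
                log.records.append((t, "arrest", rn.pos))
            g.update_around(i)
            self._push(t + g.tp.d_arrest, W_ARREST, gi, rn)
        elif code == MIS:
            rn.mis = True
            log.n_mis += 1
            if g.record_events:
                log.records.append((t, "misincorporation", rn.pos))
            g.update_rnap(i)
        elif code == EDIT_GO:
            rn.prev_phase = rn.phase
            rn.phase = EDITING
            if g.record_events:
                log.records.append((t, "editing", rn.pos))
            g.update_around(i)
            self._push(t + g.tp.d_correct, W_EDIT, gi, rn)
        elif code == PYRO:
            rn.pos -= 1
            rn.phase = O
            log.n_pyro += 1
            if g.record_events:
                log.records.append((t, "pyrophosphorolysis", rn.pos))
            g.update_around(i)
            self._maybe_long_pause(g, i)
        elif code == PREM:
            log.n_prem += 1
            if g.record_events:
                log.records.append((t, "premature_termination", rn.pos))
            self._remove_rnap(g, i)

    def _fire_collision(self, g: GeneUnit, gi: int, i: int) -> None:
        """Trailing activated RNAP ``i`` hits the paused leader ``i - 1``."""
        log = g.log
        log.n_collision += 1
        if g.record_events:
            log.records.append((self.t, "collision", g.rnaps[i].pos))
        if self._next_u() < g.tp.p_collision_pause:
            rn = g.rnaps[i]
            rn.prev_phase = rn.phase
            rn.phase = PAUSED
            rn.pause_t0 = self.t
            log.n_pause += 1
            log.n_collision_paused += 1
            g.update_around(i)
        else:
            leader = g.rnaps[i - 1]
            if leader.phase == LONGPAUSED:
                self._end_long_pause(g, gi, i - 1)
            else:
                self._end_pause(g, i - 1, collision=True)

    def _end_pause(self, g: GeneUnit, i: int, collision: bool) -> None:
        rn = g.rnaps[i]
        rn.phase = rn.prev_phase
        g.log.n_unpause += 1
        g.log.pause_durations.append(self.t - rn.pause_t0)
        if g.record_events:
            kind = "pause_end_collision" if collision else "pause_end"
            g.log.records.append((self.t, kind, rn.pos))
        g.update_around(i)

    def _end_long_pause(self, g: GeneUnit, gi: int, i: int) -> None:
        rn = g.rnaps[i]
        site = g.sites[rn.pos]
        g.log.pause_durations.append(self.t - rn.pause_t0)
        if site.premature_term_prob > 0 and self._next_u() < site.premature_term_prob:
            g.log.n_lp_term += 1
            if g.record_events:
                g.log.records.append((self.t, "long_pause_termination", rn.pos))
            self._remove_rnap(g, i)
        else:
            rn.phase = rn.prev_phase
            if g.record_events:
                g.log.records.append((self.t, "long_pause_end", rn.pos))
            g.update_around(i)

    def _maybe_long_pause(self, g: GeneUnit, i: int) -> None:
        """Bernoulli long-pause draw on arrival at a pause site."""
        rn = g.rnaps[i]
        site = g.sites.get(rn.pos)
        if site is None:
            return
        if site.once_per_rnap and rn.lp_drawn:
            return
        rn.lp_drawn = True
        if self._next_u() < site.occurrence_prob:
            rn.prev_phase = rn.phase
            rn.phase = LONGPAUSED
            rn.pause_t0 = self.t
            g.log.n_lp += 1
            if g.record_events:
                g.log.records.append((self.t, "long_pause_start", rn.pos))
            g.update_around(i)

    def _remove_rnap(self, g: GeneUnit, i: int) -> None:
        rn = g.rnaps[i]
        g.rnap_sum -= rn.rate
        del g.rnaps[i]
        if g.rnaps:
            g.update_around(min(i, len(g.rnaps) - 1))
            if i > 0:
                g.update_rnap(i - 1)


def apply_collision(g: GeneUnit, trailing_idx: int, rng_u: float) -> str:
    """Resolve one collision between RNAP ``trailing_idx`` and its leader.

    The trailing RNAP must be activated and footprint-adjacent to a paused
    leader.  Returns the outcome tag; positions are never changed.
    """
    if trailing_idx <= 0 or trailing_idx >= len(g.rnaps):
        raise ValueError("trailing RNAP must have a leader")
    trailing = g.rnaps[trailing_idx]
    leader = g.rnaps[trailing_idx - 1]
    if leader.phase not in (PAUSED, LONGPAUSED):
        raise ValueError("leader is not paused")
    if trailing.phase != A:
        raise ValueError("trailing RNAP is not activated")
    if leader.pos - trailing.pos != g.excl:
        raise ValueError("RNAPs are not footprint-adjacent")
    if rng_u < g.tp.p_collision_pause:
        trailing.prev_phase = trailing.phase
        trailing.phase = PAUSED
        g.update_around(trailing_idx)
        return TRAILING_PAUSED
    leader.phase = leader.prev_phase
    g.update_around(trailing_idx - 1)
    return LEADER_RELEASED
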