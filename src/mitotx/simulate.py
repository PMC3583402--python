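"""Event-driven stochastic simulation of polymerase traffic on circular DNA.

One trajectory is a single realization of the following processes over a
modeled physical time horizon ``t_end``:

* each promoter emits Poisson binding *attempts* at its intensity λ; an
  attempt succeeds iff no polymerase footprint and no bound factor overlaps
  the promoter footprint, even partially, and the new polymerase starts
  moving immediately at the constant elongation rate v;
* each factor site (mTERF) emits Poisson binding attempts; an attempt
  succeeds iff the site is unbound and free of polymerases.  A bound site
  stops a polymerase arriving on the heavy strand with probability 1−p and
  on the light strand with probability 1−q; a passing polymerase dissociates
  the complex.  Spontaneous dissociation is folded into the binding
  intensity and is not a separate event;
* a G-quadruplex site terminates each passing polymerase on its strand
  independently with a configured probability (default 0);
* two oncoming polymerases annihilate at their meeting point (head-on
  collision terminates both); equal speeds make same-direction collisions
  impossible;
* unterminated polymerases circle the chromosome indefinitely until the
  horizon truncates them.

Elongation is continuous-position and event-driven: each polymerase carries
one scheduled arrival at its nearest obstacle and is rescheduled whenever
the obstacle landscape changes.  Simultaneous events have probability zero
in continuous time; floating-point ties are broken by event creation order.

A transcript covers a gene iff the polymerase traversed the gene's full
span on the gene's strand; each additional full circle over the gene counts
again, and partial coverage counts zero.  Counting is restricted to
completion times in ``(run_up, t_end]``.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from . import _circular as circ
from .geometry import (FOOTPRINT_REL, GenomeGeometry, HEAVY, LIGHT, Promoter,
                       strand_direction)


@dataclass
class SimulationParams:
    """Rate and horizon parameters of one simulation condition.

    promoter_intensities and factor_intensities map feature names to
    Poisson attempt intensities (per second of modeled time).  ``p`` and
    ``q`` override the per-site passage probabilities for all factor sites
    when given.  ``footprint`` is the polymerase exclusion size in nt.
    """

    promoter_intensities: dict[str, float] = field(default_factory=dict)
    factor_intensities: dict[str, float] = field(default_factory=dict)
    p: float | None = None
    q: float | None = None
    elongation_rate: float = 500.0
    footprint: int = 17
    quadruplex_termination: dict[str, float] | None = None
    t_end: float = 32400.0          # 9 h of modeled time
    run_up: float = 0.0

    def validate(self) -> None:
        for name, lam in {**self.promoter_intensities,
                          **self.factor_intensities}.items():
            if lam < 0:
                raise ValueError(f"negative intensity for {name}")
        for v, what in ((self.p, "p"), (self.q, "q")):
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{what}={v} outside [0,1]")
        if self.elongation_rate <= 0:
            raise ValueError("elongation rate must be positive")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if not 0.0 <= self.run_up < self.t_end:
            raise ValueError("need 0 <= run_up < t_end")

    def pass_prob(self, site, strand: str) -> float:
        if strand == HEAVY:
            return self.p if self.p is not None else site.pass_prob_heavy
        return self.q if self.q is not None else site.pass_prob_light

    def site_intensity(self, site) -> float:
        return self.factor_intensities.get(site.name, site.binding_intensity)

    def quad_probability(self, quad) -> float:
        if self.quadruplex_termination and quad.name in self.quadruplex_termination:
            return self.quadruplex_termination[quad.name]
        return quad.termination_prob


@dataclass
class TrajectoryCounts:
    """Per-trajectory tallies produced by :func:`run_trajectory`."""

    per_gene_transcripts: dict[str, int]
    terminator_stops: dict[tuple[str, str], int]
    terminator_passes: dict[tuple[str, str], int]
    circling_polymerases: dict[str, int]
    collisions: int
    bindings: int
    terminations: int
    active_at_end: int

    def encounters(self, site: str, strand: str) -> int:
        return (self.terminator_stops.get((site, strand), 0)
                + self.terminator_passes.get((site, strand), 0))


# ----------------------------------------------------------------------
# Pure kinematics / decision helpers (unit-testable in isolation)
# ----------------------------------------------------------------------

def next_meeting_time(pos_a: float, dir_a: int, pos_b: float, dir_b: int,
                      v: float, length: int) -> float | None:
    """Seconds until two polymerases meet head-on, or None if co-directional.

    Both move at speed v; converging polymerases close their forward gap at
    2v, so the first meeting is gap/(2v) where the gap is measured from
    either polymerase in its own direction of travel (the two measures
    coincide for opposite directions, modulo the circle length).
    """
    if dir_a == dir_b:
        return None
    gap = circ.forward_gap(pos_a, pos_b, dir_a, length)
    return gap / (2.0 * v)


def encounter_factor(strand: str, site, rng, params: SimulationParams | None = None):
    """Resolve a polymerase's arrival at a bound factor site.

    Returns ``'pass'`` (complex dissociates) or ``'terminate'`` (complex
    survives, polymerase stops) from a Bernoulli draw with the directional
    passage probability.
    """
    if params is not None:
        prob = params.pass_prob(site, strand)
    else:
        prob = site.pass_prob_heavy if strand == HEAVY else site.pass_prob_light
    return "pass" if rng.random() < prob else "terminate"


def polymerase_occupancy_arc(pos: float, direction: int, length: int,
                             footprint_rel=FOOTPRINT_REL):
    """Circular arc occupied by a polymerase at ``pos`` (−15..+1 by default)."""
    lo, hi = footprint_rel
    width = hi - lo + 1
    start = pos + lo if direction > 0 else pos - hi
    return (start % length, float(width))


def footprint_is_free(target_arc, polymerases, bound_site_arcs, length) -> bool:
    """True iff no polymerase occupancy and no bound factor overlaps the arc.

    ``polymerases`` is an iterable of (position, direction) pairs.
    """
    for pos, d in polymerases:
        if circ.arcs_overlap(target_arc, polymerase_occupancy_arc(pos, d, length),
                             length):
            return False
    for sa in bound_site_arcs:
        if circ.arcs_overlap(target_arc, sa, length):
            return False
    return True


def attempt_binding(promoter: Promoter, occupancy, rng=None) -> str:
    """Decide one promoter binding attempt given the current occupancy state.

    ``occupancy`` is (polymerases, bound_site_arcs, length) as in
    :func:`footprint_is_free`.  Returns ``'bound'`` or ``'rejected'``.
    """
    polys, site_arcs, length = occupancy
    fp = promoter.footprint_arc(length)
    return "bound" if footprint_is_free(fp, polys, site_arcs, length) else "rejected"


def count_full_covers(start_pos: float, direction: int, dist: float,
                      gene_start: int, gene_end: int, length: int) -> tuple[int, float]:
    """Full covers of a gene by a polymerase path, and distance to first cover.

    Returns (n_covers, d1) where d1 is the distance travelled at which the
    first full cover completes.  The polymerase transcribes from its start
    position; a cover completes when it passes the gene's downstream end
    having earlier passed its upstream end, and every further full circle
    adds one cover.
    """
    glen = (gene_end - gene_start) % length or length
    downstream_end = gene_end if direction > 0 else gene_start
    d_end = circ.forward_gap(start_pos, downstream_end, direction, length)
    d1 = d_end if d_end >= glen else d_end + length
    # float slack: a polymerase terminating exactly at the gene's downstream
    # end has dist == d1 up to rounding of v*(t - t0)
    eps = 1e-6
    if dist < d1 - eps:
        return 0, d1
    return 1 + int((dist - d1 + eps) // length), d1


# ----------------------------------------------------------------------
# The engine
# ----------------------------------------------------------------------

_PROM, _FACTOR, _MOVE = 0, 1, 2


@dataclass
class _Poly:
    pid: int
    strand: str
    direction: int
    start_pos: float
    start_time: float
    version: int = 0

    def pos(self, t: float, v: float, L: int) -> float:
        return (self.start_pos + self.direction * v * (t - self.start_time)) % L

    def dist(self, t: float, v: float) -> float:
        return v * (t - self.start_time)


class _Engine:
    def __init__(self, geometry: GenomeGeometry, params: SimulationParams, rng):
        params.validate()
        if geometry.length <= 0:
            raise ValueError("zero-length geometry")
        self.g = geometry
        self.par = params
        self.rng = rng
        self.L = geometry.length
        self.v = params.elongation_rate
        self.t = 0.0
        self.heap: list = []
        self.seq = 0
        self.polys: dict[int, _Poly] = {}
        self.next_pid = 0
        self.site_bound = [False] * len(geometry.factor_sites)
        self.site_arcs = [s.arc(self.L) for s in geometry.factor_sites]
        self.quad_arcs = [q.arc(self.L) for q in geometry.quadruplex_sites]
        # occupancy spans footprint nt ending 1 nt ahead of the active position
        self.footprint_rel = (-(params.footprint - 2), 1)
        # tallies
        self.counts = TrajectoryCounts(
            per_gene_transcripts={g.name: 0 for g in geometry.genes},
            terminator_stops={}, terminator_passes={},
            circling_polymerases={HEAVY: 0, LIGHT: 0},
            collisions=0, bindings=0, terminations=0, active_at_end=0)

    # -- queue helpers -------------------------------------------------
    def _push(self, time: float, kind: int, payload) -> None:
        self.seq += 1
        heapq.heappush(self.heap, (time, self.seq, kind, payload))

    def _schedule_attempt(self, kind: int, idx: int, lam: float) -> None:
        if lam > 0:
            self._push(self.t + self.rng.exponential(1.0 / lam), kind, idx)

    # -- occupancy -----------------------------------------------------
    def _poly_states(self):
        return [(p.pos(self.t, self.v, self.L), p.direction)
                for p in self.polys.values()]

    def _bound_arcs(self):
        return [a for a, b in zip(self.site_arcs, self.site_bound) if b]

    def _arc_free(self, target_arc) -> bool:
        for p in self.polys.values():
            occ = polymerase_occupancy_arc(p.pos(self.t, self.v, self.L),
                                           p.direction, self.L, self.footprint_rel)
            if circ.arcs_overlap(target_arc, occ, self.L):
                return False
        for sa in self._bound_arcs():
            if circ.arcs_overlap(target_arc, sa, self.L):
                return False
        return True

    # -- polymerase scheduling ----------------------------------------
    def _reschedule(self, poly: _Poly) -> None:
        """Recompute and queue the polymerase's single next arrival event."""
        poly.version += 1
        pos = poly.pos(self.t, self.v, self.L)
        best_dt = self.par.t_end - self.t
        best = None        # (subkind, aux)
        for i, site in enumerate(self.g.factor_sites):
            if not self.site_bound[i]:
                continue
            s0, slen = self.site_arcs[i]
            edge = s0 if poly.direction > 0 else (s0 + slen) % self.L
            d = circ.forward_gap(pos, edge, poly.direction, self.L)
            if d <= 1e-9:
                d += self.L
            dt = d / self.v
            if dt < best_dt:
                best_dt, best = dt, ("site", i)
        for i, quad in enumerate(self.g.quadruplex_sites):
            if quad.strand != poly.strand:
                continue
            if self.par.quad_probability(quad) <= 0:
                continue
            q0, qlen = self.quad_arcs[i]
            edge = q0 if poly.direction > 0 else (q0 + qlen) % self.L
            d = circ.forward_gap(pos, edge, poly.direction, self.L)
            if d <= 1e-9:
                d += self.L
            dt = d / self.v
            if dt < best_dt:
                best_dt, best = dt, ("quad", i)
        for other in self.polys.values():
            if other.pid == poly.pid or other.direction == poly.direction:
                continue
            mt = next_meeting_time(pos, poly.direction,
                                   other.pos(self.t, self.v, self.L),
                                   other.direction, self.v, self.L)
            if mt is not None and mt < best_dt:
                # the meeting time of two live polymerases is invariant (equal
                # speeds), so the event only needs the partner's identity
                best_dt = mt
                best = ("meet", other.pid)
        if best is not None:
            self._push(self.t + best_dt, _MOVE,
                       (poly.pid, poly.version, best[0], best[1]))
        # else: survives untouched to the horizon

    def _reschedule_all(self) -> None:
        for p in list(self.polys.values()):
            self._reschedule(p)

    # -- terminations and counting ------------------------------------
    def _finalize(self, poly: _Poly, t_stop: float, terminated: bool) -> None:
        par = self.par
        dist = poly.dist(t_stop, self.v)
        for gene in self.g.genes:
            if gene.strand != poly.strand:
                continue
            n, d1 = count_full_covers(poly.start_pos, poly.direction, dist,
                                      gene.start, gene.end, self.L)
            if n == 0:
                continue
            if par.run_up > 0:
                # drop covers completing during the run-up
                for i in range(n):
                    if poly.start_time + (d1 + i * self.L) / self.v > par.run_up:
                        n -= i
                        break
                else:
                    n = 0
            self.counts.per_gene_transcripts[gene.name] += n
        if dist >= self.L - 1e-6:
            t_first_circle = poly.start_time + self.L / self.v
            if t_first_circle > par.run_up:
                self.counts.circling_polymerases[poly.strand] += 1
        if terminated:
            self.counts.terminations += 1
        else:
            self.counts.active_at_end += 1

    def _kill(self, poly: _Poly, t_stop: float) -> None:
        self._finalize(poly, t_stop, terminated=True)
        del self.polys[poly.pid]

    # -- event handlers ------------------------------------------------
    def _on_promoter_attempt(self, idx: int) -> None:
        prom = self.g.promoters[idx]
        lam = self.par.promoter_intensities.get(prom.name, 0.0)
        self._schedule_attempt(_PROM, idx, lam)
        if not self._arc_free(prom.footprint_arc(self.L)):
            return
        poly = _Poly(self.next_pid, prom.strand, prom.direction,
                     float(prom.tss), self.t)
        self.next_pid += 1
        self.polys[poly.pid] = poly
        self.counts.bindings += 1
        # new oncoming pair constraints: opposite-direction polymerases may
        # now meet this one earlier than their current scheduled event
        for other in list(self.polys.values()):
            if other.pid != poly.pid and other.direction != poly.direction:
                self._reschedule(other)
        self._reschedule(poly)

    def _on_factor_attempt(self, idx: int) -> None:
        site = self.g.factor_sites[idx]
        lam = self.par.site_intensity(site)
        self._schedule_attempt(_FACTOR, idx, lam)
        if self.site_bound[idx]:
            return
        arc = self.site_arcs[idx]
        for p in self.polys.values():
            occ = polymerase_occupancy_arc(p.pos(self.t, self.v, self.L),
                                           p.direction, self.L, self.footprint_rel)
            if circ.arcs_overlap(arc, occ, self.L):
                return
        self.site_bound[idx] = True
        self._reschedule_all()

    def _on_move(self, payload) -> None:
        pid, version, subkind, aux = payload
        poly = self.polys.get(pid)
        if poly is None or poly.version != version:
            return                                    # stale event
        if subkind == "site":
            i = aux
            if not self.site_bound[i]:
                self._reschedule(poly)
                return
            site = self.g.factor_sites[i]
            key = (site.name, poly.strand)
            if encounter_factor(poly.strand, site, self.rng, self.par) == "pass":
                self.counts.terminator_passes[key] = \
                    self.counts.terminator_passes.get(key, 0) + 1
                self.site_bound[i] = False
                self._reschedule_all()
            else:
                self.counts.terminator_stops[key] = \
                    self.counts.terminator_stops.get(key, 0) + 1
                self._kill(poly, self.t)
                self._reschedule_all()
        elif subkind == "quad":
            quad = self.g.quadruplex_sites[aux]
            if self.rng.random() < self.par.quad_probability(quad):
                self._kill(poly, self.t)
                self._reschedule_all()
            else:
                self._reschedule(poly)
        elif subkind == "meet":
            other = self.polys.get(aux)
            if other is None:       # partner died; a reschedule is in flight
                self._reschedule(poly)
                return
            self.counts.collisions += 1
            self._kill(poly, self.t)
            self._kill(other, self.t)
            self._reschedule_all()

    # -- main loop ------------------------------------------------------
    def run(self) -> TrajectoryCounts:
        for i, prom in enumerate(self.g.promoters):
            self._schedule_attempt(
                _PROM, i, self.par.promoter_intensities.get(prom.name, 0.0))
        for i, site in enumerate(self.g.factor_sites):
            self._schedule_attempt(_FACTOR, i, self.par.site_intensity(site))
        t_end = self.par.t_end
        while self.heap:
            time, _, kind, payload = heapq.heappop(self.heap)
            if time > t_end:
                break
            self.t = time
            if kind == _PROM:
                self._on_promoter_attempt(payload)
            elif kind == _FACTOR:
                self._on_factor_attempt(payload)
            else:
                self._on_move(payload)
        self.t = t_end
        for poly in list(self.polys.values()):
            self._finalize(poly, t_end, terminated=False)
        return self.counts


def run_trajectory(geometry: GenomeGeometry, params: SimulationParams,
                   seed) -> TrajectoryCounts:
    """Simulate one trajectory; identical (geometry, params, seed) gives
    identical counts."""
    rng = np.random.default_rng(seed)
    return _Engine(geometry, params, rng).run()
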