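"""Naive fixed-step reference simulator (1 nt per tick).

This is a deliberately simple, independently coded simulator used as an
oracle for the event-driven engine: time advances in ticks of 1/v seconds,
every polymerase moves exactly one nucleotide per tick, and all stochastic
attempts are pre-drawn as Poisson event times and consumed tick by tick.
It is orders of magnitude slower than the event-driven engine and is only
suitable for toy genomes, which is its purpose.

Semantics mirror the model contract: Poisson promoter/factor binding with
footprint exclusion, polarized passage through a bound factor site,
head-on annihilation of converging polymerases, multi-circle full-cover
transcript counting.
"""

from __future__ import annotations

import numpy as np

from .geometry import GenomeGeometry, HEAVY
from .simulate import SimulationParams, TrajectoryCounts


def _draw_times(rng, lam: float, t_end: float) -> list[float]:
    """All events of a Poisson process with rate lam on (0, t_end]."""
    times = []
    if lam <= 0:
        return times
    t = rng.exponential(1.0 / lam)
    while t <= t_end:
        times.append(t)
        t += rng.exponential(1.0 / lam)
    return times


def _arc_overlap(a0, la, b0, lb, L) -> bool:
    return ((b0 - a0) % L) < la or ((a0 - b0) % L) < lb


def run_trajectory_fixed_step(geometry: GenomeGeometry, params: SimulationParams,
                              seed) -> TrajectoryCounts:
    params.validate()
    rng = np.random.default_rng(seed)
    L = geometry.length
    v = params.elongation_rate
    dt = 1.0 / v
    n_ticks = int(np.ceil(params.t_end * v))
    fp = params.footprint

    prom_times = [_draw_times(rng, params.promoter_intensities.get(p.name, 0.0),
                              params.t_end) for p in geometry.promoters]
    site_times = [_draw_times(rng, params.site_intensity(s), params.t_end)
                  for s in geometry.factor_sites]
    prom_ptr = [0] * len(prom_times)
    site_ptr = [0] * len(site_times)
    site_bound = [False] * len(geometry.factor_sites)
    site_arcs = [(s.start, s.length_on(L)) for s in geometry.factor_sites]
    # entry edge of each site per direction
    site_edge = [{1: a[0], -1: (a[0] + a[1]) % L} for a in site_arcs]
    quad_edge = [{1: q.start, -1: (q.start + q.length_on(L)) % L}
                 for q in geometry.quadruplex_sites]

    # active polymerases: parallel lists
    pos: list[int] = []
    dirs: list[int] = []
    strands: list[str] = []
    t0s: list[float] = []
    x0s: list[int] = []
    travelled: list[int] = []

    counts = TrajectoryCounts(
        per_gene_transcripts={g.name: 0 for g in geometry.genes},
        terminator_stops={}, terminator_passes={},
        circling_polymerases={"heavy": 0, "light": 0},
        collisions=0, bindings=0, terminations=0, active_at_end=0)

    def occupancy_blocks(a0, la) -> bool:
        for j in range(len(pos)):
            if dirs[j] > 0:
                o0 = (pos[j] - (fp - 2)) % L
            else:
                o0 = (pos[j] - 1) % L
            if _arc_overlap(a0, la, o0, fp, L):
                return True
        return False

    def finalize(j: int, t_stop: float, terminated: bool) -> None:
        dist = travelled[j]
        for gene in geometry.genes:
            if gene.strand != strands[j]:
                continue
            glen = (gene.end - gene.start) % L or L
            dend = gene.end if dirs[j] > 0 else gene.start
            d_end = ((dend - x0s[j]) * dirs[j]) % L
            d1 = d_end if d_end >= glen else d_end + L
            if dist < d1:
                continue
            n = 1 + (dist - d1) // L
            if params.run_up > 0:
                kept = 0
                for i in range(n):
                    if t0s[j] + (d1 + i * L) / v > params.run_up:
                        kept = n - i
                        break
                n = kept
            counts.per_gene_transcripts[gene.name] += int(n)
        if dist >= L and t0s[j] + L / v > params.run_up:
            counts.circling_polymerases[strands[j]] += 1
        if terminated:
            counts.terminations += 1
        else:
            counts.active_at_end += 1

    def remove(indices, t_stop) -> None:
        for j in sorted(indices, reverse=True):
            finalize(j, t_stop, terminated=True)
            for arr in (pos, dirs, strands, t0s, x0s, travelled):
                del arr[j]

    for tick in range(n_ticks):
        t_now = (tick + 1) * dt

        # 1. move everyone one nucleotide, resolving head-on collisions:
        # converging pairs with forward gap <= 2 nt meet during this tick.
        doomed = set()
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                if dirs[a] == dirs[b]:
                    continue
                gap = ((pos[b] - pos[a]) * dirs[a]) % L
                if gap <= 2:
                    if a not in doomed and b not in doomed:
                        doomed.update((a, b))
                        counts.collisions += 1
        for j in range(len(pos)):
            if j in doomed:
                travelled[j] += 1        # meet roughly mid-gap
            else:
                pos[j] = (pos[j] + dirs[j]) % L
                travelled[j] += 1
        remove(doomed, t_now)

        # 2. factor-site encounters at the entry edge
        for i, site in enumerate(geometry.factor_sites):
            if not site_bound[i]:
                continue
            stopped = []
            for j in range(len(pos)):
                if pos[j] == site_edge[i][dirs[j]]:
                    prob = params.pass_prob(site, strands[j])
                    key = (site.name, strands[j])
                    if rng.random() < prob:
                        counts.terminator_passes[key] = \
                            counts.terminator_passes.get(key, 0) + 1
                        site_bound[i] = False
                    else:
                        counts.terminator_stops[key] = \
                            counts.terminator_stops.get(key, 0) + 1
                        stopped.append(j)
            remove(stopped, t_now)

        # 3. quadruplex passage
        for i, quad in enumerate(geometry.quadruplex_sites):
            tp = params.quad_probability(quad)
            if tp <= 0:
                continue
            killed = [j for j in range(len(pos))
                      if strands[j] == quad.strand
                      and pos[j] == quad_edge[i][dirs[j]]
                      and rng.random() < tp]
            remove(killed, t_now)

        # 4. binding attempts that fell in this tick
        for i, prom in enumerate(geometry.promoters):
            times = prom_times[i]
            while prom_ptr[i] < len(times) and times[prom_ptr[i]] <= t_now:
                t_att = times[prom_ptr[i]]
                prom_ptr[i] += 1
                a0, la = prom.footprint_arc(L)
                blocked = occupancy_blocks(a0, la)
                if not blocked:
                    for k, sb in enumerate(site_bound):
                        if sb and _arc_overlap(a0, la, *site_arcs[k], L):
                            blocked = True
                            break
                if not blocked:
                    pos.append(prom.tss)
                    dirs.append(1 if prom.strand == HEAVY else -1)
                    strands.append(prom.strand)
                    t0s.append(t_att)
                    x0s.append(prom.tss)
                    travelled.append(0)
                    counts.bindings += 1
        for i, site in enumerate(geometry.factor_sites):
            times = site_times[i]
            while site_ptr[i] < len(times) and times[site_ptr[i]] <= t_now:
                site_ptr[i] += 1
                if not site_bound[i] and not occupancy_blocks(*site_arcs[i]):
                    site_bound[i] = True

    for j in range(len(pos)):
        finalize(j, params.t_end, terminated=False)
    return counts
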