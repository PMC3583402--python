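"""Inverse problem: infer binding intensities and passage probabilities.

The observable data are (relative or absolute) per-gene transcription
levels; the unknowns are the promoter binding intensities, the factor
(mTERF) binding intensity, and the terminator passage probabilities p and
q.  The objective is the normalised L1 functional Σ|x−y|/max(x,y) between
model and experimental levels, evaluated by Monte-Carlo ensembles of the
event-driven simulator with common random numbers (the same ensemble seed
for every candidate, so that candidate comparisons are not drowned by
sampling noise on a response landscape full of local minima).

The optimizer is a log-spaced multi-start coordinate descent with the
"active search" boundary rule: raising a strand's promoter intensity is
abandoned as soon as any opposing-strand gene's transcription drops to
zero, since a silent strand signals that it is blocked by the heavy
opposing polymerase flow and further increase cannot improve the fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import l1n, l1n_total
from .geometry import GenomeGeometry, HEAVY, LIGHT
from .observables import ensemble
from .simulate import SimulationParams


@dataclass
class SearchConfig:
    """Bounds and schedule of the active-search coordinate descent.

    ``free`` lists the parameters to optimize: ``"promoter:<NAME>"``,
    ``"factor:<NAME>"``, ``"p"``, ``"q"``.  Intensities move on a log scale
    within ``intensity_bounds`` (attempts/s); probabilities within
    ``prob_bounds``.  The multiplicative step starts at ``step_init`` and
    shrinks by ``step_shrink`` after every sweep without improvement, down
    to ``step_min``.
    """

    free: list[str]
    intensity_bounds: tuple[float, float] = (1e-4, 1.0)
    prob_bounds: tuple[float, float] = (1e-3, 1.0)
    step_init: float = 4.0
    step_min: float = 1.1
    step_shrink: float = 0.5       # exponent scaling: step -> step**0.5
    max_sweeps: int = 12
    restarts: int = 3

    def bounds_of(self, name: str) -> tuple[float, float]:
        return self.prob_bounds if name in ("p", "q") else self.intensity_bounds


@dataclass
class Condition:
    """One experimental condition: target levels + which parameters apply."""

    name: str
    experiment: pd.Series              # gene -> target level
    weight_dim: int | None = None      # n_k for the multi-dataset functional


@dataclass
class TranscriptionFitResults:
    """Result of :meth:`TranscriptionModel.fit`.

    Carries the best parameter point, the objective value, the full audit
    log of evaluations, and the precision of the final search grid (the
    multiplicative factor separating the last candidates considered, which
    bounds the resolution of each estimate).
    """

    model: "TranscriptionModel"
    params: dict[str, float]
    fun: float
    history: list[dict] = field(repr=False)
    n_traj: int = 0
    master_seed: object = None
    grid_factor: float = 1.0
    boundary_flags: dict[str, str] = field(default_factory=dict)

    def evaluate(self) -> float:
        """Re-evaluate the objective at the solution with the fit's seed."""
        return self.model.objective(self.params, self.n_traj, self.master_seed)

    def ensemble(self, condition: int = 0, n_traj: int | None = None, seed=None):
        par = self.model.build_params(self.params, condition)
        return ensemble(self.model.geometry, par, n_traj or self.n_traj,
                        self.model._eval_seed(seed if seed is not None
                                              else self.master_seed))

    def summary(self) -> str:
        lines = [
            "Transcription inverse-problem fit (active search)",
            f"  conditions: {[c.name for c in self.model.conditions]}",
            f"  objective L1n = {self.fun:.4f}   "
            f"(n_traj={self.n_traj}, evaluations={len(self.history)})",
            f"  grid resolution: x{self.grid_factor:.3f} multiplicative",
            "  parameter        estimate",
        ]
        for k, v in sorted(self.params.items()):
            flag = f"   [{self.boundary_flags[k]}]" if k in self.boundary_flags else ""
            lines.append(f"  {k:<16} {v:.6g}{flag}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"params": self.params, "fun": self.fun,
                "n_traj": self.n_traj, "grid_factor": self.grid_factor,
                "boundary_flags": self.boundary_flags,
                "history": self.history}


class TranscriptionModel:
    """Forward/inverse transcription model bound to data.

    Parameters
    ----------
    geometry : GenomeGeometry
    conditions : one Condition, a gene->level Series, or a list of Condition
    base_params : SimulationParams carrying everything not being fitted
        (elongation rate, horizon, fixed intensities).
    mode : 'absolute' compares raw mean transcript counts; 'relative'
        divides both model and experiment by ``reference_gene``.
    """

    def __init__(self, geometry: GenomeGeometry, conditions,
                 base_params: SimulationParams | None = None,
                 mode: str = "absolute", reference_gene: str | None = None,
                 n_traj: int = 200):
        self.geometry = geometry
        if isinstance(conditions, pd.Series):
            conditions = [Condition("default", conditions)]
        elif isinstance(conditions, Condition):
            conditions = [conditions]
        self.conditions: list[Condition] = list(conditions)
        self.base_params = base_params or SimulationParams()
        if mode not in ("absolute", "relative"):
            raise ValueError("mode must be 'absolute' or 'relative'")
        if mode == "relative" and reference_gene is None:
            raise ValueError("relative mode needs a reference gene")
        self.mode = mode
        self.reference_gene = reference_gene
        self.default_n_traj = n_traj
        gene_names = {g.name for g in geometry.genes}
        for c in self.conditions:
            missing = set(c.experiment.index) - gene_names
            if missing:
                raise ValueError(f"experiment genes absent from geometry: {missing}")

    @classmethod
    def from_dataframe(cls, geometry, frame: pd.DataFrame, level_col="level",
                       gene_col="gene", **kw) -> "TranscriptionModel":
        s = frame.set_index(gene_col)[level_col].astype(float)
        return cls(geometry, s, **kw)

    # -- forward machinery --------------------------------------------
    @staticmethod
    def _eval_seed(master_seed):
        """One shared evaluation seed (common random numbers)."""
        return np.random.SeedSequence([0x5EED, int(master_seed) & 0x7FFFFFFF]) \
            if isinstance(master_seed, (int, np.integer)) else master_seed

    def build_params(self, point: dict[str, float],
                     condition: int = 0) -> SimulationParams:
        b = self.base_params
        prom = dict(b.promoter_intensities)
        fact = dict(b.factor_intensities)
        p, q = b.p, b.q
        for key, val in point.items():
            if key.startswith("promoter:"):
                prom[key.split(":", 1)[1]] = val
            elif key.startswith("factor:"):
                fact[key.split(":", 1)[1]] = val
            elif key == "p":
                p = val
            elif key == "q":
                q = val
            else:
                raise KeyError(f"unknown parameter {key!r}")
        return SimulationParams(
            promoter_intensities=prom, factor_intensities=fact, p=p, q=q,
            elongation_rate=b.elongation_rate, footprint=b.footprint,
            quadruplex_termination=b.quadruplex_termination,
            t_end=b.t_end, run_up=b.run_up)

    def model_levels(self, point: dict[str, float], n_traj: int, seed,
                     condition: int = 0) -> pd.Series:
        par = self.build_params(point, condition)
        res = ensemble(self.geometry, par, n_traj, self._eval_seed(seed))
        mean = res.per_gene_mean
        if self.mode == "relative":
            ref = mean[self.reference_gene]
            if ref <= 0:
                return mean * math.nan
            mean = mean / ref
        return mean

    def objective(self, point: dict[str, float], n_traj: int | None = None,
                  seed=0) -> float:
        """L1n (single condition) or weighted L1n-total (several)."""
        n_traj = n_traj or self.default_n_traj
        datasets = []
        for ci, cond in enumerate(self.conditions):
            model = self.model_levels(point, n_traj, seed, ci)
            x = model.reindex(cond.experiment.index).to_numpy(dtype=float)
            y = cond.experiment.to_numpy(dtype=float)
            if np.any(~np.isfinite(x)):
                return math.inf
            datasets.append((x, y, cond.weight_dim or len(y)))
        if len(datasets) == 1:
            return l1n(datasets[0][0], datasets[0][1])
        return l1n_total(datasets)

    def opposing_strand_silent(self, point, n_traj, seed, raised_key) -> bool:
        """Active-search boundary: did raising this intensity silence a gene
        on the opposite strand?"""
        if not raised_key.startswith("promoter:"):
            return False
        name = raised_key.split(":", 1)[1]
        try:
            strand = self.geometry.promoter(name).strand
        except KeyError:
            return False
        opposite = LIGHT if strand == HEAVY else HEAVY
        opp_genes = [g.name for g in self.geometry.genes if g.strand == opposite]
        if not opp_genes:
            return False
        for ci in range(len(self.conditions)):
            levels = self.model_levels(point, n_traj, seed, ci)
            if any(levels.get(g, 0.0) == 0.0 for g in opp_genes):
                return True
        return False

    # -- the fitter ----------------------------------------------------
    def fit(self, config: SearchConfig | None = None,
            n_traj: int | None = None, seed: int = 0) -> TranscriptionFitResults:
        """Multi-start log-coordinate active search; deterministic in seed."""
        if config is None:
            free = [f"promoter:{p.name}" for p in self.geometry.promoters]
            free += [f"factor:{s.name}" for s in self.geometry.factor_sites]
            free += ["p", "q"]
            config = SearchConfig(free=free)
        n_traj = n_traj or self.default_n_traj
        rng = np.random.default_rng(np.random.SeedSequence([0xAC7, seed]))
        history: list[dict] = []
        boundary_flags: dict[str, str] = {}

        def clip(name, value):
            lo, hi = config.bounds_of(name)
            return min(max(value, lo), hi)

        def evaluate(point):
            val = self.objective(point, n_traj, seed)
            history.append({"params": dict(point), "value": val})
            return val

        best_point, best_val = None, math.inf
        for restart in range(config.restarts):
            point = {}
            for name in config.free:
                lo, hi = config.bounds_of(name)
                if restart == 0:
                    point[name] = math.sqrt(lo * hi)      # geometric centre
                else:
                    point[name] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            val = evaluate(point)
            step = config.step_init
            for _ in range(config.max_sweeps):
                improved = False
                for name in config.free:
                    # greedy multiplicative line search along this coordinate
                    for factor in (step, 1.0 / step):
                        moved = True
                        while moved:
                            moved = False
                            cand = dict(point)
                            cand[name] = clip(name, point[name] * factor)
                            if cand[name] == point[name]:
                                break
                            if factor > 1.0 and self.opposing_strand_silent(
                                    cand, max(20, n_traj // 10), seed, name):
                                boundary_flags[name] = \
                                    "stopped: opposing strand silent"
                                break
                            cval = evaluate(cand)
                            if cval < val:
                                point, val = cand, cval
                                improved = moved = True
                # ridge moves: the objective couples an intensity with the
                # passage probability behind the same flux (e.g. level of a
                # downstream gene ~ lambda*p), so single-coordinate steps can
                # stall on a diagonal valley; try paired opposite moves
                for i, a in enumerate(config.free):
                    for b in config.free[i + 1:]:
                        for fa, fb in ((step, 1.0 / step), (1.0 / step, step)):
                            moved = True
                            while moved:
                                moved = False
                                cand = dict(point)
                                cand[a] = clip(a, point[a] * fa)
                                cand[b] = clip(b, point[b] * fb)
                                if cand[a] == point[a] and cand[b] == point[b]:
                                    break
                                cval = evaluate(cand)
                                if cval < val:
                                    point, val = cand, cval
                                    improved = moved = True
                if not improved:
                    if step <= config.step_min:
                        break
                    step = max(config.step_min, step ** config.step_shrink)
            if val < best_val:
                best_point, best_val = dict(point), val
        # flag estimates pinned at (or within one coarse grid step of) the
        # search bounds: below the data's detection limit the objective is
        # flat, so anywhere near the floor is boundary-indistinguishable
        for name, v in best_point.items():
            lo, hi = config.bounds_of(name)
            if v <= lo * config.step_init:
                boundary_flags[name] = "at lower bound"
            elif v >= hi / config.step_init and name not in ("p", "q"):
                boundary_flags[name] = "at upper bound"
        return TranscriptionFitResults(
            model=self, params=best_point, fun=best_val, history=history,
            n_traj=n_traj, master_seed=seed, grid_factor=config.step_min,
            boundary_flags=boundary_flags)


def active_search(geometry: GenomeGeometry, experiment, config: SearchConfig,
                  master_seed: int = 0, base_params=None,
                  n_traj: int = 200, **kw) -> TranscriptionFitResults:
    """Functional wrapper around :meth:`TranscriptionModel.fit`."""
    model = TranscriptionModel(geometry, experiment, base_params=base_params,
                               n_traj=n_traj, **kw)
    return model.fit(config, n_traj=n_traj, seed=master_seed)
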