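"""Ensemble statistics over simulated trajectories.

The simulator's per-trajectory transcript counts are averaged over many
independent trajectories (mean ± unbiased standard deviation); derived
observables are relative transcription levels, the rRNA/mRNA ratio R,
the polarization of a protein-dependent terminator and counts of
polymerases completing full circles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import GenomeGeometry, HEAVY, LIGHT
from .simulate import SimulationParams, TrajectoryCounts, run_trajectory


def derive_seeds(master_seed, n_traj: int, start: int = 0):
    """Deterministic per-trajectory seeds, independent of execution order."""
    ss = (master_seed if isinstance(master_seed, np.random.SeedSequence)
          else np.random.SeedSequence(master_seed))
    return ss.spawn(start + n_traj)[start:]


@dataclass
class EnsembleResult:
    """Summary of ``n_traj`` independent trajectories."""

    n_traj: int
    gene_counts: pd.DataFrame = field(repr=False)   # n_traj × genes
    terminator_stops: dict[tuple[str, str], int]
    terminator_passes: dict[tuple[str, str], int]
    circling: pd.DataFrame = field(repr=False)      # n_traj × strand
    collisions_mean: float
    master_seed: object = None

    @property
    def per_gene_mean(self) -> pd.Series:
        return self.gene_counts.mean(axis=0)

    @property
    def per_gene_sd(self) -> pd.Series:
        """Unbiased standard deviation; NaN for a single trajectory."""
        if self.n_traj < 2:
            return pd.Series(np.nan, index=self.gene_counts.columns)
        return self.gene_counts.std(axis=0, ddof=1)

    @property
    def per_gene_se(self) -> pd.Series:
        return self.per_gene_sd / math.sqrt(self.n_traj)

    def circling_mean_sd(self) -> dict[str, tuple[float, float]]:
        out = {}
        for strand in (HEAVY, LIGHT):
            col = self.circling[strand]
            sd = float(col.std(ddof=1)) if self.n_traj > 1 else float("nan")
            out[strand] = (float(col.mean()), sd)
        return out

    def relative_levels(self, reference_gene: str) -> pd.Series:
        ref = self.per_gene_mean[reference_gene]
        if ref <= 0:
            raise ZeroDivisionError(f"reference gene {reference_gene} has zero mean")
        return self.per_gene_mean / ref

    def to_dict(self) -> dict:
        circ_stats = self.circling_mean_sd()
        return {
            "n_traj": self.n_traj,
            "per_gene_mean": self.per_gene_mean.to_dict(),
            "per_gene_sd": {k: (None if not np.isfinite(v) else v)
                            for k, v in self.per_gene_sd.items()},
            "terminator_stops": {f"{s}|{d}": n for (s, d), n
                                 in self.terminator_stops.items()},
            "terminator_passes": {f"{s}|{d}": n for (s, d), n
                                  in self.terminator_passes.items()},
            "circling": {k: {"mean": m, "sd": (None if not np.isfinite(sd) else sd)}
                         for k, (m, sd) in circ_stats.items()},
            "collisions_mean": self.collisions_mean,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"mean": self.per_gene_mean, "sd": self.per_gene_sd})
        df.to_csv(path, sep="\t")


def ensemble(geometry: GenomeGeometry, params: SimulationParams, n_traj: int,
             master_seed, checkpoint=None, runner=run_trajectory) -> EnsembleResult:
    """Average ``n_traj`` independent trajectories.

    Per-trajectory seeds are derived deterministically from ``master_seed``
    and the trajectory index, so the result is invariant to execution order
    and to interruption/resume through ``checkpoint`` (a TSV path where
    finished trajectories are appended and re-read on restart).
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    gene_names = [g.name for g in geometry.genes]
    seeds = derive_seeds(master_seed, n_traj)

    done: dict[int, dict] = {}
    if checkpoint is not None:
        try:
            prev = pd.read_csv(checkpoint, sep="\t", index_col=0)
            done = {int(i): row.to_dict() for i, row in prev.iterrows()}
        except (FileNotFoundError, pd.errors.EmptyDataError):
            done = {}

    rows = []
    stops: dict[tuple[str, str], int] = {}
    passes: dict[tuple[str, str], int] = {}
    circ_rows = []
    collisions = []
    extra_cols = [f"__circ_{HEAVY}", f"__circ_{LIGHT}", "__collisions"]

    for i in range(n_traj):
        if i in done:
            row = done[i]
        else:
            tc: TrajectoryCounts = runner(geometry, params, seeds[i])
            row = {g: tc.per_gene_transcripts.get(g, 0) for g in gene_names}
            row[f"__circ_{HEAVY}"] = tc.circling_polymerases.get(HEAVY, 0)
            row[f"__circ_{LIGHT}"] = tc.circling_polymerases.get(LIGHT, 0)
            row["__collisions"] = tc.collisions
            for k, v in tc.terminator_stops.items():
                stops[k] = stops.get(k, 0) + v
            for k, v in tc.terminator_passes.items():
                passes[k] = passes.get(k, 0) + v
            if checkpoint is not None:
                pd.DataFrame([row], index=[i]).to_csv(
                    checkpoint, sep="\t", mode="a",
                    header=not bool(done) and i == 0)
        rows.append({g: row.get(g, 0) for g in gene_names})
        circ_rows.append({HEAVY: row.get(f"__circ_{HEAVY}", 0),
                          LIGHT: row.get(f"__circ_{LIGHT}", 0)})
        collisions.append(row.get("__collisions", 0))

    gene_counts = pd.DataFrame(rows, columns=gene_names, dtype=float)
    circ_df = pd.DataFrame(circ_rows, columns=[HEAVY, LIGHT], dtype=float)
    return EnsembleResult(
        n_traj=n_traj, gene_counts=gene_counts,
        terminator_stops=stops, terminator_passes=passes,
        circling=circ_df, collisions_mean=float(np.mean(collisions)),
        master_seed=master_seed)


def ratio_R(result: EnsembleResult, rrna_gene: str = "12S",
            ref_gene: str = "COX2") -> float:
    """Ratio of rRNA to reference-mRNA mean transcription levels."""
    denom = result.per_gene_mean[ref_gene]
    if denom == 0:
        raise ZeroDivisionError(f"{ref_gene} has zero mean transcription")
    return float(result.per_gene_mean[rrna_gene] / denom)


def polarization(result: EnsembleResult, site: str) -> dict[str, float]:
    """Fraction of encounters with the *bound* site that terminate, per strand.

    Undefined (NaN) for a direction with no encounters — e.g. when the
    factor never binds.
    """
    out = {}
    for strand in (HEAVY, LIGHT):
        s = result.terminator_stops.get((site, strand), 0)
        p = result.terminator_passes.get((site, strand), 0)
        out[strand] = s / (s + p) if (s + p) > 0 else float("nan")
    return out


def plot_levels(result: EnsembleResult, ax=None, relative_to: str | None = None):
    """Minimal bar chart of per-gene mean levels with SD whiskers."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, 0.3 * len(result.gene_counts.columns)), 3))
    mean = result.per_gene_mean
    sd = result.per_gene_sd
    if relative_to is not None:
        ref = mean[relative_to]
        mean, sd = mean / ref, sd / ref
    ax.bar(mean.index, mean.values, yerr=np.nan_to_num(sd.values))
    ax.set_ylabel("transcripts / window" if relative_to is None
                  else f"level relative to {relative_to}")
    ax.tick_params(axis="x", rotation=90)
    return ax
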