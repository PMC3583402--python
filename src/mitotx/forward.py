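"""Whole-genome forward simulations with published fitted parameter sets.

The fitted binding intensities and passage probabilities are forward-
simulation *inputs* here (they came from a large-scale optimization that
this package does not attempt to repeat).  These helpers run the human
healthy and MELAS parameter sets on the bundled rCRS geometry and collect
the headline observables: the 12S/COX2 ratio R, protein-coding-gene levels
relative to ND1, the healthy/MELAS fold changes of tRNA-Phe and the rRNAs,
and the counts of polymerases completing full circles.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .fixtures import FITTED_SOLUTIONS, human_geometry
from .observables import EnsembleResult, ensemble, polarization, ratio_R
from .simulate import SimulationParams

#: protein-coding genes reported relative to ND1 in the healthy-human table
HUMAN_PROTEIN_PANEL = ["ND2", "COX1", "COX2", "ATP6/8", "ND3", "ND5", "CYTB"]

#: genes whose healthy/MELAS fold change is reported
MELAS_PANEL = ["tRNA-Phe", "12S", "tRNA-Val", "16S", "tRNA-Leu(UUR)",
               "tRNA-Lys", "CYTB"]

_ALIASES = {"ATP6/8": "ATP8", "tRNA-Leu(UUR)": "tRNA-Leu(UUR)"}


def _resolve(gene: str) -> str:
    return _ALIASES.get(gene, gene)


def params_from_solution(solution: str | dict, t_end: float = 32400.0,
                         run_up: float = 0.0) -> SimulationParams:
    sol = FITTED_SOLUTIONS[solution] if isinstance(solution, str) else solution
    return SimulationParams(
        promoter_intensities=dict(sol["promoter_intensities"]),
        factor_intensities=dict(sol["factor_intensities"]),
        p=sol["p"], q=sol["q"],
        elongation_rate=sol.get("elongation_rate", 500.0),
        t_end=t_end, run_up=run_up)


@dataclass
class HumanForwardReport:
    healthy: EnsembleResult
    melas: EnsembleResult
    ratio_R_healthy: float
    ratio_R_melas: float
    relative_protein_levels: pd.Series      # healthy, relative to ND1
    melas_fold_drop: pd.Series              # healthy mean / MELAS mean
    circling_healthy: dict
    polarization_healthy: dict


def human_forward_report(n_traj: int = 100, master_seed: int = 0,
                         t_end: float = 32400.0) -> HumanForwardReport:
    """Run the healthy and MELAS human parameter sets on the rCRS geometry."""
    geom = human_geometry()
    healthy = ensemble(geom, params_from_solution("human_healthy", t_end),
                       n_traj, master_seed)
    melas = ensemble(geom, params_from_solution("human_melas", t_end),
                     n_traj, master_seed + 1)
    nd1 = healthy.per_gene_mean["ND1"]
    rel = pd.Series({g: healthy.per_gene_mean[_resolve(g)] / nd1
                     for g in HUMAN_PROTEIN_PANEL})
    drops = {}
    for g in MELAS_PANEL:
        m = melas.per_gene_mean[_resolve(g)]
        drops[g] = healthy.per_gene_mean[_resolve(g)] / m if m > 0 else float("inf")
    return HumanForwardReport(
        healthy=healthy, melas=melas,
        ratio_R_healthy=ratio_R(healthy, "12S", "COX2"),
        ratio_R_melas=ratio_R(melas, "12S", "COX2"),
        relative_protein_levels=rel,
        melas_fold_drop=pd.Series(drops),
        circling_healthy=healthy.circling_mean_sd(),
        polarization_healthy=polarization(healthy, "mTERF"))


def genome_traversal_time(length: int = 16569, rate: float = 500.0) -> float:
    """Seconds for one polymerase to transcribe the full circle."""
    return length / rate
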