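"""Bundled genome geometries, experiment tables and fitted parameter sets.

The human geometry carries the full canonical rCRS gene annotation
(NC_012920.1) embedded as coordinates, so forward simulations of the whole
genome run without any download.  The rat (NC_001665.2) and frog
(NC_001573.1) fixtures carry genome length plus the experimentally mapped
promoter positions; their gene tables must be supplied by the user (GenBank
flat file, GFF3 or TSV) and merged with :func:`mitotx.geometry.merge_overlay`.
The mTERF site coordinates are editable per genome — for human the site is
the 28-bp region inside tRNA-Leu(UUR) immediately downstream of 16S rRNA.
"""

from __future__ import annotations

import pandas as pd

from .geometry import (HEAVY, LIGHT, FactorSite, Gene, GenomeGeometry,
                       Promoter)

# ----------------------------------------------------------------------
# Human (rCRS, NC_012920.1): 1-based inclusive coordinates from the
# canonical reference annotation.
# ----------------------------------------------------------------------

_HUMAN_LENGTH = 16569

_HUMAN_GENES_1BASED = [
    # (name, start, end, strand)
    ("tRNA-Phe", 577, 647, HEAVY),
    ("12S", 648, 1601, HEAVY),
    ("tRNA-Val", 1602, 1670, HEAVY),
    ("16S", 1671, 3229, HEAVY),
    ("tRNA-Leu(UUR)", 3230, 3304, HEAVY),
    ("ND1", 3307, 4262, HEAVY),
    ("tRNA-Ile", 4263, 4331, HEAVY),
    ("tRNA-Gln", 4329, 4400, LIGHT),
    ("tRNA-Met", 4402, 4469, HEAVY),
    ("ND2", 4470, 5511, HEAVY),
    ("tRNA-Trp", 5512, 5579, HEAVY),
    ("tRNA-Ala", 5587, 5655, LIGHT),
    ("tRNA-Asn", 5657, 5729, LIGHT),
    ("tRNA-Cys", 5761, 5826, LIGHT),
    ("tRNA-Tyr", 5826, 5891, LIGHT),
    ("COX1", 5904, 7445, HEAVY),
    ("tRNA-Ser(UCN)", 7446, 7514, LIGHT),
    ("tRNA-Asp", 7518, 7585, HEAVY),
    ("COX2", 7586, 8269, HEAVY),
    ("tRNA-Lys", 8295, 8364, HEAVY),
    ("ATP8", 8366, 8572, HEAVY),
    ("ATP6", 8527, 9207, HEAVY),
    ("COX3", 9207, 9990, HEAVY),
    ("tRNA-Gly", 9991, 10058, HEAVY),
    ("ND3", 10059, 10404, HEAVY),
    ("tRNA-Arg", 10405, 10469, HEAVY),
    ("ND4L", 10470, 10766, HEAVY),
    ("ND4", 10760, 12137, HEAVY),
    ("tRNA-His", 12138, 12206, HEAVY),
    ("tRNA-Ser(AGY)", 12207, 12265, HEAVY),
    ("tRNA-Leu(CUN)", 12266, 12336, HEAVY),
    ("ND5", 12337, 14148, HEAVY),
    ("ND6", 14149, 14673, LIGHT),
    ("tRNA-Glu", 14674, 14742, LIGHT),
    ("CYTB", 14747, 15887, HEAVY),
    ("tRNA-Thr", 15888, 15953, HEAVY),
    ("tRNA-Pro", 15956, 16023, LIGHT),
]

#: Experimentally mapped transcription-initiation sites (1-based).
PROMOTER_TSS = {
    "human": {"HSP1": (561, HEAVY), "HSP2": (646, HEAVY), "LSP": (407, LIGHT)},
    "rat": {"HSP1": (16298, HEAVY), "HSP2": (66, HEAVY), "LSP": (16193, LIGHT)},
    "frog": {"HSP1": (2102, HEAVY), "HSP2": (2049, HEAVY),
             "LSP1": (2103, LIGHT), "LSP2A": (2042, LIGHT), "LSP2B": (2033, LIGHT)},
}

GENOME_LENGTHS = {"human": _HUMAN_LENGTH, "rat": 16313, "frog": 17553}

#: mTERF binding region, 1-based inclusive (28 bp inside tRNA-Leu(UUR),
#: immediately downstream of 16S rRNA; the MELAS position 3243 lies inside).
HUMAN_MTERF_SITE = (3230, 3257)


def _promoters(species: str) -> list[Promoter]:
    return [Promoter(name, tss - 1, strand)
            for name, (tss, strand) in PROMOTER_TSS[species].items()]


def human_geometry() -> GenomeGeometry:
    """Full human mtDNA geometry: 37 genes, 3 promoters, the mTERF site."""
    L = _HUMAN_LENGTH
    genes = [Gene(n, s - 1, e % L, st) for n, s, e, st in _HUMAN_GENES_1BASED]
    s1, e1 = HUMAN_MTERF_SITE
    site = FactorSite("mTERF", s1 - 1, e1 % L)
    return GenomeGeometry(L, genes, _promoters("human"), [site], name="NC_012920.1")


def rat_geometry() -> GenomeGeometry:
    """Rat mtDNA skeleton: promoters only (genes supplied by the user)."""
    return GenomeGeometry(GENOME_LENGTHS["rat"], [], _promoters("rat"),
                          name="NC_001665.2")


def frog_geometry() -> GenomeGeometry:
    """Frog mtDNA skeleton: five promoters only (genes supplied by the user)."""
    return GenomeGeometry(GENOME_LENGTHS["frog"], [], _promoters("frog"),
                          name="NC_001573.1")


# ----------------------------------------------------------------------
# Experimental comparison data: rat transcript ratios and half-lives.
# Normalized mRNA/16S-rRNA ratios (u ± Δu, %) and half-lives (t ± Δt, min)
# per condition.  16S is the reference species (half-life only).
# ----------------------------------------------------------------------

_RAT_ROWS = [
    # gene, u_e, du_e, t_e, dt_e, u_h, du_h, t_h, dt_h
    ("16S", None, None, 44.48, 6.34, None, None, 87.50, 27.52),
    ("COX1", 100.0, 16.0, 84.41, 27.49, 86.0, 13.0, 235.12, 48.68),
    ("ATP6/8", 100.0, 19.0, 78.14, 21.05, 59.0, 9.0, 277.52, 31.58),
    ("COX3", 100.0, 19.0, 78.14, 21.05, 59.0, 9.0, 277.52, 31.58),
    ("ND4", 100.0, 16.0, 84.41, 27.49, 86.0, 13.0, 235.12, 48.68),
    ("ND5", 100.0, 25.0, 46.00, 10.41, 52.0, 11.0, 60.52, 5.92),
    ("CYTB", 100.0, 27.0, 63.70, 7.82, 57.0, 7.0, 204.30, 28.64),
]


def rat_experiment_frame() -> pd.DataFrame:
    """Rat steady-state data, long format: one row per gene × condition."""
    rows = []
    for g, ue, due, te, dte, uh, duh, th, dth in _RAT_ROWS:
        rows.append({"gene": g, "condition": "euthyroid",
                     "u": ue, "du": due, "t": te, "dt": dte})
        rows.append({"gene": g, "condition": "hypothyroid",
                     "u": uh, "du": duh, "t": th, "dt": dth})
    return pd.DataFrame(rows)


#: Transcription levels relative to ND1 in healthy human (experimental
#: estimates with absolute errors under the independence assumption, and
#: under the dependent-error bound).
HUMAN_EXPERIMENT_LEVELS = pd.DataFrame({
    "gene": ["ND2", "COX1", "COX2", "ATP6/8", "ND3", "ND5", "CYTB"],
    "level": [1.40, 1.04, 1.72, 0.91, 1.04, 1.86, 2.31],
    "delta_indep": [0.23, 0.52, 0.61, 0.43, 0.12, 0.56, 0.56],
    "delta_dep": [0.40, 0.82, 0.95, 0.71, 0.20, 0.99, 1.01],
}).set_index("gene")


# ----------------------------------------------------------------------
# Fitted parameter sets (forward-simulation inputs; obtained by the
# original large-scale optimization and NOT re-derived here).
# All intensities in binding attempts per second; elongation 500 nt/s.
# ----------------------------------------------------------------------

PASSAGE_PROBABILITIES = {
    # elongation rate nt/s -> (p heavy, q light)
    500: (0.0164, 0.0056),
    200: (0.2165, 0.0015),
}

FITTED_SOLUTIONS = {
    "human_healthy": {
        "promoter_intensities": {"LSP": 0.0031, "HSP1": 0.0031, "HSP2": 0.0126},
        "factor_intensities": {"mTERF": 0.6456},
        "p": 0.0164, "q": 0.0056, "elongation_rate": 500.0,
    },
    "human_melas": {
        "promoter_intensities": {"LSP": 0.0031, "HSP1": 0.0004, "HSP2": 0.0126},
        "factor_intensities": {"mTERF": 0.5336},
        "p": 0.0164, "q": 0.0056, "elongation_rate": 500.0,
    },
    # Rat reports the pooled intensity HSP = HSP1 + HSP2; the split between
    # the two heavy-strand promoters is exposed as a ratio option.
    "rat_euthyroid": {
        "promoter_intensities": {"LSP": 0.1056, "HSP": 0.0721},
        "factor_intensities": {"mTERF": 0.9453},
        "p": 0.0164, "q": 0.0056, "elongation_rate": 500.0,
    },
    "rat_hypothyroid": {
        "promoter_intensities": {"LSP": 0.1056, "HSP": 0.0336},
        "factor_intensities": {"mTERF": 0.9453},
        "p": 0.0164, "q": 0.0056, "elongation_rate": 500.0,
    },
}

#: Model-predicted reference observables reported with the fitted solutions.
REPORTED_OBSERVABLES = {
    "human_healthy": {"R": 23.955, "L1n": 1.945},
    "human_melas": {"R": 24.333},
    "rat_euthyroid": {"R": 30.605},
    "rat_hypothyroid": {"R": 30.637, "L1n": 1.736},
}


def split_hsp(total: float, hsp1_fraction: float = 0.5) -> dict[str, float]:
    """Split a pooled HSP intensity into HSP1/HSP2 by a fixed ratio."""
    if not 0.0 <= hsp1_fraction <= 1.0:
        raise ValueError("hsp1_fraction must be in [0,1]")
    return {"HSP1": total * hsp1_fraction, "HSP2": total * (1.0 - hsp1_fraction)}


def list_fixtures() -> dict[str, str]:
    return {
        "human": "full rCRS geometry (genes + promoters + mTERF site)",
        "rat": "promoter skeleton for NC_001665.2 (supply genes separately)",
        "frog": "promoter skeleton for NC_001573.1 (supply genes separately)",
        "rat_experiment": "steady-state mRNA/rRNA ratios and half-lives, both thyroid states",
        "human_experiment": "transcription levels relative to ND1 with absolute errors",
        "solutions": "fitted parameter sets for forward simulation",
    }
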