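"""Model-vs-experiment comparison statistics.

Transcription levels ``z`` predicted by the simulator are linked to
measured relative RNA concentrations ``u`` and half-lives ``t`` through
steady-state ratios: for a stationary pool, concentration ∝ z·t, so the
half-lives cancel out of time-course ratios of the same gene and enter
ratio comparisons between genes or conditions.  This module implements

* the steady-state expected ratios (u·t0/tj and the two-condition
  variant u·t0h·tje/(tjh·t0e)),
* the L1-type comparison functional Σ|x−y|/max(x,y) and its weighted
  multi-dataset generalisation,
* the absolute-error calculus for products/ratios/sums under the
  independence assumption or the dependent bound,
* the |a−b|/Δ within-error multiples and the signed percentage deviation,
* the lower bound on the phage-type polymerase elongation rate implied by
  concurrent transcription/translation (first exon/intron lengths).

Internal computation is full precision; the ``*_reported`` helpers round
to the conventional reporting precision (2 decimals for levels, 1 decimal
for Δ-multiples, integers for percentage deviations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: rule-of-thumb band of "insignificant" transcription-level change:
#: between halving (−50%) and doubling (+100%).
INSIGNIFICANT_BAND = (-50.0, 100.0)


# ----------------------------------------------------------------------
# Level ratios
# ----------------------------------------------------------------------

def relative_timecourse(z_ij: float, z_0j: float) -> float:
    """Level of a gene at time point i relative to the null time point.

    Half-lives of the same gene cancel, so u_ij = z_ij / z_0j.
    """
    if z_0j <= 0:
        raise ValueError("reference level must be positive")
    return z_ij / z_0j


def steady_state_expected(u_j: float, t0: float, t_j: float) -> float:
    """Expected model level ratio z_j/z_0 from measured u_j and half-lives.

    In a stationary state u_j = (z_j t_j)/(z_0 t_0), hence the model ratio
    z_j/z_0 is compared against u_j · t0 / t_j.
    """
    if t_j <= 0 or t0 <= 0:
        raise ValueError("half-lives must be positive")
    return u_j * t0 / t_j


def hypo_eu_ratio(u_j: float, t0h: float, t_je: float,
                  t_jh: float, t0e: float) -> float:
    """Two-condition (hypothyroid/euthyroid) expected level ratio.

    The measured quantity is u_j = (z_jh t_jh / z_0h t_0h) /
    (z_je t_je / z_0e t_0e); the model ratio z_jh z_0e/(z_0h z_je) is
    therefore compared with u_j · (t0h · t_je)/(t_jh · t0e).
    """
    for t in (t0h, t_je, t_jh, t0e):
        if t <= 0:
            raise ValueError("half-lives must be positive")
    return u_j * (t0h * t_je) / (t_jh * t0e)


# ----------------------------------------------------------------------
# Comparison functionals
# ----------------------------------------------------------------------

def l1n(x, y) -> float:
    """Σ |x−y| / max(x, y), the natural normalised L1 functional.

    Symmetric, non-negative, zero iff the vectors coincide; each term is
    at most 1, so the total is bounded by the number of entries.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    m = np.maximum(x, y)
    if np.any(m < 0):
        raise ValueError("entries must be non-negative")
    terms = np.zeros_like(m)
    nz = m > 0
    terms[nz] = np.abs(x[nz] - y[nz]) / m[nz]
    return float(terms.sum())


def l1n_total(datasets) -> float:
    """Weighted combination of per-dataset L1n scores.

    ``datasets`` is a sequence of (x, y, n_k) with dataset "dimension"
    n_k > 0; each dataset contributes with weight 1/(n_k · s),
    s = Σ_k 1/n_k.
    """
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    s = 0.0
    for _, _, nk in datasets:
        if nk <= 0:
            raise ValueError("dataset dimension must be positive")
        s += 1.0 / nk
    return sum(l1n(x, y) / (nk * s) for x, y, nk in datasets)


# ----------------------------------------------------------------------
# Absolute-error calculus
# ----------------------------------------------------------------------

def propagate_error(values, abs_errors, op: str = "product",
                    independent: bool = True) -> float:
    """Absolute error of a chain of products/ratios or of a sum.

    ``op='product'`` treats every entry as a multiplicative factor (a
    divisor has the same relative error as a multiplier, so the caller
    simply lists all factors of the numerator and denominator); the result
    error is |Π or result|·sqrt(Σ(Δx/x)²) when independent, or the bound
    |result|·Σ|Δx/x| otherwise.  The caller supplies the result magnitude
    via :func:`product_ratio_error` when the chain mixes ratios.

    ``op='sum'`` returns sqrt(ΣΔ²) (independent) or ΣΔ (dependent).
    """
    values = list(map(float, values))
    abs_errors = list(map(float, abs_errors))
    if len(values) != len(abs_errors):
        raise ValueError("values and errors must have equal length")
    if op == "sum":
        if independent:
            return math.sqrt(sum(e * e for e in abs_errors))
        return sum(abs(e) for e in abs_errors)
    if op == "product":
        result = math.prod(values)
        return product_ratio_error(result, values, abs_errors, independent)
    raise ValueError(f"unknown op {op!r}")


def product_ratio_error(result: float, values, abs_errors,
                        independent: bool = True) -> float:
    """Error of a product/ratio expression with known result magnitude."""
    rel = []
    for v, e in zip(values, abs_errors, strict=True):
        if v == 0:
            raise ZeroDivisionError("zero factor in relative-error propagation")
        rel.append(abs(e / v))
    if independent:
        return abs(result) * math.sqrt(sum(r * r for r in rel))
    return abs(result) * sum(rel)


@dataclass(frozen=True)
class WithinError:
    multiples: float          # c = |a−b|/Δ, full precision
    within: bool              # c <= 1
    reported: float           # c rounded to 1 decimal (table convention)
    infinite: bool = False


def within_error(a: float, b: float, delta: float) -> WithinError:
    """How many absolute errors Δ separate model value a from experiment b."""
    if delta < 0:
        raise ValueError("Δ must be non-negative")
    if delta == 0:
        if a == b:
            return WithinError(0.0, True, 0.0)
        return WithinError(math.inf, False, math.inf, infinite=True)
    c = abs(a - b) / delta
    return WithinError(c, c <= 1.0, round(c, 1))


def deviation_percent(a: float, b: float) -> float:
    """Signed percentage concordance (a−b)·100/b."""
    if b == 0:
        raise ValueError("experimental value b must be non-zero")
    return (a - b) * 100.0 / b


def deviation_reported(a: float, b: float) -> int:
    return round(deviation_percent(a, b))


def is_insignificant(dev_percent: float) -> bool:
    lo, hi = INSIGNIFICANT_BAND
    return lo < dev_percent < hi


def nep_rate_lower_bound(ratio: float | None = None,
                         exon: float | None = None,
                         intron: float | None = None,
                         ribosome_rate: float = 45.0) -> float:
    """Lower bound on the phage-type polymerase elongation rate (nt/s).

    Where transcription and translation are concurrent, transcription of
    the first intron must finish before translation of the first exon
    does, so the polymerase/ribosome rate ratio must exceed (E+I)/E.
    ``ribosome_rate`` defaults to 45 nt/s (15 codons/s).
    """
    if ratio is None:
        if exon is None or intron is None:
            raise ValueError("supply ratio, or exon and intron lengths")
        if exon <= 0 or intron < 0:
            raise ValueError("E must be > 0 and I >= 0")
        ratio = (exon + intron) / exon
    if ratio < 1:
        raise ValueError("(E+I)/E cannot be below 1")
    return ratio * ribosome_rate


# ----------------------------------------------------------------------
# Experiment tables and condition-level reports
# ----------------------------------------------------------------------

@dataclass
class ExperimentTable:
    """Per-gene relative concentrations and half-lives for one condition."""

    condition: str
    data: pd.DataFrame        # index: gene; columns u, du, t, dt
    reference_gene: str = "16S"

    def __post_init__(self):
        missing = {"u", "du", "t", "dt"} - set(self.data.columns)
        if missing:
            raise ValueError(f"experiment table lacks columns {sorted(missing)}")

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame, condition: str,
                        reference_gene: str = "16S") -> "ExperimentTable":
        sub = frame[frame["condition"] == condition].set_index("gene")
        return cls(condition, sub[["u", "du", "t", "dt"]], reference_gene)

    def genes(self) -> list[str]:
        return [g for g in self.data.index if g != self.reference_gene]


def read_experiment_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_experiment_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def two_condition_expected(eu: ExperimentTable, hypo: ExperimentTable) -> pd.DataFrame:
    """Experimental expected ratios for a two-condition comparison.

    For every gene present in both tables, computes the expected
    hypothyroid/euthyroid model ratio u·(t0h·tje)/(tjh·t0e) where
    u = u_h/u_e, together with its propagated absolute error under the
    independence assumption and the dependent bound.  Column
    ``value_reported`` rounds to 2 decimals.
    """
    ref = eu.reference_gene
    t0e, dt0e = eu.data.loc[ref, "t"], eu.data.loc[ref, "dt"]
    t0h, dt0h = hypo.data.loc[ref, "t"], hypo.data.loc[ref, "dt"]
    rows = {}
    for gene in eu.genes():
        if gene not in hypo.data.index:
            continue
        ue, due, tje, dtje = eu.data.loc[gene, ["u", "du", "t", "dt"]]
        uh, duh, tjh, dtjh = hypo.data.loc[gene, ["u", "du", "t", "dt"]]
        value = hypo_eu_ratio(uh / ue, t0h, tje, tjh, t0e)
        factors = [uh, ue, t0h, tje, tjh, t0e]
        errors = [duh, due, dt0h, dtje, dtjh, dt0e]
        rows[gene] = {
            "value": value,
            "value_reported": round(value, 2),
            "delta_indep": product_ratio_error(value, factors, errors, True),
            "delta_dep": product_ratio_error(value, factors, errors, False),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class ComparisonReport:
    """Per-gene model-vs-experiment comparison with error multiples."""

    table: pd.DataFrame = field(repr=False)
    l1n: float = 0.0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def compare_levels(model: pd.Series, experiment: pd.Series,
                   delta: pd.Series | None = None) -> ComparisonReport:
    """Compare model levels ``a`` with experimental levels ``b`` gene-wise."""
    genes = [g for g in experiment.index if g in model.index]
    rows = {}
    xs, ys = [], []
    for g in genes:
        a, b = float(model[g]), float(experiment[g])
        xs.append(a)
        ys.append(b)
        row = {"model": a, "experiment": b,
               "deviation_percent": deviation_reported(a, b),
               "insignificant": is_insignificant(deviation_percent(a, b))}
        if delta is not None and g in delta.index and delta[g] > 0:
            we = within_error(a, b, float(delta[g]))
            row["delta"] = float(delta[g])
            row["multiples_of_delta"] = we.reported
            row["within_error"] = we.within
        rows[g] = row
    return ComparisonReport(pd.DataFrame.from_dict(rows, orient="index"),
                            l1n=l1n(xs, ys))
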