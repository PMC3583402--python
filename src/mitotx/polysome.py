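"""Polysome–ribonuclease interaction model of mRNA half-life.

Ribosomes load onto an mRNA as a Poisson stream with intensity
λ = νN/(1+αN) (ν: specific binding intensity at low ribosome number N;
α: Michaelis–Menten saturation parameter, λ → ν/α as N → ∞) and then
translocate deterministically at V codons/s with mutual exclusion over
their own size h1 codons.  A ribonuclease of linear size h = V·w codons
attacks a specific cleavage site at intensity μ, but succeeds only while
a ribosome-free *window* of at least h codons is open at the site.
Averaging over the stationary window process gives the decay intensity

    κ = μ · exp(−λw) / (1 + dλ),        d = h1/V,

and hence the half-life τ = ln2/κ = ln2 · (1+dλ) · exp(wλ) / μ.  With k
independent cleavage sites per RNA, κ is replaced by κk (and τ by τ/k).
τ·κ = ln 2 identically (k = 1).

Defaults: V = 15 codons/s, h1 = 10 codons (d = 2/3 s), k = 1; physically
w ≥ 1/15 s and plausibly w ≤ 4/3 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

LN2 = math.log(2.0)

#: documented plausibility bounds on w (s): ribonuclease at least one codon,
#: likely at most 20 codons at V = 15 codons/s.
W_BOUNDS = (1.0 / 15.0, 4.0 / 3.0)


def binding_intensity(nu: float, alpha: float, N: float) -> float:
    """Ribosome-binding intensity λ = νN/(1+αN); saturates at ν/α."""
    if nu < 0 or alpha < 0 or N < 0:
        raise ValueError("nu, alpha and N must be non-negative")
    return nu * N / (1.0 + alpha * N)


@dataclass(frozen=True)
class PolysomeParams:
    """Parameter set of the polysome–ribonuclease model.

    mu: cleavage-attempt intensity at the site (1/s); nu, alpha, N define
    the ribosome-binding intensity; w is the ribonuclease size divided by
    the ribosome rate (s); V the ribosome rate (codons/s); h1 the ribosome
    size (codons); k the number of cleavage sites per RNA.
    """

    mu: float
    nu: float = 0.0
    alpha: float = 0.0
    N: float = 0.0
    w: float = W_BOUNDS[0]
    V: float = 15.0
    h1: float = 10.0
    k: int = 1
    enforce_w_bounds: bool = True

    def __post_init__(self):
        if self.mu < 0 or self.w < 0 or self.V <= 0 or self.h1 < 0 or self.k < 1:
            raise ValueError("invalid polysome parameters")
        if self.enforce_w_bounds and not (W_BOUNDS[0] <= self.w <= W_BOUNDS[1]):
            raise ValueError(
                f"w={self.w} outside the plausible bounds {W_BOUNDS}; "
                "pass enforce_w_bounds=False to override")

    @property
    def d(self) -> float:
        """Ribosome dead time h1/V (s)."""
        return self.h1 / self.V

    @property
    def lam(self) -> float:
        return binding_intensity(self.nu, self.alpha, self.N)


def half_life(params: PolysomeParams, lam: float | None = None) -> float:
    """mRNA half-life τ = ln2·(1+dλ)·exp(wλ)/(μk); infinite when μ = 0."""
    lam = params.lam if lam is None else lam
    if params.mu == 0:
        return math.inf
    return LN2 * (1.0 + params.d * lam) * math.exp(params.w * lam) / (params.mu * params.k)


def decay_intensity(params: PolysomeParams, lam: float | None = None) -> float:
    """Decay intensity κk = k·μ·exp(−λw)/(1+dλ)."""
    lam = params.lam if lam is None else lam
    return params.k * params.mu * math.exp(-lam * params.w) / (1.0 + params.d * lam)


def half_life_ratio(lam: float, lam_prime: float, d: float, w: float) -> float:
    """τ/τ′ between two ribosome-loading states with shared μ, d, w.

    Equals [(1+dλ)/(1+dλ′)]·exp(w(λ−λ′)); > 1 whenever λ > λ′ (more
    ribosomes protect the transcript).
    """
    return (1.0 + d * lam) / (1.0 + d * lam_prime) * math.exp(w * (lam - lam_prime))


def solve_lambda(tau_obs: float, mu: float, w: float, d: float, k: int = 1) -> float:
    """Invert the half-life formula for λ (unique root: τ is increasing in λ)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    tau_min = LN2 / (mu * k)
    if tau_obs < tau_min * (1.0 - 1e-12):
        raise ValueError(f"observed half-life {tau_obs} below the unprotected "
                         f"minimum ln2/(mu*k) = {tau_min}")
    c = tau_obs * mu * k / LN2     # (1+dλ)exp(wλ) = c, c >= 1

    def f(lam):
        return (1.0 + d * lam) * math.exp(w * lam) - c

    if f(0.0) >= 0.0:
        return 0.0
    hi = 1.0
    while f(hi) < 0.0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket λ")
    return float(brentq(f, 0.0, hi, xtol=1e-14, rtol=1e-14))


def solve_nu(tau_obs: float, w: float, d: float, alpha: float, N: float,
             mu: float, k: int = 1) -> float:
    """Specific binding intensity ν reproducing an observed half-life.

    Inverts τ(λ) for λ and then ν = λ(1+αN)/N.  Requires N > 0 unless the
    observed half-life equals the unprotected minimum (λ = 0 → ν = 0).
    """
    lam = solve_lambda(tau_obs, mu, w, d, k)
    if lam == 0.0:
        return 0.0
    if N <= 0:
        raise ValueError("N must be positive to recover ν from λ > 0")
    return lam * (1.0 + alpha * N) / N


@dataclass
class PolysomeModel:
    """Closed-form polysome protection model for one mRNA species.

    A thin model object bundling the parameter set with the derived
    observables; `summary()` prints λ, τ and κ.
    """

    params: PolysomeParams
    results_: dict = field(default_factory=dict, init=False)

    @classmethod
    def from_rates(cls, mu, nu=0.0, alpha=0.0, N=0.0, w=W_BOUNDS[0], k=1,
                   **kw) -> "PolysomeModel":
        return cls(PolysomeParams(mu=mu, nu=nu, alpha=alpha, N=N, w=w, k=k, **kw))

    def evaluate(self) -> dict:
        p = self.params
        lam = p.lam
        self.results_ = {
            "lambda": lam,
            "half_life_s": half_life(p),
            "decay_intensity_per_s": decay_intensity(p),
            "window_codons": p.V * p.w,
        }
        return self.results_

    def half_life_ratio_vs(self, N_prime: float) -> float:
        """τ/τ′ when the ribosome number changes from N to N′ (same ν, α)."""
        p = self.params
        lam = p.lam
        lam_p = binding_intensity(p.nu, p.alpha, N_prime)
        return half_life_ratio(lam, lam_p, p.d, p.w)

    def summary(self) -> str:
        r = self.evaluate()
        p = self.params
        lines = [
            "Polysome-ribonuclease decay model",
            f"  mu={p.mu:g}/s  nu={p.nu:g}  alpha={p.alpha:g}  N={p.N:g}  "
            f"w={p.w:g}s  d={p.d:g}s  k={p.k}",
            f"  ribosome binding intensity lambda = {r['lambda']:.6g} /s",
            f"  decay intensity kappa*k           = {r['decay_intensity_per_s']:.6g} /s",
            f"  half-life tau                     = {r['half_life_s']:.6g} s",
            f"  ribonuclease window h = V*w       = {r['window_codons']:.6g} codons",
        ]
        return "\n".join(lines)
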