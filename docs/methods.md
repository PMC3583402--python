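# Methods

## The model

Animal mitochondrial DNA is a circle of 15–18 kbp transcribed exclusively
by nuclear-encoded phage-type (T7/T3-like) RNA polymerases.  `mitotx`
simulates polymerase traffic on such a circle as a continuous-time
event-driven process:

* **Promoter binding.**  Each promoter emits binding *attempts* as a
  Poisson process with intensity λ (attempts per second of modeled time).
  An attempt succeeds iff no polymerase footprint and no bound protein
  overlaps the promoter footprint, even partially.  A successful attempt
  creates a polymerase at the TSS that starts elongating immediately.
* **Elongation.**  Deterministic, at a constant rate v (nt/s) shared by
  all polymerases.  The default is 500 nt/s; 200 nt/s is the conventional
  control value.  A lower bound on v follows from loci where transcription
  and translation are concurrent: transcription of the first intron must
  finish before translation of the first exon, so v/v_ribosome ≥ (E+I)/E.
  With v_ribosome = 45 nt/s the largest reliable exon/intron ratios give
  bounds of 177–462 nt/s (`nep_rate_lower_bound`).
* **Footprint.**  A polymerase occupies −15..+1 nt around its active
  position in transcription direction (17 nt, from footprinting and
  crystallography of the T7 enzyme).  Promoter footprints use the same
  span around the TSS.
* **Protein terminator (mTERF).**  A factor site (28 bp by default)
  receives Poisson binding attempts at intensity λ_mTERF; an attempt
  succeeds iff the site is unbound and clear of polymerases.  A polymerase
  reaching a *bound* site passes with probability p (heavy strand) or q
  (light strand); a pass dissociates the complex, a stop terminates the
  polymerase and leaves the complex in place.  Spontaneous dissociation is
  folded into λ_mTERF and is not a separate event; the only route from
  bound to unbound is a pass-through.  The directional asymmetry of the
  stop fractions is the terminator *polarization*.
* **G-quadruplex terminators.**  Optional sites that terminate each
  passing polymerase on their strand with a fixed probability.  The
  default probability is 0 everywhere; a user must supply a value.
* **Collisions.**  Two polymerases converging on the circle meet after
  gap/(2v) seconds, where the gap is the arc both are entering; a head-on
  collision terminates *both*.  Equal speeds make same-direction
  collisions impossible, and in continuous time simultaneous events have
  probability zero (floating-point ties break by event creation order).
* **Circular transcription.**  An unterminated polymerase keeps circling;
  a transcript covers a gene iff the polymerase traversed the gene's full
  span on the gene's strand, and every additional full circle over the
  gene counts again.  Partial coverage counts zero.  Counting is
  restricted to cover-completion times in `(run_up, t_end]`; the default
  window is 9 h of modeled time with no run-up.

The engine keeps one scheduled arrival event per polymerase (nearest bound
site edge, quadruplex, predicted meeting, or horizon) in a binary heap and
reschedules affected polymerases whenever the obstacle landscape changes.
Because two live polymerases move at the same speed, their meeting time is
invariant from the moment both exist; meeting events therefore validate on
the partner still being alive rather than on a version stamp.  The engine
is statistically equivalent to naive 1-nt-per-tick stepping; the test
suite enforces this against `mitotx.reference.run_trajectory_fixed_step`,
an independently coded fixed-step simulator kept deliberately simple.

### Consequences worth knowing

* On a circle with no terminators a polymerase never leaves, so circling
  traffic periodically occludes its own promoter: sustained binding rates
  are below λ/(1+λ·17/v) whenever polymerases accumulate.  Oracle tests
  that need the clean renewal rate place an opaque terminator downstream.
* With pass-through as the only dissociation route, a terminator with any
  appreciable binding intensity is bound essentially always.  Polarization
  then equals (1−p, 1−q) exactly, and the ratio of rRNA to downstream
  mRNA transcription approaches 1/p.  With the published human parameter
  set this yields R ≈ 60 and ≈ 8 heavy-strand polymerases completing
  circles per 9 h, whereas the source analysis reports R ≈ 24 and 23 ± 6;
  reproducing those values would require partial site occupancy (an
  explicit dissociation process), which this package deliberately does not
  model.  The MELAS rRNA fold change (≈ 1.2×) and the near-uniform
  protein-gene levels are reproduced.

## Ensembles and observables

Per-trajectory seeds derive from one master seed via
`numpy.random.SeedSequence.spawn`, so ensemble results are independent of
execution order and an interrupted run resumed from a checkpoint file is
bit-identical to an uninterrupted one.  Ensembles report per-gene mean ±
unbiased SD, terminator stop/pass tallies per direction, head-on collision
counts, and the number of polymerases that completed at least one full
circle inside the counting window (the alternative statistic — crossings
of the polymerase's own TSS — differs only for polymerases terminating
mid-circle).

## Comparison statistics

Measured relative RNA concentrations u and half-lives t connect to
transcription levels z through stationarity (concentration ∝ z·t):

* same-gene time courses: u_ij = z_ij/z_0j (half-lives cancel);
* steady-state gene ratios: compare model z_j/z_0 with u_j·t0/tj;
* two-condition (hypothyroid/euthyroid) ratios: compare with
  u_j·(t0h·tje)/(tjh·t0e).

The comparison functional is L1n = Σ|x−y|/max(x,y) (each term ≤ 1), with
a 1/(n_k·s) weighted combination across datasets of dimension n_k,
s = Σ 1/n_k.  Absolute errors propagate by root-sum-square of relative
errors under independence, or by the sum bound otherwise; the independent
estimate never exceeds the dependent bound.  Agreement is reported as the
multiple c = |a−b|/Δ and as the signed percentage deviation (a−b)·100/b,
with changes between −50% and +100% conventionally "insignificant".
Reporting rounds to 2 decimals for levels, 1 decimal for c, integers for
deviations; computation keeps full precision.  Deviations are computed
against the 2-decimal reported experimental values (that convention, not
full precision, reproduces the published deviation rows); error multiples
use full-precision errors.

Known source-table discrepancies that this package documents but does not
chase: the ND3 deviation (−4 printed, −8 from the printed cells), the COX1
error (0.35 printed, 0.34 recomputed), the ND2 error multiple (1.8
printed, 1.7 from printed cells), and the weighted L1n totals (≈ 2% off
when recombined from the printed per-dataset values).

## Inverse problem ("active search")

`TranscriptionModel(geometry, experiment).fit()` minimizes L1n over
promoter intensities, λ_mTERF, p and q by multi-start coordinate descent
on a log scale, with three refinements:

* **Common random numbers.**  Every candidate is evaluated with the same
  derived ensemble seed, so the Monte-Carlo objective is deterministic and
  candidate comparisons are not dominated by sampling noise — essential on
  a response landscape with many shallow valleys.
* **Ridge moves.**  Levels of genes downstream of the terminator scale
  like λ·p, so the objective has diagonal valleys where single-coordinate
  steps stall; each sweep also tries paired opposite moves (×f on one
  parameter, ÷f on another) for every parameter pair.
* **Active-search boundary.**  Raising a strand's promoter intensity is
  abandoned as soon as any opposing-strand gene's transcription reaches
  zero: a silent strand means it is blocked by the opposing polymerase
  flow, and further increase cannot improve the fit.

Bounds default to [1e-4, 1] attempts/s for intensities (the magnitude of
the published solutions) and [1e-3, 1] for probabilities.  The
multiplicative step starts at 4 and anneals to 1.1, which bounds the
resolution of each estimate and is reported in the results object.
Estimates pinned at a bound are flagged.  Fitting against purely relative
levels leaves the absolute intensity scale only weakly identified (through
collisions and occupancy); the parameter-recovery validation therefore
uses absolute per-gene counts.  Verified at desk scale: on a 3-kb
two-promoter toy genome with a polarized terminator, 200 trajectories per
evaluation and 3 restarts recover (λ_H, λ_L) within a few percent
(tolerance 25%) and p within ±0.01 (tolerance ±0.1) in ~7 minutes on one
CPU.

## Polysome–ribonuclease decay model

Ribosomes load on an mRNA at λ = νN/(1+αN) (saturating at ν/α) and
translocate at V = 15 codons/s with exclusion over their own h1 = 10
codons (dead time d = h1/V = 2/3 s).  A ribonuclease of size h = V·w
codons attacks a cleavage site at intensity μ but succeeds only during a
ribosome-free window of at least h codons; averaging the stationary window
process gives κ = μ·e^{−λw}/(1+dλ) and τ = ln2/κ, with κ → κk for k
independent cleavage sites.  τ·κ = ln 2 identically; τ is strictly
increasing in λ, w, d, and κ strictly decreasing in λ.  Physically
w ∈ [1/15, 4/3] s (enforced by default, overridable).  Inversion for ν
from an observed half-life uses bracketed root finding on the strictly
increasing τ(λ); τ_obs below ln2/(μk) is infeasible, since ribosome
protection can only lengthen the naked half-life.

The closed form describes the *stationary* stream; the Monte-Carlo oracle
in the test suite therefore measures the long-run cleavage rate of the
literal window process (renewal gaps, dead time, Poisson attacks gated on
window age ≥ w) rather than a cold-start first passage, whose initial
naked-mRNA transient inflates the first-passage time by roughly d+w.

## Synthetic data and scope

The toy-genome generator produces small circular geometries (two
convergent promoters, genes on both strands on both sides of a polarized
terminator) that exercise every mechanism — occupancy exclusion,
collisions, polarized termination, multi-circle counting — at sizes where
the fixed-step oracle is affordable.  What it does not emulate: sequence
effects on elongation, transcription-factor (mtTFA/mtTFB) kinetics,
abortive initiation, RNA secondary structure, replication, or the real
genomes' full gene complements (only the human fixture bundles a complete
annotation).  Passing tests therefore validate the traffic model and its
statistics, not the biological completeness of any particular genome
description.

Problem sizes in the default test run were chosen for single-CPU work:
ensembles of 200–500 trajectories, toy genomes of 2–3 kb, 90 s–30 min
horizons for oracle comparisons, and 9-h horizons only for the
whole-genome forward checks at 80 trajectories.

## Numerical choices

* Coordinates are 0-based half-open modulo the genome length; external
  formats are 1-based inclusive.  Heavy-strand transcription moves toward
  increasing coordinates.
* A 1e-6 nt tolerance absorbs float rounding when a polymerase terminates
  exactly at a gene's downstream end (it happens systematically where a
  terminator abuts a gene).
* Promoter attempt streams draw exponential gaps lazily; all randomness
  flows from `numpy.random.default_rng` seeded per trajectory.
* Factor-site encounters trigger at the site's entry edge in the
  polymerase's direction of travel; after a pass the dissociated site
  cannot retrigger, and a site that rebinds behind a polymerase already
  inside the interval is not re-encountered until the next circle.
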