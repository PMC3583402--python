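"""Event-engine correctness: kinematics, occupancy, conservation, limits."""

import numpy as np
import pytest
from scipy import stats

from mitotx import (SimulationParams, attempt_binding, encounter_factor,
                    make_toy_genome, next_meeting_time, run_trajectory)
from mitotx.geometry import FactorSite, Promoter
from mitotx.observables import derive_seeds, ensemble


class TestMeetingKinematics:
    def test_head_on_basic(self):
        # gap 1000 nt closing at 2*500 nt/s
        assert next_meeting_time(0, +1, 1000, -1, 500.0, 2000) == pytest.approx(1.0)

    def test_codirectional_never_meet(self):
        assert next_meeting_time(0, +1, 1000, +1, 500.0, 2000) is None

    def test_converging_across_origin(self):
        # heavy at 1900 moving up, light at 100 moving down: the arc both are
        # entering spans the origin and is (100-1900) mod 2000 = 200 nt
        t = next_meeting_time(1900, +1, 100, -1, 500.0, 2000)
        assert t == pytest.approx(200 / 1000)
        # and the gap measure is symmetric between the two partners
        assert t == pytest.approx(next_meeting_time(100, -1, 1900, +1, 500.0, 2000))


class TestFactorEncounter:
    def test_deterministic_limits(self):
        rng = np.random.default_rng(0)
        site = FactorSite("T", 100, 128, pass_prob_heavy=1.0, pass_prob_light=0.0)
        assert all(encounter_factor("heavy", site, rng) == "pass" for _ in range(50))
        assert all(encounter_factor("light", site, rng) == "terminate"
                   for _ in range(50))

    def test_bernoulli_frequency_at_published_p(self):
        # p = 0.0164: heavy-strand passage probability of the bound terminator
        p = 0.0164
        rng = np.random.default_rng(12345)
        site = FactorSite("T", 0, 28, pass_prob_heavy=p)
        n = 100_000
        passes = sum(encounter_factor("heavy", site, rng) == "pass"
                     for _ in range(n))
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(passes / n - p) < 3 * sigma + 1e-12


class TestBindingOccupancy:
    def test_empty_locus_binds(self):
        prom = Promoter("P", 100, "heavy")
        assert attempt_binding(prom, ([], [], 1000)) == "bound"

    def test_single_nt_overlap_rejects(self):
        prom = Promoter("P", 100, "heavy")   # footprint arc [85, 102)
        # heavy polymerase at 117 occupies [102,119) -> no overlap
        assert attempt_binding(prom, ([(117, +1)], [], 1000)) == "bound"
        # at 116 it occupies [101,118): one nucleotide of overlap
        assert attempt_binding(prom, ([(116, +1)], [], 1000)) == "rejected"

    def test_bound_factor_overlapping_rejects(self):
        prom = Promoter("P", 100, "heavy")
        assert attempt_binding(prom, ([], [(101, 28)], 1000)) == "rejected"
        assert attempt_binding(prom, ([], [(102, 28)], 1000)) == "bound"

    def test_promoter_dead_time_thinning(self):
        """High-frequency attempts are thinned by the footprint clearance
        dead time: after each success the promoter is blocked for
        footprint/v seconds, so the renewal rate is exactly λ/(1+λτ)."""
        lam, v = 10.0, 500.0
        tau = 17 / v
        # polymerases retire at an opaque terminator so that only the
        # freshly bound polymerase ever occludes the promoter footprint
        g = make_toy_genome(2000, promoter_specs=[("P", 50, "heavy")],
                            factor_specs=[("STOP", 1500, 28, 0.0, 0.0, 5.0)])
        par = SimulationParams(promoter_intensities={"P": lam},
                               factor_intensities={"STOP": 5.0}, p=0.0, q=0.0,
                               elongation_rate=v, t_end=200.0)
        n = 40
        rates = np.array([run_trajectory(g, par, s).bindings / par.t_end
                          for s in derive_seeds(0, n)])
        expected = lam / (1 + lam * tau)
        se = np.std(rates, ddof=1) / np.sqrt(n)
        assert abs(np.mean(rates) - expected) < 4 * se


class TestTrajectoryInvariants:
    def test_zero_intensities_zero_counts(self, toy_convergent):
        par = SimulationParams(promoter_intensities={}, t_end=100.0)
        tc = run_trajectory(toy_convergent, par, 3)
        assert tc.bindings == 0 and tc.collisions == 0
        assert all(v == 0 for v in tc.per_gene_transcripts.values())

    def test_conservation_and_determinism(self, toy_convergent, toy_params):
        a = run_trajectory(toy_convergent, toy_params, 11)
        b = run_trajectory(toy_convergent, toy_params, 11)
        assert a.bindings == a.terminations + a.active_at_end
        assert a.per_gene_transcripts == b.per_gene_transcripts
        assert a.terminator_stops == b.terminator_stops
        assert a.collisions == b.collisions

    def test_stop_plus_pass_equals_encounters(self, toy_convergent, toy_params):
        tc = run_trajectory(toy_convergent, toy_params, 7)
        for strand in ("heavy", "light"):
            enc = tc.encounters("TERM", strand)
            assert enc == (tc.terminator_stops.get(("TERM", strand), 0)
                           + tc.terminator_passes.get(("TERM", strand), 0))
            assert enc > 0

    def test_run_up_discards_early_covers(self):
        """With a warm-up window only covers completing after run_up count:
        halving the counting window roughly halves the transcript count."""
        g = make_toy_genome(2000, promoter_specs=[("P", 50, "heavy")],
                            gene_specs=[("G", 70, 570, "heavy")],
                            factor_specs=[("STOP", 1500, 28, 0.0, 0.0, 2.0)])
        full = SimulationParams(promoter_intensities={"P": 0.05},
                                factor_intensities={"STOP": 2.0}, p=0.0, q=0.0,
                                elongation_rate=500.0, t_end=1200.0)
        half = SimulationParams(promoter_intensities={"P": 0.05},
                                factor_intensities={"STOP": 2.0}, p=0.0, q=0.0,
                                elongation_rate=500.0, t_end=1200.0,
                                run_up=600.0)
        n = 100
        seeds = derive_seeds(21, n)
        m_full = np.mean([run_trajectory(g, full, s).per_gene_transcripts["G"]
                          for s in seeds])
        m_half = np.mean([run_trajectory(g, half, s).per_gene_transcripts["G"]
                          for s in seeds])
        assert m_half == pytest.approx(m_full / 2, rel=0.2)

    def test_invalid_inputs_raise(self, toy_convergent):
        with pytest.raises(ValueError):
            run_trajectory(toy_convergent,
                           SimulationParams(t_end=-1.0), 0)
        with pytest.raises(ValueError):
            SimulationParams(promoter_intensities={"P": -0.1}).validate()


class TestTerminatorLimits:
    def test_transparent_terminator_matches_no_terminator(self):
        """p=q=1: every encounter passes, so gene statistics must be
        indistinguishable from the same geometry without the site."""
        spec = dict(
            length=2000,
            promoter_specs=[("PH", 100, "heavy"), ("PL", 1900, "light")],
            gene_specs=[("GH", 1100, 1600, "heavy"), ("GL", 1300, 1800, "light")])
        with_site = make_toy_genome(
            factor_specs=[("T", 900, 28, 1.0, 1.0, 0.5)], **spec)
        without = make_toy_genome(**spec)
        par = SimulationParams(promoter_intensities={"PH": 0.05, "PL": 0.03},
                               factor_intensities={"T": 0.5}, p=1.0, q=1.0,
                               elongation_rate=200.0, t_end=200.0)
        n = 500
        r1 = ensemble(with_site, par, n, 101)
        r2 = ensemble(without, par, n, 202)
        for gene in ("GH", "GL"):
            res = stats.ttest_ind(r1.gene_counts[gene], r2.gene_counts[gene],
                                  equal_var=False)
            assert res.pvalue > 0.01

    def test_always_bound_stop_fractions_approach_complements(self):
        """With a saturating binding intensity the stop fraction per
        direction converges to 1-p (heavy) and 1-q (light)."""
        p, q = 0.3, 0.1
        g = make_toy_genome(
            2000,
            promoter_specs=[("PH", 100, "heavy"), ("PL", 1900, "light")],
            gene_specs=[("GH", 200, 700, "heavy")],
            factor_specs=[("T", 900, 28, p, q, 50.0)])
        par = SimulationParams(promoter_intensities={"PH": 0.05, "PL": 0.03},
                               factor_intensities={"T": 50.0}, p=p, q=q,
                               elongation_rate=200.0, t_end=200.0)
        res = ensemble(g, par, 300, 5)
        for strand, prob in (("heavy", p), ("light", q)):
            stops = res.terminator_stops.get(("T", strand), 0)
            passes = res.terminator_passes.get(("T", strand), 0)
            n = stops + passes
            assert n > 500
            frac = stops / n
            sigma = np.sqrt(prob * (1 - prob) / n)
            assert abs(frac - (1 - prob)) < 4 * sigma

    def test_unbound_site_is_transparent(self):
        g = make_toy_genome(
            2000, promoter_specs=[("PH", 100, "heavy")],
            gene_specs=[("GH", 1100, 1600, "heavy")],
            factor_specs=[("T", 900, 28, 0.0, 0.0, 0.0)])  # never binds
        par = SimulationParams(promoter_intensities={"PH": 0.05},
                               factor_intensities={"T": 0.0}, p=0.0, q=0.0,
                               elongation_rate=200.0, t_end=100.0)
        tc = run_trajectory(g, par, 1)
        assert tc.encounters("T", "heavy") == 0
        assert tc.per_gene_transcripts["GH"] > 0


class TestMonotonicity:
    def test_raising_opposing_intensity_cannot_raise_heavy_levels(self):
        """More light-strand flux means more head-on annihilation of heavy
        polymerases, never less (paired ensembles, common random numbers)."""
        g = make_toy_genome(
            2000,
            promoter_specs=[("PH", 100, "heavy"), ("PL", 1900, "light")],
            gene_specs=[("GH", 1100, 1600, "heavy")])
        low = SimulationParams(promoter_intensities={"PH": 0.05, "PL": 0.005},
                               elongation_rate=200.0, t_end=300.0)
        high = SimulationParams(promoter_intensities={"PH": 0.05, "PL": 0.2},
                                elongation_rate=200.0, t_end=300.0)
        n = 200
        m_low = ensemble(g, low, n, 77).per_gene_mean["GH"]
        m_high = ensemble(g, high, n, 77).per_gene_mean["GH"]
        assert m_high < m_low
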