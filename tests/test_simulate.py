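"""Probe sampling, judgment rules, trial simulation, and dataset generation."""

import numpy as np
import pandas as pd
import pytest

from wmbias import circular as c
from wmbias import simulate as s
from wmbias.exceptions import InvalidDesignError, InvalidParameterError


class TestProbeSamplingExp1:
    def test_distances_within_range_and_sides_balanced(self, rng):
        dists = []
        for _ in range(10_000):
            probe = s.sample_probe_exp1(90.0, rng)
            dists.append(float(c.signed_circ_dist(probe, 90.0)))
        mags = np.abs(dists)
        assert mags.min() >= 16 and mags.max() <= 105
        clockwise = np.mean(np.array(dists) > 0)
        assert 0.48 <= clockwise <= 0.52

    def test_seeded_determinism(self):
        a = s.sample_probe_exp1(0.0, np.random.default_rng(3))
        b = s.sample_probe_exp1(0.0, np.random.default_rng(3))
        assert a == b


class TestProbePairsExp2:
    def test_same_side_shares_sign(self, rng):
        for _ in range(200):
            (sim1, dis1), (sim2, dis2) = s.sample_probe_pairs_exp2(50.0, "same", rng)
            o1 = float(c.signed_circ_dist(sim1, 50.0))
            o2 = float(c.signed_circ_dist(sim2, 50.0))
            assert np.sign(o1) == np.sign(o2)
            assert 16 <= abs(o1) <= 45 and 16 <= abs(o2) <= 45
            assert c.signed_circ_dist(dis1, sim1) == pytest.approx(180)
            assert c.signed_circ_dist(dis2, sim2) == pytest.approx(180)

    def test_opposite_side_flips_sign(self, rng):
        for _ in range(200):
            (sim1, _), (sim2, _) = s.sample_probe_pairs_exp2(310.0, "opposite", rng)
            o1 = float(c.signed_circ_dist(sim1, 310.0))
            o2 = float(c.signed_circ_dist(sim2, 310.0))
            assert np.sign(o1) == -np.sign(o2)

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(InvalidDesignError):
            s.sample_probe_pairs_exp2(0.0, "sideways", rng)


class TestJudgments:
    def test_probability_half_at_criterion(self):
        rng = np.random.default_rng(0)
        hits = sum(
            s.simulate_similarity_judgment(0.0, 60.0, c=60, beta=15, rng=rng) == "similar"
            for _ in range(4000)
        )
        assert 0.46 <= hits / 4000 <= 0.54

    def test_small_beta_approaches_threshold_rule(self):
        rng = np.random.default_rng(0)
        assert (
            s.simulate_similarity_judgment(0.0, 30.0, c=60, beta=1e-6, rng=rng)
            == "similar"
        )
        assert (
            s.simulate_similarity_judgment(0.0, 90.0, c=60, beta=1e-6, rng=rng)
            == "dissimilar"
        )

    def test_similarity_decreases_with_distance(self):
        rng = np.random.default_rng(1)
        near = sum(
            s.simulate_similarity_judgment(0.0, 25.0, 60, 15, rng) == "similar"
            for _ in range(2000)
        )
        far = sum(
            s.simulate_similarity_judgment(0.0, 95.0, 60, 15, rng) == "similar"
            for _ in range(2000)
        )
        assert near > far

    def test_2afc_picks_perceptually_closer_probe(self, rng):
        assert s.simulate_2afc_choice(30.0, (30.0, 210.0), rng) == 30.0
        # near-ceiling accuracy under moderate memory noise
        correct = 0
        for _ in range(5000):
            x_m = 0.0 + np.rad2deg(rng.vonmises(0.0, 10.0))
            correct += s.simulate_2afc_choice(x_m, (30.0, 210.0), rng) == 30.0
        assert correct / 5000 > 0.85

    def test_2afc_ties_split_evenly(self):
        rng = np.random.default_rng(9)
        picks = [s.simulate_2afc_choice(0.0, (90.0, 270.0), rng) for _ in range(2000)]
        frac = np.mean(np.array(picks) == 90.0)
        assert 0.45 <= frac <= 0.55


class TestTrialSimulation:
    def test_baseline_reports_are_unbiased(self):
        rng = np.random.default_rng(4)
        design = s.exp1_design()
        obs = s.ObserverSpec(lapse_rate=0.0)
        offsets = []
        for _ in range(10_000):
            rec = s.simulate_trial(design, obs, "baseline", rng)
            offsets.append(float(c.signed_circ_dist(rec.response, rec.s_m)))
        assert abs(np.mean(offsets)) < 1.0

    def test_joint_observer_attracted_to_similar_probe(self):
        rng = np.random.default_rng(5)
        design = s.exp1_design()
        obs = s.ObserverSpec(lapse_rate=0.0)
        toward = []
        for _ in range(4000):
            rec = s.simulate_trial(design, obs, "comparison", rng)
            if rec.judgment1 == "similar":
                off = float(c.signed_circ_dist(rec.response, rec.s_m))
                direction = np.sign(float(c.signed_circ_dist(rec.probe1_sim, rec.s_m)))
                toward.append(off * direction)
        assert np.mean(toward) > 2.0

    def test_unknown_condition_rejected(self, rng):
        with pytest.raises(InvalidDesignError):
            s.simulate_trial(s.exp1_design(), s.ObserverSpec(), "same_side", rng)

    def test_lapse_trials_get_no_confidence(self):
        rng = np.random.default_rng(6)
        obs = s.ObserverSpec(lapse_rate=1.0)
        rec = s.simulate_trial(s.exp1_design(), obs, "baseline", rng)
        assert rec.confidence == 3


class TestDatasetGeneration:
    def test_exp1_trial_counts(self):
        table = s.generate_dataset(s.exp1_design(), [s.ObserverSpec()], seed=1)
        assert len(table) == 12 * (12 + 36)
        counts = table["condition"].value_counts()
        assert counts["baseline"] == 144 and counts["comparison"] == 432

    def test_exp3_trial_counts(self):
        table = s.generate_dataset(s.exp3_design(), [s.ObserverSpec()] * 2, seed=1)
        per = table.groupby("participant_id").size()
        assert (per == 4 * 30).all()

    def test_same_seed_gives_identical_tables(self):
        pop = [s.ObserverSpec(), s.ObserverSpec(kappa_m=6.0)]
        t1 = s.generate_dataset(s.exp2_design(), pop, seed=42)
        t2 = s.generate_dataset(s.exp2_design(), pop, seed=42)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_generated_rows_satisfy_probe_invariants(self):
        table = s.generate_dataset(s.exp2_design(), [s.ObserverSpec()] * 3, seed=7)
        comp = table.dropna(subset=["probe1_sim"])
        for i in (1, 2):
            d_sim = np.abs(
                c.signed_circ_dist(comp[f"probe{i}_sim"], comp["S_M"])
            )
            assert (d_sim >= 16).all() and (d_sim <= 45).all()
            anti = c.signed_circ_dist(comp[f"probe{i}_dis"], comp[f"probe{i}_sim"])
            assert np.allclose(anti, 180)
        same = comp[comp["condition"] == "same_side"]
        s1 = np.sign(c.signed_circ_dist(same["probe1_sim"], same["S_M"]))
        s2 = np.sign(c.signed_circ_dist(same["probe2_sim"], same["S_M"]))
        assert np.array_equal(s1, s2)
        assert table["confidence"].isin([1, 2, 3]).all()

    def test_empty_population_rejected(self):
        with pytest.raises(InvalidParameterError):
            s.generate_dataset(s.exp1_design(), [], seed=0)


class TestPopulation:
    def test_population_size_and_determinism(self):
        pop = s.generate_population_exp3(110, seed=3)
        pop2 = s.generate_population_exp3(110, seed=3)
        assert len(pop) == 110
        assert [o.kappa_m for o in pop] == [o.kappa_m for o in pop2]

    def test_zero_spread_gives_identical_kappas(self):
        pop = s.generate_population_exp3(5, sigma_log=0.0, seed=1)
        kappas = {o.kappa_m for o in pop}
        assert len(kappas) == 1 and kappas.pop() == pytest.approx(12.0)

    def test_minimum_size_enforced(self):
        with pytest.raises(InvalidParameterError):
            s.generate_population_exp3(1, seed=0)
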