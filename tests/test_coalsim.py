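import math

import numpy as np
import pytest
from scipy import stats as sps

from rookery import coalsim as cs


def _one_deme(n, N=200, rate=1e-5, sites=100):
    return cs.ScenarioSpec("one", [cs.Deme("A", cs.Prior.fixed(N), n)], [],
                           mutation_rate=cs.Prior.fixed(rate), sites=sites)


class TestValidation:
    def _two_deme(self, **kw):
        demes = [cs.Deme("A", cs.Prior.fixed(100), 2),
                 cs.Deme("B", cs.Prior.fixed(100), 2)]
        events = kw.pop("events", [cs.Event("split", "B",
                                            cs.Prior.fixed(1000), source="A")])
        return cs.ScenarioSpec("t", demes, events, **kw)

    def test_valid_two_deme_split(self):
        cs.validate_scenario(self._two_deme())

    def test_event_at_time_zero_rejected(self):
        s = self._two_deme(events=[cs.Event("split", "B", cs.Prior.fixed(0),
                                            source="A")])
        with pytest.raises(cs.ScenarioError, match="time"):
            cs.validate_scenario(s)

    def test_admixture_fraction_above_one_rejected(self):
        with pytest.raises(cs.ScenarioError):
            ev = cs.Event("admixture", "B", cs.Prior.fixed(10), source="A",
                          fraction=cs.Prior.fixed(1.2))
            cs.validate_scenario(self._two_deme(
                events=[ev, cs.Event("split", "B", cs.Prior.fixed(1000),
                                     source="A")]))

    def test_orphan_deme_rejected(self):
        demes = [cs.Deme("A", cs.Prior.fixed(100), 2),
                 cs.Deme("B", cs.Prior.fixed(100), 2),
                 cs.Deme("C", cs.Prior.fixed(100), 0)]
        s = cs.ScenarioSpec("t", demes,
                            [cs.Event("split", "B", cs.Prior.fixed(1000),
                                      source="A")])
        with pytest.raises(cs.ScenarioError, match="root|orphan"):
            cs.validate_scenario(s)

    def test_unknown_deme_named_in_error(self):
        s = self._two_deme(events=[cs.Event("split", "X",
                                            cs.Prior.fixed(10), source="A")])
        with pytest.raises(cs.ScenarioError, match="X"):
            cs.validate_scenario(s)


class TestPriors:
    def test_size_draws_within_bounds_mean_central(self):
        spec = cs.ScenarioSpec(
            "p", [cs.Deme("A", cs.Prior("uniform_int", 100, 500), 2)], [],
            mutation_rate=cs.Prior.fixed(1e-6))
        rng = np.random.default_rng(0)
        draws = [cs.sample_priors(spec, rng)["sizes"]["A"]
                 for _ in range(10_000)]
        assert min(draws) >= 100 and max(draws) <= 500
        assert np.mean(draws) == pytest.approx(300, abs=5)

    def test_t1_window_draws(self):
        s5 = cs.builtin_scenarios()["S5"]
        rng = np.random.default_rng(1)
        med = [ev for ev in s5.events
               if ev.kind == "split" and ev.deme == "Mediterranean"][0]
        i = s5.events.index(med)
        times = [cs.sample_priors(s5, rng)["times"][i] for _ in range(300)]
        assert min(times) >= 80 and max(times) <= 100

    def test_seeded_repeatability(self):
        spec = _one_deme(4)
        d1 = cs.sample_priors(spec, 42)
        d2 = cs.sample_priors(spec, 42)
        assert d1 == d2
        ds1 = cs.simulate_dataset(spec, 42)
        ds2 = cs.simulate_dataset(spec, 42)
        assert np.array_equal(ds1.matrix, ds2.matrix)
        assert ds1.sample_demes == ds2.sample_demes


class TestGenealogy:
    def test_pair_tmrca_mean_and_distribution(self):
        """n=2 in one deme of size N: TMRCA ~ Exponential(mean N)."""
        spec = _one_deme(2, N=150)
        rng = np.random.default_rng(0)
        tm = np.array([cs.simulate_genealogy(spec, cs.sample_priors(spec, rng),
                                             rng).tmrca
                       for _ in range(4000)])
        se = tm.std() / math.sqrt(len(tm))
        assert abs(tm.mean() - 150) < 3 * se
        assert sps.kstest(tm, "expon", args=(0, 150)).pvalue > 0.01

    def test_total_length_matches_harmonic_sum(self):
        spec = _one_deme(10, N=200)
        rng = np.random.default_rng(1)
        tl = np.array([cs.simulate_genealogy(spec, cs.sample_priors(spec, rng),
                                             rng).total_length
                       for _ in range(4000)])
        expected = 200 * sum(2.0 / i for i in range(1, 10))
        se = tl.std() / math.sqrt(len(tl))
        assert abs(tl.mean() - expected) < 3 * se

    def test_cross_deme_tmrca_is_split_plus_ancestral(self):
        demes = [cs.Deme("A", cs.Prior.fixed(100), 1),
                 cs.Deme("B", cs.Prior.fixed(100), 1)]
        spec = cs.ScenarioSpec(
            "s", demes, [cs.Event("split", "B", cs.Prior.fixed(5000),
                                  source="A")],
            mutation_rate=cs.Prior.fixed(1e-6))
        rng = np.random.default_rng(2)
        tm = np.array([cs.simulate_genealogy(spec, cs.sample_priors(spec, rng),
                                             rng).tmrca
                       for _ in range(3000)])
        se = tm.std() / math.sqrt(len(tm))
        assert abs(tm.mean() - 5100) < 3 * se

    def test_sample_sizes_honoured(self):
        spec = cs.builtin_scenarios()["S3"].with_samples(
            {"Brazil": 5, "CaboVerde": 7, "USAMexico": 3, "Mediterranean": 2})
        ds = cs.simulate_dataset(spec, 0)
        from collections import Counter
        assert Counter(ds.sample_demes) == {"Brazil": 5, "CaboVerde": 7,
                                            "USAMexico": 3, "Mediterranean": 2}


class TestMutation:
    def _pair_tree(self, t=1000.0):
        return cs.Genealogy(2, np.array([2, 2, -1]),
                            np.array([0.0, 0.0, t]), ["A", "A"])

    def test_zero_rate_identical_to_root(self):
        root = np.zeros(50, dtype=np.uint8)
        m = cs.mutate_k2p(self._pair_tree(), 0.0, 2.0, 50, 0, root_seq=root)
        assert (m == 0).all()

    def test_divergence_matches_k2p_closed_form(self):
        rate, t, sites = 1e-4, 1000.0, 1000
        from rookery.coalsim import _k2p_probs
        p_ts, p_tv = _k2p_probs(rate, 2.0, 2 * t)
        expected = p_ts + 2 * p_tv
        rng = np.random.default_rng(5)
        obs = np.array([(lambda m: (m[0] != m[1]).mean())(
            cs.mutate_k2p(self._pair_tree(t), rate, 2.0, sites, rng))
            for _ in range(300)])
        se = obs.std() / math.sqrt(len(obs))
        assert abs(obs.mean() - expected) < 3 * se
        # low-divergence linearisation: ~ 2 mu t per site
        assert expected == pytest.approx(2 * rate * t, rel=0.15)

    def test_infinite_kappa_gives_pure_transitions(self):
        rng = np.random.default_rng(7)
        m = cs.mutate_k2p(self._pair_tree(), 1e-3, 1e12, 2000, rng)
        changed = m[0] != m[1]
        assert changed.any()
        # in the 0..3 encoding transitions flip only the lowest bit
        assert np.all((m[0][changed] ^ m[1][changed]) == 1)

    def test_within_deme_pi_matches_theta(self):
        """E[mean pairwise differences] = theta = 2 N mu L at low rate."""
        N, rate, sites = 200, 5e-6, 500
        spec = _one_deme(8, N=N, rate=rate, sites=sites)
        rng = np.random.default_rng(8)
        pis = []
        for _ in range(400):
            ds = cs.simulate_dataset(spec, rng)
            mat = ds.matrix
            tot = sum((mat[i] != mat[j]).sum()
                      for i in range(8) for j in range(i + 1, 8))
            pis.append(tot / 28)
        theta = 2 * N * rate * sites
        se = np.std(pis) / math.sqrt(len(pis))
        assert abs(np.mean(pis) - theta) < 4 * se


class TestBuiltinScenarios:
    def test_all_five_validate_and_share_structure(self):
        specs = cs.builtin_scenarios()
        assert set(specs) == {"S1", "S2", "S3", "S4", "S5"}
        structures = {tuple(sorted((d.name, d.samples) for d in s.demes))
                      for s in specs.values()}
        assert len(structures) == 1   # exchangeable for ABC

    def test_s5_mediterranean_founding_in_calendar_years(self):
        """The youngest founding window times the 50-year generation places
        the Mediterranean foundation 4000-5000 years before present."""
        s5 = cs.builtin_scenarios()["S5"]
        med = [ev for ev in s5.events
               if ev.kind == "split" and ev.deme == "Mediterranean"][0]
        years = (med.time.min * s5.generation_time_years,
                 med.time.max * s5.generation_time_years)
        assert years == (4000, 5000)

    def test_s5_narrative_topology(self):
        s5 = cs.builtin_scenarios()["S5"]
        splits = {ev.deme: ev.source for ev in s5.events
                  if ev.kind == "split"}
        assert splits["Brazil"] == "HgI"
        assert splits["CaboVerde"] == "Brazil"
        assert splits["USAMexico"] == "CaboVerde"
        assert splits["Mediterranean"] == "HgII"
        admix = {ev.deme: ev.source for ev in s5.events
                 if ev.kind == "admixture"}
        assert admix == {"USAMexico": "Mediterranean",
                         "CaboVerde": "USAMexico"}

    def test_yaml_round_trip(self, tmp_path):
        s1 = cs.builtin_scenarios()["S1"]
        p = tmp_path / "s.yaml"
        p.write_text(cs.scenario_to_yaml(s1))
        again = cs.load_scenario(p)
        assert again.events == s1.events
        assert again.demes == s1.demes


class TestIslandModel:
    def test_against_msprime_coalescence_times(self):
        """Independent oracle: mean within/cross-deme pair TMRCA from
        msprime under the same two-deme migration model."""
        import msprime
        N, M = 100, 1.0
        rate = M / (2 * N)   # per-lineage rate used by island_pair_scenario
        spec = cs.island_pair_scenario(N, M, samples=1, sites=10)
        rng = np.random.default_rng(3)
        ours = np.array([cs.simulate_genealogy(spec,
                                               cs.sample_priors(spec, rng),
                                               rng).tmrca
                         for _ in range(2500)])
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=N)
        dem.add_population(name="B", initial_size=N)
        dem.set_symmetric_migration_rate(["A", "B"], rate)
        theirs = []
        for ts in msprime.sim_ancestry(
                samples={"A": 1, "B": 1}, demography=dem, ploidy=1,
                num_replicates=2500, random_seed=11):
            theirs.append(ts.max_root_time)
        theirs = np.array(theirs)
        se = math.hypot(ours.std() / 50, np.std(theirs) / 50)
        assert abs(ours.mean() - theirs.mean()) < 3 * se

    def test_coalescent_waiting_time_regime(self):
        """With k lineages in one deme the waiting time to the next event is
        Exponential(k(k-1)/(2N)) — checked via KS on the first interval."""
        N, n = 300, 6
        spec = _one_deme(n, N=N)
        rng = np.random.default_rng(9)
        firsts = []
        for _ in range(1500):
            g = cs.simulate_genealogy(spec, cs.sample_priors(spec, rng), rng)
            internal = np.sort(g.time[g.time > 0])
            firsts.append(internal[0])
        rate = n * (n - 1) / (2 * N)
        assert sps.kstest(firsts, "expon", args=(0, 1 / rate)).pvalue > 0.01
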