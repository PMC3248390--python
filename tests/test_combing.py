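"""Combing statistics: track classification against a brute-force pattern
oracle, Table-style scalar computations, the clustering Monte-Carlo test and
the adjacent origin-type homogeneity test."""

import numpy as np
import pytest

import replikinetics as rk
from replikinetics import combing as cb


def brute_force_classifier(fiber, pulses=(20.0, 20.0)):
    """Independent re-derivation of the calls by literal pattern matching
    over the list of label runs (with unlabeled gaps made explicit)."""
    runs = fiber.labeled_runs()
    labels = [r.label for r in runs]
    forks, origins, termini, velocities = [], [], [], []
    for i in range(len(runs)):
        li = labels[i]
        left = labels[i - 1] if i > 0 else "END"
        right = labels[i + 1] if i + 1 < len(runs) else "END"
        if li == "IdU":
            if left == "CldU" and right == "CldU":
                origins.append(("origin", 1, runs[i].center))
            comp = [s == "CldU" for s in (left, right)]
            if (runs[i].start > 1e-9 and runs[i].end < fiber.length - 1e-9
                    and sum(comp) == 1):
                velocities.append(runs[i].length / pulses[0])
        if li == "CldU":
            if left == "IdU" and right == "IdU":
                termini.append(("terminus", runs[i].center))
            if left != "IdU" and right != "IdU":
                origins.append(("origin", 2, runs[i].center))
            comp = [s == "IdU" for s in (left, right)]
            if (runs[i].start > 1e-9 and runs[i].end < fiber.length - 1e-9
                    and sum(comp) == 1):
                velocities.append(runs[i].length / pulses[1])
        if i + 1 < len(runs):
            if (li, labels[i + 1]) == ("IdU", "CldU"):
                forks.append(("fork", "right", runs[i].end))
            if (li, labels[i + 1]) == ("CldU", "IdU"):
                forks.append(("fork", "left", runs[i].end))
    return forks, origins, termini, sorted(velocities)


def random_fiber(rng, fiber_id="f"):
    n = rng.integers(1, 9)
    lengths = rng.uniform(2.0, 30.0, size=n)
    labels = rng.choice(["IdU", "CldU", "unlabeled"], size=n)
    tracks, pos = [], 0.0
    for lab, ln in zip(labels, lengths):
        if lab != "unlabeled":
            tracks.append(cb.Track(lab, pos, pos + ln))
        pos += ln
    return cb.FiberRecord(fiber_id, "S1", pos, tracks)


class TestClassifyTracks:
    def test_single_fork_with_velocity(self):
        f = cb.FiberRecord("f", "S1", 40.0, [cb.Track("IdU", 0, 13.6),
                                             cb.Track("CldU", 13.6, 27.2)])
        cf = cb.classify_tracks(f)
        assert len(cf.forks) == 1
        assert cf.forks[0].direction == "right"
        assert cf.forks[0].velocity == pytest.approx(0.68)

    def test_type1_origin_between_divergent_forks(self):
        f = cb.FiberRecord("f", "S1", 30.0, [cb.Track("CldU", 0, 10),
                                             cb.Track("IdU", 10, 20),
                                             cb.Track("CldU", 20, 30)])
        cf = cb.classify_tracks(f)
        assert [o.origin_type for o in cf.origins] == [1]
        assert cf.origins[0].position == pytest.approx(15.0)
        assert {fk.direction for fk in cf.forks} == {"left", "right"}

    def test_terminus_between_convergent_forks(self):
        f = cb.FiberRecord("f", "S1", 30.0, [cb.Track("IdU", 0, 10),
                                             cb.Track("CldU", 10, 20),
                                             cb.Track("IdU", 20, 30)])
        cf = cb.classify_tracks(f)
        assert len(cf.termini) == 1
        assert cf.termini[0].position == pytest.approx(15.0)

    def test_isolated_cldu_is_type2_origin(self):
        f = cb.FiberRecord("f", "S1", 50.0, [cb.Track("CldU", 20, 30)])
        cf = cb.classify_tracks(f)
        assert [o.origin_type for o in cf.origins] == [2]
        assert cf.forks == []  # type-2 forks did not exist at CldU addition

    def test_empty_fiber_yields_empty_result(self):
        cf = cb.classify_tracks(cb.FiberRecord("f", "S1", 100.0, []))
        assert cf.forks == [] and cf.origins == [] and cf.termini == []

    def test_matches_brute_force_oracle_on_random_fibers(self):
        rng = np.random.default_rng(21)
        for k in range(1000):
            f = random_fiber(rng, f"f{k}")
            cf = cb.classify_tracks(f)
            forks, origins, termini, vels = brute_force_classifier(f)
            assert [(fk.direction, fk.position) for fk in cf.forks] == \
                [(d, p) for _, d, p in forks]
            assert [(o.origin_type, o.position) for o in cf.origins] == \
                [(t, p) for _, t, p in origins]
            assert [t.position for t in cf.termini] == [p for _, p in termini]
            assert sorted(cf.velocities) == pytest.approx(vels)


class TestScalarOperations:
    def test_fork_velocity_examples(self):
        assert cb.fork_velocity(40.0, 20.0) == 2.0
        assert cb.fork_velocity(13.6, 20.0) == pytest.approx(0.68)
        assert cb.fork_velocity(0.0, 20.0) == 0.0
        with pytest.raises(ValueError):
            cb.fork_velocity(-1.0, 20.0)

    def test_corrected_dna_length(self):
        assert cb.corrected_dna_length(100.0, 0.0, 1.0) == 100.0
        assert cb.corrected_dna_length(100.0, 0.315, 1.15) == pytest.approx(59.565,
                                                                            abs=0.01)
        assert cb.corrected_dna_length(100.0, 1.0, 1.2) == 0.0
        with pytest.raises(ValueError):
            cb.corrected_dna_length(100.0, 0.1, 0.9)

    def test_fork_density_and_ftfd(self):
        density, ftfd = cb.fork_density_and_ftfd(82, 31.03)
        assert density == pytest.approx(2.64, abs=0.005)
        assert 1000.0 / 2.64 == pytest.approx(378.8, abs=0.1)
        _, f = cb.fork_density_and_ftfd(1, 1.0)
        assert f == 1000.0
        d0, f0 = cb.fork_density_and_ftfd(0, 10.0)
        assert d0 == 0.0 and np.isnan(f0)

    def test_density_ftfd_reciprocal_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 500))
            mb = float(rng.uniform(0.5, 100))
            d, f = cb.fork_density_and_ftfd(n, mb)
            assert d * f == pytest.approx(1000.0)

    def test_pairwise_distances(self):
        np.testing.assert_allclose(cb.pairwise_distances([10, 50, 110]), [40, 60])
        assert len(cb.pairwise_distances([42.0])) == 0
        rng = np.random.default_rng(1)
        pos = np.sort(rng.uniform(0, 300, size=12))
        np.testing.assert_allclose(cb.pairwise_distances(pos),
                                   [b - a for a, b in zip(pos, pos[1:])])

    def test_intercluster_distance(self):
        assert cb.intercluster_distance(10_000, 1000, 9) == 1000.0
        assert cb.intercluster_distance(5000, 0, 1) == 5000.0
        # S1 row: 31.03 Mb corrected, 152 intra-fiber FTFDs of mean 22 kb,
        # 114 fork-containing fibers
        val = cb.intercluster_distance(31_030, 152 * 22, 114)
        assert val == pytest.approx(242.9, abs=0.5)
        with pytest.raises(ValueError):
            cb.intercluster_distance(100, 200, 2)


class TestDuplicationTime:
    def test_single_compartment_analytic(self):
        inp = cb.DuplicationTimeInputs([1.0], [5.0], [1.0])
        assert cb.genome_duplication_time(inp) == pytest.approx(200.0)

    def test_four_compartment_measured_inputs(self):
        inp = cb.DuplicationTimeInputs([0.15, 0.19, 0.22, 0.20],
                                       [2.64, 3.88, 4.55, 5.40],
                                       [0.64, 0.68, 0.67, 0.72])
        total = cb.genome_duplication_time(inp)
        assert total == pytest.approx(374.2, abs=0.5)
        # consistent with 6 h 18 min within rounding of the printed inputs
        assert total == pytest.approx(378.0, rel=0.02)

    def test_doubling_densities_halves_time(self):
        a = cb.DuplicationTimeInputs([0.15, 0.19], [2.0, 3.0], [0.7, 0.7])
        b = cb.DuplicationTimeInputs([0.15, 0.19], [4.0, 6.0], [0.7, 0.7])
        assert cb.genome_duplication_time(a) == pytest.approx(
            2 * cb.genome_duplication_time(b))


class TestClusteringNull:
    def test_poisson_zero_fork_probability(self):
        lengths = np.full(400, 200.0)
        res = cb.clustering_null(lengths, density=5.0,
                                 observed_counts=np.zeros(400), n_reps=10)
        assert res.expected_props[0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_null_p_value_not_extreme_under_null(self):
        rng = np.random.default_rng(8)
        lengths = rng.lognormal(np.log(200), 0.5, size=300)
        lam = 4.0 * lengths / 1000.0
        obs = rng.poisson(lam)
        res = cb.clustering_null(lengths, 4.0, obs, n_reps=2000, seed=12)
        assert 0.01 < res.p_value

    def test_p_value_uniformity_smoke(self):
        rng = np.random.default_rng(3)
        lengths = np.full(200, 200.0)
        lam = 5.0 * lengths / 1000.0
        ps = [cb.clustering_null(lengths, 5.0, rng.poisson(lam), n_reps=499,
                                 seed=int(rng.integers(2**31))).p_value
              for _ in range(200)]
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_degenerate_zero_density(self):
        res = cb.clustering_null(np.full(10, 100.0), 0.0, np.zeros(10), n_reps=10)
        assert res.expected_props[0] == pytest.approx(1.0)


class TestTypeHomogeneity:
    def test_observed_pair_counts_strongly_non_random(self):
        chi2, df, p = cb.adjacent_type_homogeneity(254, 60, 99)
        assert chi2 == pytest.approx(61.1, abs=0.2)
        assert df == 1
        assert p < 1e-12

    def test_counts_at_expectation_give_zero(self):
        # p1 = 0.5 -> expected (N/4, N/4, N/2)
        chi2, df, p = cb.adjacent_type_homogeneity(100, 100, 200)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_pure_alternation_chi2_equals_n(self):
        chi2, _, p = cb.adjacent_type_homogeneity(0, 0, 240)
        assert chi2 == pytest.approx(240.0)
        assert p < 1e-10

    def test_small_counts_use_monte_carlo(self):
        chi2, df, p = cb.adjacent_type_homogeneity(3, 0, 1, n_reps=20_000, seed=4)
        assert 0.0 < p <= 1.0

    def test_pair_counting_across_fibers(self):
        cf = cb.ClassifiedFiber(forks=[], termini=[], velocities=[], origins=[
            cb.OriginCall(10.0, 1), cb.OriginCall(40.0, 1), cb.OriginCall(80.0, 2)])
        assert cb.adjacent_origin_pair_counts([cf]) == (1, 0, 1)


class TestSimulatorRecovery:
    def test_velocity_recovered_from_sampled_fibers(self, synchronous_config):
        fibers = rk.sample_fibers(synchronous_config, 1200)
        vels = []
        for comp in ("S1", "S2", "S3", "S4"):
            vels.extend(cb.summarize_compartment(fibers, comp).velocities)
        assert len(vels) >= 200
        assert np.mean(vels) == pytest.approx(synchronous_config.fork_velocity,
                                              rel=0.05)

    def test_clustered_firing_detected_against_uniform_null(self, synchronous_config):
        """Near-synchronous firing puts several forks on a few fibers; the
        uniform-initiation null is rejected decisively."""
        fibers = rk.sample_fibers(synchronous_config, 600)
        lengths = np.array([f.length for f in fibers])
        counts = np.array([len(cb.classify_tracks(f).forks) for f in fibers])
        density = 1000.0 * counts.sum() / lengths.sum()
        res = cb.clustering_null(lengths, density, counts, n_reps=20_000, seed=9)
        assert res.p_value < 1e-3
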