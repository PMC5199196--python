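"""Surrogate construction and significance machinery."""

import numpy as np
import pytest
from scipy import stats as sstats

import nmlock as nl
from nmlock.metrics import uniform_resultant_expectation
from nmlock.signals import PhaseSeries, wrap_phase
from nmlock.surrogates import (
    SurrogateConfig,
    mock_gamma_epoch,
    surrogate_phase_phase_plots,
)


@pytest.fixture(scope="module")
def noise_session():
    from nmlock.experiments import whitenoise_phases

    return whitenoise_phases(30.0, seed=41)


class TestTimeShift:
    def test_forced_zero_shift_is_identity(self, noise_session):
        th, ga = noise_session
        cfg = SurrogateConfig(method="time_shift", seed=1)
        s = nl.time_shift_surrogate(ga, 1000, 2000, cfg, 0, _forced_shift=0)
        assert np.array_equal(s.phases, ga.phases[1000:3000])

    def test_shift_within_bounds(self, noise_session):
        th, ga = noise_session
        cfg = SurrogateConfig(method="time_shift", seed=2)
        for r in range(20):
            s = nl.time_shift_surrogate(ga, 0, 2000, cfg, r)
            # the surrogate is some contiguous window 1..200 ms ahead
            match = [
                np.array_equal(s.phases, ga.phases[k : k + 2000]) for k in range(1, 201)
            ]
            assert sum(match) == 1

    def test_insufficient_margin_rejected(self, noise_session):
        th, ga = noise_session
        cfg = SurrogateConfig(method="time_shift", seed=3)
        with pytest.raises(ValueError):
            nl.time_shift_surrogate(ga, len(ga) - 2000, 2000, cfg, 0)

    def test_run_index_determinism(self, noise_session):
        _, ga = noise_session
        cfg = SurrogateConfig(method="time_shift", seed=4)
        a = nl.time_shift_surrogate(ga, 0, 1000, cfg, 5)
        b = nl.time_shift_surrogate(ga, 0, 1000, cfg, 5)
        assert np.array_equal(a.phases, b.phases)


class TestRandomPermutation:
    def test_two_window_session(self):
        ga = PhaseSeries(wrap_phase(np.linspace(0, 50, 1001)), 1000.0)
        cfg = SurrogateConfig(method="random_permutation", seed=5)
        starts = {
            int(np.flatnonzero(
                np.isclose(ga.phases[:2], nl.random_permutation_surrogate(ga, 1000, cfg, r).phases[0])
            )[0])
            for r in range(20)
        }
        assert starts <= {0, 1}

    def test_excludes_exact_original(self, noise_session):
        _, ga = noise_session
        cfg = SurrogateConfig(method="random_permutation", seed=6)
        for r in range(50):
            s = nl.random_permutation_surrogate(ga, len(ga) - 1, cfg, r, exclude_start=0)
            assert not np.array_equal(s.phases, ga.phases[: len(ga) - 1])

    def test_session_too_short_rejected(self, noise_session):
        _, ga = noise_session
        cfg = SurrogateConfig(method="random_permutation", seed=7)
        with pytest.raises(ValueError):
            nl.random_permutation_surrogate(ga, len(ga), cfg, 0)


class TestPhaseScramble:
    def test_marginal_distribution_preserved(self, noise_session):
        _, ga = noise_session
        epoch = ga.slice(0, 3000)
        cfg = SurrogateConfig(method="phase_scramble", seed=8)
        s = nl.phase_scramble_surrogate(epoch, cfg, 0)
        assert np.array_equal(np.sort(s.phases), np.sort(epoch.phases))
        assert not np.array_equal(s.phases, epoch.phases)

    def test_length_one_is_identity(self):
        ps = PhaseSeries(np.array([0.5]), 1000.0)
        cfg = SurrogateConfig(method="phase_scramble", seed=9)
        assert nl.phase_scramble_surrogate(ps, cfg, 0).phases[0] == 0.5

    def test_scrambled_r_matches_uniform_resultant_law(self, noise_session):
        # destroying continuity makes the N samples independent draws of
        # the (uniform) marginal: R concentrates at sqrt(pi)/2/sqrt(N)
        th, ga = noise_session
        th_ep, ga_ep = th.slice(0, 1000), ga.slice(0, 1000)
        cfg = SurrogateConfig(method="phase_scramble", seed=10, n_runs=60)
        Rs = nl.surrogate_rnm_distribution(th_ep, ga_ep, 0, 1, 5, cfg)
        assert Rs.mean() == pytest.approx(uniform_resultant_expectation(1000), rel=0.2)


class TestDistributions:
    def test_pooled_equals_concatenated_single_runs(self, noise_session):
        th, ga = noise_session
        th_ep = th.slice(0, 1000)
        cfg = SurrogateConfig(method="time_shift", mode="pooled", n_runs=10, n_pool=1, seed=11)
        pooled = nl.surrogate_rnm_distribution(th_ep, ga, 0, 1, 5, cfg)
        # same runs, pooled by hand through the identity R(concat) = |mean z|
        zs = []
        for r in range(10):
            g = mock_gamma_epoch(ga, 0, 1000, cfg, r)
            zs.append(np.mean(np.exp(1j * nl.phase_difference(th_ep, g, 1, 5).values)))
        assert pooled[0] == pytest.approx(float(np.abs(np.mean(zs))), abs=1e-12)

    def test_pooled_chance_below_single_runs(self, noise_session):
        th, ga = noise_session
        th_ep = th.slice(0, 1000)
        single = nl.surrogate_rnm_distribution(
            th_ep, ga, 0, 1, 5, SurrogateConfig(method="time_shift", n_runs=20, seed=12)
        )
        pooled = nl.surrogate_rnm_distribution(
            th_ep, ga, 0, 1, 5,
            SurrogateConfig(method="time_shift", mode="pooled", n_runs=100, n_pool=5, seed=13),
        )
        assert pooled.max() < np.median(single)

    def test_time_shift_and_permutation_indistinguishable(self, noise_session):
        # ensemble design: one surrogate value per original window, as in a
        # 300-sample single-run distribution; the two relocation methods
        # then draw from the same stationary marginal
        th, ga = noise_session
        cfg_a = SurrogateConfig(method="time_shift", n_runs=1, seed=14)
        cfg_b = SurrogateConfig(method="random_permutation", n_runs=1, seed=15)
        a, b = [], []
        for i in range(28):
            th_ep = th.slice(i * 1000, 1000)
            ga_a = mock_gamma_epoch(ga, i * 1000, 1000, cfg_a, i)
            ga_b = mock_gamma_epoch(ga, i * 1000, 1000, cfg_b, i)
            a.append(nl.rnm(nl.phase_difference(th_ep, ga_a, 1, 5)))
            b.append(nl.rnm(nl.phase_difference(th_ep, ga_b, 1, 5)))
        assert sstats.ks_2samp(a, b).pvalue > 0.01

    def test_single_run_length(self, noise_session):
        th, ga = noise_session
        th_ep = th.slice(0, 500)
        cfg = SurrogateConfig(method="time_shift", n_runs=17, seed=16)
        assert len(nl.surrogate_rnm_distribution(th_ep, ga, 0, 1, 5, cfg)) == 17


class TestTestRnm:
    def test_identical_groups_p_half(self, rng):
        vals = rng.uniform(0.1, 0.2, 200)
        res = nl.test_rnm(vals, vals.copy())
        assert res.p == pytest.approx(0.5, abs=0.01)

    def test_degenerate_variance_flagged(self):
        res = nl.test_rnm(np.full(5, 0.3), np.full(5, 0.3))
        assert res.degenerate and np.isnan(res.p)

    def test_reports_percentile(self, rng):
        orig = np.full(10, 0.9)
        surr = rng.uniform(0.0, 0.5, 100)
        res = nl.test_rnm(orig, surr)
        assert res.percentile == 100.0
        assert res.p < 1e-6

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            nl.test_rnm(np.array([0.1]), np.array([0.1, 0.2]))


class TestPhasePhaseSignificance:
    def _plots(self, seed, n_plots, n=5000):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_plots):
            th = PhaseSeries(wrap_phase(rng.uniform(-np.pi, np.pi, n)), 1000.0)
            ga = PhaseSeries(wrap_phase(rng.uniform(-np.pi, np.pi, n)), 1000.0)
            out.append(nl.phase_phase_histogram(th, ga))
        return out

    def test_original_equal_to_surrogates_never_significant(self):
        plots = self._plots(0, 1)
        sig = nl.phase_phase_significance(plots[0], [plots[0], plots[0], plots[0]])
        assert sig.n_significant == 0
        assert sig.zero_sd.all()
        assert np.all(sig.p == 1.0)

    def test_uncorrected_fires_on_noise_holm_does_not(self, noise_session):
        th, ga = noise_session
        th_ep = th.slice(0, 20_000)
        original = nl.phase_phase_histogram(th_ep, ga.slice(0, 20_000))
        cfg = SurrogateConfig(method="time_shift", n_runs=120, seed=17)
        plots = surrogate_phase_phase_plots(th_ep, ga, 0, cfg)
        uncorrected = nl.phase_phase_significance(original, plots, correction="none")
        holm = nl.phase_phase_significance(original, plots, correction="holm")
        assert uncorrected.n_significant > 0
        assert holm.n_significant == 0

    def test_empirical_mode_and_fdr(self):
        plots = self._plots(1, 21)
        sig = nl.phase_phase_significance(plots[0], plots[1:], correction="fdr", empirical=True)
        assert sig.p.min() >= 1 / 21
        assert sig.n_significant == 0

    def test_binning_mismatch_rejected(self, rng):
        a = self._plots(2, 1)[0]
        th = PhaseSeries(wrap_phase(rng.uniform(-np.pi, np.pi, 100)), 1000.0)
        small = nl.phase_phase_histogram(th, th, n_bins=60)
        with pytest.raises(ValueError):
            nl.phase_phase_significance(a, [small, small])


def test_all_methods_preserve_gamma_marginal(noise_session):
    """Every surrogate is a relocation/permutation of recorded gamma phases."""
    th, ga = noise_session
    for method in ("time_shift", "random_permutation", "phase_scramble"):
        cfg = SurrogateConfig(method=method, seed=18)
        s = mock_gamma_epoch(ga, 100, 1000, cfg, 0)
        # all surrogate values exist in the session's phase multiset
        assert np.isin(s.phases, ga.phases).all()


def test_uncoupled_kuramoto_not_flagged(uncoupled_kuramoto_100s):
    """R_1:5 of independent oscillators stays inside its chance distribution."""
    th, ga = uncoupled_kuramoto_100s
    n_sims = 20
    exceed = 0
    for s in range(n_sims):
        t, g = nl.simulate_kuramoto_pair(nl.KuramotoParams(epsilon=0.0), 40.0, seed=500 + s)
        epoch = int(30.0 * t.fs)
        orig = nl.rnm(nl.phase_difference(t.slice(0, epoch), g.slice(0, epoch), 1, 5))
        cfg = SurrogateConfig(method="random_permutation", n_runs=60, seed=600 + s)
        dist = nl.surrogate_rnm_distribution(t.slice(0, epoch), g, 0, 1, 5, cfg)
        if orig > np.percentile(dist, 97.5):
            exceed += 1
    assert exceed <= 2  # ~2.5% expected exceedance rate
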