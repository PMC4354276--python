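import numpy as np
import pytest
from scipy.special import xlogy

from visint.psi import PsiAdaptive, PsiConfig
from visint.psychometric import WeibullPF, weibull_p


def brute_force_expected_entropy(psi: PsiAdaptive) -> np.ndarray:
    """Independent enumeration of expected posterior entropy per candidate,
    computed directly from the Weibull formula (not the psi tables)."""
    p = psi.posterior
    a = psi.thresholds[:, None]
    b = psi.slopes[None, :]
    g, d = psi.config.guess, psi.config.lapse
    out = np.empty(psi.candidates.size)
    for k, c in enumerate(psi.candidates):
        pc = (g + (1 - g - d) * (1 - np.exp(-((c / a) ** b)))).ravel()
        eh = 0.0
        for like in (pc, 1 - pc):
            s = float(p @ like)
            if s > 0:
                q = p * like / s
                eh += s * float(-np.sum(xlogy(q, q)))
        out[k] = eh
    return out


class TestWeibullCriterion:
    def test_threshold_parameter_marks_81_6_percent(self):
        pf = WeibullPF(threshold=0.035, slope=3.0)
        assert weibull_p(pf, 0.035) == pytest.approx(
            0.5 + 0.5 * (1 - np.exp(-1)), abs=1e-12
        )
        assert round(100 * weibull_p(pf, 0.035), 1) == 81.6

    def test_guess_and_asymptote(self):
        pf = WeibullPF(threshold=0.035, slope=3.0, lapse=0.02)
        assert weibull_p(pf, 0.0) == 0.5
        assert weibull_p(pf, 10.0) == pytest.approx(0.98, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            WeibullPF(threshold=-1.0, slope=3.0)
        with pytest.raises(ValueError):
            WeibullPF(threshold=0.03, slope=3.0, lapse=0.5)


class TestInitialization:
    def test_uniform_prior_by_default(self):
        psi = PsiAdaptive()
        n = psi.thresholds.size * psi.slopes.size
        assert np.allclose(psi.posterior, 1.0 / n)
        assert psi.posterior.sum() == pytest.approx(1.0, abs=1e-12)

    def test_custom_prior_renormalized(self):
        psi = PsiAdaptive()
        n = psi.thresholds.size * psi.slopes.size
        raw = np.arange(n, dtype=float)
        psi2 = PsiAdaptive(prior=raw)
        assert psi2.posterior.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(psi2.posterior, raw / raw.sum())

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            PsiAdaptive(PsiConfig(n_threshold=0))


class TestUpdate:
    def test_update_matches_elementwise_bayes(self, rng):
        psi = PsiAdaptive()
        prior = rng.random(psi.posterior.size)
        psi = PsiAdaptive(prior=prior)
        prior = psi.posterior.copy()
        contrast = 0.03
        like = psi.likelihood(contrast, correct=True)
        psi.update(contrast, correct=True)
        expected = prior * like
        expected /= expected.sum()
        assert np.max(np.abs(psi.posterior - expected)) < 1e-10

    def test_degenerate_posterior_unchanged(self):
        psi = PsiAdaptive()
        prior = np.zeros(psi.posterior.size)
        prior[500] = 1.0
        psi = PsiAdaptive(prior=prior)
        psi.update(0.05, True)
        psi.update(0.01, False)
        assert psi.posterior[500] == pytest.approx(1.0, abs=1e-12)

    def test_correct_response_never_raises_threshold_mean_at_fixed_slope(self):
        # single-slope grid: a correct response is evidence for a lower
        # (or equal) threshold
        config = PsiConfig(n_slope=1, slope_range=(3.0, 3.0))
        psi = PsiAdaptive(config)
        before = float(psi.posterior @ np.log(psi.thresholds))
        psi.update(0.05, correct=True)
        after = float(psi.posterior @ np.log(psi.thresholds))
        assert after <= before + 1e-12

    def test_posterior_stays_normalized_through_a_run(self, rng):
        psi = PsiAdaptive()
        for _ in range(100):
            c = psi.select()
            psi.update(c, bool(rng.random() < 0.7))
        assert psi.posterior.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(psi.posterior >= 0)
        assert psi.trial_count == 100


class TestSelect:
    def test_selection_minimizes_expected_entropy_by_enumeration(self, rng):
        psi = PsiAdaptive()
        # put the posterior in a non-trivial state
        for contrast, correct in [(0.05, True), (0.02, False), (0.1, True)]:
            psi.update(contrast, correct)
        chosen = psi.select()
        eh = brute_force_expected_entropy(psi)
        assert chosen == psi.candidates[np.argmin(eh)]
        internal = np.array(
            [psi.expected_entropy(k) for k in range(psi.candidates.size)]
        )
        assert np.max(np.abs(internal - eh)) < 1e-10

    def test_concentrated_posterior_selection_verified_by_enumeration(self):
        psi = PsiAdaptive()
        prior = np.zeros(psi.thresholds.size * psi.slopes.size)
        prior[psi.slopes.size * 30 + 15] = 1.0  # one (threshold, slope) point
        psi = PsiAdaptive(prior=prior)
        eh = brute_force_expected_entropy(psi)
        assert psi.select() == psi.candidates[np.argmin(eh)]

    def test_placements_concentrate_near_true_threshold(self, rng):
        pf = WeibullPF(threshold=0.035, slope=3.0)
        psi = PsiAdaptive()
        placed = []
        for _ in range(120):
            c = psi.select()
            placed.append(c)
            psi.update(c, bool(rng.random() < weibull_p(pf, c)))
        late = np.array(placed[40:])
        assert 0.035 / 2 <= np.median(late) <= 0.035 * 2


class TestEstimate:
    def test_concentrated_posterior_returns_its_threshold(self):
        psi = PsiAdaptive()
        i = int(np.argmin(np.abs(psi.thresholds - 0.035)))
        prior = np.zeros((psi.thresholds.size, psi.slopes.size))
        prior[i, :] = 1.0
        psi = PsiAdaptive(prior=prior.ravel())
        est = psi.estimate()
        assert est.threshold == pytest.approx(psi.thresholds[i], rel=1e-12)
        assert est.diagnostics["posterior_sd_log"] == pytest.approx(0.0, abs=1e-9)

    def test_estimate_corresponds_to_81_6_percent_level(self, rng):
        psi = PsiAdaptive()
        psi.update(0.05, True)
        est = psi.estimate()
        assert est.criterion == pytest.approx(0.8161, abs=1e-3)

    def test_short_run_recovery(self, rng):
        # 60-trial runs on a (0.035, 3) observer: mean estimate within 15%
        pf = WeibullPF(threshold=0.035, slope=3.0)
        estimates = []
        for _ in range(60):
            psi = PsiAdaptive()
            for _ in range(60):
                c = psi.select()
                psi.update(c, bool(rng.random() < weibull_p(pf, c)))
            estimates.append(psi.estimate().threshold)
        assert np.mean(estimates) == pytest.approx(0.035, rel=0.15)
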