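import numpy as np
import pytest

from g3plt import (ChainConfig, ItemParams, PriorConfig, ProposalConfig,
                   run_mcmc, psrf, hpd_interval, SimulationDesign,
                   generate_item_parameters, generate_abilities,
                   generate_structured_times, generate_responses)
from g3plt.model import _prob_matrix
from g3plt.sampler import (mh_step_theta, mh_step_a, mh_step_c, _cell_ll)


class ScriptedRNG:
    """Feeds predetermined normal/uniform variates to a block update."""

    def __init__(self, normals, uniforms):
        self.normals = list(normals)
        self.uniforms = list(uniforms)

    def normal(self, size=None):
        return np.asarray(self.normals.pop(0), dtype=float)

    def random(self, size=None):
        return np.asarray(self.uniforms.pop(0), dtype=float)

    def uniform(self, lo, hi, size=None):
        u = np.asarray(self.uniforms.pop(0), dtype=float)
        return lo + (hi - lo) * u


def _toy_state():
    y = np.array([[1, 0]], dtype=np.int8)
    a = np.array([1.0, 1.3])
    b = np.array([-0.2, 0.6])
    c = np.array([0.1, 0.05])
    t = np.array([[0.4, 1.1]])
    Et = np.exp(-t)
    return y, a, b, c, Et


class TestBlockUpdates:
    def test_identity_proposal_always_accepted(self):
        y, a, b, c, Et = _toy_state()
        theta = np.array([0.3])
        L = _cell_ll(theta, a, b, c, 1.7, Et, y)
        rng = ScriptedRNG(normals=[[0.0]], uniforms=[[1.0 - 1e-12]])
        acc = mh_step_theta(theta, L, y, Et, a, b, c, 1.7, (0.0, 1.0),
                            np.array([1.0]), rng)
        assert acc.all()

    def test_theta_acceptance_ratio_matches_hand_computation(self):
        """One person, two items: the decision boundary of the MH step sits
        exactly at the hand-computed likelihood-times-prior ratio."""
        from scipy.stats import bernoulli, norm

        y, a, b, c, Et = _toy_state()
        D, v = 1.7, 0.8
        cur, step = 0.3, 0.9
        prop = cur + v * step

        def joint(th):
            items = ItemParams(a=a, b=b, c=c, D=D)
            p = _prob_matrix(np.array([th]), items, -np.log(Et))
            return (bernoulli.logpmf(y, p).sum()
                    + norm.logpdf(th, 0.0, 1.0))

        logr = joint(prop) - joint(cur)
        assert logr < 0  # this move is downhill; acceptance is stochastic
        for offset, expect in ((-1e-9, True), (1e-9, False)):
            theta = np.array([cur])
            L = _cell_ll(theta, a, b, c, D, Et, y)
            u = np.exp(logr) + offset
            rng = ScriptedRNG(normals=[[step]], uniforms=[[u]])
            acc = mh_step_theta(theta, L, y, Et, a, b, c, D, (0.0, 1.0),
                                np.array([v]), rng)
            assert bool(acc[0]) is expect
            assert theta[0] == pytest.approx(prop if expect else cur)

    def test_out_of_range_guessing_proposal_rejected(self):
        y, a, b, c, Et = _toy_state()
        c = np.array([0.005, 0.05])
        theta = np.array([0.3])
        L = _cell_ll(theta, a, b, c, 1.7, Et, y)
        # first uniform drives the proposal below 0 -> auto-reject
        rng = ScriptedRNG(normals=[], uniforms=[[0.0, 0.5], [1e-12, 1e-12]])
        acc = mh_step_c(theta, L, y, Et, a, b, c, 1.7, (2.0, 10.0), 0.01, rng)
        assert not acc[0]
        assert c[0] == pytest.approx(0.005)


class TestPriorRecovery:
    def test_no_items_samples_ability_prior(self):
        """With zero items the likelihood is flat and the chain reproduces
        the standard-normal prior."""
        y = np.zeros((100, 0), dtype=int)
        draws = run_mcmc(y, None, chains=ChainConfig(iterations=4000,
                                                     burn_in=1000,
                                                     n_chains=1, seed=1),
                         sample_blocks=("theta",))
        pooled = draws.theta.ravel()
        assert abs(pooled.mean()) < 0.05
        assert abs(pooled.var() - 1.0) < 0.1

    def test_flat_likelihood_recovers_guessing_prior(self):
        """A saturated cell (p ~ 1 regardless of c) leaves the Beta(2,10)
        prior as the c posterior."""
        y = np.array([[1]], dtype=int)
        init = (np.array([10.0]), np.array([1.0]), np.array([0.0]),
                np.array([1 / 6]))
        draws = run_mcmc(y, None, chains=ChainConfig(iterations=60_000,
                                                     burn_in=10_000,
                                                     n_chains=1, seed=2),
                         sample_blocks=("c",), init_state=init)
        c = draws.c.ravel()
        assert c.mean() == pytest.approx(2 / 12, abs=0.03)
        assert c.std() == pytest.approx(np.sqrt(20 / (144 * 13)), abs=0.03)


def _quadrature_posterior_a(y, theta, b, c, D, t):
    """Grid-quadrature posterior mean/sd of a single discrimination."""
    agrid = np.linspace(1e-3, 10, 5001)
    lls = []
    for av in agrid:
        items = ItemParams(a=[av], b=[b], c=[c], D=D)
        p = np.clip(_prob_matrix(theta, items, t), 1e-12, 1 - 1e-12)
        lls.append(np.where(y == 1, np.log(p), np.log1p(-p)).sum())
    la = np.log(agrid)
    logpost = np.array(lls) - la - 0.5 * la ** 2
    w = np.exp(logpost - logpost.max())
    w /= np.trapezoid(w, agrid)
    mean = np.trapezoid(agrid * w, agrid)
    sd = np.sqrt(np.trapezoid((agrid - mean) ** 2 * w, agrid))
    return mean, sd


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(11)
    N = 40
    theta = rng.normal(0, 1, N)
    b, c, D = 0.3, 0.15, 1.7
    items = ItemParams(a=[1.2], b=[b], c=[c], D=D)
    t = rng.normal(0.5, 0.7, size=(N, 1))
    p = _prob_matrix(theta, items, t)
    y = (rng.random(p.shape) < p).astype(np.int8)
    quad = _quadrature_posterior_a(y, theta, b, c, D, t)
    return y, theta, b, c, D, t, quad


class TestPosteriorCorrectness:
    """Master oracle: MH-within-Gibbs marginals vs grid quadrature."""

    def test_discrimination_marginal_matches_quadrature(self, toy):
        y, theta, b, c, D, t, (qmean, qsd) = toy
        draws = run_mcmc(y, t, chains=ChainConfig(iterations=30_000,
                                                  burn_in=5_000, n_chains=1,
                                                  seed=3),
                         D=D, sample_blocks=("a",),
                         init_state=(theta, np.array([1.0]), np.array([b]),
                                     np.array([c])))
        assert draws.a.mean() == pytest.approx(qmean, abs=0.08)
        assert draws.a.std() == pytest.approx(qsd, abs=0.15)

    def test_omitting_jacobian_is_detectable(self, toy):
        """A lognormal random walk treated as symmetric (no a*/a factor)
        targets the wrong distribution; the oracle shows a clear shift."""
        y, theta, b, c, D, t, (qmean, _) = toy
        items_base = ItemParams(a=[1.0], b=[b], c=[c], D=D)

        def loglik(av):
            items = ItemParams(a=[av], b=[b], c=[c], D=D)
            p = np.clip(_prob_matrix(theta, items, t), 1e-12, 1 - 1e-12)
            return float(np.where(y == 1, np.log(p), np.log1p(-p)).sum())

        r = np.random.default_rng(3)
        la, cur = 0.0, None
        cur = loglik(1.0) - 0.5 * 0.0 ** 2 - 0.0
        out = []
        for i in range(30_000):
            la_p = la + 0.3 * r.normal()
            new = loglik(np.exp(la_p)) - 0.5 * la_p ** 2 - la_p  # no Jacobian
            if np.log(r.random()) < new - cur:
                la, cur = la_p, new
            if i >= 5_000:
                out.append(np.exp(la))
        biased_mean = float(np.mean(out))
        assert abs(biased_mean - qmean) > 0.2


class TestRunMCMC:
    def test_seeded_runs_identical(self):
        d = SimulationDesign(N=60, J=5, W=1.0)
        items = generate_item_parameters(5, 1, d)
        theta = generate_abilities(60, 2)
        t = generate_structured_times(items, theta, 3, d)
        y = generate_responses(theta, items, t, 1.0, 4)
        cfg = ChainConfig(iterations=400, burn_in=200, n_chains=2, seed=9)
        d1 = run_mcmc(y, t + 1.0, chains=cfg)
        d2 = run_mcmc(y, t + 1.0, chains=cfg)
        assert np.array_equal(d1.theta, d2.theta)
        assert np.array_equal(d1.a, d2.a)
        assert np.array_equal(d1.chain, d2.chain)

    def test_retained_draws_respect_support(self):
        d = SimulationDesign(N=80, J=6, W=0.0)
        items = generate_item_parameters(6, 5, d)
        theta = generate_abilities(80, 6)
        t = generate_structured_times(items, theta, 7, d)
        y = generate_responses(theta, items, t, 0.0, 8)
        draws = run_mcmc(y, t, chains=ChainConfig(iterations=800, burn_in=400,
                                                  n_chains=1, seed=10))
        assert np.all(draws.a > 0)
        assert np.all((draws.c > 0) & (draws.c < 1))
        assert set(draws.acceptance) == {"theta", "a", "b", "c"}

    def test_empty_or_invalid_data_rejected(self):
        with pytest.raises(ValueError):
            run_mcmc(np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            run_mcmc(np.full((2, 2), 2))

    def test_hpd_is_shortest_interval(self):
        x = np.concatenate([np.zeros(90), np.full(10, 50.0)])
        lo, hi = hpd_interval(x, 0.9)
        assert lo == 0.0 and hi == 0.0

    def test_summary_table_schema(self):
        y = np.random.default_rng(0).integers(0, 2, (20, 3))
        draws = run_mcmc(y, None, chains=ChainConfig(iterations=200,
                                                     burn_in=100, n_chains=1,
                                                     seed=0))
        df = draws.summary()
        assert {"parameter", "eap", "sd", "hpd_lower", "hpd_upper"} <= set(
            df.columns)
        assert len(df) == 20 + 3 * 3


class TestPSRF:
    def test_identical_chains_give_unity(self, rng):
        x = rng.normal(0, 1, 2000)
        r = psrf(np.stack([x, x, x]))
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_flagged(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(5, 1, 2000)
        assert psrf(np.stack([a, b])) > 3.0

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            psrf(rng.normal(size=(1, 100)))

    def test_converged_fit_passes_threshold(self):
        """Four overdispersed chains at the full-length protocol: all
        parameters below the conventional 1.2 cut."""
        d = SimulationDesign(N=200, J=10, W=1.0)
        items = generate_item_parameters(10, 3, d)
        theta = generate_abilities(200, 4)
        t = generate_structured_times(items, theta, 5, d)
        y = generate_responses(theta, items, t, 1.0, 6)
        draws = run_mcmc(y, t + 1.0,
                         chains=ChainConfig(iterations=10_000, burn_in=5_000,
                                            n_chains=4, seed=7))
        for name in ("theta", "a", "b", "c"):
            r = psrf(draws.split_by_chain(name))
            assert np.all(r < 1.2), f"{name}: max PSRF {r.max():.3f}"


class TestConfigValidation:
    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            ChainConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            PriorConfig(theta=(0.0, 0.0))
        with pytest.raises(ValueError):
            ProposalConfig(v_theta=-1.0)
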