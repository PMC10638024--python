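"""Metropolis-Hastings machinery: normalization, proposals, acceptance,
two-phase schedule, stationarity and diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from empop import mcmc
from empop.mcmc import MCMCSettings, ParameterSpace


@pytest.fixture
def space2d():
    return ParameterSpace(names=["a", "b"], lower=np.array([0.0, -5.0]), upper=np.array([10.0, 5.0]))


def norm_cost(scale=10.0):
    """Analytic cost C = scale * ||p_hat||_2 evaluated in native coordinates."""

    def _cost(params):
        a, b = params["a"], params["b"]
        p_hat = np.array([(a - 5.0) / 5.0, b / 5.0])
        return scale * float(np.linalg.norm(p_hat))

    return _cost


class TestNormalization:
    def test_midpoint_maps_to_zero(self, space2d):
        assert np.allclose(space2d.normalize([5.0, 0.0]), [0.0, 0.0])

    def test_upper_bound_maps_to_one(self, space2d):
        assert np.allclose(space2d.normalize([10.0, 5.0]), [1.0, 1.0])

    def test_round_trip(self, space2d):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(space2d.lower, space2d.upper)
            assert np.allclose(space2d.denormalize(space2d.normalize(p)), p, atol=1e-12)

    def test_out_of_bounds_rejected(self, space2d):
        with pytest.raises(ValueError):
            space2d.normalize([11.0, 0.0])
        with pytest.raises(ValueError):
            space2d.denormalize([1.2, 0.0])


class TestPropose:
    def test_zero_eps_identity(self):
        rng = np.random.default_rng(0)
        p = np.array([0.3, -0.7])
        assert np.array_equal(mcmc.propose(p, 0.0, rng), p)

    def test_always_inside_hypercube_near_corner(self):
        rng = np.random.default_rng(1)
        p = np.array([0.99, 0.99, 0.99])
        for _ in range(10_000):
            q = mcmc.propose(p, 0.05, rng)
            assert np.all(np.abs(q) <= 1.0)

    def test_empirical_sd_matches_eps_at_center(self):
        rng = np.random.default_rng(2)
        eps, n = 0.05, 100_000
        draws = np.array([mcmc.propose(np.zeros(1), eps, rng)[0] for _ in range(n)])
        mc_sd = eps / math.sqrt(2 * n)  # sd of a sample-sd estimate
        assert abs(draws.std() - eps) < 3 * mc_sd


class TestMHAccept:
    def test_downhill_always_accepted(self):
        assert mcmc.mh_accept(5.0, 1.0, 0.5, 0.999999)

    def test_equal_cost_always_accepted(self):
        assert mcmc.mh_accept(2.0, 2.0, 0.5, 0.999999)

    def test_uphill_acceptance_rate_matches_closed_form(self):
        # C 2 -> 4 at T = 0.5: p_accept = exp(-4) ~ 0.0183
        rng = np.random.default_rng(3)
        n = 100_000
        acc = sum(mcmc.mh_accept(2.0, 4.0, 0.5, rng.uniform()) for _ in range(n))
        p = math.exp(-4.0)
        assert abs(acc / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_rule_matches_enumerated_transition_matrix(self):
        """3-state toy problem with uniform proposals to the other 2 states:
        the acceptance region of the implemented rule in the uniform draw
        is enumerated exactly, so the resulting transition matrix equals the
        Metropolis matrix exactly."""
        costs = np.array([0.0, 1.0, 3.0])
        T = 0.7
        ours = np.zeros((3, 3))
        exact = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                p = min(1.0, math.exp((costs[i] - costs[j]) / T))
                # the rule accepts iff a <= p: check both sides of the boundary
                # and the interior, then the acceptance measure is exactly p
                assert mcmc.mh_accept(costs[i], costs[j], T, p * 0.5 + 1e-12)
                assert mcmc.mh_accept(costs[i], costs[j], T, p - 1e-12)
                if p < 1.0:
                    assert not mcmc.mh_accept(costs[i], costs[j], T, p + 1e-12)
                    assert not mcmc.mh_accept(costs[i], costs[j], T, 1.0 - 1e-12)
                ours[i, j] = 0.5 * p
                exact[i, j] = 0.5 * min(1.0, math.exp((costs[i] - costs[j]) / T))
            ours[i, i] = 1 - ours[i].sum()
            exact[i, i] = 1 - exact[i].sum()
        assert np.array_equal(ours, exact)


class TestTwoPhase:
    def test_fixed_seed_bitwise_identical(self, space2d):
        cost = norm_cost()
        bi = MCMCSettings(temperature=5.0, proposal_sd=0.2, steps=30, chains=2, phase="burnin")
        ma = MCMCSettings(temperature=0.5, proposal_sd=0.02, steps=50, chains=2, phase="main")
        r1 = mcmc.run_two_phase(space2d, cost, bi, ma, seed=7)
        r2 = mcmc.run_two_phase(space2d, cost, bi, ma, seed=7)
        assert len(r1) == len(r2)
        for a, b in zip(r1, r2):
            assert a.cost == b.cost
            assert np.array_equal(a.p_hat, b.p_hat)
            assert a.accepted == b.accepted

    def test_all_samples_inside_hypercube(self, space2d):
        recs = mcmc.run_two_phase(
            space2d, norm_cost(),
            MCMCSettings(temperature=5.0, proposal_sd=0.2, steps=50, chains=2, phase="burnin"),
            MCMCSettings(temperature=0.5, proposal_sd=0.05, steps=100, chains=2, phase="main"),
            seed=1,
        )
        for r in recs:
            assert np.all(np.abs(r.p_hat) <= 1.0)

    def test_main_chains_start_from_best_burnin(self, space2d):
        bi = MCMCSettings(temperature=5.0, proposal_sd=0.2, steps=40, chains=3, phase="burnin")
        ma = MCMCSettings(temperature=0.5, proposal_sd=0.02, steps=5, chains=3, phase="main")
        recs = mcmc.run_two_phase(space2d, norm_cost(), bi, ma, seed=3)
        burn = [r for r in recs if r.phase == "burnin"]
        starts = [r for r in recs if r.phase == "main" and r.iteration == 0]
        best = sorted(burn, key=lambda r: r.cost)[: len(starts)]
        assert sorted(r.cost for r in starts) == pytest.approx(
            sorted(r.cost for r in best)
        )

    def test_lower_temperature_gives_smaller_costs(self, space2d):
        bi = MCMCSettings(temperature=5.0, proposal_sd=0.2, steps=50, chains=2, phase="burnin")
        costs = {}
        for T in (0.25, 2.0):
            ma = MCMCSettings(temperature=T, proposal_sd=0.1, steps=400, chains=2, phase="main")
            recs = mcmc.run_two_phase(space2d, norm_cost(), bi, ma, seed=5)
            costs[T] = [r.cost for r in recs if r.phase == "main" and r.iteration > 50]
        u = stats.mannwhitneyu(costs[0.25], costs[2.0], alternative="less")
        assert u.pvalue < 1e-6


class TestStationarity:
    def test_samples_match_quadrature_density(self, space2d):
        """Main-phase histogram vs exp(-C/T)/Z computed by quadrature."""
        T, scale = 0.5, 10.0
        bi = MCMCSettings(temperature=5.0, proposal_sd=0.2, steps=100, chains=8, phase="burnin")
        ma = MCMCSettings(temperature=T, proposal_sd=0.02, steps=12_500, chains=8, phase="main")
        recs = mcmc.run_two_phase(space2d, norm_cost(scale), bi, ma, seed=11)
        pts = np.array([r.p_hat for r in recs if r.phase == "main"])
        assert len(pts) >= 100_000
        # density is radially concentrated at scale T/scale = 0.05
        lim = 0.35
        nbins = 8
        edges = np.linspace(-lim, lim, nbins + 1)
        hist, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges])
        inside = np.all(np.abs(pts) <= lim, axis=1)
        p_emp = np.concatenate([hist.ravel() / len(pts), [np.mean(~inside)]])
        # quadrature of exp(-scale*||x||/T) over each bin (fine subgrid)
        sub = 60
        q = np.zeros((nbins, nbins))
        xs = (np.arange(sub) + 0.5) / sub
        for i in range(nbins):
            for j in range(nbins):
                gx = edges[i] + (edges[i + 1] - edges[i]) * xs
                gy = edges[j] + (edges[j + 1] - edges[j]) * xs
                X, Y = np.meshgrid(gx, gy)
                q[i, j] = np.mean(np.exp(-scale * np.hypot(X, Y) / T)) * (2 * lim / nbins) ** 2
        # outside mass by coarse quadrature over the rest of the hypercube
        g = np.linspace(-1, 1, 400)
        X, Y = np.meshgrid(g, g)
        dens = np.exp(-scale * np.hypot(X, Y) / T)
        total = dens.mean() * 4.0
        outside = total - q.sum()
        p_quad = np.concatenate([q.ravel(), [outside]]) / total
        tv = 0.5 * np.abs(p_emp - p_quad).sum()
        assert tv < 0.05

    def test_infinite_temperature_limit_is_uniform(self, space2d):
        """T -> inf: every proposal is accepted and the stationary law is
        uniform away from the boundary (chi-square on a 10x10 grid of the
        interior).  The outermost proposal-sd-wide layer is excluded: the
        rejection-resampling boundary rule measurably depletes it, which is
        the documented cost of handling the hypercube edge exactly as the
        sampler specifies."""
        eps = 0.1
        bi = MCMCSettings(temperature=1e6, proposal_sd=eps, steps=10, chains=4, phase="burnin")
        ma = MCMCSettings(temperature=1e6, proposal_sd=eps, steps=50_000, chains=4, phase="main")
        recs = mcmc.run_two_phase(space2d, norm_cost(), bi, ma, seed=13)
        moves = [r for r in recs if r.phase == "main" and r.iteration > 0]
        # near-flat target: essentially every proposal is accepted
        assert np.mean([r.accepted for r in moves]) > 0.999
        pts = np.array([r.p_hat for r in moves])
        thin = pts[::30]  # decorrelate before the iid chi-square test
        inner = thin[np.all(np.abs(thin) <= 0.8, axis=1)]
        hist, _, _ = np.histogram2d(
            inner[:, 0], inner[:, 1], bins=[np.linspace(-0.8, 0.8, 11)] * 2
        )
        chi2, p = stats.chisquare(hist.ravel())
        assert p > 0.01


class TestDiagnostics:
    def _records(self, costs, accepted=None, chain=0):
        accepted = accepted or [True] * len(costs)
        return [
            mcmc.ChainRecord(
                iteration=i, chain=chain, phase="main",
                p_hat=np.zeros(1), params=np.zeros(1),
                cost=c, zscores={}, accepted=a,
            )
            for i, (c, a) in enumerate(zip(costs, accepted))
        ]

    def test_full_acceptance(self):
        recs = self._records([1.0, 0.9, 0.8, 0.7])
        d = mcmc.diagnostics(recs)
        assert d["acceptance_rate"][0] == 1.0

    def test_white_noise_autocorrelation_near_zero(self):
        rng = np.random.default_rng(17)
        recs = self._records(list(rng.normal(size=2000)))
        d = mcmc.diagnostics(recs)
        acf = d["autocorrelation"]
        assert np.all(np.abs(acf[1:20]) < 3 / math.sqrt(2000))

    def test_ar1_autocorrelation_recovered(self):
        rng = np.random.default_rng(19)
        n, phi = 20_000, 0.9
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        acf = mcmc.autocorrelation(x, 5)
        assert acf[1] == pytest.approx(phi, abs=3 * math.sqrt(1 / n) * 3)

    def test_saturation_fractions_sum_to_one(self):
        rng = np.random.default_rng(23)
        recs = []
        for i in range(50):
            z = {("p", "a"): rng.uniform(), ("p", "b"): rng.uniform()}
            recs.append(
                mcmc.ChainRecord(
                    iteration=i, chain=0, phase="main", p_hat=np.zeros(1),
                    params=np.zeros(1), cost=max(z.values()), zscores=z,
                )
            )
        d = mcmc.diagnostics(recs)
        assert sum(d["feature_saturation"].values()) == pytest.approx(1.0)

    def test_filtered_below_threshold(self):
        recs = self._records([1.0, 6.0, 2.0, 7.0])
        d = mcmc.diagnostics(recs, validity_threshold=5.0)
        assert [r.cost for r in d["filtered"]] == [1.0, 2.0]
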