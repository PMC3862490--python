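"""Likelihood, conjugate updates, diagnostics and sampler contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cartrend as ct
from cartrend.model import draw_sig2, draw_tau2


def tiny_dataset(counts, years=None, lon=0.5, lat=0.5):
    n = len(counts)
    years = years if years is not None else [2000 + i for i in range(n)]
    df = pd.DataFrame(
        {
            "route_id": "r0",
            "observer_id": "a",
            "year": years,
            "count": counts,
            "start_lon": lon,
            "start_lat": lat,
        }
    )
    return ct.SurveyDataset(df)


class TestLogLikelihood:
    def _state(self, ds, lattice, alpha=0.0, omega=0.0, b=0.0):
        return {
            "alpha": np.full(ds.n_years, alpha),
            "omega": np.full(ds.n_observers, omega),
            "b": np.full((len(lattice), ds.n_years), b),
        }

    def test_zero_count_unit_mean(self):
        ds = tiny_dataset([0], years=[2000])
        lat = ct.build_lattice([(0, 0), (1, 0)], connectivity="strict")
        assert ct.log_likelihood(ds, self._state(ds, lat), lat) == pytest.approx(-1.0)

    def test_closed_form_two_count(self):
        ds = tiny_dataset([2], years=[2000])
        lat = ct.build_lattice([(0, 0), (1, 0)], connectivity="strict")
        ll = ct.log_likelihood(ds, self._state(ds, lat, alpha=np.log(2.0)), lat)
        assert ll == pytest.approx(np.log(4 * np.exp(-2) / 2))

    def test_matches_termwise_poisson_logpmf(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {
                "route_id": [f"r{i%3}" for i in range(10)],
                "observer_id": [f"o{i%2}" for i in range(10)],
                "year": [2000 + i for i in range(10)],
                "count": rng.poisson(4.0, 10),
                "start_lon": [[0.5, 1.5, 0.2][i % 3] for i in range(10)],
                "start_lat": 0.5,
            }
        )
        ds = ct.SurveyDataset(df)
        lat = ct.build_lattice(ds, connectivity="strict")
        state = {
            "alpha": rng.normal(1.0, 0.3, ds.n_years),
            "omega": rng.normal(0, 0.2, ds.n_observers),
            "b": rng.normal(0, 0.3, (len(lat), ds.n_years)),
        }
        c_i = [lat.position(c) for c in ds.cell_ids]
        expect = sum(
            stats.poisson.logpmf(
                y, np.exp(state["alpha"][t] + state["omega"][k] + state["b"][c, t])
            )
            for y, t, k, c in zip(ds.counts, ds.year_idx, ds.obs_idx, c_i)
        )
        assert ct.log_likelihood(ds, state, lat) == pytest.approx(expect, rel=1e-12)

    def test_dimension_mismatch_errors(self):
        ds = tiny_dataset([1, 2])
        lat = ct.build_lattice([(0, 0), (1, 0)], connectivity="strict")
        state = {"alpha": np.zeros(5), "omega": np.zeros(1), "b": np.zeros((2, 2))}
        with pytest.raises(ValueError):
            ct.log_likelihood(ds, state, lat)


class TestConjugateUpdates:
    def test_sig2_gibbs_matches_analytic_invgamma(self):
        rng = np.random.default_rng(10)
        omega = rng.normal(0, 0.5, 40)
        a0, r0 = 0.001, 0.001
        draws = np.array([draw_sig2(rng, omega, a0, r0) for _ in range(10_000)])
        post = stats.invgamma(a0 + 20.0, scale=r0 + 0.5 * omega @ omega)
        # QQ agreement across the distribution's bulk
        qs = np.linspace(0.01, 0.99, 50)
        assert np.allclose(
            np.quantile(draws, qs), post.ppf(qs), rtol=0.1
        )
        assert stats.kstest(draws, post.cdf).pvalue > 0.01

    def test_tau2_gibbs_matches_analytic_invgamma(self, grid_3x3):
        rng = np.random.default_rng(11)
        b = np.column_stack(
            [ct.sample_icar_field(0.5, grid_3x3, rng) for _ in range(4)]
        )
        a0, r0 = 0.001, 0.001
        quad = float(np.sum(b * (grid_3x3.laplacian @ b)))
        draws = np.array([draw_tau2(rng, b, grid_3x3, a0, r0) for _ in range(10_000)])
        # shape gains (C-1)/2 per yearly field: rank deficiency of the ICAR
        post = stats.invgamma(a0 + 4 * (9 - 1) / 2.0, scale=r0 + 0.5 * quad)
        assert stats.kstest(draws, post.cdf).pvalue > 0.01


class TestGelmanRubin:
    def test_identical_chains_give_one(self):
        x = np.sin(np.arange(50.0))
        assert ct.gelman_rubin(np.stack([x, x])) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_chains_diverge(self):
        r = ct.gelman_rubin(np.stack([np.zeros(30) + 1e-9 * np.arange(30), np.full(30, 10.0) - 1e-9 * np.arange(30)]))
        assert r > 10

    def test_matches_hand_formula(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 7.0]])
        m, n = chains.shape
        W = chains.var(axis=1, ddof=1).mean()
        B_over_n = chains.mean(axis=1).var(ddof=1)
        expect = max(1.0, np.sqrt(((n - 1) / n * W + B_over_n) / W))
        assert ct.gelman_rubin(chains) == pytest.approx(expect, rel=1e-14)

    def test_single_chain_errors(self):
        with pytest.raises(ValueError):
            ct.gelman_rubin(np.arange(10.0)[None])


class TestFit:
    def test_same_seed_bitwise_identical(self):
        data, _ = ct.simulate(shape=(3, 3), n_years=4, seed=8)
        cfg = dict(n_chains=2, n_keep=200, n_burn=100, random_state=8)
        m1 = ct.CARTrendModel(**cfg).fit(data)
        m2 = ct.CARTrendModel(**cfg).fit(data)
        for name in ("alpha", "omega", "b", "sig2", "tau2"):
            assert np.array_equal(
                getattr(m1.draws_, name), getattr(m2.draws_, name)
            ), name

    def test_fields_centered_every_retained_draw(self, small_fit):
        _, _, model = small_fit
        means = model.draws_.b.mean(axis=2)  # over cells
        assert np.abs(means).max() < 1e-12

    def test_variances_positive(self, small_fit):
        _, _, model = small_fit
        assert (model.draws_.stacked("sig2") > 0).all()
        assert (model.draws_.stacked("tau2") > 0).all()

    def test_alpha_recovers_log_mean_at_large_counts(self):
        # two adjacent cells, stable observers, Poisson(500) counts:
        # the intercept posterior must concentrate on log of the yearly mean
        rng = np.random.default_rng(21)
        rows = []
        for t in range(20):
            for r, lonc in [("r0", 0.5), ("r1", 1.5)]:
                rows.append(
                    {
                        "route_id": r,
                        "observer_id": f"obs_{r}",
                        "year": 2000 + t,
                        "count": rng.poisson(500),
                        "start_lon": lonc,
                        "start_lat": 0.5,
                    }
                )
        ds = ct.SurveyDataset(pd.DataFrame(rows))
        m = ct.CARTrendModel(n_chains=2, n_keep=1500, n_burn=600, random_state=2)
        m.fit(ds)
        al = m.draws_.stacked("alpha")
        df = ds.df
        for t, year in enumerate(m.draws_.years):
            emp = np.log(df.loc[df.year == year, "count"].mean())
            mu, sd = al[:, t].mean(), al[:, t].std()
            assert abs(mu - emp) < 3 * max(sd, 1e-3), f"year {year}"

    def test_all_zero_year_warns(self):
        df = pd.DataFrame(
            {
                "route_id": ["r0", "r0", "r1", "r1"],
                "observer_id": "a",
                "year": [2000, 2001, 2000, 2001],
                "count": [5, 0, 4, 0],
                "start_lon": [0.5, 0.5, 1.5, 1.5],
                "start_lat": 0.5,
            }
        )
        ds = ct.SurveyDataset(df)
        with pytest.warns(UserWarning, match="weakly identified"):
            ct.CARTrendModel(n_chains=1, n_keep=50, n_burn=20, random_state=0).fit(ds)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ct.ModelConfig(n_keep=-1)
        with pytest.raises(ValueError):
            ct.ModelConfig(ig_shape=0.0)
        with pytest.raises(ValueError):
            ct.ModelConfig(variance_prior="flat")

    def test_half_normal_prior_runs(self):
        data, _ = ct.simulate(shape=(3, 3), n_years=4, seed=9)
        m = ct.CARTrendModel(
            n_chains=1, n_keep=200, n_burn=150, random_state=9,
            variance_prior="half-normal",
        ).fit(data)
        assert (m.draws_.stacked("tau2") > 0).all()

    def test_overdispersion_option_runs(self):
        data, _ = ct.simulate(shape=(3, 3), n_years=4, seed=10)
        m = ct.CARTrendModel(
            n_chains=1, n_keep=150, n_burn=100, random_state=10, overdispersion=True
        ).fit(data)
        assert m.draws_.alpha.shape[-1] == 4
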