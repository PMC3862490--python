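"""Hierarchical Poisson model with per-year intrinsic CAR spatial effects.

Observation model for route-level counts:

    Y_it ~ Poisson(lambda_it),  log lambda_it = alpha_t + omega_K(i,t) + b_c(i),t

with year intercepts ``alpha_t ~ N(0, A)`` (A diffuse, default 1e6),
observer(-route) effects ``omega_k ~ N(0, sigma^2)`` and, for each year, an
intrinsic CAR (Besag) spatial field on the degree-block lattice:

    b_ct | B_-c,t ~ N( mean of neighbors, tau^2 / n_c )

equivalently the improper joint density ``exp(-(1/2 tau^2) sum_{c~k}
(b_c - b_k)^2)`` of rank C-1, made proper by the per-year sum-to-zero
constraint.  Variances sigma^2 and tau^2 carry conjugate inverse-gamma
hyperpriors (half-normal SD priors available as an alternative).

Fitting is Metropolis-within-Gibbs: vectorized adaptive random-walk updates
for alpha, omega and (by graph coloring) b; conjugate Gibbs draws for the
variances; each year's field re-centered every sweep with the mean folded
into alpha_t so the likelihood is untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .lattice import Lattice, SurveyDataset, build_lattice

__all__ = [
    "ModelConfig",
    "PosteriorDraws",
    "CARTrendModel",
    "fit",
    "log_likelihood",
    "icar_conditional",
    "icar_log_density",
    "sample_icar_field",
    "gelman_rubin",
    "draw_sig2",
    "draw_tau2",
]


@dataclass
class ModelConfig:
    """MCMC and prior settings.

    ``n_keep`` is the total number of retained draws pooled across chains
    (the run manifest also records the per-chain count); ``n_burn`` is the
    per-chain number of discarded adaptation sweeps.
    """

    n_chains: int = 3
    n_keep: int = 20_000
    n_burn: int = 5_000
    thin: int = 1
    alpha_prior_var: float = 1e6
    ig_shape: float = 0.001
    ig_rate: float = 0.001
    variance_prior: str = "inverse-gamma"  # or "half-normal"
    halfnormal_scale: float = 10.0
    target_accept: float = 0.44
    seed: Optional[int] = None
    observer_mode: str = "observer-route"
    overdispersion: bool = False

    def __post_init__(self):
        if self.n_keep < 0 or self.n_burn < 0:
            raise ValueError("n_keep and n_burn must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if min(self.alpha_prior_var, self.ig_shape, self.ig_rate) <= 0:
            raise ValueError("prior parameters must be > 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.variance_prior not in ("inverse-gamma", "half-normal"):
            raise ValueError(f"unknown variance_prior {self.variance_prior!r}")

    @property
    def n_keep_per_chain(self) -> int:
        return -(-self.n_keep // self.n_chains)  # ceil division


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, leading axes (chain, iteration).

    ``alpha``: (m, n, T) year intercepts on the log scale; ``omega``:
    (m, n, K) observer effects; ``b``: (m, n, C, T) spatial fields, each
    year's field centered to mean zero; ``sig2``/``tau2``: (m, n).
    """

    alpha: np.ndarray
    omega: np.ndarray
    b: np.ndarray
    sig2: np.ndarray
    tau2: np.ndarray
    years: np.ndarray
    cell_ids: list
    obs_labels: np.ndarray
    lattice: Lattice
    config: ModelConfig
    acceptance: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_draws(self) -> int:
        return self.alpha.shape[0] * self.alpha.shape[1]

    def year_pos(self, year: int) -> int:
        pos = int(year) - int(self.years[0])
        if not (0 <= pos < len(self.years)):
            raise KeyError(f"year {year} outside fitted range {self.years[0]}..{self.years[-1]}")
        return pos

    def cell_pos(self, cell_id) -> int:
        try:
            return self.lattice.position(cell_id)
        except KeyError:
            raise KeyError(f"cell {cell_id!r} not in fitted lattice") from None

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter block with chains pooled on axis 0."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])

    def rhat(self) -> dict:
        """Gelman-Rubin potential scale reduction per scalar/summary block."""
        out = {}
        for t, year in enumerate(self.years):
            out[f"alpha[{year}]"] = gelman_rubin(self.alpha[:, :, t])
        out["sig2"] = gelman_rubin(self.sig2)
        out["tau2"] = gelman_rubin(self.tau2)
        return out

    def to_frame(self):
        """Columnar layout: one row per (chain, iteration), labeled columns."""
        import pandas as pd

        m, n, T = self.alpha.shape
        data = {
            "chain": np.repeat(np.arange(m), n),
            "iteration": np.tile(np.arange(n), m),
            "sig2": self.sig2.reshape(-1),
            "tau2": self.tau2.reshape(-1),
        }
        for t, year in enumerate(self.years):
            data[f"alpha[{year}]"] = self.alpha[:, :, t].reshape(-1)
        for c, cid in enumerate(self.cell_ids):
            for t, year in enumerate(self.years):
                data[f"b[{cid[0]},{cid[1]},{year}]"] = self.b[:, :, c, t].reshape(-1)
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# ICAR primitives


def icar_conditional(c: int, t, B, tau2: float, lattice: Lattice):
    """Full conditional of one cell's spatial effect given the rest.

    Returns ``(mean, variance)`` = (average of neighbor values, tau2/n_c).
    ``B`` may be a (C,) field (t ignored) or a (C, T) per-year stack.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be > 0")
    n_c = lattice.n[c]
    if n_c < 1:
        raise ValueError(f"cell {c} has no neighbors; ICAR conditional undefined")
    B = np.asarray(B, dtype=float)
    col = B if B.ndim == 1 else B[:, t]
    nbr_sum = lattice.W[c].dot(col)
    nbr_sum = float(np.asarray(nbr_sum).ravel()[0])
    return nbr_sum / n_c, tau2 / n_c


def icar_log_density(B_t, tau2: float, lattice: Lattice, *, strict: bool = True,
                     tol: float = 1e-8) -> float:
    """Log density (up to a constant) of one year's centered ICAR field.

    Pairwise-difference form of rank C-1:
    ``-(1/(2 tau2)) sum_{c<k} w_ck (b_c-b_k)^2 - ((C-1)/2) log tau2``.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be > 0")
    b = np.asarray(B_t, dtype=float)
    if b.shape != (len(lattice),):
        raise ValueError("field length does not match lattice")
    if strict and abs(b.mean()) > tol:
        raise ValueError("field is not centered (sum-to-zero constraint)")
    quad = float(b @ (lattice.laplacian @ b))
    C = len(lattice)
    return -quad / (2.0 * tau2) - 0.5 * (C - 1) * np.log(tau2)


def sample_icar_field(tau2: float, lattice: Lattice, seed=None) -> np.ndarray:
    """Draw a centered field from the ICAR distribution on the sum-zero subspace.

    The proper Gaussian with precision ``(1/tau2)(D - W)`` restricted to the
    orthogonal complement of the constant vector, sampled by
    eigendecomposition of the Laplacian (zero eigenvalue dropped).
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals, vecs = lattice.icar_eigensystem()
    if (vals[1:] <= 1e-10).any():
        raise ValueError("lattice graph is disconnected; ICAR undefined")
    z = rng.standard_normal(len(vals) - 1)
    fld = vecs[:, 1:] @ (z * np.sqrt(tau2 / vals[1:]))
    return fld - fld.mean()


def gelman_rubin(traces) -> float:
    """Potential scale reduction factor from >= 2 equal-length chains.

    Standard between/within formulation: with m chains of length n,
    ``Rhat = sqrt(((n-1)/n * W + B/n) / W)`` where W is the mean of the
    within-chain variances and B/n the variance of the chain means.
    Floored at 1.0 (values below 1 are finite-sample artifacts).
    """
    x = np.asarray(traces, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains, iterations) array with >= 2 chains")
    m, n = x.shape
    if n < 2:
        raise ValueError("chains must have length >= 2")
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = x.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return max(1.0, float(np.sqrt(var_plus / W)))


# ---------------------------------------------------------------------------
# Likelihood and sampler


def draw_sig2(rng, omega, shape0: float, rate0: float) -> float:
    """Conjugate inverse-gamma Gibbs draw for the observer-effect variance.

    Posterior IG(shape0 + K/2, rate0 + sum(omega^2)/2) for K iid N(0, sig2)
    effects under an IG(shape0, rate0) prior.
    """
    K = len(omega)
    rate = rate0 + 0.5 * float(np.dot(omega, omega))
    return 1.0 / rng.gamma(shape0 + K / 2.0, 1.0 / rate)


def draw_tau2(rng, b, lattice: Lattice, shape0: float, rate0: float) -> float:
    """Conjugate inverse-gamma Gibbs draw for the CAR conditional variance.

    The ICAR pairwise quadratic form contributes (C-1)/2 to the shape per
    year (rank deficiency of one per field) and b_t'(D-W)b_t / 2 to the
    rate; ``b`` is (C,) or (C, T).
    """
    b = np.atleast_2d(np.asarray(b, float).T).T  # (C,) -> (C, 1)
    C, T = b.shape
    quad = float(np.sum(b * (lattice.laplacian @ b)))
    return 1.0 / rng.gamma(
        shape0 + T * (C - 1) / 2.0, 1.0 / (rate0 + 0.5 * quad)
    )


def _poisson_logpmf(y, log_mu):
    return y * log_mu - np.exp(log_mu) - gammaln(y + 1.0)


def log_likelihood(dataset: SurveyDataset, state: dict, lattice: Lattice) -> float:
    """Poisson log likelihood of the full dataset at one parameter state.

    ``state`` holds ``alpha`` (T,), ``omega`` (K,) and ``b`` (C, T); the
    linear predictor of record i is ``alpha[t_i] + omega[K_i] + b[c_i, t_i]``.
    """
    alpha = np.asarray(state["alpha"], float)
    omega = np.asarray(state["omega"], float)
    b = np.asarray(state["b"], float)
    if alpha.shape != (dataset.n_years,):
        raise ValueError("alpha has wrong length for dataset year range")
    if omega.shape != (dataset.n_observers,):
        raise ValueError("omega has wrong length for dataset observers")
    if b.shape != (len(lattice), dataset.n_years):
        raise ValueError("b has wrong shape for lattice/year range")
    c_i = np.array([lattice.position(cid) for cid in dataset.cell_ids])
    eta = alpha[dataset.year_idx] + omega[dataset.obs_idx] + b[c_i, dataset.year_idx]
    return float(_poisson_logpmf(dataset.counts, eta).sum())


class _BlockAdapter:
    """Per-parameter random-walk scales, adapted in batches during burn-in."""

    def __init__(self, shape, target):
        self.s = np.full(shape, 0.2)
        self.target = target
        self.acc = np.zeros(shape)
        self.tries = 0
        self.batch = 0

    def record(self, accepted):
        self.acc += accepted
        self.tries += 1

    def maybe_adapt(self, every=50):
        if self.tries >= every:
            self.batch += 1
            rate = self.acc / self.tries
            step = min(0.5, 1.0 / np.sqrt(self.batch))
            self.s *= np.exp(step * (rate - self.target))
            np.clip(self.s, 1e-4, 25.0, out=self.s)
            self.acc[:] = 0.0
            self.tries = 0

    def rate(self):
        return self.acc, self.tries


def _run_chain(data, cfg: ModelConfig, rng: np.random.Generator, n_keep: int):
    y, t_i, k_i, c_i, T, K, C, W, n_c, colors, Lap = data
    N = len(y)

    sum_y_t = np.bincount(t_i, weights=y, minlength=T)
    sum_y_k = np.bincount(k_i, weights=y, minlength=K)
    sum_y_ct = np.zeros((C, T))
    np.add.at(sum_y_ct, (c_i, t_i), y)
    n_rec_t = np.bincount(t_i, minlength=T)
    if (n_rec_t == 0).any() or (sum_y_t == 0).any():
        empty = [int(t) for t in np.flatnonzero((n_rec_t == 0) | (sum_y_t == 0))]
        warnings.warn(
            f"years (indices {empty}) with no records or all-zero counts: "
            "their intercepts are weakly identified",
            stacklevel=3,
        )

    # init: alpha at log mean count, effects at overdispersed jitter
    with np.errstate(divide="ignore"):
        ybar = np.where(n_rec_t > 0, sum_y_t / np.maximum(n_rec_t, 1), np.nan)
    alpha = np.log(np.where(np.isfinite(ybar), ybar, np.nanmean(ybar)) + 0.5)
    alpha += 0.1 * rng.standard_normal(T)
    if not np.isfinite(alpha).all():
        raise ValueError("non-finite initialization (check counts)")
    omega = 0.05 * rng.standard_normal(K)
    b = 0.05 * rng.standard_normal((C, T))
    b -= b.mean(axis=0, keepdims=True)
    eps = np.zeros(N)
    sig2, tau2, nu2 = 1.0, 1.0, 1.0

    ad_a = _BlockAdapter(T, cfg.target_accept)
    ad_o = _BlockAdapter(K, cfg.target_accept)
    ad_b = _BlockAdapter((C, T), cfg.target_accept)
    ad_e = _BlockAdapter(N, cfg.target_accept) if cfg.overdispersion else None
    ad_v = _BlockAdapter(2, cfg.target_accept)  # half-normal variance MH only

    n_sweeps = cfg.n_burn + n_keep * cfg.thin
    out_alpha = np.empty((n_keep, T))
    out_omega = np.empty((n_keep, K))
    out_b = np.empty((n_keep, C, T))
    out_sig2 = np.empty(n_keep)
    out_tau2 = np.empty(n_keep)
    kept = 0
    acc_totals = {"alpha": [0, 0], "omega": [0, 0], "b": [0, 0]}

    a0, r0 = cfg.ig_shape, cfg.ig_rate
    apv = cfg.alpha_prior_var
    half_n = cfg.variance_prior == "half-normal"

    for sweep in range(n_sweeps):
        adapting = sweep < cfg.n_burn

        # ---- alpha (years are independent given the rest)
        rest = omega[k_i] + b[c_i, t_i] + eps
        S_t = np.bincount(t_i, weights=np.exp(rest), minlength=T)
        prop = alpha + ad_a.s * rng.standard_normal(T)
        dll = (
            sum_y_t * (prop - alpha)
            - S_t * (np.exp(prop) - np.exp(alpha))
            + (alpha**2 - prop**2) / (2.0 * apv)
        )
        acc = np.log(rng.random(T)) < dll
        alpha = np.where(acc, prop, alpha)
        ad_a.record(acc)
        acc_totals["alpha"][0] += int(acc.sum())
        acc_totals["alpha"][1] += T

        # ---- omega (observer effects have disjoint record sets)
        rest = alpha[t_i] + b[c_i, t_i] + eps
        S_k = np.bincount(k_i, weights=np.exp(rest), minlength=K)
        prop = omega + ad_o.s * rng.standard_normal(K)
        dll = (
            sum_y_k * (prop - omega)
            - S_k * (np.exp(prop) - np.exp(omega))
            + (omega**2 - prop**2) / (2.0 * sig2)
        )
        acc = np.log(rng.random(K)) < dll
        omega = np.where(acc, prop, omega)
        ad_o.record(acc)
        acc_totals["omega"][0] += int(acc.sum())
        acc_totals["omega"][1] += K

        # ---- b by color classes: within a class, cells are non-adjacent so
        # likelihood terms and ICAR conditionals do not interact
        S_ct = np.zeros((C, T))
        np.add.at(S_ct, (c_i, t_i), np.exp(alpha[t_i] + omega[k_i] + eps))
        b_acc = 0
        for grp in colors:
            nbr_mean = (W @ b)[grp] / n_c[grp, None]
            cur = b[grp]
            prop = cur + ad_b.s[grp] * rng.standard_normal(cur.shape)
            pv = tau2 / n_c[grp, None]
            dll = (
                sum_y_ct[grp] * (prop - cur)
                - S_ct[grp] * (np.exp(prop) - np.exp(cur))
                + ((cur - nbr_mean) ** 2 - (prop - nbr_mean) ** 2) / (2.0 * pv)
            )
            acc = np.log(rng.random(cur.shape)) < dll
            b[grp] = np.where(acc, prop, cur)
            gacc = np.zeros((C, T), dtype=bool)
            gacc[grp] = acc
            ad_b.acc += gacc
            b_acc += int(acc.sum())
        ad_b.tries += 1
        acc_totals["b"][0] += b_acc
        acc_totals["b"][1] += C * T

        # ---- sum-to-zero: recenter each year's field, fold mean into alpha
        m_t = b.mean(axis=0)
        b -= m_t
        alpha = alpha + m_t

        # ---- optional record-level overdispersion effect
        if cfg.overdispersion:
            eta_base = alpha[t_i] + omega[k_i] + b[c_i, t_i]
            prop = eps + ad_e.s * rng.standard_normal(N)
            dll = (
                y * (prop - eps)
                - np.exp(eta_base) * (np.exp(prop) - np.exp(eps))
                + (eps**2 - prop**2) / (2.0 * nu2)
            )
            acc = np.log(rng.random(N)) < dll
            eps = np.where(acc, prop, eps)
            ad_e.record(acc)
            nu2 = 1.0 / rng.gamma(a0 + N / 2.0, 1.0 / (r0 + 0.5 * float(eps @ eps)))
            if adapting:
                ad_e.maybe_adapt()

        # ---- variances
        quad = float(np.sum(b * (Lap @ b)))  # sum_t b_t' (D-W) b_t
        ss_omega = float(omega @ omega)
        if not half_n:
            sig2 = 1.0 / rng.gamma(a0 + K / 2.0, 1.0 / (r0 + 0.5 * ss_omega))
            tau2 = 1.0 / rng.gamma(a0 + T * (C - 1) / 2.0, 1.0 / (r0 + 0.5 * quad))
        else:
            # random-walk on log SD under a half-normal prior on the SD
            for j, (cur, ssq, dof) in enumerate(
                [(sig2, ss_omega, K), (tau2, quad, T * (C - 1))]
            ):
                ls = 0.5 * np.log(cur)
                lp = ls + ad_v.s[j] * rng.standard_normal()
                vnew = np.exp(2 * lp)

                def logpost(v, lsd):
                    return (
                        -dof * lsd
                        - 0.5 * ssq / v
                        - 0.5 * v / cfg.halfnormal_scale**2
                        + lsd  # Jacobian of the log-SD parameterization
                    )

                if np.log(rng.random()) < logpost(vnew, lp) - logpost(cur, ls):
                    if j == 0:
                        sig2 = vnew
                    else:
                        tau2 = vnew
                    ad_v.acc[j] += 1
            ad_v.tries += 1
            if adapting:
                ad_v.maybe_adapt()

        if adapting:
            ad_a.maybe_adapt()
            ad_o.maybe_adapt()
            ad_b.maybe_adapt()
        elif (sweep - cfg.n_burn + 1) % cfg.thin == 0 and kept < n_keep:
            out_alpha[kept] = alpha
            out_omega[kept] = omega
            out_b[kept] = b
            out_sig2[kept] = sig2
            out_tau2[kept] = tau2
            kept += 1

    rates = {k: v[0] / max(v[1], 1) for k, v in acc_totals.items()}
    return out_alpha, out_omega, out_b, out_sig2, out_tau2, rates


def _prepare_data(dataset: SurveyDataset, lattice: Lattice):
    c_i = np.array([lattice.position(cid) for cid in dataset.cell_ids])
    return (
        dataset.counts.astype(float),
        dataset.year_idx,
        dataset.obs_idx,
        c_i,
        dataset.n_years,
        dataset.n_observers,
        len(lattice),
        lattice.W,
        lattice.n,
        lattice.coloring(),
        sp.csr_matrix(lattice.laplacian),
    )


def fit(dataset: SurveyDataset, lattice: Lattice, config: ModelConfig) -> PosteriorDraws:
    """Fit the model by Metropolis-within-Gibbs MCMC; reproducible given seed."""
    missing = set(dataset.cell_ids) - set(lattice.index)
    if missing:
        raise ValueError(f"dataset cells absent from lattice: {sorted(missing)[:5]}")
    data = _prepare_data(dataset, lattice)
    npc = config.n_keep_per_chain
    ss = np.random.SeedSequence(config.seed)
    chains = [np.random.default_rng(s) for s in ss.spawn(config.n_chains)]

    alphas, omegas, bs, sig2s, tau2s, rates = [], [], [], [], [], []
    for rng in chains:
        a, o, b, s2, t2, r = _run_chain(data, config, rng, npc)
        alphas.append(a)
        omegas.append(o)
        bs.append(b)
        sig2s.append(s2)
        tau2s.append(t2)
        rates.append(r)

    return PosteriorDraws(
        alpha=np.stack(alphas),
        omega=np.stack(omegas),
        b=np.stack(bs),
        sig2=np.stack(sig2s),
        tau2=np.stack(tau2s),
        years=dataset.years.copy(),
        cell_ids=[c.id for c in lattice.cells],
        obs_labels=dataset.obs_labels,
        lattice=lattice,
        config=config,
        acceptance={
            k: float(np.mean([r[k] for r in rates])) for k in rates[0]
        },
    )


class CARTrendModel(BaseEstimator):
    """Spatially explicit trend model for route-level survey counts.

    A scikit-learn style estimator around the hierarchical Poisson/ICAR
    model.  ``fit`` accepts a DataFrame with columns ``route_id,
    observer_id, year, count, start_lon, start_lat`` (or a SurveyDataset),
    builds the degree-block lattice and runs the MCMC.

    Parameters mirror :class:`ModelConfig` plus the lattice options; fitted
    state lives in trailing-underscore attributes (``draws_``, ``lattice_``,
    ``rhat_``, ``acceptance_``).

    Examples
    --------
    >>> from cartrend import synthdata
    >>> data, truth = synthdata.simulate(shape=(4, 4), n_years=5, seed=0)
    >>> m = CARTrendModel(n_chains=2, n_keep=400, n_burn=200, random_state=0)
    >>> m.fit(data.df)                                   # doctest: +ELLIPSIS
    CARTrendModel(...)
    >>> est = m.cell_trend(truth.cell_ids[0], truth.years[0], truth.years[-1])
    """

    def __init__(
        self,
        resolution: float = 1.0,
        scheme: str = "rook",
        connectivity: str = "largest-component",
        buffer: int = 0,
        n_chains: int = 3,
        n_keep: int = 20_000,
        n_burn: int = 5_000,
        thin: int = 1,
        alpha_prior_var: float = 1e6,
        ig_shape: float = 0.001,
        ig_rate: float = 0.001,
        variance_prior: str = "inverse-gamma",
        halfnormal_scale: float = 10.0,
        target_accept: float = 0.44,
        observer_mode: str = "observer-route",
        overdispersion: bool = False,
        retransform: str = "lognormal",
        point_estimate: str = "median",
        random_state: Optional[int] = None,
    ):
        self.resolution = resolution
        self.scheme = scheme
        self.connectivity = connectivity
        self.buffer = buffer
        self.n_chains = n_chains
        self.n_keep = n_keep
        self.n_burn = n_burn
        self.thin = thin
        self.alpha_prior_var = alpha_prior_var
        self.ig_shape = ig_shape
        self.ig_rate = ig_rate
        self.variance_prior = variance_prior
        self.halfnormal_scale = halfnormal_scale
        self.target_accept = target_accept
        self.observer_mode = observer_mode
        self.overdispersion = overdispersion
        self.retransform = retransform
        self.point_estimate = point_estimate
        self.random_state = random_state

    def _config(self) -> ModelConfig:
        return ModelConfig(
            n_chains=self.n_chains,
            n_keep=self.n_keep,
            n_burn=self.n_burn,
            thin=self.thin,
            alpha_prior_var=self.alpha_prior_var,
            ig_shape=self.ig_shape,
            ig_rate=self.ig_rate,
            variance_prior=self.variance_prior,
            halfnormal_scale=self.halfnormal_scale,
            target_accept=self.target_accept,
            seed=self.random_state,
            observer_mode=self.observer_mode,
            overdispersion=self.overdispersion,
        )

    def fit(self, X, y=None, lattice: Optional[Lattice] = None):
        """Run the MCMC on a counts table (DataFrame, CSV path or dataset)."""
        if isinstance(X, SurveyDataset):
            ds = X
        elif isinstance(X, (str,)) or hasattr(X, "__fspath__"):
            ds = SurveyDataset.from_csv(
                X, resolution=self.resolution, observer_mode=self.observer_mode
            )
        else:
            ds = SurveyDataset(
                X, resolution=self.resolution, observer_mode=self.observer_mode
            )
        if lattice is None:
            lattice = build_lattice(
                ds,
                resolution=self.resolution,
                scheme=self.scheme,
                connectivity=self.connectivity,
                buffer=self.buffer,
            )
        self.dataset_ = ds
        self.lattice_ = lattice
        self.draws_ = fit(ds, lattice, self._config())
        self.acceptance_ = self.draws_.acceptance
        self.rhat_ = self.draws_.rhat() if self.n_chains >= 2 else {}
        return self

    def _check_fitted(self):
        if not hasattr(self, "draws_"):
            raise AttributeError("model is not fitted; call fit() first")

    def abundance(self, cell_id, year) -> np.ndarray:
        """Posterior draws of the theoretical-route abundance n_ct."""
        from .trend import expected_abundance

        self._check_fitted()
        return expected_abundance(
            self.draws_, cell_id, year, retransform=self.retransform
        )

    def predict(self, X) -> np.ndarray:
        """Posterior point estimate of theoretical-route abundance per row.

        ``X`` needs ``start_lon``, ``start_lat`` and ``year`` columns; each
        row is mapped to its degree block and the point estimate (median or
        mean, per ``point_estimate``) of n_ct is returned.
        """
        from .lattice import assign_route

        self._check_fitted()
        stat = np.median if self.point_estimate == "median" else np.mean
        out = np.empty(len(X))
        for j, row in enumerate(X.itertuples(index=False)):
            cid = assign_route(row.start_lon, row.start_lat, self.resolution)
            out[j] = stat(self.abundance(cid, int(row.year)))
        return out

    def cell_trend(self, cell_id, year_a: int, year_b: int):
        from .trend import cell_trend

        self._check_fitted()
        return cell_trend(
            self.draws_, cell_id, year_a, year_b,
            retransform=self.retransform, point=self.point_estimate,
        )

    def region_trend(self, region, year_a: int, year_b: int, region_id="region"):
        """Trend for a region: a shapely geometry, GeoJSON mapping or RegionSpec."""
        from .poststrat import RegionSpec, build_region_weights, region_trend

        self._check_fitted()
        if not isinstance(region, RegionSpec):
            region = build_region_weights(region, self.lattice_, region_id=region_id)
        return region_trend(
            self.draws_, region, year_a, year_b,
            retransform=self.retransform, point=self.point_estimate,
        )
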