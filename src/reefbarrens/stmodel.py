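"""Bayesian hierarchical presence/absence models for barrens occurrence.

Three nested models of image-level barren presence y(s_i, t):

* **M1** - Bernoulli logistic regression with fixed effects only.
* **M2** - M1 plus a spatial random field z(s) per year: Matérn (nu = 1)
  correlation, independent across years (temporal correlation fixed at 0).
* **M3** - the full separable space-time model: the yearly spatial fields
  follow a stationary AR(1) in time,

      z(., t) = phi z(., t-1) + omega(., t),  omega ~ N(0, Sigma(rho, sigma^2)),
      z(., 1) ~ N(0, Sigma / (1 - phi^2)),

  so cor(z(s,t), z(s',t')) = H(|s-s'|; rho) * phi^|t-t'|.

The spatial range rho is the distance at which the Matérn correlation
H(d) = kappa d K1(kappa d), kappa = sqrt(8)/rho, drops to ~0.1.

Hyperpriors are Gaussian on transformed scales: log rho, log sigma, and
theta = log((1+phi)/(1-phi)); each beta ~ N(0, s^2).

Inference for M2/M3 is a Laplace-within-importance-sampling scheme: for a
given hyperparameter vector the latent Gaussian block (beta, z) is
integrated out by a Laplace approximation (Newton/IRLS on the joint
posterior mode, exploiting the per-site Kronecker (years x points)
structure of the space-time prior), and the low-dimensional hyperparameter
posterior is handled by a multivariate-t importance sampler centred on its
mode.  The marginal likelihood is a by-product of the same computation.
M1, which has no latent field, is sampled exactly with an affine-invariant
ensemble MCMC (emcee) and its evidence is estimated by iterative bridge
sampling.  Covariance matrices are dense: intended for desk-scale problems
(up to a few thousand latent sites; the cost is O(n^3) per factorisation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.special import expit, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "FIXED_EFFECT_NAMES",
    "PriorSpec",
    "Hyperparameters",
    "EngineConfig",
    "ModelFit",
    "spatial_correlation",
    "build_design_matrix",
    "log_prior",
    "fit",
    "fit_logistic_mcmc",
    "log_marginal_likelihood",
]

#: Fixed-effect columns, in reporting order.
FIXED_EFFECT_NAMES = [
    "intercept", "ntr", "year", "rugosity", "depth", "depth_squared",
    "ntr_year",
]

_TABLE_COLUMN_FOR = {
    "ntr": "ntr",
    "year": "year_coded",
    "rugosity": "rugosity_logit_std",
    "depth": "depth_std",
    "depth_squared": "depth_sq_std",
}


@dataclass
class PriorSpec:
    """Gaussian hyperpriors on transformed scales.

    (a, b) are the mean and sd of log rho, theta(phi) and log sigma;
    ``s_beta`` is the prior sd of every fixed-effect coefficient.
    """

    a_rho: float = float(np.log(20.0))
    b_rho: float = 1.0
    a_phi: float = 0.0
    b_phi: float = 1.0
    a_sigma: float = 0.0
    b_sigma: float = 1.0
    s_beta: float = 10.0

    def __post_init__(self) -> None:
        if min(self.b_rho, self.b_phi, self.b_sigma, self.s_beta) <= 0:
            raise ValueError("prior standard deviations must be positive")


@dataclass
class Hyperparameters:
    rho: float
    sigma2: float
    phi: float

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if abs(self.phi) >= 1:
            raise ValueError("phi must lie in (-1, 1)")


@dataclass
class EngineConfig:
    """Knobs of the inference engines (Laplace+IS for M2/M3, MCMC for M1)."""

    seed: int = 0
    n_draws: int = 5000
    # Laplace + importance sampling (M2/M3)
    n_is: int = 192
    proposal_scale: float = 1.4
    proposal_df: float = 7.0
    nm_maxfev: int = 160
    newton_tol: float = 1e-8
    newton_maxiter: int = 60
    jitter: float = 1e-6
    evidence_method: str = "is"  # "is" | "laplace"
    min_kish_ess: float = 50.0
    # ensemble MCMC (M1)
    mcmc_walkers: int = 48
    mcmc_steps: int = 2400
    mcmc_burn: int = 1000
    bridge_iters: int = 200
    compute_evidence: bool = True

    @classmethod
    def fast(cls, seed: int = 0) -> "EngineConfig":
        """Cheaper settings for replicate experiments: modal-hyperparameter
        evidence, fewer MCMC steps."""
        return cls(
            seed=seed, n_is=64, nm_maxfev=90, evidence_method="laplace",
            mcmc_steps=400, mcmc_burn=500,
        )


@dataclass
class ModelFit:
    model_id: str
    fixed_effect_summary: pd.DataFrame
    hyper_summary: pd.DataFrame | None
    draws: pd.DataFrame
    log_marginal_likelihood: float
    log_ml_se: float
    diagnostics: dict = field(default_factory=dict)
    priors: PriorSpec | None = None
    engine: EngineConfig | None = None


# ---------------------------------------------------------------------------
# building blocks


def spatial_correlation(distance, rho: float):
    """Matérn (nu = 1) correlation H(d) = kappa d K1(kappa d), kappa = sqrt(8)/rho.

    With this convention H(rho) ~ 0.1: the range is the distance at which
    correlation has decayed to close to 0.1.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    x = np.sqrt(8.0) * d / rho
    out = np.ones_like(x)
    pos = x > 0
    with np.errstate(over="ignore", invalid="ignore"):
        vals = x[pos] * special.kv(1, x[pos])
    out[pos] = np.where(np.isfinite(vals), vals, 0.0)
    return out if out.ndim else float(out)


def build_design_matrix(table) -> tuple[np.ndarray, list[str]]:
    """Design matrix in reporting order:
    (intercept, ntr, year, rugosity, depth, depth_squared, ntr x year)."""
    df = table.df if hasattr(table, "df") else table
    for name, col in _TABLE_COLUMN_FOR.items():
        if col not in df.columns:
            raise ValueError(f"analysis table missing column {col!r} ({name})")
    n = len(df)
    X = np.empty((n, 7))
    X[:, 0] = 1.0
    X[:, 1] = df["ntr"].to_numpy(dtype=float)
    X[:, 2] = df["year_coded"].to_numpy(dtype=float)
    X[:, 3] = df["rugosity_logit_std"].to_numpy(dtype=float)
    X[:, 4] = df["depth_std"].to_numpy(dtype=float)
    X[:, 5] = df["depth_sq_std"].to_numpy(dtype=float)
    X[:, 6] = X[:, 1] * X[:, 2]
    return X, list(FIXED_EFFECT_NAMES)


def phi_to_theta(phi):
    return np.log((1.0 + phi) / (1.0 - phi))


def theta_to_phi(theta):
    return np.tanh(np.asarray(theta, dtype=float) / 2.0)


def log_prior(hyper: Hyperparameters, beta: np.ndarray, priors: PriorSpec) -> float:
    """Joint log prior density evaluated on the natural scale.

    Includes the Jacobians of the log rho, log sigma and
    theta = log((1+phi)/(1-phi)) transforms.
    """
    if abs(hyper.phi) >= 1:
        return -np.inf
    from scipy.stats import norm

    lp = 0.0
    lp += norm.logpdf(np.log(hyper.rho), priors.a_rho, priors.b_rho) - np.log(hyper.rho)
    sigma = np.sqrt(hyper.sigma2)
    if sigma <= 0:
        return -np.inf
    lp += norm.logpdf(np.log(sigma), priors.a_sigma, priors.b_sigma) - np.log(sigma)
    theta = phi_to_theta(hyper.phi)
    lp += norm.logpdf(theta, priors.a_phi, priors.b_phi) + np.log(
        2.0 / (1.0 - hyper.phi**2)
    )
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    lp += float(np.sum(norm.logpdf(beta, 0.0, priors.s_beta)))
    return float(lp)


def _log1pexp(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# latent structure: per-site Kronecker (years x merged points) grids


class _LatentStructure:
    """Per-site latent grids (merged spatial points x observed years).

    Image locations repeated across years (within 0.5 m) are merged to a
    single spatial point, as the AR recursion requires.  Each site keeps a
    full (years x points) grid; rows map into it and grid cells without an
    observation simply contribute no likelihood.
    """

    MERGE_TOL = 0.5  # metres

    def __init__(self, df: pd.DataFrame):
        if "site_id" in df.columns:
            site_labels = df["site_id"].to_numpy()
        else:
            site_labels = np.zeros(len(df), dtype=int)
        xy = df[["x_m", "y_m"]].to_numpy(dtype=float)
        years = df["year"].to_numpy(dtype=int)

        self.sites = []
        self.row_latent_index = np.empty(len(df), dtype=int)
        offset = 0
        for site in pd.unique(site_labels):
            rows = np.flatnonzero(site_labels == site)
            key = np.round(xy[rows] / self.MERGE_TOL).astype(np.int64)
            uniq, point_idx = np.unique(key, axis=0, return_inverse=True)
            m = len(uniq)
            # representative coordinates: mean of merged rows
            coords = np.zeros((m, 2))
            counts = np.bincount(point_idx, minlength=m).astype(float)
            for k in range(2):
                coords[:, k] = np.bincount(
                    point_idx, weights=xy[rows, k], minlength=m
                ) / counts
            site_years = np.sort(np.unique(years[rows]))
            year_idx = np.searchsorted(site_years, years[rows])
            self.row_latent_index[rows] = offset + year_idx * m + point_idx
            dist = np.sqrt(
                ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
            )
            self.sites.append(
                {"site": site, "coords": coords, "dist": dist,
                 "years": site_years, "m": m, "offset": offset}
            )
            offset += m * len(site_years)
        self.n_latent = offset

    def precision_blocks(self, rho, sigma2, phi, jitter):
        """Per-site precision blocks of the separable prior, with log-dets.

        Returns (blocks, logdet_cov_total): blocks[g] is the dense
        precision of site g's (years x points) latent grid, ordered
        year-major to match ``row_latent_index``.
        """
        blocks = []
        logdet_cov = 0.0
        for s in self.sites:
            m, yrs = s["m"], s["years"]
            T = len(yrs)
            S = spatial_correlation(s["dist"], rho)
            S[np.diag_indices_from(S)] += jitter
            cS = cho_factor(S, lower=True)
            logdet_S = 2.0 * float(np.sum(np.log(np.diag(cS[0]))))
            S_inv = cho_solve(cS, np.eye(m))
            lags = np.abs(yrs[:, None] - yrs[None, :]).astype(float)
            if phi != 0.0:
                A = (sigma2 / (1.0 - phi**2)) * np.power(phi, lags)
            else:
                A = sigma2 * np.eye(T)
            sign, logdet_A = np.linalg.slogdet(A)
            if sign <= 0:
                raise np.linalg.LinAlgError("temporal covariance not PD")
            A_inv = np.linalg.inv(A)
            blocks.append(np.kron(A_inv, S_inv))
            logdet_cov += m * logdet_A + T * logdet_S
        return blocks, logdet_cov


# ---------------------------------------------------------------------------
# Laplace approximation of the latent block for fixed hyperparameters


class _LaplaceEvaluator:
    """Laplace-approximate log evidence of (y | hyperparameters).

    The latent Gaussian vector is u = (beta, z) with prior
    N(0, blockdiag(s^2 I, C_z(theta))).  For each hyperparameter value the
    posterior mode of u is found by damped Newton iterations; the β block
    of the Gaussian approximation is retained for posterior sampling.
    Warm-starts from the previous mode keep repeated nearby evaluations
    cheap.
    """

    def __init__(self, X, y, structure: _LatentStructure, priors: PriorSpec,
                 model_id: str, engine: EngineConfig):
        self.X = X
        self.y = y.astype(float)
        self.structure = structure
        self.priors = priors
        self.model_id = model_id
        self.engine = engine
        self.p = X.shape[1]
        self.n_latent = structure.n_latent
        self._u = np.zeros(self.p + self.n_latent)
        self.n_failed = 0

    def theta_to_natural(self, theta):
        if self.model_id == "M3":
            lr, ls, tp = theta
            return float(np.exp(lr)), float(np.exp(2 * ls)), float(theta_to_phi(tp))
        lr, ls = theta
        return float(np.exp(lr)), float(np.exp(2 * ls)), 0.0

    def log_hyperprior(self, theta):
        pr = self.priors
        means = [pr.a_rho, pr.a_sigma]
        sds = [pr.b_rho, pr.b_sigma]
        if self.model_id == "M3":
            means.append(pr.a_phi)
            sds.append(pr.b_phi)
        theta = np.asarray(theta, dtype=float)
        return float(
            np.sum(-0.5 * ((theta - means) / sds) ** 2 - np.log(sds))
            - 0.5 * len(sds) * np.log(2 * np.pi)
        )

    def evaluate(self, theta):
        """Return a dict with the Laplace log evidence and the beta block,
        or None when the inner optimisation fails."""
        rho, sigma2, phi = self.theta_to_natural(theta)
        try:
            Q_blocks, logdet_cov = self.structure.precision_blocks(
                rho, sigma2, phi, self.engine.jitter
            )
        except np.linalg.LinAlgError:
            self.n_failed += 1
            return None
        X, y, p = self.X, self.y, self.p
        lat_idx = self.structure.row_latent_index
        s2 = self.priors.s_beta**2
        n_lat = self.n_latent

        def unpack(u):
            return u[:p], u[p:]

        def q_prod(z):
            out = np.empty_like(z)
            for s, Q in zip(self.structure.sites, Q_blocks):
                lo = s["offset"]
                hi = lo + Q.shape[0]
                out[lo:hi] = Q @ z[lo:hi]
            return out

        def objective(u):
            beta, z = unpack(u)
            eta = X @ beta + z[lat_idx]
            ll = float(np.sum(y * eta - _log1pexp(eta)))
            qz = q_prod(z)
            return ll - 0.5 * float(z @ qz) - 0.5 * float(beta @ beta) / s2

        u = self._u.copy()
        f = objective(u)
        if not np.isfinite(f):
            u = np.zeros_like(u)
            f = objective(u)
        converged = False
        for _ in range(self.engine.newton_maxiter):
            beta, z = unpack(u)
            eta = X @ beta + z[lat_idx]
            prob = expit(eta)
            w = np.clip(prob * (1.0 - prob), 1e-10, None)
            resid = y - prob
            g_beta = X.T @ resid - beta / s2
            g_z = np.zeros(n_lat)
            np.add.at(g_z, lat_idx, resid)
            g_z -= q_prod(z)

            W_lat = np.zeros(n_lat)
            np.add.at(W_lat, lat_idx, w)
            C_zb = np.zeros((n_lat, p))
            wX = w[:, None] * X
            np.add.at(C_zb, lat_idx, wX)
            B = X.T @ wX + np.eye(p) / s2

            # block solve via Schur complement on beta
            Minv_g = np.empty(n_lat)
            Minv_C = np.empty((n_lat, p))
            logdet_M = 0.0
            chols = []
            try:
                for s_, Q in zip(self.structure.sites, Q_blocks):
                    lo = s_["offset"]
                    hi = lo + Q.shape[0]
                    M = Q + np.diag(W_lat[lo:hi])
                    cM = cho_factor(M, lower=True)
                    chols.append((lo, hi, cM))
                    logdet_M += 2.0 * float(np.sum(np.log(np.diag(cM[0]))))
                    Minv_g[lo:hi] = cho_solve(cM, g_z[lo:hi])
                    Minv_C[lo:hi] = cho_solve(cM, C_zb[lo:hi])
                S_b = B - C_zb.T @ Minv_C
                cS_b = cho_factor(S_b, lower=True)
            except np.linalg.LinAlgError:
                self.n_failed += 1
                return None
            d_beta = cho_solve(cS_b, g_beta - C_zb.T @ Minv_g)
            rhs_z = g_z - C_zb @ d_beta
            d_z = np.empty(n_lat)
            for lo, hi, cM in chols:
                d_z[lo:hi] = cho_solve(cM, rhs_z[lo:hi])
            step = np.concatenate([d_beta, d_z])

            gnorm = max(np.abs(g_beta).max(), np.abs(g_z).max())
            # damped update
            t = 1.0
            for _ in range(30):
                u_new = u + t * step
                f_new = objective(u_new)
                if np.isfinite(f_new) and f_new >= f - 1e-12:
                    break
                t *= 0.5
            else:
                self.n_failed += 1
                return None
            delta = f_new - f
            u, f = u_new, f_new
            if gnorm < 1e-6 or abs(delta) < self.engine.newton_tol:
                converged = True
                break
        if not converged and gnorm > 1e-3:
            self.n_failed += 1
            return None
        self._u = u.copy()

        logdet_S_b = 2.0 * float(np.sum(np.log(np.diag(cS_b[0]))))
        logdet_H = logdet_M + logdet_S_b
        logdet_Q_u = -p * np.log(s2) - logdet_cov
        log_evidence = f + 0.5 * logdet_Q_u - 0.5 * logdet_H
        beta_mode, _ = unpack(u)
        return {
            "log_evidence": float(log_evidence),
            "log_post": float(log_evidence + self.log_hyperprior(theta)),
            "beta_mode": beta_mode.copy(),
            # (H^-1)_{beta,beta} = S_b^-1: store its Cholesky for sampling
            "S_b_chol": cholesky(S_b, lower=True),
            "natural": (rho, sigma2, phi),
        }


# ---------------------------------------------------------------------------
# M1: ensemble MCMC over beta


def _logpost_beta(beta, X, y, s_beta):
    """Normalised log posterior kernel, vectorised over rows of ``beta``
    (walkers).  The prior normalising constant is included so that bridge
    sampling on this function yields the marginal likelihood directly."""
    B = np.atleast_2d(beta)
    p = B.shape[1]
    eta = B @ X.T
    ll = eta @ y - _log1pexp(eta).sum(axis=1)
    lp = (
        -0.5 * (B**2).sum(axis=1) / s_beta**2
        - 0.5 * p * np.log(2 * np.pi * s_beta**2)
    )
    out = ll + lp
    return out if np.ndim(beta) > 1 else float(out[0])


def fit_logistic_mcmc(X, y, priors: PriorSpec | None = None,
                      engine: EngineConfig | None = None,
                      coef_names: list[str] | None = None) -> ModelFit:
    """Bayesian logistic regression (model M1) via ensemble MCMC.

    Exposed separately so restricted designs (for example an
    intercept-plus-one-slope model) can be fitted directly from (X, y).
    """
    import emcee

    priors = priors or PriorSpec()
    engine = engine or EngineConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = coef_names or [f"beta{j}" for j in range(p)]

    # posterior mode for initialisation (and separation check)
    def negpost(b):
        eta = X @ b
        return -(float(y @ eta - _log1pexp(eta).sum())
                 - 0.5 * float(b @ b) / priors.s_beta**2)

    def neggrad(b):
        eta = X @ b
        return -(X.T @ (y - expit(eta)) - b / priors.s_beta**2)

    res = optimize.minimize(negpost, np.zeros(p), jac=neggrad, method="BFGS")
    mode = res.x
    if np.abs(mode).max() > 10.0:
        warnings.warn(
            "possible separation: a posterior mode coefficient exceeds 10 "
            "in magnitude; the prior regularises the fit", stacklevel=2
        )
    eta = X @ mode
    w = expit(eta) * (1 - expit(eta))
    H = X.T @ (w[:, None] * X) + np.eye(p) / priors.s_beta**2
    L = cholesky(np.linalg.inv(H), lower=True)

    rng = np.random.default_rng(engine.seed)
    # two independent ensembles: potential-scale-reduction is then computed
    # between genuinely independent chains (walkers within one ensemble
    # interact, so walker-wise split-rhat would be miscalibrated)
    nw = max(engine.mcmc_walkers // 2, 2 * p + 2)
    # stretch moves keep the tails calibrated; differential-evolution
    # moves speed up mixing along correlated directions
    moves = [
        (emcee.moves.StretchMove(), 0.5),
        (emcee.moves.DEMove(), 0.4),
        (emcee.moves.DESnookerMove(), 0.1),
    ]
    thinned, flats, taus, accs = [], [], [], []
    for k in range(2):
        sampler = emcee.EnsembleSampler(
            nw, p, _logpost_beta, args=(X, y, priors.s_beta),
            vectorize=True, moves=moves,
        )
        sampler.random_state = np.random.RandomState(
            engine.seed * 2 + k
        ).get_state()
        p0 = mode + (rng.standard_normal((nw, p)) @ L.T)
        state = sampler.run_mcmc(p0, engine.mcmc_burn, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, engine.mcmc_steps, progress=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tau = float(np.max(sampler.get_autocorr_time(quiet=True)))
        thin = max(1, int(round(tau / 2.0)))
        thinned.append(sampler.get_chain(thin=thin).reshape(-1, p))
        flats.append(sampler.get_chain().reshape(-1, p))
        taus.append(tau)
        accs.append(float(np.mean(sampler.acceptance_fraction)))

    import arviz as az

    n_thin = min(len(c) for c in thinned)
    arr = np.stack([c[:n_thin] for c in thinned])  # (2, n_thin, p)
    idata = az.from_dict(posterior={names[j]: arr[:, :, j] for j in range(p)})
    rhat = az.rhat(idata).to_array().to_numpy()
    ess = az.ess(idata).to_array().to_numpy()
    # rhat across the independent ensembles is the primary convergence
    # check; the length guard only protects the tau estimate itself
    long_enough = engine.mcmc_steps > 30 * max(taus)
    converged = bool(np.all(rhat < 1.01) and np.all(ess > 400) and long_enough)
    if not converged:
        warnings.warn(
            f"M1 MCMC convergence flags: max rhat {float(np.max(rhat)):.4f}, "
            f"min ess {float(np.min(ess)):.0f}, "
            f"steps/tau {engine.mcmc_steps / max(taus):.0f}", stacklevel=2
        )

    flat = np.vstack(flats)
    if len(flat) > engine.n_draws:
        keep = rng.choice(len(flat), size=engine.n_draws, replace=False)
        draws = flat[np.sort(keep)]
    else:
        draws = flat

    if engine.compute_evidence:
        bridge_draws = flat
        if len(bridge_draws) > 20000:
            idx = rng.choice(len(bridge_draws), size=20000, replace=False)
            bridge_draws = bridge_draws[np.sort(idx)]
        logml, logml_se = _bridge_sampling(
            lambda B: _logpost_beta(B, X, y, priors.s_beta), bridge_draws,
            rng, n_iter=engine.bridge_iters,
        )
    else:
        logml, logml_se = float("nan"), float("nan")
    summary = _summaries_from_draws(draws, names)
    draws_df = pd.DataFrame(draws, columns=names)
    return ModelFit(
        model_id="M1",
        fixed_effect_summary=summary,
        hyper_summary=None,
        draws=draws_df,
        log_marginal_likelihood=logml,
        log_ml_se=logml_se,
        diagnostics={
            "engine": "emcee",
            "converged": converged,
            "max_rhat": float(np.max(rhat)),
            "min_ess": float(np.min(ess)),
            "max_tau": max(taus),
            "acceptance_fraction": float(np.mean(accs)),
        },
        priors=priors,
        engine=engine,
    )


def _bridge_sampling(logpost, draws, rng, n_iter=200, tol=1e-10):
    """Iterative (Meng-Wong) bridge-sampling estimate of the log evidence.

    Uses a moment-matched Gaussian proposal; returns (log_ml, se) with the
    standard error from batch resampling of the bridge terms.
    """
    draws = np.asarray(draws, dtype=float)
    n1, p = draws.shape
    mu = draws.mean(axis=0)
    cov = np.cov(draws.T).reshape(p, p) + 1e-12 * np.eye(p)
    Lc = cholesky(cov, lower=True)
    n2 = n1
    prop = mu + rng.standard_normal((n2, p)) @ Lc.T

    def logq(B):
        d = solve_triangular(Lc, (B - mu).T, lower=True)
        return (
            -0.5 * (d**2).sum(axis=0)
            - float(np.sum(np.log(np.diag(Lc))))
            - 0.5 * p * np.log(2 * np.pi)
        )

    l1 = logpost(draws) - logq(draws)   # at posterior draws
    l2 = logpost(prop) - logq(prop)     # at proposal draws
    ls1 = np.log(n1 / (n1 + n2))
    ls2 = np.log(n2 / (n1 + n2))

    def iterate(l1, l2):
        n1_, n2_ = len(l1), len(l2)
        logr = logsumexp(l2) - np.log(n2_)  # simple IS start
        for _ in range(n_iter):
            num = logsumexp(l2 - np.logaddexp(ls1 + l2, ls2 + logr)) - np.log(n2_)
            den = logsumexp(-np.logaddexp(ls1 + l1, ls2 + logr)) - np.log(n1_)
            logr_new = num - den
            if abs(logr_new - logr) < tol:
                logr = logr_new
                break
            logr = logr_new
        return logr

    logml = iterate(l1, l2)
    # batch SE
    nb = 10
    ests = []
    for b in range(nb):
        s1 = slice(b * n1 // nb, (b + 1) * n1 // nb)
        s2 = slice(b * n2 // nb, (b + 1) * n2 // nb)
        ests.append(iterate(l1[s1], l2[s2]))
    se = float(np.std(ests, ddof=1) / np.sqrt(nb))
    return float(logml), se


# ---------------------------------------------------------------------------
# M2/M3: Laplace + importance sampling over hyperparameters


def _summaries_from_draws(draws: np.ndarray, names: list[str]) -> pd.DataFrame:
    qs = np.percentile(draws, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean": draws.mean(axis=0),
            "sd": draws.std(axis=0, ddof=1),
            "q0.025": qs[0],
            "q0.5": qs[1],
            "q0.975": qs[2],
        },
        index=names,
    )


def _weighted_summary(values: np.ndarray, weights: np.ndarray) -> dict:
    w = weights / weights.sum()
    mean = float(np.sum(w * values))
    sd = float(np.sqrt(max(np.sum(w * (values - mean) ** 2), 0.0)))
    order = np.argsort(values)
    v, ws = values[order], w[order]
    cw = np.cumsum(ws) - 0.5 * ws
    q = np.interp([0.025, 0.5, 0.975], cw, v)
    return {"mean": mean, "sd": sd, "q0.025": q[0], "q0.5": q[1], "q0.975": q[2]}


def _fit_latent_model(table, model_id, priors, engine) -> ModelFit:
    df = table.df if hasattr(table, "df") else table
    X, names = build_design_matrix(df)
    y = df["barren"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("outcome is all 0 or all 1: model not estimable")
    structure = _LatentStructure(df)
    ev = _LaplaceEvaluator(X, y, structure, priors, model_id, engine)
    d = 3 if model_id == "M3" else 2
    rng = np.random.default_rng(engine.seed)

    def negpsi(theta):
        out = ev.evaluate(theta)
        return np.inf if out is None else -out["log_post"]

    # coarse deterministic grid to seed the optimiser: the hyper-posterior
    # can be ridged, and a single simplex run from the prior mean may
    # stall on the wrong flank
    ax_rho = priors.a_rho + np.array([-1.5, 0.0, 1.5])
    ax_sig = priors.a_sigma + np.array([-1.0, 0.0, 1.0, 2.0])
    axes = [ax_rho, ax_sig]
    if d == 3:
        axes.append(priors.a_phi + np.array([-1.0, 0.0, 1.0, 2.0]))
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(d, -1).T
    grid_vals = np.array([negpsi(t) for t in grid])
    theta_best = grid[int(np.argmin(grid_vals))]

    res = optimize.minimize(
        negpsi, theta_best, method="Nelder-Mead",
        options={"maxfev": engine.nm_maxfev, "xatol": 1e-2, "fatol": 1e-3},
    )
    # restart once from the incumbent: cheap (warm-started) and guards
    # against premature simplex collapse
    res2 = optimize.minimize(
        negpsi, res.x, method="Nelder-Mead",
        options={"maxfev": engine.nm_maxfev // 2, "xatol": 1e-2,
                 "fatol": 1e-3},
    )
    if res2.fun < res.fun:
        res = res2
    theta_hat = res.x
    psi_hat = -res.fun
    if not np.isfinite(psi_hat):
        raise RuntimeError(f"{model_id}: hyperparameter optimisation failed")

    # numerical Hessian of psi at the mode (central differences)
    h = 0.15
    Hs = np.zeros((d, d))
    f0 = psi_hat

    def psi(theta):
        out = ev.evaluate(theta)
        return -np.inf if out is None else out["log_post"]

    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            if i == j:
                val = (psi(theta_hat + ei) - 2 * f0 + psi(theta_hat - ei)) / h**2
            else:
                val = (
                    psi(theta_hat + ei + ej) - psi(theta_hat + ei - ej)
                    - psi(theta_hat - ei + ej) + psi(theta_hat - ei - ej)
                ) / (4 * h**2)
            Hs[i, j] = Hs[j, i] = val
    prec = -Hs
    evals, evecs = np.linalg.eigh(prec)
    evals = np.clip(evals, 1e-2, None)  # floor: proposal never wider than ~10 sd
    cov_theta = (evecs / evals) @ evecs.T

    if engine.evidence_method == "laplace":
        # evidence and draws from the modal approximation only
        sign, logdet_prec = np.linalg.slogdet(prec)
        out_hat = ev.evaluate(theta_hat)
        logml = (
            psi_hat + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet_prec
        )
        theta_draws = theta_hat + rng.multivariate_normal(
            np.zeros(d), cov_theta, size=engine.n_draws
        )
        beta_draws = out_hat["beta_mode"] + solve_triangular(
            out_hat["S_b_chol"].T,
            rng.standard_normal((X.shape[1], engine.n_draws)),
            lower=False,
        ).T
        weights = np.ones(engine.n_draws)
        kish = float(engine.n_draws)
        logml_se = np.nan
        theta_for_summary = theta_draws
        w_for_summary = weights
    else:
        # multivariate-t importance sampler centred at the mode
        Lp = cholesky(cov_theta * engine.proposal_scale**2, lower=True)
        df_t = engine.proposal_df
        n_is = engine.n_is
        z = rng.standard_normal((n_is, d))
        g = rng.chisquare(df_t, size=n_is) / df_t
        theta_s = theta_hat + (z @ Lp.T) / np.sqrt(g)[:, None]

        def logq_t(T):
            dev = solve_triangular(Lp, (T - theta_hat).T, lower=True)
            q2 = (dev**2).sum(axis=0)
            return float(
                special.gammaln((df_t + d) / 2) - special.gammaln(df_t / 2)
                - 0.5 * d * np.log(df_t * np.pi)
                - np.sum(np.log(np.diag(Lp)))
            ) - 0.5 * (df_t + d) * np.log1p(q2 / df_t)

        lw = np.full(n_is, -np.inf)
        cache = [None] * n_is
        for i in range(n_is):
            out = ev.evaluate(theta_s[i])
            if out is not None:
                cache[i] = out
                lw[i] = out["log_post"]
        lq = logq_t(theta_s)
        lw = np.where(np.isfinite(lw), lw - lq, -np.inf)
        if not np.any(np.isfinite(lw)):
            raise RuntimeError(f"{model_id}: all importance weights degenerate")
        lw_max = np.max(lw)
        wt = np.exp(lw - lw_max)
        logml = float(lw_max + np.log(np.mean(wt)))
        logml_se = float(np.std(wt, ddof=1) / (np.mean(wt) * np.sqrt(n_is)))
        kish = float(wt.sum() ** 2 / np.sum(wt**2))

        # resample hyperparameters, draw beta | theta from the Laplace block
        probs = wt / wt.sum()
        counts = rng.multinomial(engine.n_draws, probs)
        beta_list, theta_list = [], []
        for i in np.flatnonzero(counts):
            out = cache[i]
            c = counts[i]
            bd = out["beta_mode"] + solve_triangular(
                out["S_b_chol"].T, rng.standard_normal((X.shape[1], c)),
                lower=False,
            ).T
            beta_list.append(bd)
            theta_list.append(np.repeat(theta_s[i][None, :], c, axis=0))
        beta_draws = np.vstack(beta_list)
        theta_draws = np.vstack(theta_list)
        perm = rng.permutation(len(beta_draws))
        beta_draws, theta_draws = beta_draws[perm], theta_draws[perm]
        theta_for_summary = theta_s
        w_for_summary = wt

    # hyperparameter summaries (weighted over the IS sample)
    finite = np.isfinite(w_for_summary) & (w_for_summary > 0)
    ths, ws = theta_for_summary[finite], w_for_summary[finite]
    rho_v = np.exp(ths[:, 0])
    sig_v = np.exp(ths[:, 1])
    rows = {"range_m": _weighted_summary(rho_v, ws),
            "spatial_sd": _weighted_summary(sig_v, ws)}
    if model_id == "M3":
        rows["temporal_correlation"] = _weighted_summary(
            np.asarray(theta_to_phi(ths[:, 2])), ws
        )
    hyper_summary = pd.DataFrame(rows).T[["mean", "sd", "q0.025", "q0.5", "q0.975"]]

    draws_df = pd.DataFrame(beta_draws, columns=names)
    draws_df["range_m"] = np.exp(theta_draws[:, 0])
    draws_df["spatial_sd"] = np.exp(theta_draws[:, 1])
    if model_id == "M3":
        draws_df["temporal_correlation"] = theta_to_phi(theta_draws[:, 2])

    converged = bool(
        res.success
        and (engine.evidence_method == "laplace" or kish >= engine.min_kish_ess)
    )
    if not converged:
        warnings.warn(
            f"{model_id} fit convergence flags: optimizer success={res.success}, "
            f"Kish ESS={kish:.1f}", stacklevel=2
        )
    summary = _summaries_from_draws(beta_draws, names)
    return ModelFit(
        model_id=model_id,
        fixed_effect_summary=summary,
        hyper_summary=hyper_summary,
        draws=draws_df,
        log_marginal_likelihood=float(logml),
        log_ml_se=float(logml_se) if np.isfinite(logml_se) else float("nan"),
        diagnostics={
            "engine": f"laplace_{engine.evidence_method}",
            "converged": converged,
            "kish_ess": kish,
            "optimizer_success": bool(res.success),
            "optimizer_nfev": int(res.nfev),
            "n_failed_inner": ev.n_failed,
            "theta_mode": theta_hat.tolist(),
            "n_latent": structure.n_latent,
        },
        priors=priors,
        engine=engine,
    )


def fit(table, model_id: str, priors: PriorSpec | None = None,
        engine_config: EngineConfig | None = None) -> ModelFit:
    """Fit one of the nested models M1/M2/M3 to an analysis table.

    M2 fixes the temporal correlation at zero; M1 additionally removes the
    spatial field.  Returns posterior summaries, >= ``n_draws`` joint draws
    of the coefficients (and hyperparameters where present), the log
    marginal likelihood with a standard error, and convergence diagnostics.
    """
    priors = priors or PriorSpec()
    engine = engine_config or EngineConfig()
    if model_id == "M1":
        df = table.df if hasattr(table, "df") else table
        X, names = build_design_matrix(df)
        y = df["barren"].to_numpy(dtype=float)
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError("outcome is all 0 or all 1: model not estimable")
        return replace_model_id(fit_logistic_mcmc(
            X, y, priors=priors, engine=engine, coef_names=names
        ), "M1")
    if model_id in ("M2", "M3"):
        return _fit_latent_model(table, model_id, priors, engine)
    raise ValueError(f"unknown model_id {model_id!r}")


def replace_model_id(fit_: ModelFit, model_id: str) -> ModelFit:
    return replace(fit_, model_id=model_id)


def log_marginal_likelihood(fit_: ModelFit) -> float:
    """The fit's log evidence estimate; refuses a non-converged fit."""
    if not fit_.diagnostics.get("converged", False):
        raise RuntimeError(
            f"{fit_.model_id}: refusing marginal likelihood from a "
            "non-converged fit"
        )
    return float(fit_.log_marginal_likelihood)
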