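"""Two-pool first-order SOM decomposition model and its MCMC inversion.

The control-soil CO2 emission rate, normalized per g SOC, is modelled as
the sum of a fast and a slow pool each decaying first-order:

    R(t) = k1 f1 C_tot exp(-k1 t) + k2 (1 - f1) C_tot exp(-k2 t)

with R in mg C g-1 SOC d-1, C_tot fixed at 1000 mg C g-1 SOC (so pool
sizes read as percent of SOC), f1 the fast-pool fraction and k1 > k2
the decay constants (d-1).  Parameters are estimated by random-walk
Metropolis under independent uniform priors; the Gaussian noise scale
is treated as a free parameter under a Jeffreys prior and integrated
out analytically, leaving a marginal posterior proportional to
SSR^(-n/2) on the prior box.

A short incubation cannot pin down the slow pool: k2 is typically
poorly constrained, which is why the posterior summary distinguishes
well- from poorly-constrained parameters and reports the MAP for the
former and the posterior mean for the latter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PARAM_NAMES = ("f1", "k1", "k2")

#: default uniform prior box; overridable per fit
DEFAULT_PRIORS = {
    "f1": (1e-4, 0.5),
    "k1": (0.005, 1.0),
    "k2": (1e-6, 0.005),
}

C_TOT_DEFAULT = 1000.0   # mg C g-1 SOC == 100% of SOC


@dataclass(frozen=True)
class TwoPoolParams:
    """Fast-pool fraction and decay constants of the two-pool model."""

    f1: float
    k1: float
    k2: float
    c_tot: float = C_TOT_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 < self.f1 < 1.0:
            raise ValueError("f1 must lie in (0, 1)")
        if not self.k1 > self.k2 > 0.0:
            raise ValueError("need k1 > k2 > 0 (fast pool decays faster)")
        if self.c_tot <= 0:
            raise ValueError("c_tot must be positive")


@dataclass
class PosteriorSummary:
    """Pooled post-burn-in MCMC summary for one site."""

    map_estimate: dict[str, float]
    mean: dict[str, float]
    q025: dict[str, float]
    q975: dict[str, float]
    constraint_class: dict[str, str]       # well_constrained / poorly_constrained
    point_estimate: dict[str, float]       # MAP if well-, mean if poorly constrained
    gelman_rubin: dict[str, float]
    acceptance_rate: float
    r2: float
    rmse: float
    priors: dict[str, tuple[float, float]]
    draws: np.ndarray = field(repr=False)      # (n_kept_total, 3)
    log_post: np.ndarray = field(repr=False)   # (n_kept_total,)

    @property
    def params(self) -> TwoPoolParams:
        return TwoPoolParams(**self.point_estimate)


def two_pool_rate(t, params: TwoPoolParams):
    """CO2 emission rate R(t) in mg C g-1 SOC d-1 (t in days)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    fast = params.k1 * params.f1 * params.c_tot * np.exp(-params.k1 * t)
    slow = params.k2 * (1.0 - params.f1) * params.c_tot * np.exp(-params.k2 * t)
    out = fast + slow
    return float(out) if out.ndim == 0 else out


def fit_quality(days, observed, params: TwoPoolParams) -> tuple[float, float]:
    """R^2 and RMSE of the model against observed rates."""
    observed = np.asarray(observed, dtype=float)
    if observed.size < 2:
        raise ValueError("need at least 2 observations")
    pred = two_pool_rate(days, params)
    ss_res = float(np.sum((observed - pred) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / observed.size))
    if ss_tot == 0.0:
        return float("nan"), rmse
    return 1.0 - ss_res / ss_tot, rmse


def log_posterior(
    params: TwoPoolParams,
    days,
    observed,
    priors: dict[str, tuple[float, float]] | None = None,
    noise_sd: float = 0.1,
    relative_noise: bool = False,
) -> float:
    """Fixed-noise log posterior: iid Gaussian likelihood + flat prior.

    Returns -inf outside the prior box or when k1 <= k2.  With
    ``relative_noise`` the per-point SD is ``noise_sd * |observed|``.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    priors = priors or DEFAULT_PRIORS
    theta = (params.f1, params.k1, params.k2)
    for name, value in zip(PARAM_NAMES, theta):
        lo, hi = priors[name]
        if not lo <= value <= hi:
            return -np.inf
    if params.k1 <= params.k2:
        return -np.inf
    observed = np.asarray(observed, dtype=float)
    pred = two_pool_rate(days, params)
    sd = noise_sd * np.abs(observed) if relative_noise else noise_sd
    sd = np.broadcast_to(np.asarray(sd, dtype=float), observed.shape)
    return float(
        -0.5 * np.sum(((observed - pred) / sd) ** 2)
        - np.sum(np.log(sd))
        - 0.5 * observed.size * np.log(2.0 * np.pi)
    )


# ---------------------------------------------------------------------------
# Metropolis machinery
#
# The walk runs in an unconstrained space z: f1 through a linear logit over
# its prior interval, k1/k2 through a logit of log-position within theirs
# (they span decades).  The Jacobian of each map is included in the target
# so the prior stays uniform on the ORIGINAL scale.

def _to_z(theta: np.ndarray, bounds: np.ndarray, log_scale: np.ndarray) -> np.ndarray:
    lo, hi = bounds[:, 0], bounds[:, 1]
    u = np.where(
        log_scale,
        (np.log(theta) - np.log(lo)) / (np.log(hi) - np.log(lo)),
        (theta - lo) / (hi - lo),
    )
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return np.log(u / (1.0 - u))


def _from_z(z: np.ndarray, bounds: np.ndarray, log_scale: np.ndarray):
    lo, hi = bounds[..., 0], bounds[..., 1]
    u = 1.0 / (1.0 + np.exp(-z))
    theta = np.where(
        log_scale,
        np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))),
        lo + u * (hi - lo),
    )
    # log |d theta / d z|, summed over parameters
    span = np.where(log_scale, np.log(hi) - np.log(lo), hi - lo)
    log_jac = np.sum(
        np.log(span) + np.log(u) + np.log1p(-u)
        + np.where(log_scale, np.log(theta), 0.0),
        axis=-1,
    )
    return theta, log_jac


def _marginal_loglik(theta: np.ndarray, days: np.ndarray, observed: np.ndarray,
                     c_tot: float) -> np.ndarray:
    """log SSR^(-n/2) likelihood for a (m, 3) parameter block."""
    f1, k1, k2 = theta[..., 0], theta[..., 1], theta[..., 2]
    pred = (
        k1[..., None] * f1[..., None] * c_tot * np.exp(-k1[..., None] * days)
        + k2[..., None] * (1.0 - f1[..., None]) * c_tot
        * np.exp(-k2[..., None] * days)
    )
    ssr = np.sum((observed - pred) ** 2, axis=-1)
    n = days.size
    return -0.5 * n * np.log(np.maximum(ssr, 1e-300))


def mcmc_fit(
    days,
    observed,
    priors: dict[str, tuple[float, float]] | None = None,
    n_chains: int = 3,
    n_iter: int = 50_000,
    seed: int = 0,
    c_tot: float = C_TOT_DEFAULT,
    noise_sd: float | None = None,
    relative_noise: bool = False,
    thin: int = 1,
) -> PosteriorSummary:
    """Random-walk Metropolis inversion of the two-pool model.

    Proposal scales adapt toward ~30% acceptance during burn-in (first
    half, discarded) and are frozen afterwards.  With ``noise_sd=None``
    (default) the noise scale is marginalized under a Jeffreys prior;
    pass a value for a fixed absolute (or, with ``relative_noise``,
    relative) Gaussian error model.  Deterministic for a fixed seed.
    """
    days = np.asarray(days, dtype=float)
    observed = np.asarray(observed, dtype=float)
    priors = dict(priors or DEFAULT_PRIORS)
    if n_chains < 2:
        raise ValueError("need >= 2 chains for convergence diagnostics")
    bounds = np.array([priors[p] for p in PARAM_NAMES], dtype=float)
    log_scale = np.array([False, True, True])
    rng = np.random.default_rng(seed)

    def target(theta_block: np.ndarray) -> np.ndarray:
        """Log posterior density on the ORIGINAL scale (flat prior)."""
        if noise_sd is None:
            ll = _marginal_loglik(theta_block, days, observed, c_tot)
        else:
            sd = noise_sd * np.abs(observed) if relative_noise else noise_sd
            sd = np.broadcast_to(np.asarray(sd, dtype=float), observed.shape)
            f1, k1, k2 = (theta_block[..., i] for i in range(3))
            pred = (
                k1[..., None] * f1[..., None] * c_tot
                * np.exp(-k1[..., None] * days)
                + k2[..., None] * (1.0 - f1[..., None]) * c_tot
                * np.exp(-k2[..., None] * days)
            )
            ll = -0.5 * np.sum(((observed - pred) / sd) ** 2, axis=-1)
        # identifiability guard: forbid label switching
        ll = np.where(theta_block[..., 1] > theta_block[..., 2], ll, -np.inf)
        return ll

    # overdispersed starts drawn uniformly in z
    z = rng.uniform(-2.0, 2.0, size=(n_chains, 3))
    theta, log_jac = _from_z(z, bounds, log_scale)
    log_p = target(theta) + log_jac

    # component-wise updates with one adaptive scale per chain x parameter:
    # the fast-pool terms are tightly constrained while k2 is nearly flat,
    # so a shared scale cannot serve all coordinates
    scales = np.full((n_chains, 3), 1.0)
    burn = n_iter // 2
    adapt_window = 100
    accepted_window = np.zeros((n_chains, 3))
    accepted_post = 0

    n_kept = (n_iter - burn) // thin
    draws = np.empty((n_chains, n_kept, 3))
    kept_lp = np.empty((n_chains, n_kept))
    burn_z = np.empty((n_chains, burn, 3))
    # joint (correlated) proposal, learned from burn-in samples: the three
    # parameters trade off along a ridge that axis-aligned steps cannot
    # travel efficiently
    joint_chol: np.ndarray | None = None
    joint_scale = np.full(n_chains, 1.0)
    joint_window = np.zeros(n_chains)
    k = 0
    for it in range(n_iter):
        for j in range(3):
            prop_z = z.copy()
            prop_z[:, j] += rng.normal(size=n_chains) * scales[:, j]
            prop_theta, prop_jac = _from_z(prop_z, bounds, log_scale)
            prop_lp = target(prop_theta) + prop_jac
            accept = np.log(rng.uniform(size=n_chains)) < (prop_lp - log_p)
            z = np.where(accept[:, None], prop_z, z)
            theta = np.where(accept[:, None], prop_theta, theta)
            log_p = np.where(accept, prop_lp, log_p)
            if it < burn:
                accepted_window[:, j] += accept
            else:
                accepted_post += int(accept.sum())
        if joint_chol is not None:
            step = rng.normal(size=(n_chains, 3)) @ joint_chol.T
            prop_z = z + joint_scale[:, None] * step
            prop_theta, prop_jac = _from_z(prop_z, bounds, log_scale)
            prop_lp = target(prop_theta) + prop_jac
            accept = np.log(rng.uniform(size=n_chains)) < (prop_lp - log_p)
            z = np.where(accept[:, None], prop_z, z)
            theta = np.where(accept[:, None], prop_theta, theta)
            log_p = np.where(accept, prop_lp, log_p)
            if it < burn:
                joint_window += accept
            else:
                accepted_post += int(accept.sum())
        if it < burn:
            burn_z[:, it, :] = z
            if (it + 1) % adapt_window == 0:
                rate = accepted_window / adapt_window
                scales = np.clip(scales * np.exp(rate - 0.35), 1e-3, 20.0)
                accepted_window[:] = 0.0
                if joint_chol is not None:
                    jrate = joint_window / adapt_window
                    joint_scale = np.clip(
                        joint_scale * np.exp(jrate - 0.3), 1e-2, 10.0
                    )
                    joint_window[:] = 0.0
            # (re)estimate the proposal covariance from pooled recent history
            if (it + 1) % max(burn // 4, 1) == 0:
                lo_it = (it + 1) // 2
                pooled = burn_z[:, lo_it: it + 1, :].reshape(-1, 3)
                cov = np.cov(pooled.T) + 1e-8 * np.eye(3)
                joint_chol = np.linalg.cholesky((2.38 ** 2 / 3.0) * cov)
        elif (it - burn) % thin == 0 and k < n_kept:
            draws[:, k, :] = theta
            kept_lp[:, k] = log_p
            k += 1

    acceptance = accepted_post / ((n_iter - burn) * n_chains * 4)
    if acceptance < 0.01:
        raise RuntimeError(
            f"Metropolis acceptance rate {acceptance:.4f} < 1%; "
            "review prior bounds or proposal scales"
        )

    rhat = {
        name: _split_rhat(draws[:, :, i]) for i, name in enumerate(PARAM_NAMES)
    }
    flat = draws.reshape(-1, 3)
    flat_lp = kept_lp.reshape(-1)
    i_map = int(np.argmax(flat_lp))
    map_est = dict(zip(PARAM_NAMES, flat[i_map]))
    mean = dict(zip(PARAM_NAMES, flat.mean(axis=0)))
    q025 = dict(zip(PARAM_NAMES, np.quantile(flat, 0.025, axis=0)))
    q975 = dict(zip(PARAM_NAMES, np.quantile(flat, 0.975, axis=0)))

    constraint, point = {}, {}
    for name in PARAM_NAMES:
        lo, hi = priors[name]
        narrow = (q975[name] - q025[name]) < 0.8 * (hi - lo)
        central = lo + 0.05 * (hi - lo) <= map_est[name] <= hi - 0.05 * (hi - lo)
        cls = "well_constrained" if (narrow and central) else "poorly_constrained"
        constraint[name] = cls
        point[name] = map_est[name] if cls == "well_constrained" else mean[name]

    fitted = TwoPoolParams(c_tot=c_tot, **point)
    r2, rmse = fit_quality(days, observed, fitted)
    return PosteriorSummary(
        map_estimate=map_est, mean=mean, q025=q025, q975=q975,
        constraint_class=constraint, point_estimate=point,
        gelman_rubin=rhat, acceptance_rate=float(acceptance),
        r2=r2, rmse=rmse, priors=priors,
        draws=flat, log_post=flat_lp,
    )


def _split_rhat(chains: np.ndarray) -> float:
    """Classic split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); each chain is split in half
    so within-chain drift also inflates the statistic.
    """
    n_chains, n = chains.shape
    half = n // 2
    segs = np.concatenate(
        [chains[:, :half], chains[:, half: 2 * half]], axis=0
    )   # (2m, half)
    m, n = segs.shape
    means = segs.mean(axis=1)
    b = n * means.var(ddof=1)
    w = segs.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(max(np.sqrt(var_plus / w), 1.0))
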