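"""Differential-equation model of long-term biomarker trajectories.

Short longitudinal segments give each carrier a biomarker value x and a
rate of change dx/dt. Treating rate as an unknown function of value,
f(x) = dx/dt, turns trajectory reconstruction into 1-D regression: we
place a Gaussian-process prior on f with a squared-exponential
covariance

    k(x_i, x_j) = eta^2 * exp(-rho^2 * (x_i - x_j)^2) + delta_ij * sigma^2

(output scale eta in rate units, inverse length-scale rho in 1/value
units, observation noise sigma), broad half-Cauchy hyperpriors, and
draw posterior function samples. Integrating dt = dx / f_s(x) for each
sample f_s from a data-driven anchor — the canonical abnormal level,
the median value at carriers' first symptomatic visit, defining t = 0 —
yields a distribution of monotone long-time trajectories x_s(t), a
distribution of abnormality transition times (years from the canonical
normal to the canonical abnormal level), and an empirical
cumulative-probability-of-abnormality curve per biomarker.

Hyperparameter inference is MAP with a Laplace approximation by
default; full MCMC over the hyperparameters (affine-invariant ensemble
sampler) is available via ``method="mcmc"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from scipy.special import logsumexp

from .preprocess import AdjustedPanel

__all__ = [
    "Kernel",
    "RateFunctionPosterior",
    "AnchorLevels",
    "TrajectoryPosterior",
    "fit_rate_function",
    "compute_anchor_levels",
    "integrate_trajectory",
    "cumulative_abnormality_curve",
    "crossvalidate_fit",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Kernel:
    """Squared-exponential kernel hyperparameters."""

    eta: float    # output scale, rate units
    rho: float    # inverse length-scale, 1/value units
    sigma: float  # observation noise sd, rate units

    def __post_init__(self):
        if min(self.eta, self.rho, self.sigma) <= 0:
            raise ValueError("kernel hyperparameters must be positive")

    def cov(self, x1: np.ndarray, x2: np.ndarray | None = None,
            noise: bool = False) -> np.ndarray:
        x1 = np.asarray(x1, float)
        x2 = x1 if x2 is None else np.asarray(x2, float)
        K = self.eta ** 2 * np.exp(-self.rho ** 2 * np.subtract.outer(x1, x2) ** 2)
        if noise:
            if K.shape[0] != K.shape[1]:
                raise ValueError("noise only applies to square covariances")
            K = K + self.sigma ** 2 * np.eye(K.shape[0])
        return K


def _chol_with_jitter(K: np.ndarray):
    """Cholesky with an escalating jitter ramp starting at 1e-8."""
    jitter = 0.0
    scale = max(float(np.mean(np.diag(K))), 1e-30)
    for attempt in range(10):
        try:
            return linalg.cho_factor(K + jitter * np.eye(K.shape[0]), lower=True)
        except linalg.LinAlgError:
            jitter = 1e-8 * scale * (10 ** attempt)
            log.warning("covariance not positive definite; jitter %.2e", jitter)
    raise linalg.LinAlgError("covariance not positive definite even with jitter")


def _log_marginal_likelihood(kern: Kernel, x: np.ndarray, y: np.ndarray) -> float:
    K = kern.cov(x, noise=True)
    cf = _chol_with_jitter(K)
    alpha = linalg.cho_solve(cf, y)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * len(y) * np.log(2 * np.pi))


def _log_half_cauchy(theta: float, scale: float) -> float:
    return float(np.log(2.0 / (np.pi * scale)) - np.log1p((theta / scale) ** 2))


@dataclass
class RateFunctionPosterior:
    """Posterior over the rate function f(x) = dx/dt for one biomarker."""

    grid: np.ndarray            # value grid (G,)
    mean: np.ndarray            # posterior mean rate on grid (G,)
    samples: np.ndarray         # (M, G) sampled rate functions
    hyper_samples: np.ndarray   # (M, 3) [eta, rho, sigma] draws
    kernel_map: Kernel          # MAP hyperparameters
    x: np.ndarray               # training values
    y: np.ndarray               # training rates
    y_center: float             # rate offset removed before GP fitting

    def predict(self, x_star) -> tuple:
        """Posterior predictive mean and sd of the observed rate (noise
        included) at new values, marginalized over hyperparameter draws."""
        x_star = np.atleast_1d(np.asarray(x_star, float))
        yc = self.y - self.y_center
        means, varis = [], []
        for eta, rho, sigma in self.hyper_samples:
            kern = Kernel(eta, rho, sigma)
            cf = _chol_with_jitter(kern.cov(self.x, noise=True))
            ks = kern.cov(x_star, self.x)
            mu = ks @ linalg.cho_solve(cf, yc)
            v = kern.eta ** 2 - np.einsum(
                "ij,ji->i", ks, linalg.cho_solve(cf, ks.T)) + sigma ** 2
            means.append(mu + self.y_center)
            varis.append(np.maximum(v, 1e-12))
        means = np.array(means)
        varis = np.array(varis)
        mix_mean = means.mean(axis=0)
        mix_var = (varis + means ** 2).mean(axis=0) - mix_mean ** 2
        return mix_mean, np.sqrt(np.maximum(mix_var, 1e-12))

    def log_predictive_density(self, x_star, y_star) -> np.ndarray:
        """Pointwise held-out log density under the hyperparameter mixture."""
        x_star = np.atleast_1d(np.asarray(x_star, float))
        y_star = np.atleast_1d(np.asarray(y_star, float))
        yc = self.y - self.y_center
        comps = []
        for eta, rho, sigma in self.hyper_samples:
            kern = Kernel(eta, rho, sigma)
            cf = _chol_with_jitter(kern.cov(self.x, noise=True))
            ks = kern.cov(x_star, self.x)
            mu = ks @ linalg.cho_solve(cf, yc) + self.y_center
            v = kern.eta ** 2 - np.einsum(
                "ij,ji->i", ks, linalg.cho_solve(cf, ks.T)) + sigma ** 2
            v = np.maximum(v, 1e-12)
            comps.append(-0.5 * np.log(2 * np.pi * v) - 0.5 * (y_star - mu) ** 2 / v)
        comps = np.array(comps)          # (M, n_star)
        return logsumexp(comps, axis=0) - np.log(len(comps))


def _prior_scales(x: np.ndarray, y: np.ndarray) -> tuple:
    sy = float(np.std(y))
    sy = max(sy, 1e-3 * max(abs(float(np.mean(y))), 1.0))
    rx = float(np.ptp(x))
    return 2.0 * sy, 4.0 / rx, 2.0 * sy   # eta, rho, sigma half-Cauchy scales


def fit_rate_function(x, dxdt, grid_size: int = 200, margin: float = 0.10,
                      n_samples: int = 100, method: str = "laplace",
                      n_walkers: int = 12, n_steps: int = 1500,
                      n_burn: int = 500, rng=None) -> RateFunctionPosterior:
    """Fit the GP regression of rate on value and draw posterior function
    samples on a grid spanning the observed values extended ``margin``
    each side.

    ``method="laplace"``: MAP hyperparameters (three deterministic
    starts) with a Laplace approximation in log-hyperparameter space;
    ``method="mcmc"``: ensemble MCMC over the hyperparameters with a
    split-chain convergence check. Either way one function sample is
    drawn per retained hyperparameter draw.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x, float)
    y = np.asarray(dxdt, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 8:
        raise ValueError(f"need >= 8 differential points, got {len(x)}")
    if np.ptp(x) <= 0:
        raise ValueError("x range is degenerate")
    y_center = float(np.mean(y))
    yc = y - y_center
    s_eta, s_rho, s_sig = _prior_scales(x, y)

    log_scales = np.log([s_eta, s_rho, s_sig])

    def log_post(log_theta):
        # confine the search to a generous box around the prior scales;
        # outside it the kernel under/overflows on degenerate data
        if np.any(log_theta < log_scales - 15) or np.any(log_theta > log_scales + 8):
            return -np.inf
        theta = np.exp(log_theta)
        if np.any(~np.isfinite(theta)) or np.any(theta <= 0):
            return -np.inf
        kern = Kernel(*theta)
        try:
            lml = _log_marginal_likelihood(kern, x, yc)
        except linalg.LinAlgError:
            return -np.inf
        lp = (_log_half_cauchy(theta[0], s_eta)
              + _log_half_cauchy(theta[1], s_rho)
              + _log_half_cauchy(theta[2], s_sig)
              + np.sum(log_theta))           # Jacobian of the log transform
        return lml + lp

    starts = [
        np.log([s_eta / 2, s_rho / 4, s_sig / 2]),
        np.log([s_eta, s_rho, s_sig / 10]),
        np.log([s_eta / 4, s_rho, s_sig]),
    ]
    best = None
    for s0 in starts:
        res = optimize.minimize(lambda lt: -log_post(lt), s0, method="Nelder-Mead",
                                options={"xatol": 1e-5, "fatol": 1e-7,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    map_log = best.x
    kernel_map = Kernel(*np.exp(map_log))

    if method == "laplace":
        H = _numeric_hessian(lambda lt: -log_post(lt), map_log)
        w, V = np.linalg.eigh(0.5 * (H + H.T))
        w = np.maximum(w, 1e-6)
        cov = (V / w) @ V.T
        L = np.linalg.cholesky(cov)
        draws = map_log[None, :] + (L @ rng.standard_normal((3, max(n_samples, 1)))).T
    elif method == "mcmc":
        import emcee
        p0 = map_log + 0.05 * rng.standard_normal((n_walkers, 3))
        sampler = emcee.EnsembleSampler(n_walkers, 3, log_post)
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2 ** 31))).get_state()
        state = sampler.run_mcmc(p0, n_burn, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, n_steps, progress=False)
        chains = sampler.get_chain()          # (n_steps, n_walkers, 3)
        rhat = _split_rhat(chains)
        if np.any(rhat > 1.05):
            log.warning("split-chain statistic above 1.05: %s", rhat)
        flat = chains.reshape(-1, 3)
        idx = rng.choice(len(flat), size=max(n_samples, 1), replace=False)
        draws = flat[idx]
    else:
        raise ValueError(f"unknown method {method!r}")

    lo = x.min() - margin * np.ptp(x)
    hi = x.max() + margin * np.ptp(x)
    grid = np.linspace(lo, hi, grid_size)

    samples = np.empty((len(draws), grid_size))
    mean_acc = np.zeros(grid_size)
    for m, lt in enumerate(draws):
        kern = Kernel(*np.exp(lt))
        cf = _chol_with_jitter(kern.cov(x, noise=True))
        ks = kern.cov(grid, x)
        mu = ks @ linalg.cho_solve(cf, yc)
        cov_f = kern.cov(grid) - ks @ linalg.cho_solve(cf, ks.T)
        cf_g = _chol_with_jitter(cov_f + 1e-10 * kern.eta ** 2 * np.eye(grid_size))
        Lg = np.tril(cf_g[0])
        samples[m] = mu + y_center + Lg @ rng.standard_normal(grid_size)
        mean_acc += mu + y_center
    mean = mean_acc / len(draws)

    return RateFunctionPosterior(grid=grid, mean=mean, samples=samples,
                                 hyper_samples=np.exp(draws),
                                 kernel_map=kernel_map, x=x, y=y,
                                 y_center=y_center)


def _numeric_hessian(f, x0, eps: float = 1e-3) -> np.ndarray:
    n = len(x0)
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps ** 2)
    if not np.all(np.isfinite(H)):
        H = np.where(np.isfinite(H), H, 0.0)
        H += np.eye(n)
    _ = f0
    return H


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction per parameter."""
    n, w, p = chains.shape
    half = n // 2
    seq = np.concatenate([chains[:half], chains[half: 2 * half]], axis=1)  # (half, 2w, p)
    m = seq.shape[1]
    means = seq.mean(axis=0)
    W = seq.var(axis=0, ddof=1).mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    return np.sqrt(var_plus / np.maximum(W, 1e-300))


# ---------------------------------------------------------------------------
# Anchors

@dataclass(frozen=True)
class AnchorLevels:
    """Data-driven canonical levels for one biomarker: the median among
    asymptomatic carriers (normal) and among symptomatic carriers at their
    first symptomatic visit (abnormal, defining t = 0)."""

    canonical_normal: float
    canonical_abnormal: float
    direction: int

    def __post_init__(self):
        if self.direction * (self.canonical_abnormal - self.canonical_normal) <= 0:
            raise ValueError(
                "canonical_abnormal must lie on the pathological side of canonical_normal")


def compute_anchor_levels(panel: AdjustedPanel, biomarker: str,
                          direction: int | None = None) -> AnchorLevels:
    """Medians as defined above. Symptomatic = each carrier's first visit
    with global CDR > 0 (a carrier symptomatic from baseline contributes
    its baseline row); asymptomatic = carrier baseline rows with CDR 0."""
    tab = panel.table
    carriers = tab[tab["carrier"].astype(bool)].sort_values(
        ["subject_id", "visit_index"])
    asym = carriers[(carriers["visit_index"] == 0)
                    & (carriers["cdr_global"] == 0)][biomarker].dropna()
    sym_rows = carriers[carriers["cdr_global"] > 0]
    first_sym = sym_rows.groupby("subject_id", sort=True).head(1)[biomarker].dropna()
    if len(asym) == 0:
        raise ValueError(f"{biomarker}: no asymptomatic carrier values")
    if len(first_sym) == 0:
        raise ValueError(f"{biomarker}: no symptomatic carrier values")
    normal = float(asym.median())
    abnormal = float(first_sym.median())
    if direction is None:
        direction = (panel.directions or {}).get(biomarker)
    if direction is None:
        direction = int(np.sign(abnormal - normal)) or 1
    return AnchorLevels(canonical_normal=normal, canonical_abnormal=abnormal,
                        direction=direction)


# ---------------------------------------------------------------------------
# Trajectory integration

@dataclass
class TrajectoryPosterior:
    """Sampled monotone time-courses anchored at t = 0 at the canonical
    abnormal level, with the abnormality-transition-time distribution."""

    values: np.ndarray           # value grid for the time curves (G,)
    sample_times: np.ndarray     # (M_acc, G) t_s at each value; NaN outside range
    mean_times: np.ndarray       # (G,) times from the posterior-mean rate
    transition_times: np.ndarray  # (M_ok,) T_s > 0, years
    anchors: AnchorLevels
    n_rejected: int = 0          # wrong-sign samples
    n_truncated: int = 0         # |f| < eps inside the anchor span

    @property
    def transition_time_quartiles(self) -> tuple:
        q = np.percentile(self.transition_times, [25, 50, 75])
        return tuple(float(v) for v in q)

    def times_at_value(self, value: float) -> np.ndarray:
        """Per-sample times at a measured value (NaN where out of range)."""
        out = np.full(len(self.sample_times), np.nan)
        v = self.values
        for i, ts in enumerate(self.sample_times):
            okm = np.isfinite(ts)
            if okm.sum() < 2:
                continue
            vlo, vhi = v[okm].min(), v[okm].max()
            if vlo <= value <= vhi:
                out[i] = np.interp(value, v[okm], ts[okm])
        return out

    def mean_time_at_value(self, value: float) -> float:
        okm = np.isfinite(self.mean_times)
        v = self.values[okm]
        if not (v.min() <= value <= v.max()):
            return np.nan
        return float(np.interp(value, v, self.mean_times[okm]))

    def value_at_time(self, t, sample: int | None = None) -> np.ndarray:
        """Invert a monotone time curve back to biomarker values."""
        ts = self.mean_times if sample is None else self.sample_times[sample]
        okm = np.isfinite(ts)
        order = np.argsort(ts[okm])
        return np.interp(t, ts[okm][order], self.values[okm][order])


def _integrate_one(f_grid: np.ndarray, values: np.ndarray,
                   anchors: AnchorLevels, eps: float):
    """Times t(x) = int_{abnormal}^{x} du / f(u) along ``values``.

    Returns (times, truncated) or None if f has the wrong sign anywhere
    strictly between the anchors. Integration stops where |f| < eps.
    """
    d = anchors.direction
    a_lo = min(anchors.canonical_normal, anchors.canonical_abnormal)
    a_hi = max(anchors.canonical_normal, anchors.canonical_abnormal)
    inside = (values > a_lo) & (values < a_hi)
    if np.any(d * f_grid[inside] <= 0):
        return None
    i0 = int(np.argmin(np.abs(values - anchors.canonical_abnormal)))
    usable = d * f_grid > 0
    small = np.abs(f_grid) < eps
    valid = usable & ~small
    # maximal contiguous valid run containing the abnormal anchor
    if not valid[i0]:
        return None
    left = i0
    while left > 0 and valid[left - 1]:
        left -= 1
    right = i0
    while right < len(values) - 1 and valid[right + 1]:
        right += 1
    truncated = bool(small[left:right + 1].any() or
                     (left > 0 and small[left - 1]) or
                     (right < len(values) - 1 and small[right + 1]))
    times = np.full(len(values), np.nan)
    seg = slice(left, right + 1)
    inv = 1.0 / f_grid[seg]
    v = values[seg]
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (inv[1:] + inv[:-1]) * np.diff(v))])
    t0 = np.interp(anchors.canonical_abnormal, v, cum)
    times[seg] = cum - t0
    return times, truncated


def integrate_trajectory(post: RateFunctionPosterior, anchors: AnchorLevels,
                         eps_frac: float = 1e-4) -> TrajectoryPosterior:
    """Turn sampled rate functions into sampled time-courses.

    Per sample: t_s(x) = integral from the canonical abnormal level to x
    of du / f_s(u) (trapezoid on the value grid, anchors inserted as grid
    nodes); the transition time is T_s = |t_s(canonical normal)|.
    Samples whose rate has the wrong sign between the anchors are
    rejected; where |f_s| falls below eps = eps_frac * value-range per
    year the integration is truncated and the sample excluded from the
    transition-time density. More than 50% rejections raises, advising a
    review of the differential-data exclusion rules.
    """
    a = np.array([anchors.canonical_normal, anchors.canonical_abnormal])
    values = np.union1d(post.grid, a)
    lo = min(values.min(), a.min())
    hi = max(values.max(), a.max())
    if lo < post.grid.min() or hi > post.grid.max():
        extra = np.linspace(lo, hi, len(post.grid))
        values = np.union1d(values, extra)
    eps = eps_frac * float(np.ptp(values))

    def resample(f):
        return np.interp(values, post.grid, f)

    kept, trans = [], []
    n_rej = n_trunc = 0
    for f in post.samples:
        res = _integrate_one(resample(f), values, anchors, eps)
        if res is None:
            n_rej += 1
            continue
        times, truncated = res
        kept.append(times)
        if truncated:
            n_trunc += 1
            continue
        okm = np.isfinite(times)
        if values[okm].min() <= anchors.canonical_normal <= values[okm].max():
            t_norm = np.interp(anchors.canonical_normal, values[okm], times[okm])
            trans.append(abs(float(t_norm)))
    if n_rej > 0.5 * len(post.samples):
        raise RuntimeError(
            f"{n_rej}/{len(post.samples)} trajectory samples have the wrong "
            "sign between the anchors; review the differential-data "
            "exclusion rules (normal non-progressing points)")

    mres = _integrate_one(resample(post.mean), values, anchors, eps)
    mean_times = mres[0] if mres is not None else np.full(len(values), np.nan)

    return TrajectoryPosterior(values=values,
                               sample_times=np.array(kept),
                               mean_times=mean_times,
                               transition_times=np.array(trans),
                               anchors=anchors,
                               n_rejected=n_rej, n_truncated=n_trunc)


def cumulative_abnormality_curve(traj: TrajectoryPosterior,
                                 n_grid: int = 400) -> tuple:
    """Empirical cumulative probability of abnormality.

    C(t) = fraction of samples already abnormal by time t <= 0, i.e. the
    empirical CDF of -T_s. Returns (t_grid, C, t50) where t50 is the time
    at which C first reaches one half — the summary used to order
    biomarkers on a shared pre-abnormality time axis.
    """
    T = np.sort(traj.transition_times)
    if len(T) < 50:
        raise ValueError(f"need >= 50 accepted samples, got {len(T)}")
    neg = -T[::-1]                      # sorted ascending, all <= 0
    t_grid = np.linspace(neg[0] - 1e-9, 0.0, n_grid)
    C = np.searchsorted(neg, t_grid, side="right") / len(neg)
    k = int(np.ceil(0.5 * len(neg))) - 1
    t50 = float(neg[k])
    return t_grid, C, t50


# ---------------------------------------------------------------------------
# Cross-validation

def crossvalidate_fit(x, dxdt, k_folds: int = 10, method: str = "laplace",
                      n_hyper: int = 30, rng=None) -> dict:
    """K-fold cross-validation of the rate-function fit: held-out log
    predictive density and empirical coverage of the central 50%
    predictive interval. Folds with fewer than 2 points are merged into a
    neighbour."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2 (fitting and evaluating on "
                         "the same single fold is not a validation)")
    rng = np.random.default_rng(rng)
    x = np.asarray(x, float)
    y = np.asarray(dxdt, float)
    n = len(x)
    k_folds = min(k_folds, n)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    if k_folds == n:
        merged = folds                      # leave-one-out: keep singletons
    else:
        merged = []
        for f in folds:
            if len(f) < 2 and merged:
                log.warning("fold with < 2 points merged into neighbour")
                merged[-1] = np.concatenate([merged[-1], f])
            else:
                merged.append(f)
    covered = []
    lpds = []
    for f in merged:
        train = np.setdiff1d(perm, f)
        post = fit_rate_function(x[train], y[train], n_samples=n_hyper,
                                 grid_size=50, method=method, rng=rng)
        mu, sd = post.predict(x[f])
        z = 0.6744897501960817   # central 50% of a normal
        covered.append((y[f] >= mu - z * sd) & (y[f] <= mu + z * sd))
        lpds.append(post.log_predictive_density(x[f], y[f]))
    covered = np.concatenate(covered)
    lpds = np.concatenate(lpds)
    return {
        "coverage_50": float(np.mean(covered)),
        "mean_log_predictive_density": float(np.mean(lpds)),
        "n_folds": len(merged),
        "n_points": n,
    }
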