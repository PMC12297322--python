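"""Bayesian uncertainty quantification for the lineage models.

Measurements at each age are treated as Gaussian and independent across
ages (different mice).  Because replication per age is sparse, the
measurement SD is interpolated over age by an exponential decay

    sigma(t) = d0 + d1 * exp(-d3 * (t - t_ref)),

fitted per observable to the per-age sample SDs.  The same model supplies
the spread of the initial-condition distribution at the first age.  The
posterior over model parameters (flat priors on boxes) is explored with
the Adaptive Metropolis sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .data import Dataset
from .observables import initial_state_from_observables, predict_observables
from .params import ModelParameters
from .scenarios import ScenarioSpec

__all__ = [
    "VarianceModel",
    "MCMCChain",
    "fit_variance_decay",
    "sample_initial_conditions",
    "neg_log_likelihood",
    "adaptive_metropolis",
    "posterior_predictive",
    "effective_sample_size",
    "rhat",
]

LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class VarianceModel:
    """Exponentially decaying measurement SD over age."""

    d0: float
    d1: float
    d3: float
    t_ref: float = 0.0
    observable: Optional[str] = None

    def __post_init__(self) -> None:
        if self.d3 < 0:
            raise ValueError("decay rate d3 must be nonnegative")

    def sigma(self, t) -> np.ndarray:
        return self.d0 + self.d1 * np.exp(-self.d3 * (np.asarray(t, float) - self.t_ref))


def fit_variance_decay(
    dataset: Dataset, observable: str, setting: str = "WT"
) -> VarianceModel:
    """Least-squares fit of sigma(t) to the per-age sample SDs.

    Ages with fewer than two mice carry no SD information; with fewer than
    three informative ages the fit degenerates to the pooled SD
    (``d1 = d3 = 0``) with a warning.
    """
    stats = dataset.subset(settings=[setting], observables=[observable]).group_stats()
    stats = stats[stats["n_mice"] >= 2]
    t_ref = float(dataset.subset(settings=[setting]).ages.min())
    if len(stats) < 3:
        df = dataset.subset(settings=[setting], observables=[observable]).records
        pooled = float(df["value"].std(ddof=1)) if len(df) > 1 else float(df["value"].abs().mean())
        warnings.warn(
            f"fewer than 3 replicated ages for {observable!r}; "
            "falling back to pooled SD",
            stacklevel=2,
        )
        return VarianceModel(d0=max(pooled, 1e-12), d1=0.0, d3=0.0,
                             t_ref=t_ref, observable=observable)
    t = stats["age_days"].to_numpy(float) - t_ref
    sd = stats["sd"].to_numpy(float)
    span = max(t.max() - t.min(), 1.0)

    def resid(p):
        d0, d1, d3 = p
        return d0 + d1 * np.exp(-d3 * t) - sd

    # the asymptotic SD is floored at half the smallest observed spread:
    # letting d0 collapse to zero extrapolates vanishing measurement error
    # beyond the data and produces unbounded weights downstream
    d0_floor = max(0.5 * float(sd.min()), 1e-12)
    x0 = np.array([max(sd.min(), d0_floor), max(sd[0] - sd.min(), 1e-9), 1.0 / span])
    fit = least_squares(resid, x0,
                        bounds=([d0_floor, 0.0, 0.0], [np.inf, np.inf, 1.0]))
    d0, d1, d3 = fit.x
    return VarianceModel(d0=d0, d1=d1, d3=d3, t_ref=t_ref, observable=observable)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_attempts: int = 100) -> float:
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_attempts):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError(
        f"failed to draw a value in [{lo:g}, {hi:g}] from N({mean:g}, {sd:g}) "
        f"after {max_attempts} attempts"
    )


def sample_initial_conditions(
    obs_means: Dict[str, float],
    obs_sds: Dict[str, float],
    params: ModelParameters,
    seed=None,
) -> np.ndarray:
    """Random initial state consistent with Gaussian first-age observables.

    The four observables (NSC total, active fraction, TAP total, NB total)
    are drawn from truncated Gaussians (totals on [0, inf), the fraction
    on [0, 1]) and the compartments adjusted to reproduce the draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = _truncated_normal(rng, obs_means["nsc_total"], obs_sds.get("nsc_total", 0.0),
                          0.0, np.inf)
    f = _truncated_normal(rng, obs_means["frac_active"], obs_sds.get("frac_active", 0.0),
                          0.0, 1.0)
    tap = _truncated_normal(rng, obs_means["tap_total"], obs_sds.get("tap_total", 0.0),
                            0.0, np.inf)
    nb = _truncated_normal(rng, obs_means["nb_total"], obs_sds.get("nb_total", 0.0),
                           0.0, np.inf)
    return initial_state_from_observables(S, f, tap, nb, params.n)


def _summarize(dataset: Dataset, setting: str, variance_models: Dict[str, VarianceModel]):
    """Per (age, observable) data means and interpolated SDs."""
    stats = dataset.subset(settings=[setting]).group_stats()
    ages = stats["age_days"].to_numpy(float)
    obs = stats["observable"].to_numpy()
    mu = stats["mean"].to_numpy(float)
    sigma = np.array([variance_models[o].sigma(a) for o, a in zip(obs, ages)], float)
    if np.any(sigma <= 0):
        raise ValueError("variance model yields nonpositive sigma at a data age")
    return ages, obs, mu, sigma


def neg_log_likelihood(
    params: ModelParameters,
    scenario: ScenarioSpec,
    dataset: Dataset,
    variance_models: Dict[str, VarianceModel],
    n_ic_reps: int = 10,
    seed=None,
    setting: str = "WT",
    rtol: float = 1e-6,
    atol: float = 1e-8,
    full_output: bool = False,
):
    """Gaussian negative log-likelihood with randomized initial conditions.

    f(theta) = sum_i (y_i^model - mu_i)^2 / (2 sigma_i^2)
             + sum_i log(sigma_i sqrt(2 pi)),

    where mu_i, sigma_i are the per-(age, observable) data means and
    interpolated SDs.  The initial state is drawn ``n_ic_reps`` times from
    the first-age observable distributions and the resulting f values are
    averaged; with ``full_output`` the replicate SD is returned as well.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ages, obs, mu, sigma = _summarize(dataset, setting, variance_models)
    uniq_ages = np.unique(ages)
    t0 = float(uniq_ages.min())
    means0 = dataset.first_age_means(setting)
    sds0 = {o: float(vm.sigma(t0)) for o, vm in variance_models.items()}
    const = float(np.sum(np.log(sigma) + LOG_SQRT_2PI))

    fvals = []
    for _ in range(max(n_ic_reps, 1)):
        init = sample_initial_conditions(means0, sds0, params, rng)
        pred = predict_observables(params, scenario, init, uniq_ages,
                                   rtol=rtol, atol=atol)
        age_idx = np.searchsorted(uniq_ages, ages)
        ymod = np.array([pred[o][j] for o, j in zip(obs, age_idx)])
        fvals.append(const + float(np.sum((ymod - mu) ** 2 / (2.0 * sigma**2))))
    fvals = np.asarray(fvals)
    f_mean = float(fvals.mean())
    if full_output:
        return f_mean, float(fvals.std(ddof=1)) if len(fvals) > 1 else 0.0
    return f_mean


@dataclass
class MCMCChain:
    """Adaptive Metropolis output with adaptation metadata."""

    samples: np.ndarray  # (iterations, dim)
    log_posterior: np.ndarray
    acceptance_rate: float
    config: Dict = field(default_factory=dict)
    bounds: Optional[np.ndarray] = None  # (dim, 2)
    param_names: Optional[List[str]] = None
    burn_in_fraction: float = 0.2

    def posterior(self, burn: Optional[int] = None) -> np.ndarray:
        if burn is None:
            burn = int(self.burn_in_fraction * len(self.samples))
        return self.samples[burn:]


def adaptive_metropolis(
    target: Callable[[np.ndarray], float],
    init: np.ndarray,
    n_samples: int,
    bounds: Sequence[Tuple[float, float]],
    config: Optional[Dict] = None,
    seed=None,
) -> MCMCChain:
    """Adaptive Metropolis sampler (Haario-style covariance adaptation).

    After ``adaptation_start`` iterations the Gaussian proposal covariance
    is ``s_d * (cov(history) + eps * I)`` with ``s_d = 2.4^2 / dim``.
    Proposals outside the bounds are rejected (the bounds double as flat
    priors).  Fully reproducible under ``seed``.
    """
    cfg = {
        "adaptation_start": 1000,
        "eps": 1e-10,
        "initial_cov": None,
        "burn_in_fraction": 0.2,
        "seed": seed,
    }
    if config:
        cfg.update(config)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(init, dtype=float).copy()
    dim = x.size
    lo = np.array([b[0] for b in bounds], float)
    hi = np.array([b[1] for b in bounds], float)
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError("initial point must lie inside the bounds")
    lp = float(target(x))
    if not np.isfinite(lp):
        raise ValueError("target log-density not finite at the initial point")

    s_d = 2.4**2 / dim
    eps = cfg["eps"]
    t_adapt = int(cfg["adaptation_start"])
    C0 = cfg["initial_cov"]
    if C0 is None:
        C0 = 1e-4 * np.diag(np.maximum(x, 1e-3) ** 2)
    C0 = np.atleast_2d(np.asarray(C0, float))
    L = np.linalg.cholesky(C0 + eps * np.eye(dim))

    samples = np.empty((n_samples, dim))
    logps = np.empty(n_samples)
    # running moments (Welford) for the adaptive covariance
    mean = np.zeros(dim)
    M2 = np.zeros((dim, dim))
    count = 0
    n_acc = 0
    for i in range(n_samples):
        prop = x + L @ rng.standard_normal(dim)
        if np.all(prop >= lo) and np.all(prop <= hi):
            lp_prop = float(target(prop))
            if np.isfinite(lp_prop) and np.log(rng.uniform()) < lp_prop - lp:
                x, lp = prop, lp_prop
                n_acc += 1
        samples[i] = x
        logps[i] = lp
        count += 1
        delta = x - mean
        mean += delta / count
        M2 += np.outer(delta, x - mean)
        if count >= max(t_adapt, 2):
            cov = M2 / (count - 1)
            L = np.linalg.cholesky(s_d * (cov + eps * np.eye(dim)))
        if i == 999 and n_acc == 0:
            raise RuntimeError(
                "no accepted moves in the first 1000 iterations; "
                "shrink the initial proposal covariance or rescale parameters"
            )
    return MCMCChain(
        samples=samples,
        log_posterior=logps,
        acceptance_rate=n_acc / n_samples,
        config=cfg,
        bounds=np.column_stack([lo, hi]),
        burn_in_fraction=cfg["burn_in_fraction"],
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a 1-d chain from the initial-positive-sequence autocorrelation."""
    x = np.asarray(x, float)
    n = x.size
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (n * var)
    tau = 1.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        tau += 2.0 * acf[k]
    return n / tau


def rhat(chains: Sequence[np.ndarray]) -> float:
    """Split-free Gelman-Rubin statistic across multiple 1-d chains."""
    arr = np.asarray(chains, float)
    m, n = arr.shape
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def posterior_predictive(
    chain: MCMCChain,
    scenario: ScenarioSpec,
    dataset: Dataset,
    n_draws: int,
    seed=None,
    *,
    make_params: Callable[[np.ndarray], ModelParameters],
    variance_models: Dict[str, VarianceModel],
    setting: str = "WT",
    t_grid: Optional[np.ndarray] = None,
    quantiles: Sequence[float] = (0.025, 0.5, 0.975),
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Trajectory ensemble from posterior draws with randomized initial states.

    ``make_params`` maps a chain row to a full :class:`ModelParameters`
    (free parameters inserted among the fixed ones).  Returns per-observable
    quantile bands on ``t_grid`` (default: the observation-age span).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    post = chain.posterior()
    if n_draws > len(post):
        raise ValueError(f"n_draws={n_draws} exceeds post-burn-in chain length {len(post)}")
    rows = post[rng.choice(len(post), size=n_draws, replace=False)]
    ages = dataset.subset(settings=[setting]).ages
    if t_grid is None:
        t_grid = np.linspace(ages.min(), ages.max(), 80)
    t_grid = np.asarray(t_grid, float)
    means0 = dataset.first_age_means(setting)
    t0 = float(ages.min())
    sds0 = {o: float(vm.sigma(t0)) for o, vm in variance_models.items()}

    obs_names = ("nsc_total", "frac_active", "tap_total", "nb_total")
    ens = {o: np.empty((n_draws, t_grid.size)) for o in obs_names}
    for i, row in enumerate(rows):
        p = make_params(row)
        init = sample_initial_conditions(means0, sds0, p, rng)
        pred = predict_observables(p, scenario, init, t_grid, rtol=rtol, atol=atol)
        for o in obs_names:
            ens[o][i] = pred[o]
    out: Dict[str, Dict[str, np.ndarray]] = {"t": {"grid": t_grid}}  # type: ignore[dict-item]
    for o in obs_names:
        out[o] = {f"q{q:g}": np.quantile(ens[o], q, axis=0) for q in quantiles}
        out[o]["mean"] = ens[o].mean(axis=0)
    return out
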