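"""Weighted-least-squares estimation of feedback-scenario parameters.

The cost is the weighted sum of squared data-model differences

    E = sum_j (1/sigma_j^2) sum_i (y_i^data - y_i^model)^2,

with one weight per (age, observable) group.  By default the group SDs
are interpolated over age with the exponential variance-decay model
fitted to the per-age sample SDs (a few mice per age leave the raw
sample variance far too unstable to weight by directly); the raw
per-group sample variance is available as the "sample" weighting mode.
Minimization is bound-constrained local least squares
restarted from many log-uniform start points; the smallest-cost start
wins.  Parameter uncertainty comes from the generalized inverse of the
weighted-residual Jacobian at the optimum.

Which parameters are free depends on the experiment: the wild-type fit
estimates (r0, K, b0, beta); the receptor-knock-out fit adds r1 and pT;
the chemotherapy fits estimate the post-treatment (pT, d, rho), plus r0
for old mice, on top of fixed wild-type values.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from . import __version__ as _pkg_version
from .data import Dataset
from .observables import build_initial_state, predict_observables
from .params import ModelParameters, TmzProtocol
from .scenarios import ScenarioSpec, get_scenario

__all__ = [
    "FREE_PARAMETERS",
    "DEFAULT_BOUNDS",
    "TmzContext",
    "WlsProblem",
    "FitResult",
    "wls_cost",
    "fit_multistart",
    "linearized_covariance",
    "covariance_from_residuals",
]

# free/fixed split per experiment type
FREE_PARAMETERS: Dict[str, Tuple[str, ...]] = {
    "WT": ("r0", "K", "b0", "beta"),
    "KO": ("r0", "r1", "K", "b0", "beta", "pT"),
    "TMZ_young": ("pT", "d", "rho"),
    "TMZ_old": ("r0", "pT", "d", "rho"),
}

DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "r0": (1e-4, 10.0),
    "r1": (0.0, 1e4),
    "K": (1.0, 1e5),
    "b0": (1e-6, 1.0),
    "beta": (1e-6, 1.0),
    "pT": (0.05, 2.0),
    "d": (0.0, 10.0),
    "rho": (1.0, 1e3),
}

# strictly positive floors for log-uniform start sampling of parameters
# whose lower bound is zero
_SAMPLING_FLOOR = {"r1": 1e-2, "d": 1e-3}

_PROTOCOL_PARAMS = ("d", "rho")  # routed to the treatment protocol, not the ODE

_SETTING_RECORDS = {
    "WT": (("WT",), ("nsc_total", "frac_active", "tap_total", "nb_total")),
    "KO": (("KO",), ("nsc_total", "frac_active", "tap_total", "nb_total")),
    "TMZ_young": (("TMZ_young", "saline_young"), ("brdu_section",)),
    "TMZ_old": (("TMZ_old", "saline_old"), ("brdu_section",)),
}


@dataclass(frozen=True)
class TmzContext:
    """Fixed context of a chemotherapy fit.

    ``base_params`` are the (wild-type) pre-treatment parameters;
    ``init_state`` and ``t0`` anchor the pre-treatment simulation;
    ``treatment_age`` and ``window`` define the killing regime.
    """

    treatment_age: float
    window: float
    base_params: ModelParameters
    init_state: np.ndarray
    t0: float


class EstimationError(RuntimeError):
    pass


class WlsProblem:
    """Weighted residual vector for one (dataset, scenario, setting) triple."""

    def __init__(
        self,
        dataset: Dataset,
        scenario: ScenarioSpec,
        setting: str,
        *,
        base_params: Optional[ModelParameters] = None,
        free_names: Optional[Sequence[str]] = None,
        bounds: Optional[Dict[str, Tuple[float, float]]] = None,
        tmz: Optional[TmzContext] = None,
        sigma_map: Optional[Dict[Tuple[str, float, str], float]] = None,
        weighting: str = "smoothed",
        rtol: float = 1e-6,
        atol: float = 1e-8,
    ):
        if setting not in FREE_PARAMETERS:
            raise ValueError(f"unknown setting {setting!r}; one of {sorted(FREE_PARAMETERS)}")
        self.setting = setting
        self.scenario = scenario
        self.is_tmz = setting.startswith("TMZ")
        if self.is_tmz and tmz is None:
            raise ValueError("chemotherapy fits require a TmzContext")
        self.tmz = tmz
        self.rtol, self.atol = rtol, atol

        settings_used, observables_used = _SETTING_RECORDS[setting]
        self.data = dataset.subset(settings=settings_used, observables=observables_used)
        df = self.data.records
        self.ages = df["age_days"].to_numpy(float)
        self.obs = df["observable"].to_numpy()
        self.values = df["value"].to_numpy(float)
        self.n = len(df)

        self.free_names = list(free_names if free_names is not None
                               else FREE_PARAMETERS[setting])
        b = dict(DEFAULT_BOUNDS)
        if bounds:
            b.update(bounds)
        self.bounds = [(b[name][0], b[name][1]) for name in self.free_names]

        if base_params is not None:
            self.base_params = base_params
        elif self.is_tmz:
            self.base_params = tmz.base_params
        else:
            # neutral placeholders for the free slots; fixed rates at defaults
            self.base_params = ModelParameters(r0=0.01, K=100.0, b0=0.7, beta=1e-3)

        if weighting not in ("smoothed", "sample"):
            raise ValueError("weighting must be 'smoothed' or 'sample'")
        self.weighting = weighting
        self._sigma = self._group_sigmas(dataset, sigma_map)
        if self.is_tmz:
            self.init_state = tmz.init_state
            self.t0 = tmz.t0
        else:
            self.init_state = build_initial_state(self.data, self.base_params, setting)
            self.t0 = float(self.ages.min())

    # -- weights ----------------------------------------------------------
    def _group_sigmas(self, full_dataset: Dataset, sigma_map) -> np.ndarray:
        """Per-record SDs for the weighted residuals.

        The default ("smoothed") weighting interpolates the per-age sample
        SDs of each observable with the exponential variance-decay model
        and weights every record by the interpolated SD at its age.  With
        the handful of mice measured per age, the raw sample variance has
        only a few degrees of freedom and its reciprocal is wildly
        unstable; the decay model pools information across ages.  The
        "sample" mode uses the raw per-(age, observable) sample SD, with
        the decay model only as fallback for single-mouse groups.
        """
        df = self.data.records
        stats = self.data.group_stats().set_index(["setting", "age_days", "observable"])
        variance_models: Dict[str, object] = {}

        def decay_model(observable: str, setting: str):
            key = (setting, observable)
            if key not in variance_models:
                from .bayes import fit_variance_decay  # local: avoids import cycle

                variance_models[key] = fit_variance_decay(
                    self.data, observable, setting=setting
                )
            return variance_models[key]

        sig = np.empty(self.n)
        for i, row in enumerate(df.itertuples(index=False)):
            key = (row.setting, row.age_days, row.observable)
            if sigma_map is not None and key in sigma_map:
                sig[i] = sigma_map[key]
                continue
            if self.weighting == "smoothed":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    sd = float(decay_model(row.observable, row.setting).sigma(row.age_days))
            else:
                g = stats.loc[key]
                sd = float(g["sd"]) if g["n_mice"] >= 2 else np.nan
                if not np.isfinite(sd) or sd <= 0:
                    warnings.warn(
                        f"group {key} has no replicate variance; "
                        "using the variance-decay model",
                        stacklevel=3,
                    )
                    sd = float(decay_model(row.observable, row.setting).sigma(row.age_days))
            floor = 1e-6 * max(1.0, abs(row.value))
            if not np.isfinite(sd) or sd < floor:
                # degenerate spread (e.g. replicate-free synthetic data):
                # fall back to unit weights rather than exploding them
                sd = 1.0
            sig[i] = sd
        return sig

    # -- parameter plumbing ------------------------------------------------
    def split_theta(self, theta: np.ndarray) -> Tuple[ModelParameters, Optional[TmzProtocol]]:
        free = dict(zip(self.free_names, np.asarray(theta, float)))
        model_updates = {k: v for k, v in free.items() if k not in _PROTOCOL_PARAMS}
        params = self.base_params.with_updates(**model_updates)
        if not self.is_tmz:
            return params, None
        protocol = TmzProtocol(
            treatment_age=self.tmz.treatment_age,
            window=self.tmz.window,
            d=free.get("d", 0.0),
            rho=free.get("rho", 1.0),
            post_params=params,
        )
        return self.tmz.base_params, protocol

    # -- residuals and cost -------------------------------------------------
    def residuals(self, theta: np.ndarray) -> np.ndarray:
        params, protocol = self.split_theta(theta)
        uniq = np.unique(self.ages)
        pred = predict_observables(
            params, self.scenario, self.init_state, uniq,
            protocol=protocol, t0=self.t0, rtol=self.rtol, atol=self.atol,
        )
        idx = np.searchsorted(uniq, self.ages)
        ymod = np.array([pred[o][j] for o, j in zip(self.obs, idx)])
        return (self.values - ymod) / self._sigma

    def cost(self, theta: np.ndarray) -> float:
        return float(np.sum(self.residuals(theta) ** 2))

    def cost_for_params(self, params: ModelParameters,
                        protocol: Optional[TmzProtocol] = None) -> float:
        uniq = np.unique(self.ages)
        pred = predict_observables(
            params, self.scenario, self.init_state, uniq,
            protocol=protocol, t0=self.t0, rtol=self.rtol, atol=self.atol,
        )
        idx = np.searchsorted(uniq, self.ages)
        ymod = np.array([pred[o][j] for o, j in zip(self.obs, idx)])
        return float(np.sum(((self.values - ymod) / self._sigma) ** 2))

    def sample_starts(self, n_starts: int, rng: np.random.Generator) -> np.ndarray:
        """Log-uniform start points within (floored) bounds."""
        starts = np.empty((n_starts, len(self.free_names)))
        for j, name in enumerate(self.free_names):
            lo, hi = self.bounds[j]
            lo = max(lo, _SAMPLING_FLOOR.get(name, lo))
            lo = max(lo, 1e-12)
            starts[:, j] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_starts))
        return starts

    def heuristic_starts(self) -> np.ndarray:
        """Data-anchored start points exploiting the model structure.

        The late-age NSC level approximates the positive equilibrium (if
        any), which pins ``beta = (2*b0 - 1)/c3`` for a grid of ``b0``
        values; the first-age active fraction pins the activation rate via
        the quasi-steady balance ``A ~ r*Q/pA``, giving ``r0`` for a grid
        of ``K``.  Depletion-type guesses (``b0 < 1/2``) anchor ``beta``
        to the early realized self-renewal implied by the initial decline.
        Only produced for whole-population fits (WT/KO); chemotherapy fits
        have a low-dimensional, well-behaved landscape.
        """
        if self.is_tmz or not {"b0", "beta"} <= set(self.free_names):
            return np.empty((0, len(self.free_names)))
        df = self.data.records
        by = df.pivot_table(index="age_days", columns="observable",
                            values="value", aggfunc="mean")
        ages = by.index.to_numpy(float)
        nsc = by["nsc_total"].to_numpy(float)
        frac = by["frac_active"].to_numpy(float)
        S_late = max(float(np.mean(nsc[-2:])), 1.0)
        S0 = max(float(nsc[0]), 1.0)
        f0 = float(np.clip(frac[0], 1e-3, 0.9))
        r_guess = self.base_params.pA * f0 / (1.0 - f0)
        # initial log-slope of the NSC pool -> early realized self-renewal
        dt = ages[1] - ages[0]
        slope0 = (np.log(max(nsc[1], 1.0)) - np.log(S0)) / dt
        b_early = float(np.clip(
            0.5 * (slope0 / (self.base_params.pA * f0) + 1.0), 0.05, 0.49))

        bmap = dict(zip(self.free_names, self.bounds))
        starts = []
        for b0 in (0.55, 0.65, 0.75, 0.85, 0.95, 0.25, 0.35, 0.45):
            if b0 > 0.5:
                beta = (2.0 * b0 - 1.0) / S_late  # plateau = equilibrium
            else:
                beta = (b0 / b_early - 1.0) / S0 if b0 > b_early else 1e-6
            for K in (30.0, 300.0, 3000.0):
                theta = {}
                c2_0 = f0 * S0 if "A" in self.scenario.c2 else S0  # rough scale
                theta["r0"] = r_guess * (K + c2_0) / S0
                theta["K"] = K
                theta["b0"] = b0
                theta["beta"] = beta
                theta["r1"] = r_guess * (K + c2_0) * 0.1
                theta["pT"] = self.base_params.pT
                vec = []
                ok = True
                for name in self.free_names:
                    v = theta.get(name)
                    if v is None:
                        ok = False
                        break
                    lo, hi = bmap[name]
                    vec.append(float(np.clip(v, lo + 1e-12, hi)))
                if ok:
                    starts.append(vec)
        return np.asarray(starts) if starts else np.empty((0, len(self.free_names)))


@dataclass
class FitResult:
    """Outcome of a multistart weighted-least-squares fit."""

    scenario: str
    setting: str
    free_names: List[str]
    theta: Dict[str, float]
    fixed: Dict[str, float]
    cost: float
    n: int
    k: int
    n_starts: int
    winning_start: int
    seed: Optional[int] = None
    bounds: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    starts_summary: List[Dict] = field(default_factory=list)
    covariance: Optional[np.ndarray] = None
    std: Optional[np.ndarray] = None
    correlations: Optional[np.ndarray] = None
    software_version: str = _pkg_version

    @property
    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[name] for name in self.free_names])

    def to_json(self, path=None) -> str:
        payload = {
            "scenario": self.scenario,
            "setting": self.setting,
            "free_names": self.free_names,
            "theta": self.theta,
            "fixed": self.fixed,
            "cost": self.cost,
            "n": self.n,
            "k": self.k,
            "n_starts": self.n_starts,
            "winning_start": self.winning_start,
            "seed": self.seed,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "starts_summary": self.starts_summary,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "std": None if self.std is None else self.std.tolist(),
            "correlations": None if self.correlations is None else self.correlations.tolist(),
            "software_version": self.software_version,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and Path(str(source)).exists() else str(source)
        d = json.loads(text)
        for key in ("covariance", "std", "correlations"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key])
        d["bounds"] = {k: tuple(v) for k, v in d.get("bounds", {}).items()}
        return cls(**d)


def wls_cost(
    dataset: Dataset,
    params: ModelParameters,
    scenario: ScenarioSpec,
    setting: str = "WT",
    *,
    protocol: Optional[TmzProtocol] = None,
    tmz: Optional[TmzContext] = None,
    sigma_map=None,
    weighting: str = "smoothed",
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> float:
    """Weighted-least-squares cost of a fully specified parameter set."""
    problem = WlsProblem(dataset, scenario, setting, base_params=params,
                         free_names=[], tmz=tmz, sigma_map=sigma_map,
                         weighting=weighting, rtol=rtol, atol=atol)
    return problem.cost_for_params(params, protocol=protocol)


def fit_multistart(
    dataset: Dataset,
    scenario,
    setting: str = "WT",
    n_starts: int = 500,
    seed: int = 0,
    *,
    base_params: Optional[ModelParameters] = None,
    bounds: Optional[Dict[str, Tuple[float, float]]] = None,
    tmz: Optional[TmzContext] = None,
    weighting: str = "smoothed",
    rtol: float = 1e-6,
    atol: float = 1e-8,
    max_nfev: Optional[int] = None,
    n_refine: int = 12,
) -> FitResult:
    """Multistart bound-constrained WLS fit; the smallest-cost start wins.

    Start points are drawn log-uniformly within the bounds.  Every start
    gets a cost evaluation; the ``n_refine`` most promising are refined by
    trust-region-reflective least squares, and the refined start with the
    minimal cost wins.  Ties in cost (to 1e-10) resolve to the lowest
    start index, so results are reproducible under a fixed seed.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    problem = WlsProblem(dataset, scenario, setting, base_params=base_params,
                         bounds=bounds, tmz=tmz, weighting=weighting,
                         rtol=rtol, atol=atol)
    rng = np.random.default_rng(seed)
    random_starts = problem.sample_starts(n_starts, rng)
    anchored = problem.heuristic_starts()
    starts = (np.vstack([random_starts, anchored]) if anchored.size
              else random_starts)
    total = len(starts)
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])

    # screening pass: one cost evaluation per start
    screen = np.full(total, np.inf)
    failures: List[str] = []
    for s in range(total):
        try:
            screen[s] = problem.cost(starts[s])
        except Exception as err:
            failures.append(f"start {s}: {err}")
    order = np.argsort(screen, kind="stable")
    refine_idx = [int(s) for s in order[: max(1, min(n_refine, total))]
                  if np.isfinite(screen[s])]
    # the best data-anchored start is always refined
    if anchored.size:
        best_anchor = int(n_starts + np.argmin(screen[n_starts:]))
        if best_anchor not in refine_idx and np.isfinite(screen[best_anchor]):
            refine_idx.append(best_anchor)

    best_idx, best_cost, best_x = -1, np.inf, None
    summary: List[Dict] = []
    for s in refine_idx:
        try:
            res = least_squares(
                problem.residuals, starts[s], bounds=(lo, hi), method="trf",
                x_scale="jac", diff_step=1e-4, ftol=1e-9, xtol=1e-10,
                gtol=1e-10, max_nfev=max_nfev,
            )
            cost = 2.0 * res.cost  # least_squares reports 0.5 * sum(res^2)
            summary.append({"start": s, "cost": cost, "success": bool(res.success)})
            better = cost < best_cost - 1e-10
            tie_lower_index = abs(cost - best_cost) <= 1e-10 and s < best_idx
            if better or tie_lower_index:
                best_idx, best_cost, best_x = s, cost, res.x
        except Exception as err:  # integration failures at pathological starts
            failures.append(f"start {s}: {err}")
            summary.append({"start": s, "cost": None, "success": False})
    if best_x is None:
        raise EstimationError(
            "all multistart optimizations failed:\n" + "\n".join(failures[:10])
        )

    free = dict(zip(problem.free_names, map(float, best_x)))
    fixed = {
        name: float(getattr(problem.base_params, name))
        for name in ("r0", "r1", "K", "b0", "beta", "pA", "pT", "delta", "NSC0")
        if name not in problem.free_names
    }
    return FitResult(
        scenario=scenario.name,
        setting=setting,
        free_names=problem.free_names,
        theta=free,
        fixed=fixed,
        cost=float(best_cost),
        n=problem.n,
        k=len(problem.free_names),
        n_starts=n_starts,
        winning_start=best_idx,
        seed=seed,
        bounds={n_: tuple(b) for n_, b in zip(problem.free_names, problem.bounds)},
        starts_summary=summary,
    )


def covariance_from_residuals(
    residual_fn, theta: np.ndarray, rel_step: float = 1e-6,
    param_names: Optional[Sequence[str]] = None,
):
    """Covariance of parameter estimates from the residual Jacobian.

    Central-difference Jacobian J of the weighted residual vector; the
    covariance is the Moore-Penrose generalized inverse of J^T J.  A
    rank-deficient Jacobian triggers a warning naming the null-space
    directions (the practically unidentifiable parameter combinations).
    """
    theta = np.asarray(theta, float)
    r0 = np.asarray(residual_fn(theta))
    J = np.empty((r0.size, theta.size))
    for j in range(theta.size):
        h = rel_step * max(abs(theta[j]), 1e-8)
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        J[:, j] = (np.asarray(residual_fn(tp)) - np.asarray(residual_fn(tm))) / (2 * h)
    JtJ = J.T @ J
    u, sv, vt = np.linalg.svd(JtJ)
    tol = sv.max() * max(JtJ.shape) * np.finfo(float).eps if sv.size else 0.0
    rank = int(np.sum(sv > tol))
    if rank < theta.size:
        names = list(param_names) if param_names else [f"p{j}" for j in range(theta.size)]
        null_dirs = []
        for row in vt[rank:]:
            lead = names[int(np.argmax(np.abs(row)))]
            null_dirs.append(lead)
        warnings.warn(
            f"residual Jacobian is rank-deficient (rank {rank}/{theta.size}); "
            f"null-space directions dominated by: {null_dirs}",
            stacklevel=2,
        )
    cov = np.linalg.pinv(JtJ)
    cov = 0.5 * (cov + cov.T)  # pinv leaves asymmetry at round-off level
    std = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    denom = np.outer(std, std)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return cov, std, corr


def linearized_covariance(
    fit: FitResult,
    dataset: Dataset,
    scenario=None,
    *,
    tmz: Optional[TmzContext] = None,
    weighting: str = "smoothed",
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fill a fit's covariance, SDs and correlation matrix in place."""
    if scenario is None:
        scenario = get_scenario(fit.scenario)
    elif isinstance(scenario, str):
        scenario = get_scenario(scenario)
    base = None
    if not fit.setting.startswith("TMZ"):
        base_fields = {k: v for k, v in fit.fixed.items() if k != "n"}
        base = ModelParameters(**{**base_fields, **fit.theta})
    problem = WlsProblem(dataset, scenario, fit.setting, base_params=base,
                         free_names=fit.free_names, tmz=tmz, weighting=weighting,
                         rtol=rtol, atol=atol)
    cov, std, corr = covariance_from_residuals(
        problem.residuals, fit.theta_vector, param_names=fit.free_names
    )
    fit.covariance, fit.std, fit.correlations = cov, std, corr
    return cov, std, corr
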