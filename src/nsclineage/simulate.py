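"""Numerical integration of the lineage systems.

All simulations run on an absolute age axis (days).  The default
integrator is LSODA with tight tolerances; the explicit-signal model is
stiff at large kinetic speed-ups and automatically switches between
stiff/non-stiff modes under LSODA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import odeint, solve_ivp

from .model import make_rhs, rhs_lineage, rhs_tmz
from .params import LineageState, ModelParameters, SignalParameters, TmzProtocol
from .scenarios import ScenarioSpec

__all__ = [
    "Trajectory",
    "TmzTrajectory",
    "IntegrationError",
    "simulate",
    "simulate_tmz",
    "simulate_full_signal",
]

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """ODE solver failure, with solver diagnostics in the message."""


@dataclass
class Trajectory:
    """Solution of the lineage system on a time grid.

    ``y`` has shape ``(len(t), n + 4)`` with columns ``Q, A, T0..Tn, N``.
    """

    t: np.ndarray
    y: np.ndarray
    params: ModelParameters
    scenario: ScenarioSpec

    @property
    def Q(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def A(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def T(self) -> np.ndarray:
        return self.y[:, 2:-1]

    @property
    def N(self) -> np.ndarray:
        return self.y[:, -1]

    @property
    def nsc_total(self) -> np.ndarray:
        return self.Q + self.A

    @property
    def frac_active(self) -> np.ndarray:
        tot = self.nsc_total
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, self.A / np.where(tot > 0, tot, 1.0), 0.0)
        return frac

    @property
    def tap_total(self) -> np.ndarray:
        return self.T.sum(axis=1)

    @property
    def nb_total(self) -> np.ndarray:
        return self.N

    @property
    def brdu_total(self) -> np.ndarray:
        """Whole-region proliferating (BrdU+) cells: active NSCs plus TAPs."""
        return self.A + self.tap_total

    def observable(self, name: str) -> np.ndarray:
        try:
            return getattr(self, name)
        except AttributeError:
            raise KeyError(f"unknown observable {name!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        n = self.params.n
        cols = {"time_days": self.t, "Q": self.Q, "A": self.A}
        for i in range(n + 1):
            cols[f"T{i}"] = self.y[:, 2 + i]
        cols.update(
            N=self.N,
            nsc_total=self.nsc_total,
            frac_active=self.frac_active,
            tap_total=self.tap_total,
            nb_total=self.nb_total,
        )
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class TmzTrajectory(Trajectory):
    """Three-regime chemotherapy solution with section-scale BrdU series."""

    protocol: TmzProtocol = field(default=None)  # type: ignore[assignment]

    @property
    def brdu_section(self) -> np.ndarray:
        """BrdU+ counts rescaled to tissue-section level (divided by rho)."""
        return self.brdu_total / self.protocol.rho

    def to_dataframe(self) -> pd.DataFrame:
        df = super().to_dataframe()
        df["brdu_total"] = self.brdu_total
        df["brdu_section"] = self.brdu_section
        return df


def _init_array(init: Union[LineageState, np.ndarray], params: ModelParameters) -> np.ndarray:
    y0 = init.to_array() if isinstance(init, LineageState) else np.asarray(init, float)
    if y0.size != params.dim:
        raise ValueError(f"initial state length {y0.size} != n + 4 = {params.dim}")
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")
    return y0


class _OdeintSolution:
    __slots__ = ("t", "y")

    def __init__(self, t, y):
        self.t = t
        self.y = y


def _solve(fun, t_span, y0, t_eval, method, rtol, atol):
    t_eval = np.asarray(t_eval, dtype=float)
    if method == "LSODA" and t_eval[0] == t_span[0] and t_eval[-1] == t_span[1]:
        # odeint is the low-overhead route to the same LSODA core
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out, info = odeint(fun, y0, t_eval, tfirst=True, rtol=rtol,
                               atol=atol, full_output=True, mxstep=10_000)
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"ODE solver failed on [{t_span[0]:g}, {t_span[1]:g}]: "
                f"{info['message']} (nfev={int(info['nfe'][-1])})"
            )
        return _OdeintSolution(t=t_eval, y=out.T)
    sol = solve_ivp(
        fun, t_span, y0, method=method, t_eval=t_eval, rtol=rtol, atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE solver failed on [{t_span[0]:g}, {t_span[1]:g}]: {sol.message} "
            f"(nfev={sol.nfev}, status={sol.status})"
        )
    return sol


def _check_grid(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-d array")
    return t


def simulate(
    params: ModelParameters,
    scenario: ScenarioSpec,
    init: Union[LineageState, np.ndarray],
    t_grid,
    *,
    method: str = "LSODA",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the unperturbed lineage system over ``t_grid`` (days)."""
    t = _check_grid(t_grid)
    y0 = _init_array(init, params)
    fun = make_rhs(params, scenario)
    sol = _solve(fun, (t[0], t[-1]), y0, t, method, rtol, atol)
    return Trajectory(t=sol.t, y=np.clip(sol.y.T, 0.0, None), params=params, scenario=scenario)


def simulate_tmz(
    protocol: TmzProtocol,
    params: ModelParameters,
    scenario: ScenarioSpec,
    init: Union[LineageState, np.ndarray],
    t_grid,
    *,
    method: str = "LSODA",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> TmzTrajectory:
    """Piecewise integration across the chemotherapy treatment window.

    Three regimes: the unperturbed system with the pre-treatment ``params``
    until ``treatment_age``; the killing system with death rate ``d`` (and
    the protocol's ``post_params``, the cell properties set by treatment)
    during the window; the unperturbed system with ``post_params``
    afterwards.  The state is continuous at both switch times.
    """
    t = _check_grid(t_grid)
    ta = protocol.treatment_age
    tb = ta + protocol.window
    if not (t[0] <= ta <= t[-1]):
        raise ValueError(
            f"treatment_age {ta:g} outside simulation span [{t[0]:g}, {t[-1]:g}]"
        )
    post = protocol.post_params if protocol.post_params is not None else params
    y0 = _init_array(init, params)
    kw = dict(method=method, rtol=rtol, atol=atol)

    segments = [
        (t[0], ta, make_rhs(params, scenario)),
        (ta, min(tb, t[-1]), make_rhs(post, scenario, d=protocol.d)),
        (min(tb, t[-1]), t[-1], make_rhs(post, scenario)),
    ]
    grid = set(t.tolist())
    times: list = []
    states: list = []
    y = y0
    for t0, t1, fun in segments:
        if t1 <= t0:
            continue
        inner = t[(t > t0) & (t <= t1)]
        t_eval = np.unique(np.concatenate(([t0], inner, [t1])))
        sol = _solve(fun, (t0, t1), y, t_eval, **kw)
        y = sol.y[:, -1].copy()  # continuity: left limit seeds the next regime
        for ti, yi in zip(sol.t, sol.y.T):
            if ti in grid and (not times or ti > times[-1]):
                times.append(ti)
                states.append(yi)
    return TmzTrajectory(
        t=np.array(times), y=np.clip(np.array(states), 0.0, None),
        params=params, scenario=scenario, protocol=protocol,
    )


def quasi_steady_signals(
    sig: SignalParameters, y: np.ndarray, scenario: ScenarioSpec
) -> np.ndarray:
    """Signal levels at their quasi-steady values for a given cell state."""
    from .scenarios import resolve_selector

    c1 = resolve_selector(scenario.c1, y)
    c2 = resolve_selector(scenario.c2, y)
    c3 = resolve_selector(scenario.c3, y)
    Sr = (sig.R1 + sig.R0 * c1) / (1.0 + sig.betaR * c2)
    Sb = 1.0 / (1.0 + sig.betaB * c3)
    return np.array([Sr, Sb])


def simulate_full_signal(
    sig: SignalParameters,
    speed: float,
    params: ModelParameters,
    scenario: ScenarioSpec,
    init: Union[LineageState, np.ndarray],
    t_grid,
    *,
    signal_init: Optional[np.ndarray] = None,
    method: str = "LSODA",
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the coupled cell + explicit-signal system.

    ``speed`` multiplies all signal kinetic rates; as it grows the cell
    trajectory converges to the reduced Hill-feedback model obtained by
    the quasi-steady-state reduction.  ``params`` supplies the structural
    rates (pA, pT, delta, n); its feedback constants are ignored because
    the feedback is carried by the signals: ``r = rbar*S_r``,
    ``b = bbar*S_b``.  Signals default to their quasi-steady values at the
    initial cell state.  Stiff at large ``speed``; LSODA handles this, or
    pass ``method='BDF'`` and looser tolerances if step-size failures occur.
    """
    if speed < 1:
        raise ValueError("kinetic speed-up must be >= 1")
    t = _check_grid(t_grid)
    y0 = _init_array(init, params)
    s0 = (
        np.asarray(signal_init, float)
        if signal_init is not None
        else quasi_steady_signals(sig, y0, scenario)
    )
    z0 = np.concatenate([y0, s0])
    from .scenarios import resolve_selector

    pA, pT, delta = params.pA, params.pT, params.delta

    def fun(tt, z):
        y, Sr, Sb = z[:-2], z[-2], z[-1]
        c1 = resolve_selector(scenario.c1, y)
        c2 = resolve_selector(scenario.c2, y)
        c3 = resolve_selector(scenario.c3, y)
        r = max(sig.rbar * Sr, 0.0)
        b = min(max(sig.bbar * Sb, 0.0), 1.0)
        Q, A = y[0], y[1]
        T = y[2:-1]
        N = y[-1]
        dy = np.empty_like(z)
        dy[0] = -r * Q + 2.0 * b * pA * A
        dy[1] = r * Q - pA * A
        dy[2] = 2.0 * (1.0 - b) * pA * A - pT * T[0]
        dy[3:-3] = 2.0 * pT * T[:-1] - pT * T[1:]
        dy[-3] = 2.0 * pT * T[-1] - delta * N
        dy[-2] = speed * (sig.R1 + sig.R0 * c1 - Sr - sig.betaR * c2 * Sr)
        dy[-1] = speed * (1.0 - Sb - sig.betaB * c3 * Sb)
        return dy

    try:
        sol = _solve(fun, (t[0], t[-1]), z0, t, method, rtol, atol)
    except IntegrationError as err:
        raise IntegrationError(
            str(err) + "; the signal equations are stiff at large speed-ups -- "
            "try method='BDF' or looser tolerances"
        ) from err
    return Trajectory(
        t=sol.t, y=np.clip(sol.y.T[:, : params.dim], 0.0, None),
        params=params, scenario=scenario,
    )
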