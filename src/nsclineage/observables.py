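"""Mapping between model trajectories and experimental observables.

Shared by the fitting and Bayesian modules: building an initial state
consistent with first-age observations, and predicting the observables
(NSC total, fraction active, TAP total, NB total, section-scale BrdU)
at the observation ages.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .data import Dataset
from .params import ModelParameters, TmzProtocol
from .scenarios import ScenarioSpec
from .simulate import Trajectory, simulate, simulate_tmz

__all__ = ["build_initial_state", "initial_state_from_observables", "predict_observables"]

DEFAULT_FRAC_ACTIVE = 0.3  # fallback initial active fraction when no data


def initial_state_from_observables(
    nsc_total: float,
    frac_active: float,
    tap_total: float,
    nb_total: float,
    n: int,
) -> np.ndarray:
    """State vector reproducing the four observables exactly.

    The NSC pool is split as ``A = f*S``, ``Q = (1-f)*S``; the TAP total is
    split equally across the ``n + 1`` compartments (the data only
    constrain totals).
    """
    A = frac_active * nsc_total
    Q = nsc_total - A
    T = np.full(n + 1, tap_total / (n + 1))
    return np.concatenate(([Q, A], T, [nb_total]))


def balanced_initial_state(params: ModelParameters, f0: float = DEFAULT_FRAC_ACTIVE) -> np.ndarray:
    """Initial state with the downstream cascade at flux balance.

    ``A = f0*NSC0``, ``Q = (1-f0)*NSC0``; TAPs and NBs sit at the levels
    that balance the inflow from active NSCs (taking the realized
    self-renewal near its equilibrium value 1/2), which avoids large
    initial transients in the downstream compartments.
    """
    A = f0 * params.NSC0
    Q = params.NSC0 - A
    T0 = params.pA * A / params.pT
    T = T0 * 2.0 ** np.arange(params.n + 1)
    N = 2.0 * params.pT * T[-1] / params.delta
    return np.concatenate(([Q, A], T, [N]))


def build_initial_state(
    dataset: Optional[Dataset],
    params: ModelParameters,
    setting: str = "WT",
) -> np.ndarray:
    """Initial state anchored at the first observation age of a setting.

    The total NSC count is ``params.NSC0``; the active fraction, TAP total
    and NB total come from the first-age data means (with conservative
    fallbacks when an observable is absent).
    """
    means: Dict[str, float] = {}
    if dataset is not None:
        try:
            means = dataset.first_age_means(setting)
        except ValueError:
            means = {}
    f0 = means.get("frac_active", DEFAULT_FRAC_ACTIVE)
    tap0 = means.get("tap_total", params.NSC0)
    nb0 = means.get("nb_total", params.NSC0)
    return initial_state_from_observables(params.NSC0, f0, tap0, nb0, params.n)


def predict_observables(
    params: ModelParameters,
    scenario: ScenarioSpec,
    init: np.ndarray,
    ages: np.ndarray,
    *,
    protocol: Optional[TmzProtocol] = None,
    t0: Optional[float] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Dict[str, np.ndarray]:
    """Observable values at the given ages (absolute days).

    Simulation starts at ``t0`` (default: the first age).  With a
    ``protocol`` the chemotherapy regime switching is applied and the
    section-scale BrdU observable becomes available.
    """
    ages = np.asarray(ages, dtype=float)
    t_start = float(ages.min()) if t0 is None else float(t0)
    grid = np.unique(np.concatenate(([t_start], ages)))
    if grid.size < 2:
        grid = np.array([t_start, t_start + 1.0])
    if protocol is None:
        traj: Trajectory = simulate(params, scenario, init, grid, rtol=rtol, atol=atol)
    else:
        traj = simulate_tmz(protocol, params, scenario, init, grid, rtol=rtol, atol=atol)
    idx = np.searchsorted(traj.t, ages)
    out = {
        name: traj.observable(name)[idx]
        for name in ("nsc_total", "frac_active", "tap_total", "nb_total")
    }
    if protocol is not None:
        out["brdu_section"] = traj.brdu_total[idx] / protocol.rho
    return out
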