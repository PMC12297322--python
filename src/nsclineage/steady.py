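"""Equilibria and linear stability of the lineage system.

The total NSC pool obeys ``d(Q+A)/dt = (2b - 1)*pA*A``, so a positive
equilibrium requires the realized self-renewal fraction to equal exactly
one half, i.e. ``b0/(1 + beta*c3) = 1/2``.  For ``b0 <= 1/2`` that is
unattainable at any nonnegative state and the origin is the only
equilibrium; for ``b0 > 1/2`` a unique positive equilibrium appears, with
the inhibitor population pinned at ``c3 = (2*b0 - 1)/beta``.

The solver exploits this structure: the downstream cascade is linear in
``A`` at equilibrium (``T0 = pA*A/pT``, ``Ti = 2*T(i-1)``,
``N = 2^(n+1)*pA*A/delta``), ``Q`` follows from ``dA/dt = 0`` as the
positive root of a quadratic, and the remaining scalar condition on the
inhibitor population is solved by a bracketed root-find in ``A``.  The
assembled state is then polished against the full right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.optimize import brentq, fsolve

from .model import rhs_lineage
from .params import ModelParameters
from .scenarios import ScenarioSpec, resolve_selector

__all__ = ["SteadyStateResult", "steady_states", "stability", "numerical_jacobian"]

RESIDUAL_TOL = 1e-8
EIG_TOL = 1e-9


class EquilibriumError(RuntimeError):
    """Positive-equilibrium search failed; message carries the residual."""


@dataclass
class SteadyStateResult:
    """An equilibrium with its linearization spectrum."""

    state: np.ndarray
    kind: str  # "trivial" | "positive"
    eigenvalues: np.ndarray
    stable: bool
    residual: float


def numerical_jacobian(fun, y0: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Forward-difference Jacobian; steps stay in the nonnegative orthant."""
    y0 = np.asarray(y0, dtype=float)
    f0 = np.asarray(fun(y0))
    J = np.empty((f0.size, y0.size))
    for j in range(y0.size):
        h = rel_step * max(abs(y0[j]), 1.0)
        yp = y0.copy()
        yp[j] += h
        J[:, j] = (np.asarray(fun(yp)) - f0) / h
    return J


def _relative_residual(y: np.ndarray, params: ModelParameters, scenario: ScenarioSpec) -> float:
    r = rhs_lineage(0.0, y, params, scenario)
    scale = max(1.0, float(np.max(np.abs(y))))
    return float(np.max(np.abs(r))) / scale


def _downstream(A: float, params: ModelParameters) -> np.ndarray:
    """TAP cascade and NB at equilibrium with b = 1/2, given A."""
    T0 = params.pA * A / params.pT  # 2*(1-b)*pA*A = pT*T0 with b = 1/2
    T = T0 * 2.0 ** np.arange(params.n + 1)
    N = 2.0 * params.pT * T[-1] / params.delta
    return np.concatenate((T, [N]))


def _q_from_A(A: float, params: ModelParameters, scenario: ScenarioSpec) -> float:
    """Positive Q solving dA/dt = 0, i.e. (r1 + r0*c1)*Q = pA*A*(K + c2).

    Both selectors may contain Q itself (selector Q or Q+A); splitting
    ci = wQi*Q + resti(A) keeps the equation an explicit quadratic in Q:

        r0*wQ1*Q^2 + (r1 + r0*rest1 - pA*A*wQ2)*Q - pA*A*(K + rest2) = 0.
    """
    down = _downstream(A, params)
    probe = np.concatenate(([0.0, A], down))  # Q = 0: selectors give the Q-free part
    wQ1 = 1.0 if scenario.c1 in ("Q", "Q+A") else 0.0
    wQ2 = 1.0 if scenario.c2 in ("Q", "Q+A") else 0.0
    rest1 = resolve_selector(scenario.c1, probe)
    rest2 = resolve_selector(scenario.c2, probe)
    r1 = params.r1 if scenario.uses_r1 else 0.0
    pAA = params.pA * A
    a = params.r0 * wQ1
    b = r1 + params.r0 * rest1 - pAA * wQ2
    c = -pAA * (params.K + rest2)
    if a > 0.0:
        return (-b + np.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)
    if b <= 0.0:  # activation vanishes identically: no positive balance
        return np.inf
    return -c / b


def _assemble(A: float, params: ModelParameters, scenario: ScenarioSpec) -> np.ndarray:
    Q = _q_from_A(A, params, scenario)
    return np.concatenate(([Q, A], _downstream(A, params)))


def _positive_equilibrium(
    params: ModelParameters, scenario: ScenarioSpec
) -> Optional[np.ndarray]:
    """Scalar root-find on g(A) = beta*c3 - (2*b0 - 1); None if no root."""

    def g(A: float) -> float:
        y = _assemble(A, params, scenario)
        return params.beta * resolve_selector(scenario.c3, y) - (2.0 * params.b0 - 1.0)

    a_lo = 1e-12
    if g(a_lo) >= 0.0:  # inhibitor already too large at vanishing A: no positive root
        return None
    a_hi = 1.0
    for _ in range(200):
        if g(a_hi) > 0.0:
            break
        a_hi *= 2.0
    else:
        return None
    # root-find in log A: near the bifurcation the root is tiny and needs
    # relative, not absolute, precision
    u_star = brentq(lambda u: g(np.exp(u)), np.log(a_lo), np.log(a_hi),
                    xtol=1e-13, rtol=8.9e-16)
    A_star = float(np.exp(u_star))
    y = _assemble(A_star, params, scenario)
    # polish against the full system
    sol, info, ier, _msg = fsolve(
        lambda z: rhs_lineage(0.0, np.maximum(z, 0.0), params, scenario),
        y, full_output=True, xtol=1e-13,
    )
    if ier == 1 and np.all(sol > 0):
        y = np.maximum(sol, 0.0)
    res = _relative_residual(y, params, scenario)
    if res > RESIDUAL_TOL:
        raise EquilibriumError(
            f"positive-equilibrium search did not converge for scenario "
            f"{scenario.name!r}: relative residual {res:.3e}"
        )
    return y


def stability(
    params: ModelParameters,
    scenario: ScenarioSpec,
    equilibrium: np.ndarray,
) -> SteadyStateResult:
    """Classify an equilibrium by the spectrum of the numerical Jacobian.

    Stable iff every eigenvalue has real part below ``-EIG_TOL``.  The
    trivial equilibrium of the wild-type model is linearly degenerate (the
    activation term is quadratic near the origin, giving a zero
    eigenvalue); a marginal spectrum is resolved by probing the growth of
    the NSC pool under a small perturbation of ``A``, where
    ``d(Q+A)/dt = (2b - 1)*pA*A`` has the sign of ``2*b0 - 1``.
    """
    y = np.asarray(equilibrium, dtype=float)
    res = _relative_residual(y, params, scenario)
    J = numerical_jacobian(lambda z: rhs_lineage(0.0, np.maximum(z, 0.0), params, scenario), y)
    eig = np.linalg.eigvals(J)
    max_re = float(np.max(eig.real))
    if max_re < -EIG_TOL:
        stable = True
    elif max_re > EIG_TOL:
        stable = False
    else:
        # marginal linearization: nonlinear probe along A
        eps = 1e-6 * max(1.0, float(np.max(np.abs(y))))
        probe = y.copy()
        probe[1] += eps
        dy = rhs_lineage(0.0, probe, params, scenario)
        stable = (dy[0] + dy[1]) <= 0.0
    kind = "trivial" if np.all(y == 0) else "positive"
    return SteadyStateResult(state=y, kind=kind, eigenvalues=eig, stable=stable, residual=res)


def steady_states(
    params: ModelParameters, scenario: ScenarioSpec
) -> List[SteadyStateResult]:
    """All equilibria of the scenario: the origin, plus the positive one if present."""
    results = [stability(params, scenario, np.zeros(params.dim))]
    pos = _positive_equilibrium(params, scenario)
    if pos is not None:
        results.append(stability(params, scenario, pos))
    return results
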