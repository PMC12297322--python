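"""Parameter containers for the neural-lineage feedback models.

The lineage model tracks quiescent NSCs (``Q``), active NSCs (``A``), a
cascade of ``n + 1`` transient amplifying progenitor compartments
(``T0..Tn``) and neuroblasts (``N``), all as whole-region cell counts.
The state vector layout used throughout the package is

    ``[Q, A, T0, ..., Tn, N]``   (length ``n + 4``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "LineageState",
    "ModelParameters",
    "SignalParameters",
    "TmzProtocol",
]


@dataclass(frozen=True)
class ModelParameters:
    """Rate and feedback constants of the lineage model.

    Parameters
    ----------
    r0 : float
        Amplitude of the activation feedback (1/day).
    K : float
        Half-saturation constant of the activation Hill function (cells).
    b0 : float
        Maximal self-renewal fraction, in ``(0, 1]``.  The system has a
        positive steady state only for ``b0 > 1/2``.
    beta : float
        Strength of the self-renewal inhibition (1/cells).
    r1 : float, optional
        Basal activation production (cells/day) contributed by non-lineage
        sources; zero in the wild-type model and fitted in the
        receptor-knock-out setting.
    pA, pT : float
        Division rates of active NSCs and TAPs (1/day).
    delta : float
        Neuroblast exit rate (1/day).
    n : int
        Number of TAP amplification steps (``n + 1`` compartments).
    NSC0 : float
        Total NSC count ``Q + A`` at the start of a simulation (cells).
    """

    r0: float
    K: float
    b0: float
    beta: float
    r1: float = 0.0
    pA: float = 0.95
    pT: float = 0.81
    delta: float = 0.19
    n: int = 3
    NSC0: float = 1900.0

    def __post_init__(self) -> None:
        for name in ("r0", "K", "beta", "pA", "pT", "delta", "NSC0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.r1 < 0:
            raise ValueError("r1 must be nonnegative")
        if not 0.0 < self.b0 <= 1.0:
            raise ValueError("b0 must lie in (0, 1]")
        if self.n < 1:
            raise ValueError("need at least one amplification step (n >= 1)")

    @property
    def dim(self) -> int:
        """Length of the state vector: Q, A, the n + 1 TAPs, and N."""
        return self.n + 4

    def with_updates(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class LineageState:
    """Compartment counts at one time point."""

    Q: float
    A: float
    T: np.ndarray
    N: float

    def __post_init__(self) -> None:
        self.T = np.atleast_1d(np.asarray(self.T, dtype=float))
        if self.T.size < 2:
            raise ValueError("need at least two TAP compartments (n >= 1)")
        vec = self.to_array()
        if np.any(vec < 0):
            raise ValueError("all compartments must be nonnegative")

    @classmethod
    def from_array(cls, y: np.ndarray) -> "LineageState":
        y = np.asarray(y, dtype=float)
        if y.size < 5:
            raise ValueError("state vector must have length n + 4 with n >= 1")
        return cls(Q=y[0], A=y[1], T=y[2:-1].copy(), N=y[-1])

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.Q, self.A], self.T, [self.N]))

    # -- observables reported by the experiments ---------------------------
    @property
    def nsc_total(self) -> float:
        return self.Q + self.A

    @property
    def frac_active(self) -> float:
        tot = self.Q + self.A
        return self.A / tot if tot > 0 else 0.0

    @property
    def tap_total(self) -> float:
        return float(np.sum(self.T))

    @property
    def nb_total(self) -> float:
        return self.N


@dataclass(frozen=True)
class SignalParameters:
    """Kinetic constants of the explicit two-signal model.

    An activation signal ``S_r`` and a self-renewal signal ``S_b`` are
    produced, degraded and internalised by lineage populations:

        dS_r/dt = R1 + R0*c1 - S_r - betaR*c2*S_r
        dS_b/dt = 1 - S_b - betaB*c3*S_b

    with ``r = rbar*S_r`` and ``b = bbar*S_b``.  Under fast signal
    kinetics this reduces to the Hill feedback with ``r0 = rbar*R0/betaR``,
    ``r1 = rbar*R1/betaR``, ``K = 1/betaR``, ``b0 = bbar``, ``beta = betaB``.
    """

    R0: float
    R1: float
    betaR: float
    betaB: float
    rbar: float
    bbar: float

    def __post_init__(self) -> None:
        if self.betaR <= 0 or self.betaB <= 0:
            raise ValueError("internalization strengths betaR, betaB must be > 0")
        if self.R0 < 0 or self.R1 < 0 or self.rbar <= 0 or self.bbar <= 0:
            raise ValueError("signal production/conversion constants must be nonnegative")


@dataclass(frozen=True)
class TmzProtocol:
    """Chemotherapy (temozolomide) perturbation protocol.

    During ``[treatment_age, treatment_age + window]`` actively dividing
    compartments (``A`` and every ``Ti``) die at rate ``d``; afterwards the
    unperturbed model runs with ``post_params``.  ``rho`` converts
    whole-region proliferating-cell counts to tissue-section scale.
    """

    treatment_age: float
    window: float = 3.0
    d: float = 1.0
    rho: float = 50.0
    post_params: Optional[ModelParameters] = None

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("death rate d must be nonnegative")
        if self.rho <= 0:
            raise ValueError("section scaling factor rho must be positive")
        if self.window <= 0:
            raise ValueError("treatment window must be positive")
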