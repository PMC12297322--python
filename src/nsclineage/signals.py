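"""Quasi-steady-state mapping between signal kinetics and Hill feedback.

Fast signal kinetics reduce the explicit two-signal model to the Hill
feedback form via

    r0 = rbar*R0/betaR,  r1 = rbar*R1/betaR,  K = 1/betaR,
    b0 = bbar,           beta = betaB.

The reduction loses one degree of freedom (only the products ``rbar*R0``
and ``rbar*R1`` matter), so the expansion picks the gauge ``rbar = 1``
unless told otherwise.
"""

from __future__ import annotations

from typing import Tuple

from .params import SignalParameters

__all__ = ["qss_reduce", "qss_expand"]


def qss_reduce(sig: SignalParameters) -> Tuple[float, float, float, float, float]:
    """Map signal kinetics to reduced Hill constants ``(r0, r1, K, b0, beta)``."""
    if sig.betaR <= 0 or sig.betaB <= 0:
        raise ValueError("betaR and betaB must be strictly positive")
    r0 = sig.rbar * sig.R0 / sig.betaR
    r1 = sig.rbar * sig.R1 / sig.betaR
    K = 1.0 / sig.betaR
    return r0, r1, K, sig.bbar, sig.betaB


def qss_expand(
    r0: float, r1: float, K: float, b0: float, beta: float, rbar: float = 1.0
) -> SignalParameters:
    """Inverse of :func:`qss_reduce` for the representative gauge ``rbar``."""
    if K <= 0:
        raise ValueError("half-saturation K must be strictly positive")
    if rbar <= 0:
        raise ValueError("conversion gain rbar must be strictly positive")
    betaR = 1.0 / K
    return SignalParameters(
        R0=r0 * betaR / rbar,
        R1=r1 * betaR / rbar,
        betaR=betaR,
        betaB=beta,
        rbar=rbar,
        bbar=b0,
    )
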