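"""Feedback-scenario registry.

A scenario names the lineage subpopulations wired into the two feedback
functions

    r(c1, c2) = (r1 + r0*c1) / (K + c2),      b(c3) = b0 / (1 + beta*c3),

where each ``ci`` is one of the selectors ``Q``, ``A``, ``Q+A``, ``T0``,
``sumT`` or ``N``.  ``c1`` promotes activation, ``c2`` inhibits it, ``c3``
inhibits self-renewal.  The shorthand ``r(c)`` means ``r(c, c)``.

Wild-type scenarios keep ``r1 = 0``; the ``+r1`` variants (used for the
interferon-receptor knock-out setting and the Delta-Notch-Wnt hypothesis)
carry a basal activation term in the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "ScenarioSpec",
    "SELECTORS",
    "SCENARIOS",
    "CANONICAL_WT",
    "CANONICAL_KO",
    "get_scenario",
    "scenario_names",
    "resolve_selector",
]

SELECTORS = ("Q", "A", "Q+A", "T0", "sumT", "N")


class UnknownScenarioError(KeyError):
    """Raised when a scenario or selector name is not registered."""


def resolve_selector(name: str, y: np.ndarray) -> float:
    """Evaluate a population selector on a state vector ``[Q, A, T0..Tn, N]``."""
    if name == "Q":
        return y[0]
    if name == "A":
        return y[1]
    if name == "Q+A":
        return y[0] + y[1]
    if name == "T0":
        return y[2]
    if name == "sumT":
        return float(np.sum(y[2:-1]))
    if name == "N":
        return y[-1]
    raise UnknownScenarioError(
        f"unknown population selector {name!r}; valid selectors: {SELECTORS}"
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Wiring of the feedback functions: which populations fill c1, c2, c3."""

    name: str
    c1: str
    c2: str
    c3: str
    uses_r1: bool = False

    def __post_init__(self) -> None:
        for sel in (self.c1, self.c2, self.c3):
            if sel not in SELECTORS:
                raise UnknownScenarioError(
                    f"unknown population selector {sel!r}; valid selectors: {SELECTORS}"
                )

    def with_r1(self) -> "ScenarioSpec":
        """Knock-out extension: same wiring with the basal term enabled."""
        if self.uses_r1:
            return self
        return replace(self, name=self.name + "+r1", uses_r1=True)

    def populations(self, y: np.ndarray) -> Tuple[float, float, float]:
        return (
            resolve_selector(self.c1, y),
            resolve_selector(self.c2, y),
            resolve_selector(self.c3, y),
        )


def _build_registry() -> Dict[str, ScenarioSpec]:
    base = [
        # the five canonical wild-type scenarios
        ScenarioSpec("r(Q,A),b(A)", "Q", "A", "A"),
        ScenarioSpec("r(Q,A),b(Q)", "Q", "A", "Q"),
        ScenarioSpec("r(Q,A),b(N)", "Q", "A", "N"),
        ScenarioSpec("r(Q+A),b(Q+A)", "Q+A", "Q+A", "Q+A"),
        ScenarioSpec("r(Q,T0),b(N)", "Q", "T0", "N"),
    ]
    registry = {s.name: s for s in base}
    # knock-out extensions: identical wiring, basal activation enabled
    for s in base:
        ko = s.with_r1()
        registry[ko.name] = ko
    # Delta-Notch-Wnt scenario: qNSCs promote, all NSCs inhibit activation,
    # qNSCs inhibit self-renewal; carries the basal term (zero in WT fits).
    dnw = ScenarioSpec("r(Q,Q+A),b(Q)", "Q", "Q+A", "Q", uses_r1=True)
    registry[dnw.name] = dnw
    return registry


SCENARIOS: Dict[str, ScenarioSpec] = _build_registry()

CANONICAL_WT = (
    "r(Q,A),b(A)",
    "r(Q,A),b(Q)",
    "r(Q,A),b(N)",
    "r(Q+A),b(Q+A)",
    "r(Q,T0),b(N)",
)
CANONICAL_KO = tuple(name + "+r1" for name in CANONICAL_WT)


def get_scenario(name: str) -> ScenarioSpec:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {name!r}; registered scenarios: {sorted(SCENARIOS)}"
        ) from None


def scenario_names() -> Tuple[str, ...]:
    return tuple(sorted(SCENARIOS))
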