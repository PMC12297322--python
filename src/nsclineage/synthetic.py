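"""Synthetic per-mouse datasets with the statistical structure of the study.

Each setting is emulated by simulating the chosen feedback scenario and
drawing independent per-mouse observations around the trajectory, with a
truncated-Gaussian noise model whose SD decays over age as
``sigma(t) = d0 + d1*exp(-d3*(t - t0))``.  Defaults give a coefficient of
variation of about 25% at the first age decaying towards 10%, visually
matching the scatter of cross-sectional mouse counts; they are generator
choices, not measured values.  Ground truth (parameters, scenario, seed,
noise constants) is embedded in the dataset metadata so recovery can be
scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .bayes import VarianceModel, _truncated_normal
from .data import Dataset
from .observables import balanced_initial_state, initial_state_from_observables
from .params import ModelParameters, TmzProtocol
from .scenarios import get_scenario
from .simulate import simulate, simulate_tmz

__all__ = [
    "GeneratorConfig",
    "default_ages",
    "default_true_parameters",
    "default_variance_models",
    "generate_dataset",
    "generate_tmz_dataset",
]

# noise-scale constants: CV ~ (CV_FLOOR + CV_EXCESS) of the first-age level
# at the first age, decaying towards ~CV_FLOOR of the late-age level
CV_FLOOR = 0.04
CV_EXCESS = 0.08
CV_DECAY = 0.005  # 1/day, minimum decay rate of the excess SD

EXTINCTION_FLOOR = 1.0  # cells; below this the lineage is effectively extinct


def default_ages(n_ages: int = 10, start: float = 30.0, stop: float = 700.0) -> np.ndarray:
    """Log-spaced observation ages (days), the study's sampling pattern."""
    return np.round(np.geomspace(start, stop, n_ages), 1)


def default_true_parameters() -> ModelParameters:
    """Ground-truth defaults: a declining wild-type lineage.

    Chosen so the total NSC pool falls from ~1900 cells towards a positive
    steady state of ~300 cells over the observation window with an active
    fraction of a few percent, the regime of aged mouse data, and so that
    the self-renewal feedback pair (b0, beta) is identifiable from the
    default study design (see the identifiability discussion in
    docs/methods.md).
    """
    return ModelParameters(r0=0.0079, K=100.0, b0=0.70, beta=1.33e-3)


def default_variance_models(
    observables: Dict[str, np.ndarray], ages: np.ndarray
) -> Dict[str, VarianceModel]:
    """Variance-decay models tracking the trajectory scale.

    The SD starts at ~(CV_FLOOR + CV_EXCESS) of the first-age trajectory
    value and decays towards ~CV_FLOOR of the late-age value.  The decay
    rate follows the observable's own steepest average log-decline, so
    the coefficient of variation stays bounded relative to the current
    mean even for observables that collapse early (otherwise the SD would
    dwarf the mean mid-trajectory and zero-truncation would distort the
    emitted scatter).
    """
    ages = np.asarray(ages, dtype=float)
    t0 = float(ages[0])
    out = {}
    for name, series in observables.items():
        y = np.maximum(np.asarray(series, dtype=float), 1e-12)
        y0, y_end = y[0], y[-1]
        scale0 = y0 if y0 > 1e-12 else 1.0
        d0 = CV_FLOOR * (y_end if y_end > 1e-12 else scale0)
        d1 = max((CV_FLOOR + CV_EXCESS) * scale0 - d0, 1e-12)
        with np.errstate(divide="ignore"):
            declines = np.log(y0 / y[1:]) / (ages[1:] - t0)
        d3 = float(np.clip(np.max(declines, initial=0.0), CV_DECAY, 0.1))
        out[name] = VarianceModel(
            d0=d0, d1=d1, d3=d3, t_ref=t0, observable=name,
        )
    return out


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic generator."""

    scenario: str = "r(Q,A),b(Q)"
    true_params: ModelParameters = field(default_factory=default_true_parameters)
    ages: np.ndarray = field(default_factory=default_ages)
    mice_per_age: int = 4
    variance_models: Optional[Dict[str, VarianceModel]] = None
    setting: str = "WT"
    protocol: Optional[TmzProtocol] = None
    seed: int = 0
    frac_active_0: float = 0.07
    tmz_offsets: Sequence[float] = (1.0, 9.0, 35.0)
    saline_mice: int = 4

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=float)
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if self.mice_per_age < 1:
            raise ValueError("need at least one mouse per age")


def _metadata(config: GeneratorConfig, variance_models) -> Dict:
    p = config.true_params
    return {
        "scenario": config.scenario,
        "setting": config.setting,
        "seed": config.seed,
        "true_params": {k: getattr(p, k) for k in
                        ("r0", "r1", "K", "b0", "beta", "pA", "pT", "delta", "n", "NSC0")},
        "frac_active_0": config.frac_active_0,
        "ages": config.ages.tolist(),
        "mice_per_age": config.mice_per_age,
        "variance_models": {
            name: {"d0": vm.d0, "d1": vm.d1, "d3": vm.d3, "t_ref": vm.t_ref}
            for name, vm in variance_models.items()
        },
    }


def _draw(rng, mean, sd, upper=np.inf):
    return _truncated_normal(rng, float(mean), float(sd), 0.0, upper)


def _generator_initial_state(params: ModelParameters, f0: float) -> np.ndarray:
    """Initial state using the same observable-level convention as fitting.

    Totals (TAP, NB) are taken at downstream flux balance, but the TAP
    total is split equally across compartments -- the convention used when
    reconstructing a state from first-age data, which only constrain
    totals.  Keeping both sides on one convention makes the generator
    exactly recoverable in the noise-free limit.
    """
    bal = balanced_initial_state(params, f0)
    tap_total = float(np.sum(bal[2:-1]))
    return initial_state_from_observables(params.NSC0, f0, tap_total, bal[-1], params.n)


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Per-mouse wild-type/knock-out observations around the true trajectory."""
    scenario = get_scenario(config.scenario)
    params = config.true_params
    init = _generator_initial_state(params, config.frac_active_0)
    traj = simulate(params, scenario, init, config.ages)
    obs_series = {name: traj.observable(name)
                  for name in ("nsc_total", "frac_active", "tap_total", "nb_total")}
    if float(obs_series["nsc_total"][-1]) < EXTINCTION_FLOOR:
        warnings.warn(
            "trajectory falls below the extinction floor before the last age; "
            "late observations are noise around ~0", stacklevel=2,
        )
    vms = config.variance_models or default_variance_models(obs_series, config.ages)

    rng = np.random.default_rng(config.seed)
    rows = []
    for j, age in enumerate(config.ages):
        for name, series in obs_series.items():
            sd = float(vms[name].sigma(age))
            upper = 1.0 if name == "frac_active" else np.inf
            for m in range(config.mice_per_age):
                rows.append({
                    "setting": config.setting,
                    "mouse_id": f"m{j:02d}_{m:02d}",
                    "age_days": age,
                    "observable": name,
                    "value": _draw(rng, series[j], sd, upper),
                })
    return Dataset(records=pd.DataFrame(rows), metadata=_metadata(config, vms))


def generate_tmz_dataset(config: GeneratorConfig) -> Dataset:
    """Section-scale BrdU counts around a chemotherapy recovery trajectory.

    Emits saline baselines (untreated mice sectioned just before the
    treatment age) and post-treatment observations at the configured
    offsets (default 1, 9 and 35 days after treatment).
    """
    if config.protocol is None:
        raise ValueError("TMZ generation requires a TmzProtocol in the config")
    if not config.setting.startswith("TMZ"):
        raise ValueError("setting must be TMZ_young or TMZ_old")
    scenario = get_scenario(config.scenario)
    protocol = config.protocol
    params = config.true_params
    cohort = config.setting.split("_", 1)[1]  # young | old

    t0 = float(min(config.ages[0], protocol.treatment_age))
    obs_ages = protocol.treatment_age + np.asarray(config.tmz_offsets, float)
    grid = np.unique(np.concatenate(([t0, protocol.treatment_age], obs_ages)))
    init = _generator_initial_state(params, config.frac_active_0)
    traj = simulate_tmz(protocol, params, scenario, init, grid)
    section = dict(zip(traj.t, traj.brdu_section))

    # noise on the section scale, anchored to the pre-treatment level
    y_ref = section[protocol.treatment_age]
    vm = config.variance_models.get("brdu_section") if config.variance_models else None
    if vm is None:
        vm = VarianceModel(d0=CV_FLOOR * max(y_ref, 1e-6),
                           d1=CV_EXCESS * max(y_ref, 1e-6),
                           d3=CV_DECAY, t_ref=protocol.treatment_age,
                           observable="brdu_section")

    rng = np.random.default_rng(config.seed)
    rows = []
    for m in range(config.saline_mice):  # saline baseline: untreated sections
        rows.append({
            "setting": f"saline_{cohort}",
            "mouse_id": f"sal_{m:02d}",
            "age_days": protocol.treatment_age,
            "observable": "brdu_section",
            "value": _draw(rng, y_ref, vm.sigma(protocol.treatment_age)),
        })
    for j, age in enumerate(obs_ages):
        sd = float(vm.sigma(age))
        for m in range(config.mice_per_age):
            rows.append({
                "setting": config.setting,
                "mouse_id": f"tmz{j:02d}_{m:02d}",
                "age_days": age,
                "observable": "brdu_section",
                "value": _draw(rng, section[age], sd),
            })
    meta = _metadata(config, {"brdu_section": vm})
    meta["protocol"] = {
        "treatment_age": protocol.treatment_age, "window": protocol.window,
        "d": protocol.d, "rho": protocol.rho,
        "post_params": None if protocol.post_params is None else {
            k: getattr(protocol.post_params, k)
            for k in ("r0", "r1", "K", "b0", "beta", "pA", "pT", "delta", "n", "NSC0")
        },
    }
    meta["t0"] = t0
    return Dataset(records=pd.DataFrame(rows), metadata=meta)
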