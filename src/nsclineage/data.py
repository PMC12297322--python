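"""Tabular per-mouse observation datasets.

The canonical on-disk form is a tidy CSV with columns
``setting, mouse_id, age_days, observable, value`` (header required,
UTF-8, '.' decimal).  One row is one measurement from one mouse:
cross-sectional, so mice at different ages are distinct animals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["Dataset", "OBSERVABLES", "SETTINGS"]

OBSERVABLES = ("nsc_total", "frac_active", "tap_total", "nb_total", "brdu_section")
SETTINGS = ("WT", "KO", "TMZ_young", "TMZ_old", "saline_young", "saline_old")
COLUMNS = ("setting", "mouse_id", "age_days", "observable", "value")


@dataclass
class Dataset:
    """Per-mouse longitudinal observations, with optional generator metadata."""

    records: pd.DataFrame
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"dataset missing required columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("dataset is empty")
        bad_obs = set(df["observable"]) - set(OBSERVABLES)
        if bad_obs:
            raise ValueError(f"unknown observables: {sorted(bad_obs)}")
        bad_set = set(df["setting"]) - set(SETTINGS)
        if bad_set:
            raise ValueError(f"unknown settings: {sorted(bad_set)}")
        if (df["value"] < 0).any():
            raise ValueError("observation values must be nonnegative")
        if (df["age_days"] <= 0).any():
            raise ValueError("ages must be positive")
        frac = df.loc[df["observable"] == "frac_active", "value"]
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("frac_active values must lie in [0, 1]")
        self.records = df.reset_index(drop=True)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "Dataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(records=df, metadata=meta)

    def to_csv(self, path) -> None:
        path = Path(path)
        df = self.records.copy()
        df["value"] = df["value"].map(lambda v: format(float(v), ".10g"))
        df.to_csv(path, index=False)
        if self.metadata:
            path.with_suffix(".meta.json").write_text(
                json.dumps(self.metadata, indent=2, default=float)
            )

    # -- views -------------------------------------------------------------
    def subset(
        self,
        settings: Optional[Iterable[str]] = None,
        observables: Optional[Iterable[str]] = None,
    ) -> "Dataset":
        df = self.records
        if settings is not None:
            df = df[df["setting"].isin(list(settings))]
        if observables is not None:
            df = df[df["observable"].isin(list(observables))]
        if len(df) == 0:
            raise ValueError("subset selects no records")
        return Dataset(records=df.copy(), metadata=self.metadata)

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.records["age_days"].unique())

    def group_stats(self) -> pd.DataFrame:
        """Per (setting, age, observable): mouse count, mean, sample SD."""
        g = self.records.groupby(["setting", "age_days", "observable"])["value"]
        out = g.agg(n_mice="count", mean="mean", sd=lambda v: v.std(ddof=1))
        return out.reset_index()

    def first_age_means(self, setting: str) -> Dict[str, float]:
        """Mean of each observable at the earliest observed age of a setting."""
        df = self.records[self.records["setting"] == setting]
        if len(df) == 0:
            raise ValueError(f"no records for setting {setting!r}")
        t0 = df["age_days"].min()
        sub = df[df["age_days"] == t0]
        return {
            "age_days": float(t0),
            **sub.groupby("observable")["value"].mean().to_dict(),
        }
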