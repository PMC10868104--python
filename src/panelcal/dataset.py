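"""Core containers for overlapping-panel survey microdata.

An overlapping panel survey runs measurements M_1..M_t. Each measurement j
fields a *new* theoretical sample s^(j) (drawn by stratified SRS, disjoint
from all earlier new samples) together with the survivors of every earlier
panel: the effective sample of panel i at measurement j, written s_r^(i,j),
is the set of units of s^(i) that responded at every occasion M_i..M_j.

The data are held in long format: one row per unit x fielded measurement.
A unit of panel i has a row at measurement j >= i only while it is still
being fielded (i.e. it responded at every occasion up to j-1); the ``delta``
column records whether it responded at j.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Columns every panel dataset must carry.
REQUIRED_COLUMNS = ("unit_id", "panel", "measurement", "stratum", "delta")

#: Legal weight-provenance stages, in pipeline order.
WEIGHT_STAGES = ("design", "response_rate", "psa", "combined", "calibrated")


class PanelDataError(ValueError):
    """Raised when panel microdata violate the long-format contract."""


@dataclass
class SampleDesign:
    """Stratified design metadata: population and theoretical sample sizes.

    Parameters
    ----------
    N : int
        Population size.
    strata_sizes : mapping
        Population size N_h per stratum; must sum to ``N``.
    n_new : mapping
        For each measurement j, the per-stratum theoretical size n_h^(j)
        of the *new* sample drawn at j.
    """

    N: int
    strata_sizes: Mapping[str, int]
    n_new: Mapping[int, Mapping[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise PanelDataError(f"population size must be positive, got {self.N}")
        total = int(sum(self.strata_sizes.values()))
        if total != self.N:
            raise PanelDataError(
                f"stratum sizes sum to {total}, expected N={self.N}"
            )

    def n_new_total(self, j: int) -> int:
        """Theoretical size n^(j) of the new sample at measurement j."""
        return int(sum(self.n_new[j].values()))

    @property
    def strata(self) -> list[str]:
        return list(self.strata_sizes)


@dataclass
class WeightVector:
    """Per-unit survey weights tagged with their provenance stage.

    ``weights`` is indexed by unit_id and lives on the population-units
    scale (a respondent's weight is the number of population units it
    represents). ``panel`` identifies the component sample the weights
    belong to: an int for panel i, ``"new"`` for the fresh sample at j,
    and None for weights spanning the whole effective sample of M_j.
    """

    weights: pd.Series
    stage: str
    measurement: int
    panel: int | str | None = None

    def __post_init__(self) -> None:
        if self.stage not in WEIGHT_STAGES:
            raise ValueError(f"unknown weight stage {self.stage!r}")
        w = np.asarray(self.weights, dtype=float)
        if len(w) and not (w > 0).all():
            raise ValueError("weights must be strictly positive")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.weights.index,
                "measurement": self.measurement,
                "stage": self.stage,
                "weight": self.weights.to_numpy(),
            }
        )


@dataclass
class PanelDataset:
    """Long-format overlapping-panel microdata plus column roles.

    Parameters
    ----------
    data : DataFrame
        One row per unit x fielded measurement with the REQUIRED_COLUMNS,
        covariate columns (constant within unit), margin-cell columns and
        outcome columns (observed when delta == 1).
    covariates : sequence of str
        Frame covariates available for propensity modelling.
    outcomes : sequence of str
        Outcome columns (one value per measurement row).
    margin_columns : sequence of str
        Unit attributes used to form calibration cells (e.g. sex,
        age_group, province, urbanization, nationality).
    design : SampleDesign, optional
    """

    data: pd.DataFrame
    covariates: Sequence[str] = ()
    outcomes: Sequence[str] = ()
    margin_columns: Sequence[str] = ()
    design: SampleDesign | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PanelDataError(f"missing required columns: {missing}")
        for c in (*self.covariates, *self.outcomes, *self.margin_columns):
            if c not in df.columns:
                raise PanelDataError(f"declared column {c!r} not in data")
        dup = df.duplicated(subset=["unit_id", "measurement"])
        if dup.any():
            rows = df.loc[dup, ["unit_id", "measurement"]].head(5)
            raise PanelDataError(
                "duplicate (unit_id, measurement) rows, e.g.\n" + rows.to_string()
            )
        if not df["delta"].isin([0, 1]).all():
            raise PanelDataError("delta must be 0/1")
        npanel = df.groupby("unit_id")["panel"].nunique()
        if (npanel > 1).any():
            bad = npanel[npanel > 1].index[:5].tolist()
            raise PanelDataError(f"panel index not constant for units {bad}")
        early = df["measurement"] < df["panel"]
        if early.any():
            raise PanelDataError("units cannot appear before their panel's measurement")
        for y in self.outcomes:
            bad = (df["delta"] == 1) & df[y].isna()
            if bad.any():
                rows = df.loc[bad, ["unit_id", "measurement"]].head(5)
                raise PanelDataError(
                    f"respondents with missing outcome {y!r}:\n" + rows.to_string()
                )

    # -- selectors ----------------------------------------------------

    @property
    def n_measurements(self) -> int:
        return int(self.data["measurement"].max())

    def rows(self, j: int, panel: int | None = None) -> pd.DataFrame:
        """Rows fielded at measurement j, optionally for one panel."""
        m = self.data["measurement"] == j
        if panel is not None:
            m &= self.data["panel"] == panel
        return self.data.loc[m]

    def new_sample(self, j: int) -> pd.DataFrame:
        """Theoretical new sample s^(j): panel-j rows at measurement j."""
        return self.rows(j, panel=j)

    def respondents(self, j: int, panel: int | None = None) -> pd.DataFrame:
        r = self.rows(j, panel)
        return r.loc[r["delta"] == 1]

    def panels_at(self, j: int) -> list[int]:
        """Panels with fielded rows at measurement j, oldest first."""
        return sorted(self.data.loc[self.data["measurement"] == j, "panel"].unique())

    def effective_size(self, j: int, panel: int | None = None) -> int:
        """n_r^(i,j) (or n_r^{M_j} when panel is None)."""
        return int(self.rows(j, panel)["delta"].sum())

    def fielded_size(self, j: int, panel: int | None = None) -> int:
        return int(len(self.rows(j, panel)))

    def unit_table(self, columns: Iterable[str]) -> pd.DataFrame:
        """Unit-level attribute table (first row per unit)."""
        cols = list(columns)
        return (
            self.data.sort_values("measurement")
            .groupby("unit_id", sort=True)
            .first()[["panel", "stratum"] + [c for c in cols if c not in ("panel", "stratum")]]
        )

    def outcome_wide(self, outcome: str) -> pd.DataFrame:
        """Pivot one outcome to unit x measurement (NaN where unobserved)."""
        resp = self.data.loc[self.data["delta"] == 1]
        return resp.pivot(index="unit_id", columns="measurement", values=outcome)

    def subset_units(self, unit_ids: Iterable) -> "PanelDataset":
        keep = self.data["unit_id"].isin(set(unit_ids))
        return PanelDataset(
            self.data.loc[keep].reset_index(drop=True),
            covariates=self.covariates,
            outcomes=self.outcomes,
            margin_columns=self.margin_columns,
            design=self.design,
        )
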