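"""Delimited-text readers and writers (comma-separated, UTF-8, header
row, '.' decimal) for panel microdata, margin totals, weights and
estimate tables, plus YAML run configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .calibrate import MarginTotals
from .dataset import PanelDataset, SampleDesign, WeightVector
from .estimators import Estimate


def read_panel(
    path,
    covariates: Sequence[str] = (),
    outcomes: Sequence[str] = (),
    margin_columns: Sequence[str] = (),
    design: SampleDesign | None = None,
) -> PanelDataset:
    """Read long-format panel microdata; validation happens in
    :class:`PanelDataset` and raises listing the offending rows."""
    df = pd.read_csv(path)
    return PanelDataset(
        df,
        covariates=covariates,
        outcomes=outcomes,
        margin_columns=margin_columns,
        design=design,
    )


def write_panel(data: PanelDataset, path) -> None:
    data.data.to_csv(path, index=False)


def read_margins(path) -> list[MarginTotals]:
    """Margin totals from columns (margin, columns, cell, total);
    ``columns`` and ``cell`` join attribute names/values with '|'."""
    df = pd.read_csv(path)
    out = []
    for name, grp in df.groupby("margin", sort=False):
        columns = tuple(str(grp["columns"].iloc[0]).split("|"))
        totals = {
            tuple(str(c).split("|")): float(t)
            for c, t in zip(grp["cell"], grp["total"])
        }
        out.append(MarginTotals(name=name, columns=columns, totals=totals))
    return out


def write_margins(margins: Sequence[MarginTotals], path) -> None:
    rows = [
        {
            "margin": m.name,
            "columns": "|".join(m.columns),
            "cell": "|".join(map(str, cell)),
            "total": total,
        }
        for m in margins
        for cell, total in m.totals.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_weights(weights: Sequence[WeightVector], path) -> None:
    pd.concat([w.to_frame() for w in weights]).to_csv(path, index=False)


def read_weights(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_estimates(estimates: Sequence[Estimate], path) -> None:
    pd.DataFrame([e.to_row() for e in estimates]).to_csv(path, index=False)


def read_estimates(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
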