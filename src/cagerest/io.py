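"""CSV / YAML interchange.

All tables are tidy CSV.  Raw capacitance files carry one row per sample
with 12 electrode columns ``e01..e12``; activity and immobility files one
row per minute / second.  Timestamps are ISO-8601.  Gaps in a capacitance
file (missing sample rows) are reconstructed onto the regular grid implied
by the sampling rate and masked, never filled.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    N_ELECTRODES,
    ActivitySeries,
    AnalysisConfig,
    CageMetadata,
    CapacitanceRecord,
    DataError,
    FormatError,
    ImmobilitySeries,
)

ELECTRODE_COLS = [f"e{i:02d}" for i in range(1, N_ELECTRODES + 1)]

_CSV_FLOAT_FMT = "%.10g"  # fixed formatting keeps reruns byte-identical


def read_capacitance_csv(path: str | Path, fs: float) -> CapacitanceRecord:
    """Read a per-electrode capacitance table onto a regular ``fs``-Hz grid.

    Rows absent from the grid (sensor gaps) become masked samples.  A file
    without exactly the 12 electrode columns is a format error; timestamps
    that are not strictly increasing are a data error.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in ELECTRODE_COLS if c not in df.columns]
    extra = [c for c in df.columns if c.startswith("e") and c not in ELECTRODE_COLS]
    if missing or extra:
        raise FormatError(
            f"expected electrode columns {ELECTRODE_COLS[0]}..{ELECTRODE_COLS[-1]}; "
            f"missing {missing}, unexpected {extra}"
        )
    ts = pd.DatetimeIndex(df["timestamp"])
    if len(ts) < 2:
        raise DataError("capacitance file must contain at least two samples")
    if not ts.is_monotonic_increasing or ts.has_duplicates:
        raise DataError("timestamps must be strictly increasing")
    cage_id = str(df["cage_id"].iloc[0]) if "cage_id" in df.columns else "cage"

    step = pd.Timedelta(seconds=1.0 / fs)
    grid = pd.date_range(ts[0], ts[-1], freq=step)
    frame = df.set_index("timestamp")[ELECTRODE_COLS].reindex(grid)
    values = frame.to_numpy(dtype=float)
    mask = np.isnan(values).any(axis=1)
    return CapacitanceRecord(
        cage_id=cage_id, start_time=grid[0], fs=fs, values=values, mask=mask
    )


def write_capacitance_csv(record: CapacitanceRecord, path: str | Path) -> None:
    df = pd.DataFrame(record.values, columns=ELECTRODE_COLS)
    df.insert(0, "cage_id", record.cage_id)
    df.insert(0, "timestamp", record.timestamps())
    df = df.loc[~record.mask]  # gaps are represented by absent rows
    df.to_csv(path, index=False, float_format=_CSV_FLOAT_FMT)


def write_activity_csv(series_list: list[ActivitySeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, index=False, float_format=_CSV_FLOAT_FMT
    )


def read_activity_csv(path: str | Path) -> list[ActivitySeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for cage_id, g in df.groupby("cage_id", sort=True):
        g = g.sort_values("timestamp")
        out.append(
            ActivitySeries(
                cage_id=str(cage_id),
                start_time=g["timestamp"].iloc[0],
                values=g["activity"].to_numpy(dtype=float),
            )
        )
    return out


def write_immobility_csv(series_list: list[ImmobilitySeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series_list], ignore_index=True).to_csv(
        path, index=False
    )


def read_immobility_csv(path: str | Path) -> list[ImmobilitySeries]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for cage_id, g in df.groupby("cage_id", sort=True):
        g = g.sort_values("timestamp")
        out.append(
            ImmobilitySeries(
                cage_id=str(cage_id),
                start_time=g["timestamp"].iloc[0],
                values=g["immobile"].to_numpy(),
                mask=g["masked"].to_numpy(dtype=bool) if "masked" in g else None,
            )
        )
    return out


def write_metadata_csv(metadata: list[CageMetadata], path: str | Path) -> None:
    rows = [
        {
            "cage_id": m.cage_id,
            "genotype": m.genotype,
            "sex": m.sex,
            "cohort": m.cohort_id,
            "n_animals": m.n_animals,
            "cage_change_dates": ";".join(
                d.isoformat() for d in sorted(m.cage_change_dates)
            ),
        }
        for m in sorted(metadata, key=lambda m: m.cage_id)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> list[CageMetadata]:
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        dates = frozenset(
            dt.date.fromisoformat(s) for s in r["cage_change_dates"].split(";") if s
        )
        out.append(
            CageMetadata(
                cage_id=r["cage_id"],
                genotype=r["genotype"],
                sex=r["sex"],
                cohort_id=r.get("cohort", "C1"),
                n_animals=int(r.get("n_animals", 2) or 2),
                cage_change_dates=dates,
            )
        )
    return out


def load_config(path: str | Path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    if "bout_bins" in raw:
        raw["bout_bins"] = tuple(raw["bout_bins"])
    return AnalysisConfig(**raw)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["bout_bins"] = list(data["bout_bins"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
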