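"""Readers and writers for the tabular inputs of the pipeline.

Two tables are consumed:

* the species trait table (one row per species: dry mass, measured SMR and
  measurement temperature, plant status, climate class, bioclim covariates,
  germination scores), and
* the raw respirometry trace table (long format, one row per pO2 reading,
  grouped into chambers).

All files are UTF-8 delimited text with a header row and decimal points.
Missing optional fields are permitted and propagate as NaN; analyses drop
incomplete rows and report how many were used.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .respirometry import PO2Trace
from .trees import Phylogeny

__all__ = [
    "BIOCLIM_VARS",
    "TraitTableError",
    "read_trait_table",
    "write_trait_table",
    "read_traces",
    "write_traces",
]

#: The 15 bioclimatic covariates used in the residual-correlate analysis
#: (temperature variables in deg C, precipitation in mm, isothermality in %,
#: seasonality as a coefficient of variation).
BIOCLIM_VARS: list[str] = [
    "annual_mean_temp",
    "mean_diurnal_range",
    "isothermality",
    "temp_seasonality",
    "annual_temp_range",
    "mean_temp_wettest_quarter",
    "mean_temp_driest_quarter",
    "mean_temp_warmest_quarter",
    "mean_temp_coldest_quarter",
    "annual_precip",
    "precip_seasonality",
    "precip_wettest_quarter",
    "precip_driest_quarter",
    "precip_warmest_quarter",
    "precip_coldest_quarter",
]

REQUIRED_TRAIT_COLUMNS = ["species", "dry_mass_mg"]
VALID_STATUS = {"native", "weed", "crop"}

TRACE_COLUMNS = [
    "chamber_id",
    "species",
    "time_h",
    "po2_kpa",
    "volume_ul",
    "n_seeds",
    "temp_c",
    "pressure_kpa",
]


class TraitTableError(ValueError):
    """Raised when a trait table fails validation; message lists all rows."""


def read_trait_table(
    path,
    tree: Phylogeny | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read and validate a species trait table.

    Validation is collected per row and reported in one error.  When ``tree``
    is supplied, every species must be a tip of the tree and the rows are
    reordered to the tree's taxon order.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"missing required columns: {missing}")
    errors: list[str] = []

    df["species"] = df["species"].astype(str)
    dupes = df["species"][df["species"].duplicated()].unique()
    if len(dupes):
        errors.append(f"duplicate species rows: {sorted(dupes)}")

    mass = pd.to_numeric(df["dry_mass_mg"], errors="coerce")
    bad_mass = df.index[mass.isna() | (mass <= 0)]
    for i in bad_mass:
        errors.append(
            f"row {i} ({df.at[i, 'species']}): dry_mass_mg must be a positive "
            f"number, got {df.at[i, 'dry_mass_mg']!r}"
        )
    df["dry_mass_mg"] = mass

    for col in ("smr_t", "smr20", "t_measure_c", "gmax_pct", "t50_days", *BIOCLIM_VARS):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "smr_t" in df.columns:
        for i in df.index[df["smr_t"] < 0]:
            errors.append(f"row {i} ({df.at[i, 'species']}): smr_t must be >= 0")
    if "gmax_pct" in df.columns:
        bad = df.index[(df["gmax_pct"] < 0) | (df["gmax_pct"] > 100)]
        for i in bad:
            errors.append(f"row {i} ({df.at[i, 'species']}): gmax_pct outside [0, 100]")
    if "status" in df.columns:
        bad = df.index[df["status"].notna() & ~df["status"].isin(VALID_STATUS)]
        for i in bad:
            errors.append(
                f"row {i} ({df.at[i, 'species']}): status {df.at[i, 'status']!r} "
                f"not one of {sorted(VALID_STATUS)}"
            )

    if tree is not None:
        extra = sorted(set(df["species"]) - set(tree.taxa))
        if extra:
            errors.append(f"species absent from tree: {extra}")

    if errors:
        raise TraitTableError("; ".join(errors))

    if tree is not None:
        order = {sp: i for i, sp in enumerate(tree.taxa)}
        df = df.sort_values("species", key=lambda s: s.map(order)).reset_index(drop=True)
    return df


def write_trait_table(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_traces(path, sep: str = ",") -> list[PO2Trace]:
    """Read a long-format trace table into one :class:`PO2Trace` per chamber.

    Expected columns: chamber_id, species, time_h, po2_kpa, [pco2_kpa],
    volume_ul, n_seeds, temp_c, pressure_kpa.  Rows are grouped by chamber_id
    and sorted by time within a chamber.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"trace table missing columns: {missing}")
    traces: list[PO2Trace] = []
    for chamber, grp in df.groupby("chamber_id", sort=False):
        grp = grp.sort_values("time_h")
        meta = grp.iloc[0]
        pco2 = None
        if "pco2_kpa" in grp.columns and grp["pco2_kpa"].notna().all():
            pco2 = grp["pco2_kpa"].to_numpy(float)
        traces.append(
            PO2Trace(
                chamber_id=str(chamber),
                species=str(meta["species"]),
                times=grp["time_h"].to_numpy(float),
                po2=grp["po2_kpa"].to_numpy(float),
                pco2=pco2,
                volume_ul=float(meta["volume_ul"]),
                n_seeds=int(meta["n_seeds"]),
                t_measure=float(meta["temp_c"]),
                pressure_kpa=float(meta["pressure_kpa"]),
            )
        )
    return traces


def write_traces(traces: Sequence[PO2Trace], path, sep: str = ",") -> None:
    """Write traces back to the long-format CSV read by :func:`read_traces`."""
    frames = []
    for tr in traces:
        d = {
            "chamber_id": tr.chamber_id,
            "species": tr.species,
            "time_h": tr.times,
            "po2_kpa": tr.po2,
            "volume_ul": tr.volume_ul,
            "n_seeds": tr.n_seeds,
            "temp_c": tr.t_measure,
            "pressure_kpa": tr.pressure_kpa,
        }
        if tr.pco2 is not None:
            d["pco2_kpa"] = tr.pco2
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
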