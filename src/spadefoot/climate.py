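"""Locality vetting and species-level climate summaries.

Museum locality records carry per-point bioclim values (Bio5/6/10/11
temperatures in deg C, Bio12/16 precipitation in mm, Bio15 a coefficient of
variation).  Vetting collapses exact coordinate duplicates, drops records
flagged outside the species' accepted range, and drops records whose
elevation falls outside the reported bounds.  Summaries reduce each species
to min / max / mean / midpoint per variable, plus two aridity indices:

    Q  = P / ((Tmax + Tmin) (Tmax - Tmin))

analyzed on a log10 scale.  For ``logQ``: P is the mean Bio12 across
localities, Tmax the maximum Bio5 and Tmin the minimum Bio6 across the
range.  ``logQ2`` substitutes mean Bio10 / mean Bio11 for the temperature
extremes.  Arid environments have lower Q.

Range-polygon vetting and raster extraction are upstream concerns: the
``in_range`` flag and the bioclim columns are inputs here.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "BIOCLIM_VARS",
    "read_localities",
    "vet_localities",
    "summarize_species",
    "aridity_logQ",
    "aridity_logQ2",
]

BIOCLIM_VARS = ["bio5", "bio6", "bio10", "bio11", "bio12", "bio15", "bio16"]
_TEMP_VARS = ["bio5", "bio6", "bio10", "bio11"]

#: Coordinates are considered duplicates after rounding to 4 decimal
#: places (~11 m at the equator).
_COORD_DECIMALS = 4


def read_localities(path, temperature_units: str = None) -> pd.DataFrame:
    """Read a locality table (CSV or TSV, sniffed from the extension).

    ``temperature_units`` must be declared explicitly: ``"celsius"`` for
    ready-to-use values or ``"worldclim-raw"`` for rasters that store
    temperature multiplied by 10 (the 0.1 scale factor is applied on read).
    The aridity index Q is unit-sensitive, so no default is assumed.
    """
    if temperature_units not in ("celsius", "worldclim-raw"):
        raise ValueError(
            "temperature_units must be declared as 'celsius' or 'worldclim-raw'"
        )
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, na_values=["", "NA"])
    missing = [c for c in ("species", "lon", "lat") if c not in df.columns]
    if missing:
        raise ValueError(f"locality table missing required columns: {missing}")
    if temperature_units == "worldclim-raw":
        for c in _TEMP_VARS:
            if c in df.columns:
                df[c] = df[c] * 0.1
    _validate_localities(df)
    return df


def _validate_localities(df: pd.DataFrame) -> None:
    if ((df["lon"] < -180) | (df["lon"] > 180)).any():
        raise ValueError("longitude outside [-180, 180]")
    if ((df["lat"] < -90) | (df["lat"] > 90)).any():
        raise ValueError("latitude outside [-90, 90]")
    for c in ("bio12", "bio16"):
        if c in df.columns and (df[c].dropna() < 0).any():
            raise ValueError(f"negative precipitation in {c}")
    if "bio5" in df.columns and "bio6" in df.columns:
        both = df[["bio5", "bio6"]].dropna()
        if (both["bio5"] < both["bio6"]).any():
            raise ValueError("bio5 < bio6 in some record (units mixed up?)")


def vet_localities(
    records: pd.DataFrame,
    elevation_min: float,
    elevation_max: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vet locality records; returns ``(kept, rejection_log)``.

    In order: exact coordinate duplicates within species are collapsed to
    unique localities; records flagged ``in_range == False`` are dropped;
    records with elevation outside ``[elevation_min, elevation_max]`` are
    dropped (records without an elevation skip that filter, with a note).
    Every rejection is logged with a reason code.  A species left with no
    records is an error.
    """
    if not (math.isfinite(elevation_min) and math.isfinite(elevation_max)):
        raise ValueError("elevation bounds must be finite")
    if elevation_min > elevation_max:
        raise ValueError("elevation_min must be <= elevation_max")
    df = records.reset_index(drop=True)
    log_rows = []

    key = df.assign(
        _lon=df["lon"].round(_COORD_DECIMALS), _lat=df["lat"].round(_COORD_DECIMALS)
    )
    dup_mask = key.duplicated(subset=["species", "_lon", "_lat"], keep="first")
    for i in df.index[dup_mask]:
        log_rows.append(
            {"row": i, "species": df.at[i, "species"], "reason": "duplicate_coordinate"}
        )
    kept = df[~dup_mask]

    if "in_range" in kept.columns:
        out = kept["in_range"].astype("boolean") == False  # noqa: E712 - keep NA
        for i in kept.index[out.fillna(False)]:
            log_rows.append(
                {"row": i, "species": df.at[i, "species"], "reason": "outside_range_map"}
            )
        kept = kept[~out.fillna(False)]

    if "elevation" in kept.columns:
        elev = kept["elevation"]
        bad = (elev < elevation_min) | (elev > elevation_max)
        for i in kept.index[bad.fillna(False)]:
            log_rows.append(
                {"row": i, "species": df.at[i, "species"], "reason": "elevation_out_of_bounds"}
            )
        for i in kept.index[elev.isna()]:
            log_rows.append(
                {"row": i, "species": df.at[i, "species"], "reason": "note_no_elevation"}
            )
        kept = kept[~bad.fillna(False)]
    else:
        log_rows.append({"row": -1, "species": "*", "reason": "note_no_elevation_column"})

    lost = set(df["species"].unique()) - set(kept["species"].unique())
    if lost:
        raise ValueError(
            f"vetting removed every locality for species: {sorted(lost)}"
        )
    log = pd.DataFrame(log_rows, columns=["row", "species", "reason"])
    return kept.reset_index(drop=True), log


def aridity_logQ(P: float, tmax: float, tmin: float, base: float = 10.0) -> float:
    """Aridity index ``log(P / ((Tmax + Tmin)(Tmax - Tmin)))``.

    ``P`` in mm (mean annual precipitation across localities), ``tmax`` /
    ``tmin`` in deg C.  Log base 10 by default.  Q <= 0 (including the
    ``tmax + tmin < 0`` case) and ``tmax <= tmin`` are hard errors, never a
    silent NaN.
    """
    if P < 0:
        raise ValueError("P must be >= 0")
    if tmax <= tmin:
        raise ValueError(f"tmax ({tmax}) must exceed tmin ({tmin})")
    denom = (tmax + tmin) * (tmax - tmin)
    if denom == 0:
        raise ValueError("tmax + tmin = 0: Q undefined")
    Q = P / denom
    if Q <= 0:
        raise ValueError(f"Q = {Q:.4g} <= 0: log undefined (tmax + tmin < 0 or P = 0)")
    return math.log(Q) / math.log(base)


def aridity_logQ2(P: float, t_warm: float, t_cold: float, base: float = 10.0) -> float:
    """Aridity index using quarter means: Tmax = mean Bio10, Tmin = mean Bio11."""
    return aridity_logQ(P, t_warm, t_cold, base=base)


def summarize_species(records: pd.DataFrame, log_base: float = 10.0) -> pd.DataFrame:
    """Species-level climate summaries from vetted locality records.

    One row per species: ``n_localities``, then ``{var}_{min,max,mean,midpoint}``
    for each bioclim variable present, plus ``logQ`` and ``logQ2``.  An
    all-missing variable for a species yields NaN summary fields (flagged
    missing, never zero).
    """
    if len(records) == 0:
        raise ValueError("no locality records")
    rows = []
    for sp, grp in records.groupby("species", sort=True):
        row = {"species": sp, "n_localities": len(grp)}
        for var in BIOCLIM_VARS:
            if var not in grp.columns:
                continue
            v = grp[var].dropna()
            if len(v) == 0:
                row.update(
                    {f"{var}_{s}": np.nan for s in ("min", "max", "mean", "midpoint")}
                )
                continue
            vmin, vmax = float(v.min()), float(v.max())
            row[f"{var}_min"] = vmin
            row[f"{var}_max"] = vmax
            row[f"{var}_mean"] = float(v.mean())
            row[f"{var}_midpoint"] = (vmin + vmax) / 2.0
        # missing inputs yield NaN; true domain violations still raise
        try:
            row["logQ"] = aridity_logQ(
                row["bio12_mean"], row["bio5_max"], row["bio6_min"], base=log_base
            )
        except KeyError:
            row["logQ"] = np.nan
        try:
            row["logQ2"] = aridity_logQ2(
                row["bio12_mean"], row["bio10_mean"], row["bio11_mean"], base=log_base
            )
        except KeyError:
            row["logQ2"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
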