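"""Readers and writers for the pipeline's tabular and spatial inputs.

All interchange is plain CSV with explicit header schemas:

* ``deaths.csv``       — area, age, sex, deaths
* ``population.csv``   — area, age, sex, count           (census counts)
* ``projections.csv``  — unit, age_band, sex, period, count
* ``ses.csv``          — area, water_access, overcrowding,
  school_attendance, high_school, unemployment
* ``adjacency.csv``    — area_i, area_j (symmetric edge list)
* ``units.csv``        — area, unit
* ``standard_schedule.csv`` — age, sex, log_rate

GeoJSON polygons are accepted only to derive adjacency (areas sharing a
boundary segment, not a single point, are neighbors) and for a minimal
choropleth export.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_deaths",
    "read_population",
    "read_projections",
    "read_ses",
    "read_adjacency",
    "read_units",
    "read_schedule",
    "read_exposure",
    "read_inputs",
    "derive_adjacency",
    "write_city",
    "export_choropleth",
]

SES_COLUMNS = ("water_access", "overcrowding", "school_attendance",
               "high_school", "unemployment")
VALID_SEXES = {"F", "M"}


class SchemaError(ValueError):
    """An input file violates its declared schema."""


def _read(path, required, name):
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{name} file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _check_numeric(df, col, path, nonneg=True, integer=False):
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() & df[col].notna()
    if bad.any() or df[col].isna().any():
        row = int(np.flatnonzero(bad | df[col].isna())[0])
        raise SchemaError(f"{path}: column {col!r} non-numeric/missing at row {row}")
    if nonneg and (s < 0).any():
        row = int(np.flatnonzero((s < 0).to_numpy())[0])
        raise SchemaError(f"{path}: column {col!r} negative at row {row}")
    if integer and not np.allclose(s, np.round(s)):
        row = int(np.flatnonzero(~np.isclose(s, np.round(s)))[0])
        raise SchemaError(f"{path}: column {col!r} non-integer at row {row}")
    return s


def _check_sex(df, path):
    bad = ~df["sex"].isin(VALID_SEXES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(f"{path}: column 'sex' must be F or M (row {row}: "
                          f"{df['sex'].iloc[row]!r})")


def _check_contiguous_ages(df, path):
    for sex, grp in df.groupby("sex"):
        ages = np.sort(grp["age"].unique())
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise SchemaError(f"{path}: ages for sex {sex} not contiguous from 0")


def read_deaths(path) -> pd.DataFrame:
    df = _read(path, ["area", "age", "sex", "deaths"], "deaths")
    _check_sex(df, path)
    df["deaths"] = _check_numeric(df, "deaths", path, integer=True).astype(int)
    _check_contiguous_ages(df, path)
    return df


def read_population(path) -> pd.DataFrame:
    df = _read(path, ["area", "age", "sex", "count"], "population")
    _check_sex(df, path)
    df["count"] = _check_numeric(df, "count", path)
    _check_contiguous_ages(df, path)
    return df


def read_projections(path) -> pd.DataFrame:
    from .pclm import parse_band

    df = _read(path, ["unit", "age_band", "sex", "period", "count"], "projections")
    _check_sex(df, path)
    df["count"] = _check_numeric(df, "count", path)
    for band in df["age_band"].unique():
        parse_band(band)  # raises on malformed labels
    return df


def read_ses(path) -> pd.DataFrame:
    df = _read(path, ["area", *SES_COLUMNS], "ses")
    for col in SES_COLUMNS:
        _check_numeric(df, col, path, nonneg=False)
    return df


def read_units(path) -> pd.DataFrame:
    df = _read(path, ["area", "unit"], "units")
    if df["area"].duplicated().any():
        dup = df.loc[df["area"].duplicated(), "area"].iloc[0]
        raise SchemaError(f"{path}: area {dup!r} mapped to multiple units")
    return df


def read_adjacency(path) -> pd.DataFrame:
    """Edge list; symmetrized (with a warning) if any edge is one-way."""
    df = _read(path, ["area_i", "area_j"], "adjacency")
    if (df["area_i"] == df["area_j"]).any():
        raise SchemaError(f"{path}: self-edges are not allowed")
    pairs = set(map(tuple, df[["area_i", "area_j"]].itertuples(index=False)))
    missing = {(b, a) for a, b in pairs} - pairs
    if missing:
        warnings.warn(f"{path}: {len(missing)} one-way edges symmetrized",
                      RuntimeWarning)
    und = sorted({tuple(sorted(p, key=str)) for p in pairs})
    return pd.DataFrame(und, columns=["area_i", "area_j"])


def read_schedule(path) -> pd.DataFrame:
    df = _read(path, ["age", "sex", "log_rate"], "standard schedule")
    _check_sex(df, path)
    _check_numeric(df, "log_rate", path, nonneg=False)
    return df


def read_exposure(path) -> pd.DataFrame:
    df = _read(path, ["area", "age", "sex", "exposure"], "exposure")
    _check_sex(df, path)
    df["exposure"] = _check_numeric(df, "exposure", path)
    return df


def check_area_alignment(deaths: pd.DataFrame, exposure: pd.DataFrame):
    """Raise if deaths mention areas with no exposure record."""
    missing = sorted(set(deaths["area"]) - set(exposure["area"]))
    if missing:
        raise SchemaError(f"deaths recorded for areas absent from the "
                          f"exposure table: {missing}")


def read_inputs(paths: dict) -> dict:
    """Read and cross-validate the full input bundle.

    ``paths`` maps names (deaths, census, projections, ses, adjacency,
    units) to files.  Area sets are reconciled across files: areas
    missing from any area-indexed file are dropped everywhere, and the
    reconciliation report lists them.
    """
    bundle = {
        "deaths": read_deaths(paths["deaths"]),
        "census": read_population(paths["census"]),
        "projections": read_projections(paths["projections"]),
        "ses": read_ses(paths["ses"]),
        "adjacency": read_adjacency(paths["adjacency"]),
        "units": read_units(paths["units"]),
    }
    area_sets = {
        "deaths": set(bundle["deaths"]["area"]),
        "census": set(bundle["census"]["area"]),
        "ses": set(bundle["ses"]["area"]),
        "units": set(bundle["units"]["area"]),
    }
    common = set.intersection(*area_sets.values())
    dropped = {name: sorted(s - common) for name, s in area_sets.items()
               if s - common}
    if dropped:
        warnings.warn(f"areas dropped during reconciliation: {dropped}",
                      RuntimeWarning)
    for name in ("deaths", "census", "ses", "units"):
        df = bundle[name]
        bundle[name] = df[df["area"].isin(common)].reset_index(drop=True)
    adj = bundle["adjacency"]
    bundle["adjacency"] = adj[adj["area_i"].isin(common)
                              & adj["area_j"].isin(common)].reset_index(drop=True)
    bundle["report"] = {"n_areas": len(common), "dropped": dropped}
    return bundle


# ---------------------------------------------------------------------
# polygons
# ---------------------------------------------------------------------

def derive_adjacency(geojson) -> pd.DataFrame:
    """Rook adjacency from GeoJSON polygons.

    Two areas are neighbors when their boundaries share a segment of
    positive length (touching at a single point does not count).
    Feature ids come from properties['area'] or the feature 'id'.
    """
    from shapely.geometry import shape

    if isinstance(geojson, (str, Path)):
        with open(geojson) as fh:
            geojson = json.load(fh)
    geoms, ids = [], []
    for feat in geojson["features"]:
        fid = feat.get("properties", {}).get("area", feat.get("id"))
        try:
            geom = shape(feat["geometry"])
        except Exception as err:
            raise ValueError(f"invalid geometry for feature {fid!r}: {err}")
        if geom.is_empty or not geom.is_valid:
            raise ValueError(f"invalid geometry for feature {fid!r}")
        geoms.append(geom)
        ids.append(fid)
    edges = []
    for i in range(len(geoms)):
        for j in range(i + 1, len(geoms)):
            inter = geoms[i].boundary.intersection(geoms[j].boundary)
            if inter.length > 0:
                edges.append((ids[i], ids[j]))
    if not edges:
        warnings.warn("no shared boundaries: adjacency graph is empty",
                      RuntimeWarning)
        return pd.DataFrame(columns=["area_i", "area_j"])
    return pd.DataFrame(edges, columns=["area_i", "area_j"])


def export_choropleth(geojson, le_summary: pd.DataFrame, out_path,
                      age: int = 0):
    """Attach life-expectancy properties to polygons (no styling)."""
    if isinstance(geojson, (str, Path)):
        with open(geojson) as fh:
            geojson = json.load(fh)
    sub = le_summary[le_summary["age"] == age]
    values = {}
    for _, row in sub.iterrows():
        key = (row["area"], row.get("sex"))
        values[key] = row
    for feat in geojson["features"]:
        fid = feat.get("properties", {}).get("area", feat.get("id"))
        props = feat.setdefault("properties", {})
        for sex in sorted({s for _, s in values if s is not None} or {None}):
            row = values.get((fid, sex))
            if row is not None:
                suffix = f"_{sex}" if sex is not None else ""
                props[f"le{suffix}"] = float(row["le"])
                props[f"le_lo{suffix}"] = float(row["le_lo"])
                props[f"le_hi{suffix}"] = float(row["le_hi"])
    with open(out_path, "w") as fh:
        json.dump(geojson, fh)
    return out_path


# ---------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------

def write_city(city, out_dir) -> dict:
    """Write a SyntheticCity's inputs as the pipeline's CSV schemas."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    deaths = city.deaths.sort_values(["sex", "area", "age"], ignore_index=True)
    paths["deaths"] = out / "deaths.csv"
    deaths.to_csv(paths["deaths"], index=False)

    census = city.census.sort_values(["sex", "area", "age"], ignore_index=True)
    paths["census"] = out / "population.csv"
    census.to_csv(paths["census"], index=False)

    paths["projections"] = out / "projections.csv"
    city.projections.to_csv(paths["projections"], index=False)

    paths["ses"] = out / "ses.csv"
    city.ses.to_csv(paths["ses"], index=False)

    adj = pd.DataFrame(city.adjacency, columns=["area_i", "area_j"])
    paths["adjacency"] = out / "adjacency.csv"
    adj.to_csv(paths["adjacency"], index=False)

    paths["units"] = out / "units.csv"
    city.units.to_csv(paths["units"], index=False)

    return {k: str(v) for k, v in paths.items()}
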