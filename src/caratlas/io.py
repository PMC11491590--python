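"""Readers and writers for the package's file formats.

All tabular formats are plain CSV with required headers; floats are
written with 6 significant digits for cross-platform diffability.
GeoJSON is handled with the standard ``json`` module plus shapely for
geometry, both for polygon input (contiguity, choropleths) and for
styled output (per-feature fill/alpha properties).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .graph import RegionGraph, ValidationError, build_graph
from .mcmc import PosteriorDraws
from .models import IncidenceData, SurvivalData
from .summaries import AreaSummary
from .vizspec import StyleSpec

__all__ = [
    "read_edge_list", "write_edge_list",
    "read_geojson_polygons", "write_styled_geojson",
    "read_incidence_csv", "write_incidence_csv",
    "read_survival_csv", "write_survival_csv",
    "write_draws", "read_draws",
    "write_summaries", "read_summaries",
    "write_truth", "FLOAT_FMT",
]

FLOAT_FMT = "%.6g"


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


# -- adjacency ---------------------------------------------------------------

def read_edge_list(path, area_ids=None) -> RegionGraph:
    """Edge-list CSV (`area_id_1,area_id_2`) to a :class:`RegionGraph`.

    If ``area_ids`` is omitted the node set is the sorted union of edge
    endpoints.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["area_id_1", "area_id_2"], path)
    edges = list(zip(df["area_id_1"], df["area_id_2"]))
    if area_ids is None:
        area_ids = sorted({a for e in edges for a in e})
    return build_graph(edges, area_ids)


def write_edge_list(graph: RegionGraph, path) -> None:
    i, j = graph.edge_index_arrays()
    ids = graph.area_ids
    pd.DataFrame({
        "area_id_1": [ids[k] for k in i],
        "area_id_2": [ids[k] for k in j],
    }).to_csv(path, index=False)


# -- GeoJSON -----------------------------------------------------------------

def read_geojson_polygons(path, id_property: str = "area_id") -> dict:
    """GeoJSON FeatureCollection to an {area_id: shapely geometry} mapping."""
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        aid = props.get(id_property, feat.get("id"))
        if aid is None:
            raise ValidationError(
                f"{path}: feature missing id property {id_property!r}"
            )
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValidationError(f"{path}: invalid geometry for area {aid!r}")
        out[str(aid)] = geom
    return out


def write_styled_geojson(polygons: dict, styles: list[StyleSpec], path,
                         id_property: str = "area_id") -> None:
    """Write polygons with per-feature ``fill`` and ``fill-opacity``."""
    from shapely.geometry import mapping

    missing = [s.area_id for s in styles if s.area_id not in polygons]
    if missing:
        raise ValidationError(f"no polygon for styled areas: {missing[:5]}")
    features = [
        {
            "type": "Feature",
            "properties": {
                id_property: s.area_id,
                "fill": s.fill,
                "fill-opacity": round(s.alpha, 6),
            },
            "geometry": mapping(polygons[s.area_id]),
        }
        for s in styles
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# -- model data --------------------------------------------------------------

def read_incidence_csv(path) -> IncidenceData:
    """CSV `area_id,observed,expected` to :class:`IncidenceData`."""
    df = pd.read_csv(path)
    _require_columns(df, ["area_id", "observed", "expected"], path)
    return IncidenceData(
        area_ids=tuple(df["area_id"].astype(str)),
        observed=df["observed"].to_numpy(dtype=float),
        expected=df["expected"].to_numpy(dtype=float),
    )


def write_incidence_csv(data: IncidenceData, path) -> None:
    pd.DataFrame({
        "area_id": data.area_ids,
        "observed": data.observed.astype(int),
        "expected": [_fmt(v) for v in data.expected],
    }).to_csv(path, index=False)


def read_survival_csv(path) -> SurvivalData:
    """Long CSV `area_id,interval,deaths,expected_deaths,person_time`."""
    df = pd.read_csv(path)
    _require_columns(
        df, ["area_id", "interval", "deaths", "expected_deaths", "person_time"],
        path,
    )
    area_ids = tuple(dict.fromkeys(df["area_id"].astype(str)))
    intervals = sorted(df["interval"].unique())
    n, J = len(area_ids), len(intervals)
    idx_a = {a: i for i, a in enumerate(area_ids)}
    idx_j = {j: k for k, j in enumerate(intervals)}
    d = np.zeros((n, J))
    e = np.zeros((n, J))
    t = np.full((n, J), np.nan)
    for _, row in df.iterrows():
        i, j = idx_a[str(row["area_id"])], idx_j[row["interval"]]
        d[i, j] = row["deaths"]
        e[i, j] = row["expected_deaths"]
        t[i, j] = row["person_time"]
    if np.any(np.isnan(t)):
        raise ValidationError(f"{path}: missing area x interval cells")
    return SurvivalData(area_ids=area_ids, deaths=d, expected_deaths=e,
                        person_time=t)


def write_survival_csv(data: SurvivalData, path) -> None:
    rows = []
    for i, aid in enumerate(data.area_ids):
        for j in range(data.n_intervals):
            rows.append({
                "area_id": aid,
                "interval": j + 1,
                "deaths": int(data.deaths[i, j]),
                "expected_deaths": _fmt(data.expected_deaths[i, j]),
                "person_time": _fmt(data.person_time[i, j]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# -- posterior draws ---------------------------------------------------------

def write_draws(draws: PosteriorDraws, csv_path, meta_path) -> None:
    """Draws CSV (area columns x retained rows) plus a JSON sidecar."""
    df = pd.DataFrame(draws.draws, columns=list(draws.area_ids))
    df.to_csv(csv_path, index=False, float_format=FLOAT_FMT)
    sidecar = {
        "hyper_draws": {k: np.asarray(v).tolist()
                        for k, v in draws.hyper_draws.items()},
        "meta": draws.meta,
    }
    with open(meta_path, "w") as fh:
        json.dump(sidecar, fh)


def read_draws(csv_path, meta_path) -> PosteriorDraws:
    df = pd.read_csv(csv_path)
    with open(meta_path) as fh:
        sidecar = json.load(fh)
    return PosteriorDraws(
        area_ids=tuple(df.columns),
        draws=df.to_numpy(dtype=float),
        hyper_draws={k: np.asarray(v)
                     for k, v in sidecar.get("hyper_draws", {}).items()},
        meta=sidecar.get("meta", {}),
    )


# -- summaries ---------------------------------------------------------------

_SUMMARY_COLS = ["area_id", "point", "ci60_lo", "ci60_hi",
                 "ci80_lo", "ci80_hi", "ppd", "v_conf", "category"]


def write_summaries(summaries: list[AreaSummary], path) -> None:
    rows = [
        {
            "area_id": s.area_id,
            "point": _fmt(s.point),
            "ci60_lo": _fmt(s.ci60[0]), "ci60_hi": _fmt(s.ci60[1]),
            "ci80_lo": _fmt(s.ci80[0]), "ci80_hi": _fmt(s.ci80[1]),
            "ppd": _fmt(s.ppd), "v_conf": _fmt(s.v_conf),
            "category": s.category,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=_SUMMARY_COLS).to_csv(path, index=False)


def read_summaries(path) -> list[AreaSummary]:
    df = pd.read_csv(path)
    _require_columns(df, _SUMMARY_COLS, path)
    return [
        AreaSummary(
            area_id=str(r["area_id"]),
            point=float(r["point"]),
            ci60=(float(r["ci60_lo"]), float(r["ci60_hi"])),
            ci80=(float(r["ci80_lo"]), float(r["ci80_hi"])),
            ppd=float(r["ppd"]),
            v_conf=float(r["v_conf"]),
            category=str(r["category"]),
        )
        for _, r in df.iterrows()
    ]


def write_truth(truth: dict, path) -> None:
    """Truth sidecar CSV for simulated datasets."""
    cols = {"area_id": truth["area_ids"], "S": truth["S"]}
    if "sir" in truth:
        cols["sir"] = truth["sir"]
    if "ehr" in truth:
        cols["ehr"] = truth["ehr"]
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
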