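"""Areal geometry and value-table I/O.

Reads GeoJSON FeatureCollections of (multi)polygons and time-indexed value
tables (long or wide CSV), joins them into a validated
:class:`SpatioTemporalDataset`, and writes labeled results back out as
GeoJSON and CSV.

The in-memory missing marker is ``NaN``: a cell of the value matrix is
either a finite real or ``NaN``, never a silently imputed zero.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry

from .errors import (
    DataFormatError,
    DuplicateIdError,
    JoinError,
    UnsupportedGeometryError,
)

logger = logging.getLogger(__name__)

#: value used in GeoJSON / CSV output for cells that were not analyzed
MISSING_LABEL = "missing"


@dataclass
class AreaGeometry:
    """One areal unit: a polygonal region with a unique identifier."""

    area_id: str
    geometry: BaseGeometry
    name: str | None = None


@dataclass
class SpatioTemporalDataset:
    """Areas x times value matrix with an explicit NaN missing marker.

    ``areas`` fixes the canonical area order used by every downstream
    matrix; ``times`` is sorted ascending (numerically when every label
    parses as a number, lexically otherwise).
    """

    areas: list[AreaGeometry]
    times: list[str]
    values: np.ndarray  # shape (n_areas, n_times), NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.areas), len(self.times)):
            raise DataFormatError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.areas)} areas x {len(self.times)} times"
            )
        if len(self.areas) < 2:
            raise DataFormatError("a dataset needs at least 2 areas")
        if len(set(self.times)) != len(self.times):
            raise DataFormatError("time labels must be unique")

    @property
    def n(self) -> int:
        return len(self.areas)

    @property
    def area_ids(self) -> list[str]:
        return [a.area_id for a in self.areas]

    def time_index(self, time: str) -> int:
        try:
            return self.times.index(time)
        except ValueError:
            raise KeyError(f"unknown time label: {time!r}") from None


def read_geometries(path: str | Path, id_property: str = "id") -> list[AreaGeometry]:
    """Read a GeoJSON FeatureCollection into a list of :class:`AreaGeometry`.

    Feature order is preserved.  The identifier is taken from the feature's
    ``properties[id_property]``, falling back to the top-level feature ``id``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise DataFormatError(f"{path}: not a GeoJSON FeatureCollection")
    geoms: list[AreaGeometry] = []
    seen: set[str] = set()
    for idx, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        raw_id = props.get(id_property, feat.get("id"))
        if raw_id is None:
            raise DataFormatError(
                f"{path}: feature {idx} is missing id property {id_property!r}"
            )
        area_id = str(raw_id)
        if area_id in seen:
            raise DuplicateIdError(f"{path}: duplicate area id {area_id!r}")
        seen.add(area_id)
        geom = geom_shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise UnsupportedGeometryError(
                f"{path}: feature {idx} ({area_id!r}) has unsupported "
                f"geometry type {geom.geom_type}"
            )
        geoms.append(AreaGeometry(area_id=area_id, geometry=geom, name=props.get("name")))
    return geoms


def write_geometries(
    geoms: list[AreaGeometry], path: str | Path, id_property: str = "id"
) -> None:
    """Write areas as a GeoJSON FeatureCollection (inverse of read_geometries)."""
    features = []
    for g in geoms:
        props: dict = {id_property: g.area_id}
        if g.name is not None:
            props["name"] = g.name
        features.append(
            {"type": "Feature", "properties": props, "geometry": geom_mapping(g.geometry)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _parse_value(raw: str, sentinel: str, where: str) -> float | None:
    cell = raw.strip()
    if cell == "" or cell == sentinel:
        return None
    try:
        return float(cell)
    except ValueError:
        raise DataFormatError(f"unparseable numeric value {raw!r} at {where}") from None


def read_value_table(
    path: str | Path,
    layout: str = "long",
    id_col: str = "area_id",
    time_col: str = "time",
    value_col: str = "value",
    missing_sentinel: str = "",
) -> dict[tuple[str, str], float | None]:
    """Read a value CSV into a mapping ``(area_id, time) -> value-or-None``.

    ``layout='long'`` expects one row per (area, time); ``layout='wide'``
    expects one row per area with one column per time.  Empty cells and the
    ``missing_sentinel`` map to ``None`` (the missing marker).
    """
    if layout not in ("long", "wide"):
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")
    values: dict[tuple[str, str], float | None] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataFormatError(f"{path}: empty CSV")
        if layout == "long":
            for col in (id_col, time_col, value_col):
                if col not in reader.fieldnames:
                    raise DataFormatError(f"{path}: missing column {col!r}")
            for rownum, row in enumerate(reader, start=2):
                key = (row[id_col], row[time_col])
                if key in values:
                    raise DuplicateIdError(
                        f"{path}: duplicate record for area {key[0]!r}, "
                        f"time {key[1]!r} at row {rownum}"
                    )
                values[key] = _parse_value(
                    row[value_col], missing_sentinel, f"{path} row {rownum}"
                )
        else:
            if id_col not in reader.fieldnames:
                raise DataFormatError(f"{path}: missing column {id_col!r}")
            time_cols = [c for c in reader.fieldnames if c != id_col]
            for rownum, row in enumerate(reader, start=2):
                area = row[id_col]
                for tc in time_cols:
                    key = (area, tc)
                    if key in values:
                        raise DuplicateIdError(
                            f"{path}: duplicate record for area {area!r} at row {rownum}"
                        )
                    values[key] = _parse_value(
                        row[tc], missing_sentinel, f"{path} row {rownum} column {tc!r}"
                    )
    return values


def _sort_times(times: set[str]) -> list[str]:
    try:
        return sorted(times, key=float)
    except ValueError:
        return sorted(times)


def join_dataset(
    geoms: list[AreaGeometry],
    values: Mapping[tuple[str, str], float | None],
    strict: bool = True,
) -> SpatioTemporalDataset:
    """Join geometries and values into a :class:`SpatioTemporalDataset`.

    Areas keep geometry-file order; times are sorted ascending.  In strict
    mode, value records whose area_id is absent from the geometries raise a
    :class:`JoinError`; in lenient mode they are dropped with a warning.
    """
    known = {g.area_id: i for i, g in enumerate(geoms)}
    unknown = sorted({a for (a, _t) in values if a not in known})
    if unknown:
        if strict:
            raise JoinError(f"value table references unknown areas: {', '.join(unknown)}")
        logger.warning("dropping values for unknown areas: %s", ", ".join(unknown))
    times = _sort_times({t for (_a, t) in values})
    tindex = {t: j for j, t in enumerate(times)}
    mat = np.full((len(geoms), len(times)), np.nan)
    for (a, t), v in values.items():
        if a not in known:
            continue
        if v is not None:
            mat[known[a], tindex[t]] = v
    return SpatioTemporalDataset(areas=list(geoms), times=times, values=mat)


def _json_num(x) -> float | None:
    """NaN-safe number for JSON output (JSON has no NaN)."""
    if x is None:
        return None
    x = float(x)
    return None if not np.isfinite(x) else x


def write_labeled_geojson(
    dataset: SpatioTemporalDataset,
    results: "RunResults",  # noqa: F821 - forward ref, see pipeline module
    time: str,
    path: str | Path,
) -> None:
    """Write one time slice of results as a labeled GeoJSON FeatureCollection.

    Each feature carries ``area_id``, the raw ``value`` (null when missing),
    one ``{statistic, pseudo_p, label}`` object per enabled method, and the
    aggregate ``{category, agreement}`` assignment.
    """
    ti = dataset.time_index(time)  # raises KeyError for unknown time
    local = results.local
    sel = local[local["time"] == time].set_index(["area_id", "method"])
    agg = results.aggregate
    agg_sel = agg[agg["time"] == time].set_index("area_id") if len(agg) else None
    features = []
    for i, area in enumerate(dataset.areas):
        value = dataset.values[i, ti]
        props: dict = {"area_id": area.area_id, "value": _json_num(value)}
        if area.name is not None:
            props["name"] = area.name
        for method in results.methods:
            key = (area.area_id, method)
            if key in sel.index:
                row = sel.loc[key]
                props[method] = {
                    "statistic": _json_num(row["statistic"]),
                    "pseudo_p": _json_num(row["pseudo_p"]),
                    "label": row["label"],
                }
            else:
                props[method] = {"statistic": None, "pseudo_p": None, "label": MISSING_LABEL}
        if agg_sel is not None and area.area_id in agg_sel.index:
            arow = agg_sel.loc[area.area_id]
            props["aggregate"] = {
                "category": arow["category"],
                "agreement": _json_num(arow["agreement"]),
            }
        else:
            props["aggregate"] = {"category": MISSING_LABEL, "agreement": None}
        features.append(
            {"type": "Feature", "properties": props, "geometry": geom_mapping(area.geometry)}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


RESULT_COLUMNS = [
    "area_id",
    "time",
    "method",
    "statistic",
    "permutation_mean",
    "permutation_sd",
    "standardized",
    "pseudo_p",
    "significant",
    "label",
]


def write_results_csv(results_df, path: str | Path) -> None:
    """Write the long local-results table, one row per (area, time, method).

    Row order is the stable (area, time, method) order the pipeline emits;
    reruns with the same seed produce byte-identical files.
    """
    if len(results_df) == 0:
        raise DataFormatError("results table is empty")
    cols = [c for c in RESULT_COLUMNS if c in results_df.columns]
    results_df[cols].to_csv(path, index=False, na_rep="")
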