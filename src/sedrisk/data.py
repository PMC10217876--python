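"""Domain containers, validation, and readers/writers.

The central container is :class:`SamplePanel`, a long-format table of
site × year × analyte sediment concentrations (mg·kg⁻¹ dry weight, with TOC
in percent and pH unitless).  Geometry layers (geochemical-background map,
land-cover mosaic, site points with upstream watercourse polylines) are read
from GeoJSON FeatureCollections in a projected planar CRS; geographic
(degree) coordinates are refused rather than reprojected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from shapely.geometry import LineString, Point, mapping, shape
from shapely.geometry.base import BaseGeometry

from . import reference

PANEL_COLUMNS = ["site_id", "year", "analyte", "value", "flag"]
LANDCOVER_GROUPS = ("anthropogenic", "agricultural", "forest_seminatural", "wetland", "water")

EXPECTED_UNITS = {a: "mg/kg" for a in reference.METALS}
EXPECTED_UNITS["Fe"] = "mg/kg"
EXPECTED_UNITS["TOC"] = "%"
EXPECTED_UNITS["pH"] = "pH"


class ValidationError(ValueError):
    """Raised when an input table or layer violates a domain invariant."""


@dataclass
class SamplePanel:
    """Long-format site × year × analyte concentration panel.

    ``data`` columns: site_id (int), year (int), analyte (str, controlled
    vocabulary), value (float, > 0), flag (str: '' or 'below_loq').
    At most one record per (site, year, analyte); missing combinations are
    represented by absence, never by zero.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        validate_panel(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[int]:
        return sorted(self.data["site_id"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def pivot(self, analytes: Iterable[str] | None = None) -> pd.DataFrame:
        """Wide (site_id, year) × analyte value table."""
        df = self.data
        if analytes is not None:
            df = df[df["analyte"].isin(list(analytes))]
        return df.pivot_table(
            index=["site_id", "year"], columns="analyte", values="value", aggfunc="first"
        )


def validate_panel(df: pd.DataFrame) -> None:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"panel missing columns: {missing}")
    unknown = set(df["analyte"]) - set(reference.ANALYTES)
    if unknown:
        raise ValidationError(f"unknown analytes: {sorted(unknown)}")
    bad = df[~(df["value"] > 0) & (df["analyte"] != "pH")]
    # pH of natural sediments is positive too, but guard it the same way
    bad = pd.concat([bad, df[(df["analyte"] == "pH") & ~(df["value"] > 0)]])
    if len(bad):
        rows = bad[["site_id", "year", "analyte", "value"]].to_dict("records")
        raise ValidationError(f"non-positive concentrations: {rows[:20]}")
    dup = df.duplicated(subset=["site_id", "year", "analyte"])
    if dup.any():
        rows = df.loc[dup, ["site_id", "year", "analyte"]].to_dict("records")
        raise ValidationError(f"duplicate (site, year, analyte) records: {rows[:20]}")


@dataclass
class GBTable:
    """Per-site, per-analyte geochemical background values (mg·kg⁻¹)."""

    entries: dict[tuple[int, str], float]

    def __post_init__(self) -> None:
        for (site, analyte), gb in self.entries.items():
            if not gb > 0:
                raise ValidationError(f"GB must be > 0: site {site}, {analyte} -> {gb}")

    def get(self, site_id: int, analyte: str) -> float:
        try:
            return self.entries[(site_id, analyte)]
        except KeyError:
            raise KeyError(f"no geochemical background for site {site_id}, analyte {analyte}") from None

    def site_means(self) -> pd.Series:
        """Mean background per analyte over sites (documentation companion)."""
        df = self.to_frame()
        return df.groupby("analyte")["gb"].mean()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"site_id": s, "analyte": a, "gb": v} for (s, a), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["site_id", "analyte", "gb"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GBTable":
        df = pd.read_csv(path)
        return cls({(int(r.site_id), str(r.analyte)): float(r.gb) for r in df.itertuples()})


@dataclass
class ToxicityTables:
    """Toxic-response coefficients and TEL/PEL guideline concentrations.

    Defaults reproduce the published tables: Tr for the ten risk-assessed
    metals and TEL/PEL for the seven guideline metals.
    """

    tri_coeff: dict[str, float] = field(default_factory=lambda: dict(reference.TRI_COEFF))
    guidelines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(reference.GUIDELINES)
    )

    def __post_init__(self) -> None:
        for analyte, (tel, pel) in self.guidelines.items():
            if not (0 < tel < pel):
                raise ValidationError(f"require 0 < TEL < PEL for {analyte}: ({tel}, {pel})")


@dataclass
class SiteGeometry:
    """Sampling point plus the watercourse polyline upstream of it.

    ``upstream_line`` starts at the sampling point and runs upstream, in a
    projected planar CRS (metres).
    """

    site_id: int
    point: Point
    upstream_line: LineString
    snap_tolerance_m: float = 1.0

    def __post_init__(self) -> None:
        start = Point(self.upstream_line.coords[0])
        if start.distance(self.point) > self.snap_tolerance_m:
            raise ValidationError(
                f"site {self.site_id}: upstream polyline does not start at the "
                f"sampling point (offset {start.distance(self.point):.1f} m)"
            )

    @property
    def upstream_length_m(self) -> float:
        return self.upstream_line.length


@dataclass
class LayerMap:
    """Polygon layer: geochemical-background classes or land-cover groups.

    ``role`` is 'background' (attributes ``GB_<analyte>``) or 'landcover'
    (attribute ``clc_group``).
    """

    role: str
    features: list[tuple[BaseGeometry, dict]]

    def __post_init__(self) -> None:
        if self.role not in ("background", "landcover"):
            raise ValidationError(f"unknown layer role: {self.role}")
        if not self.features:
            raise ValidationError("empty layer")
        for i, (geom, attrs) in enumerate(self.features):
            if not geom.is_valid:
                raise ValidationError(f"feature {i}: invalid geometry")
            if self.role == "landcover":
                group = attrs.get("clc_group")
                if group not in LANDCOVER_GROUPS:
                    raise ValidationError(
                        f"feature {i}: missing or unknown land-cover group {group!r}"
                    )

    def analytes(self) -> list[str]:
        if self.role != "background":
            return []
        keys = set()
        for _, attrs in self.features:
            keys.update(k[3:] for k in attrs if k.startswith("GB_"))
        return sorted(keys)

    def query(self, geom: BaseGeometry) -> list[int]:
        """Indices of features whose bounding boxes intersect ``geom``
        (STRtree-backed; the tree is built lazily and cached)."""
        if not hasattr(self, "_tree"):
            from shapely import STRtree

            object.__setattr__(self, "_tree", STRtree([g for g, _ in self.features]))
        return list(self._tree.query(geom))


def read_panel(path: str | Path) -> SamplePanel:
    """Read a long-format concentration CSV into a validated panel.

    Columns: ``site_id,year,analyte,value,unit``.  Values written as
    ``"<x"`` (below the limit of quantification) are stored as x/2 and
    flagged ``below_loq``.
    """
    df = pd.read_csv(Path(path), dtype={"value": str})
    required = {"site_id", "year", "analyte", "value", "unit"}
    if not required.issubset(df.columns):
        raise ValidationError(f"panel CSV must have columns {sorted(required)}")
    unknown = set(df["analyte"]) - set(reference.ANALYTES)
    if unknown:
        raise ValidationError(f"unknown analytes: {sorted(unknown)}")
    bad_units = df[df["unit"] != df["analyte"].map(EXPECTED_UNITS)]
    if len(bad_units):
        rows = bad_units[["site_id", "year", "analyte", "unit"]].to_dict("records")
        raise ValidationError(f"unexpected units: {rows[:20]}")

    raw = df["value"].astype(str).str.strip()
    below = raw.str.startswith("<")
    numeric = pd.to_numeric(raw.str.lstrip("<"), errors="coerce")
    if numeric.isna().any():
        rows = df.loc[numeric.isna(), ["site_id", "year", "analyte", "value"]].to_dict("records")
        raise ValidationError(f"non-numeric values: {rows[:20]}")
    out = pd.DataFrame(
        {
            "site_id": df["site_id"].astype(int),
            "year": df["year"].astype(int),
            "analyte": df["analyte"].astype(str),
            "value": numeric.where(~below, numeric / 2.0),
            "flag": below.map({True: "below_loq", False: ""}),
        }
    )
    return SamplePanel(out)


def write_panel(panel: SamplePanel, path: str | Path) -> None:
    df = panel.data.copy()
    df["unit"] = df["analyte"].map(EXPECTED_UNITS)
    df["value"] = [
        f"<{2 * v:.12g}" if f == "below_loq" else f"{v:.12g}"
        for v, f in zip(df["value"], df["flag"])
    ]
    df[["site_id", "year", "analyte", "value", "unit"]].to_csv(path, index=False)


def _check_projected(doc: Mapping, path: Path) -> None:
    crs = doc.get("crs")
    name = ""
    if isinstance(crs, Mapping):
        name = str(crs.get("properties", {}).get("name", ""))
    if not name:
        raise ValidationError(f"{path}: missing CRS metadata; a projected planar CRS is required")
    if "CRS84" in name or "4326" in name:
        raise ValidationError(
            f"{path}: geographic (degree) coordinates are not supported; supply a projected CRS"
        )


def read_layer(path: str | Path, role: str) -> LayerMap:
    """Read a polygon FeatureCollection as a background or land-cover layer."""
    path = Path(path)
    doc = json.loads(path.read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: not a GeoJSON FeatureCollection")
    _check_projected(doc, path)
    features = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        attrs = dict(feat.get("properties") or {})
        if role == "background":
            if not any(k.startswith("GB_") for k in attrs):
                raise ValidationError(f"{path}: feature {i} has no GB_<analyte> attribute")
        features.append((geom, attrs))
    return LayerMap(role=role, features=features)


def write_layer(layer: LayerMap, path: str | Path, crs_name: str = "urn:ogc:def:crs:EPSG::2180") -> None:
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_name}},
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": attrs}
            for geom, attrs in layer.features
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_sites(path: str | Path) -> list[SiteGeometry]:
    """Read site geometries: Point features paired with LineString features.

    Each site contributes two features sharing a ``site_id`` property: its
    sampling point and its upstream watercourse polyline.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    _check_projected(doc, path)
    points: dict[int, Point] = {}
    lines: dict[int, LineString] = {}
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        sid = int(feat["properties"]["site_id"])
        if isinstance(geom, Point):
            points[sid] = geom
        elif isinstance(geom, LineString):
            lines[sid] = geom
    sites = []
    for sid in sorted(points):
        if sid not in lines:
            raise ValidationError(f"site {sid}: missing upstream polyline")
        sites.append(SiteGeometry(site_id=sid, point=points[sid], upstream_line=lines[sid]))
    return sites


def write_sites(sites: list[SiteGeometry], path: str | Path, crs_name: str = "urn:ogc:def:crs:EPSG::2180") -> None:
    features = []
    for s in sites:
        features.append(
            {"type": "Feature", "geometry": mapping(s.point), "properties": {"site_id": s.site_id}}
        )
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(s.upstream_line),
                "properties": {"site_id": s.site_id},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs_name}},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write an index-result table as long-format CSV.

    One row per (site, year, analyte, index); composite rows carry
    analyte='ALL'.  Numeric payload survives a round trip to 12 significant
    digits.
    """
    if results is None or not len(results):
        raise ValidationError("refusing to write empty results")
    df = results.copy()
    df["value"] = df["value"].map(lambda v: f"{v:.12g}" if math.isfinite(v) else "")
    df.to_csv(path, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["value"] = pd.to_numeric(df["value"])
    return df
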