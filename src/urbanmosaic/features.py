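"""Tagged geographic features and GeoJSON ingest.

A tagged feature is the unit of community-mapped geographic information:
one geometry plus a flat map of lowercase key -> value attributes
(e.g. ``landuse=residential``, ``highway=primary``, ``lanes=2``).

All processing happens in one projected CRS with meter units. Geographic
(degree) inputs are rejected rather than silently reprojected, because the
downstream buffering rules are expressed in meters. GeoJSON files therefore
carry a declared projected CRS, either as a legacy ``crs`` member or passed
by the caller — a documented dialect, since RFC 7946 mandates WGS84.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import shapely
from shapely.geometry import LineString, MultiLineString, MultiPolygon, Polygon, box, mapping, shape

logger = logging.getLogger(__name__)

__all__ = [
    "TaggedFeature",
    "TaggedFeatureCollection",
    "read_features",
    "write_features",
    "clip_to_bbox",
]

_GEOGRAPHIC_MARKERS = ("4326", "crs84", "wgs84", "epsg:4269")

#: properties column holding packed auxiliary tags in the extract dialect
PACKED_TAGS_KEY = "other_tags"

_PACKED_RE = re.compile(r'"((?:[^"\\]|\\.)*)"\s*=>\s*"((?:[^"\\]|\\.)*)"')


@dataclass
class TaggedFeature:
    """One geometry with a flat key->value attribute map."""

    id: str
    geometry: object  # shapely Polygon or LineString
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def geometry_kind(self) -> str:
        if isinstance(self.geometry, (Polygon, MultiPolygon)):
            return "polygons"
        return "lines"


@dataclass
class TaggedFeatureCollection:
    """Ordered list of features sharing one projected CRS (meter units)."""

    features: list[TaggedFeature] = field(default_factory=list)
    crs: str = "local-meters"

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, i) -> TaggedFeature:
        return self.features[i]


def _check_projected(crs: str) -> str:
    if crs is None:
        raise ValueError(
            "no CRS declared: pass crs=... or add a 'crs' member to the "
            "GeoJSON; a projected CRS with meter units is required"
        )
    low = str(crs).lower()
    if any(m in low for m in _GEOGRAPHIC_MARKERS):
        raise ValueError(
            f"CRS {crs!r} looks geographic (degrees); reproject to a "
            "projected CRS with meter units first — buffering in meters is "
            "meaningless in degrees"
        )
    return str(crs)


def parse_packed_tags(packed: str) -> dict[str, str]:
    """Parse the ``"key"=>"value","k2"=>"v2"`` packed-tag dialect.

    Unparseable fragments are skipped (logged at DEBUG); keys lowercased.
    """
    out: dict[str, str] = {}
    if not packed:
        return out
    matched_span = 0
    for m in _PACKED_RE.finditer(packed):
        key = m.group(1).replace('\\"', '"').strip().lower()
        val = m.group(2).replace('\\"', '"')
        if key:
            out[key] = val
        matched_span += m.end() - m.start()
    if matched_span == 0 and packed.strip():
        logger.debug("unparseable packed tag string skipped: %r", packed[:80])
    return out


def _normalize_tags(props: dict) -> dict[str, str]:
    """Flatten a properties dict into one lowercase-key tag map.

    Packed auxiliary tags are unpacked first so that explicit columns win
    on key collision.
    """
    tags: dict[str, str] = {}
    packed = props.get(PACKED_TAGS_KEY)
    if isinstance(packed, str):
        tags.update(parse_packed_tags(packed))
    for k, v in props.items():
        if k == PACKED_TAGS_KEY or v is None:
            continue
        tags[str(k).strip().lower()] = str(v)
    return tags


def _repair(geom):
    """Zero-width-buffer style repair; None if still invalid/empty."""
    if geom.is_empty:
        return None
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
        # make_valid may return a collection; keep polygonal parts
        if geom.geom_type == "GeometryCollection":
            parts = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
            if not parts:
                return None
            geom = shapely.union_all(parts)
    if geom.is_empty or not geom.is_valid:
        return None
    return geom


def _explode(fid: str, geom, kind: str):
    """Yield (id, single-part geometry) of the requested kind."""
    if isinstance(geom, (MultiPolygon, MultiLineString)) or geom.geom_type == "GeometryCollection":
        for i, part in enumerate(geom.geoms):
            yield from _explode(f"{fid}#{i}", part, kind)
    elif kind == "polygons" and isinstance(geom, Polygon):
        yield fid, geom
    elif kind == "lines" and isinstance(geom, LineString):
        yield fid, geom


def read_features(source, geometry_kind: str, crs: str | None = None) -> TaggedFeatureCollection:
    """Read a GeoJSON feature collection, keeping one geometry kind.

    Parameters
    ----------
    source : path to a GeoJSON FeatureCollection.
    geometry_kind : ``"polygons"`` or ``"lines"``; features of the other
        kind are excluded. Multi-geometries are exploded into single parts
        that share the parent id with a ``#<part>`` suffix.
    crs : declared projected CRS; overrides any ``crs`` member in the file.

    Features without geometry are skipped with a warning. Tag keys are
    lowercased; a packed auxiliary-tag string column is unpacked into the
    flat tag map, explicit columns winning on key collision.
    """
    if geometry_kind not in ("polygons", "lines"):
        raise ValueError(f"geometry_kind must be 'polygons' or 'lines', got {geometry_kind!r}")
    source = Path(source)
    if not source.exists():
        raise FileNotFoundError(source)
    with open(source) as fh:
        doc = json.load(fh)
    file_crs = None
    if isinstance(doc.get("crs"), dict):
        file_crs = doc["crs"].get("properties", {}).get("name")
    elif isinstance(doc.get("crs"), str):
        file_crs = doc["crs"]
    use_crs = _check_projected(crs if crs is not None else file_crs)

    feats: list[TaggedFeature] = []
    for i, f in enumerate(doc.get("features", [])):
        fid = str(f.get("id", f.get("properties", {}).get("id", i)))
        if f.get("geometry") is None:
            logger.warning("feature %s has no geometry; skipped", fid)
            continue
        geom = shape(f["geometry"])
        geom = _repair(geom)
        if geom is None:
            logger.warning("feature %s invalid after repair; dropped", fid)
            continue
        tags = _normalize_tags(f.get("properties") or {})
        tags.pop("id", None)
        for pid, part in _explode(fid, geom, geometry_kind):
            feats.append(TaggedFeature(id=pid, geometry=part, tags=dict(tags)))
    _check_unique_ids(feats)
    return TaggedFeatureCollection(features=feats, crs=use_crs)


def _check_unique_ids(feats):
    seen = set()
    for f in feats:
        if f.id in seen:
            raise ValueError(f"duplicate feature id {f.id!r}")
        seen.add(f.id)


def write_features(fc: TaggedFeatureCollection, path) -> None:
    """Write a collection as GeoJSON with a declared-CRS member."""
    doc = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": fc.crs}},
        "features": [
            {
                "type": "Feature",
                "id": f.id,
                "geometry": mapping(f.geometry),
                "properties": dict(f.tags),
            }
            for f in fc
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def clip_to_bbox(fc: TaggedFeatureCollection, bbox) -> TaggedFeatureCollection:
    """Keep features intersecting ``bbox`` and clip them to it.

    ``bbox`` is (xmin, ymin, xmax, ymax) in the collection's CRS.
    """
    xmin, ymin, xmax, ymax = bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bbox {bbox}")
    window = box(xmin, ymin, xmax, ymax)
    out: list[TaggedFeature] = []
    for f in fc:
        if not f.geometry.intersects(window):
            continue
        clipped = f.geometry.intersection(window)
        for pid, part in _explode(f.id, clipped, f.geometry_kind):
            out.append(TaggedFeature(id=pid, geometry=part, tags=dict(f.tags)))
    return TaggedFeatureCollection(features=out, crs=fc.crs)
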