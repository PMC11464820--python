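"""The land-cover classification registry.

Tagged features are mapped to 27 urban land-cover classes organised in
three categories — human land use, green cover, and infrastructure — by an
ordered set of rules, each matching key/value tag predicates. A 28th code,
"developed unknown", is reserved for cells a coarse global map labels
built/developed but for which no tagged feature supplies detail.

The default registry shipped here is a documented reconstruction: the class
semantics (including the special roles of code 7 "protected/unknown
vegetation", code 12 "water", code 17 "roads of unknown type", code 26
"linear features under construction or abandoned", and code 28 "developed
unknown") are fixed, while the exact tag lists, per-road-type mean lane
counts, and the priority table are editable configuration — the registry
serializes to YAML precisely so users can substitute published tables.

Overlap between classes is resolved later, at the raster overlay stage, by
priority rank (higher wins); classification itself is multi-membership.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ClassRule",
    "BufferSpec",
    "ClassRegistry",
    "default_registry",
    "DEVELOPED_UNKNOWN",
    "UNCLASSIFIED",
]

#: reserved code for built/developed cells with no tagged-feature detail
DEVELOPED_UNKNOWN = 28
#: diagnostic bin for features matching no rule (not a raster code)
UNCLASSIFIED = 0

CATEGORIES = ("land_use", "green_cover", "infrastructure")


@dataclass
class BufferSpec:
    """Width rule turning a linear feature into a polygon.

    Total width is ``lanes * meters_per_lane`` where ``lanes`` comes from
    the feature's ``lanes`` tag when parseable and from ``default_lanes``
    (the observed mean lane count for that road type) otherwise; or a
    ``fixed_width`` that overrides the lane rule entirely (fences, paths,
    rails). The per-lane constant defaults to 6 m.
    """

    meters_per_lane: float = 6.0
    default_lanes: float = 1.0
    fixed_width: float | None = None

    def width_for(self, tags: dict[str, str]) -> float:
        if self.fixed_width is not None:
            if self.fixed_width <= 0:
                raise ValueError("fixed_width must be positive")
            return self.fixed_width
        lanes = self.default_lanes
        raw = tags.get("lanes")
        if raw is not None:
            try:
                lanes = float(raw)
                if lanes <= 0:
                    raise ValueError
            except ValueError:
                logger.info("non-numeric lanes tag %r; using default %s", raw, self.default_lanes)
                lanes = self.default_lanes
        width = lanes * self.meters_per_lane
        if width <= 0:
            raise ValueError(f"non-positive buffer width from {self}")
        return width


@dataclass
class ClassRule:
    """One land-cover class: tag predicates plus geometry kind.

    ``predicates`` maps a tag key to a set of acceptable values ("*" means
    any value); a feature qualifies when ANY (key, value) pair matches.
    Matching is case-insensitive on both sides.
    """

    class_code: int
    class_name: str
    category: str
    predicates: dict[str, set[str]]
    geometry_kind: str = "polygon"  # or "line"
    buffer: BufferSpec | None = None

    def __post_init__(self):
        if not 1 <= self.class_code <= 27:
            raise ValueError(f"class_code must be 1-27, got {self.class_code}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.predicates:
            raise ValueError(f"rule {self.class_name!r} has no predicates")

    def matches(self, tags: dict[str, str]) -> bool:
        for key, values in self.predicates.items():
            v = tags.get(key)
            if v is None:
                continue
            if "*" in values or v.lower() in {x.lower() for x in values}:
                return True
        return False


@dataclass
class ClassRegistry:
    """Ordered rules + priority ranks + buffer specs.

    ``priority`` maps every class code 1-27 plus code 28 to a unique
    integer rank; in the overlay, higher rank wins the cell.
    """

    rules: list[ClassRule]
    priority: dict[int, int]

    def __post_init__(self):
        if not self.rules:
            raise ValueError("registry has no rules")
        codes = [r.class_code for r in self.rules]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate class codes in registry")
        needed = set(codes) | {DEVELOPED_UNKNOWN}
        missing = needed - set(self.priority)
        if missing:
            raise ValueError(f"priority rank missing for codes {sorted(missing)}")
        ranks = list(self.priority.values())
        if len(set(ranks)) != len(ranks):
            raise ValueError("priority ranks must be unique")

    # -- lookups -----------------------------------------------------------
    def rule_for(self, code: int) -> ClassRule:
        for r in self.rules:
            if r.class_code == code:
                return r
        raise KeyError(code)

    def codes(self) -> list[int]:
        return [r.class_code for r in self.rules]

    def codes_in_category(self, *categories: str) -> set[int]:
        return {r.class_code for r in self.rules if r.category in categories}

    def urban_codes(self) -> set[int]:
        """Codes counting as developed surface: land use + infrastructure
        categories, plus the developed-unknown backfill code."""
        return self.codes_in_category("land_use", "infrastructure") | {DEVELOPED_UNKNOWN}

    def legend(self) -> dict[int, str]:
        leg = {r.class_code: r.class_name for r in self.rules}
        leg[DEVELOPED_UNKNOWN] = "developed_unknown"
        return leg

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "classes": [
                {
                    "code": r.class_code,
                    "name": r.class_name,
                    "category": r.category,
                    "geometry": r.geometry_kind,
                    "predicates": {k: sorted(v) for k, v in r.predicates.items()},
                    "priority": self.priority[r.class_code],
                    **(
                        {
                            "buffer": {
                                "meters_per_lane": r.buffer.meters_per_lane,
                                "default_lanes": r.buffer.default_lanes,
                                "fixed_width": r.buffer.fixed_width,
                            }
                        }
                        if r.buffer
                        else {}
                    ),
                }
                for r in self.rules
            ],
            "developed_unknown_priority": self.priority[DEVELOPED_UNKNOWN],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ClassRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rules, priority = [], {}
        for c in doc["classes"]:
            buf = None
            if "buffer" in c:
                b = c["buffer"]
                buf = BufferSpec(
                    meters_per_lane=b.get("meters_per_lane", 6.0),
                    default_lanes=b.get("default_lanes", 1.0),
                    fixed_width=b.get("fixed_width"),
                )
            rules.append(
                ClassRule(
                    class_code=int(c["code"]),
                    class_name=c["name"],
                    category=c["category"],
                    predicates={k: set(v) for k, v in c["predicates"].items()},
                    geometry_kind=c.get("geometry", "polygon"),
                    buffer=buf,
                )
            )
            priority[int(c["code"])] = int(c["priority"])
        priority[DEVELOPED_UNKNOWN] = int(doc["developed_unknown_priority"])
        return cls(rules=rules, priority=priority)


def _rule(code, name, category, predicates, geometry="polygon", buffer=None):
    return ClassRule(
        class_code=code,
        class_name=name,
        category=category,
        predicates={k: set(v) for k, v in predicates.items()},
        geometry_kind=geometry,
        buffer=buffer,
    )


def default_registry() -> ClassRegistry:
    """The default 27-class reconstruction.

    Land use (codes 1-6) captures human activity by type; green cover
    (7-13) is split by vegetation density/management plus water and barren
    soil; infrastructure (14-27) covers buildings, parking and linear
    features by type and hence hypothetical traffic load. Road widths use
    6 m per lane with per-type mean lane defaults.
    """
    lane = lambda n: BufferSpec(meters_per_lane=6.0, default_lanes=n)
    fixed = lambda w: BufferSpec(fixed_width=w)
    rules = [
        # -- human land use ------------------------------------------------
        _rule(1, "residential", "land_use", {"landuse": ["residential"]}),
        _rule(2, "commercial", "land_use", {"landuse": ["commercial", "retail"], "shop": ["*"]}),
        _rule(3, "industrial", "land_use", {"landuse": ["industrial", "depot", "port"]}),
        _rule(
            4,
            "institutional",
            "land_use",
            {
                "landuse": ["institutional", "education", "religious", "military"],
                "amenity": ["school", "university", "college", "hospital", "townhall"],
            },
        ),
        _rule(
            5,
            "recreational",
            "land_use",
            {
                "landuse": ["recreation_ground", "winter_sports"],
                "leisure": ["golf_course", "stadium", "sports_centre", "pitch", "playground"],
            },
        ),
        _rule(6, "cemetery", "land_use", {"landuse": ["cemetery"], "amenity": ["grave_yard"]}),
        # -- green cover ---------------------------------------------------
        _rule(
            7,
            "protected_unknown_vegetation",
            "green_cover",
            {"boundary": ["protected_area", "national_park"], "leisure": ["nature_reserve"]},
        ),
        _rule(
            8,
            "forest",
            "green_cover",
            {"landuse": ["forest"], "natural": ["wood"]},
        ),
        _rule(
            9,
            "low_vegetation",
            "green_cover",
            {"natural": ["scrub", "grassland", "heath"], "landuse": ["meadow", "farmland", "orchard"]},
        ),
        _rule(
            10,
            "open_green",
            "green_cover",
            {
                "leisure": ["park", "garden", "common", "village_green"],
                "landuse": ["grass", "greenfield", "village_green", "allotments"],
            },
        ),
        _rule(
            11,
            "barren",
            "green_cover",
            {"natural": ["bare_rock", "sand", "beach", "scree"], "landuse": ["brownfield", "quarry"]},
        ),
        _rule(
            12,
            "water",
            "green_cover",
            {"natural": ["water", "bay"], "landuse": ["reservoir", "basin"], "waterway": ["riverbank", "dock"]},
        ),
        _rule(13, "wetland", "green_cover", {"natural": ["wetland", "marsh"]}),
        # -- infrastructure ------------------------------------------------
        _rule(14, "buildings", "infrastructure", {"building": ["*"]}),
        _rule(
            15,
            "parking",
            "infrastructure",
            {"amenity": ["parking"], "landuse": ["garages"], "aeroway": ["apron"]},
        ),
        _rule(
            16,
            "motorway",
            "infrastructure",
            {"highway": ["motorway", "motorway_link", "trunk", "trunk_link"]},
            "line",
            lane(4),
        ),
        _rule(
            17,
            "road_unknown",
            "infrastructure",
            {"highway": ["unclassified", "road"]},
            "line",
            lane(2),
        ),
        _rule(
            18,
            "primary_road",
            "infrastructure",
            {"highway": ["primary", "primary_link"]},
            "line",
            lane(3),
        ),
        _rule(
            19,
            "secondary_road",
            "infrastructure",
            {"highway": ["secondary", "secondary_link"]},
            "line",
            lane(2),
        ),
        _rule(
            20,
            "tertiary_road",
            "infrastructure",
            {"highway": ["tertiary", "tertiary_link"]},
            "line",
            lane(2),
        ),
        _rule(
            21,
            "residential_road",
            "infrastructure",
            {"highway": ["residential", "living_street"]},
            "line",
            lane(2),
        ),
        _rule(22, "service_road", "infrastructure", {"highway": ["service"]}, "line", lane(1)),
        _rule(
            23,
            "hiking_path",
            "infrastructure",
            {"highway": ["path", "footway", "track", "cycleway", "bridleway", "pedestrian", "steps"]},
            "line",
            fixed(2.0),
        ),
        _rule(
            24,
            "railway",
            "infrastructure",
            {"railway": ["rail", "light_rail", "subway", "tram", "narrow_gauge"]},
            "line",
            fixed(6.0),
        ),
        _rule(
            25,
            "fence",
            "infrastructure",
            {"barrier": ["fence", "wall", "hedge", "retaining_wall"]},
            "line",
            fixed(1.0),
        ),
        _rule(
            26,
            "linear_construction",
            "infrastructure",
            {"highway": ["construction"], "railway": ["construction", "abandoned", "disused"]},
            "line",
            lane(2),
        ),
        _rule(
            27,
            "airstrip",
            "infrastructure",
            {"aeroway": ["runway", "taxiway"]},
            "line",
            fixed(30.0),
        ),
    ]
    # Priority order, lowest to highest: land use under green cover, the
    # developed-unknown backfill just above land use, then barren/water,
    # then infrastructure with roads ascending by traffic load, and hiking
    # paths / railways / fences — continuous potential movement corridors
    # or barriers — above all.
    order = [
        1, 2, 3, 4, 5, 6,           # land use (lowest)
        DEVELOPED_UNKNOWN,           # developed unknown
        7, 8, 9, 10, 13,             # vegetation green cover
        11, 12,                      # barren, water
        14, 15,                      # buildings, parking
        22, 21, 17, 20, 19, 18, 16,  # roads by ascending traffic
        27, 26,                      # airstrip, construction linear
        23, 24, 25,                  # hiking path, railway, fence (highest)
    ]
    priority = {code: rank for rank, code in enumerate(order, start=1)}
    return ClassRegistry(rules=rules, priority=priority)
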