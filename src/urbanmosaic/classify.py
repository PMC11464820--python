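"""Classify tagged features into land-cover classes; buffer linear features.

Classification is multi-membership: a feature lands in every class whose
predicates it satisfies (overlaps are resolved later by raster priority,
not by vector precedence). Features matching no rule are returned under a
reserved unclassified bin for diagnostics.

Linear features are converted to polygons with flat-capped buffers whose
total width follows the per-road-type lane rule (6 m per lane by default,
lanes read from the ``lanes`` tag when parseable, imputed from the road
type's mean otherwise) or a fixed width for fences, paths and rails.
"""

from __future__ import annotations

import logging

from .features import TaggedFeature, TaggedFeatureCollection
from .registry import UNCLASSIFIED, ClassRegistry

logger = logging.getLogger(__name__)

__all__ = ["classify_features", "buffer_lines", "is_elevated"]

_ELEVATED_KEYS = ("bridge", "tunnel")
_FALSY = {"no", "false", "0"}


def is_elevated(feature: TaggedFeature) -> bool:
    """True for bridge/tunnel-tagged segments.

    Such segments cross above or below the surrounding landscape, so the
    overlay can be asked not to let them overwrite the layer beneath
    (keeping e.g. the river or the park under a bridge passable in the
    map, the way an animal would experience it).
    """
    for key in _ELEVATED_KEYS:
        v = feature.tags.get(key)
        if v is not None and v.lower() not in _FALSY:
            return True
    return False


def classify_features(
    fc: TaggedFeatureCollection, reg: ClassRegistry
) -> dict[int, TaggedFeatureCollection]:
    """Map features to classes; key 0 (UNCLASSIFIED) collects non-matches.

    A feature appears under every class whose predicates it satisfies and
    whose geometry kind it has; membership is independent of input order.
    """
    if not reg.rules:
        raise ValueError("registry has no rules")
    out: dict[int, list[TaggedFeature]] = {r.class_code: [] for r in reg.rules}
    out[UNCLASSIFIED] = []
    kind_map = {"polygon": "polygons", "line": "lines"}
    for f in fc:
        hit = False
        for rule in reg.rules:
            if kind_map[rule.geometry_kind] != f.geometry_kind:
                continue
            if rule.matches(f.tags):
                out[rule.class_code].append(f)
                hit = True
        if not hit:
            out[UNCLASSIFIED].append(f)
    return {
        code: TaggedFeatureCollection(features=feats, crs=fc.crs)
        for code, feats in out.items()
    }


def buffer_lines(
    lines: TaggedFeatureCollection, reg: ClassRegistry, class_code: int | None = None
) -> TaggedFeatureCollection:
    """Replace each line with a flat-capped polygon of its rule's width.

    ``class_code`` selects which rule's buffer spec to use; when omitted,
    the first matching line rule is used per feature. Zero-length lines
    are dropped with a warning; original tags are preserved.
    """
    out = []
    for f in lines:
        if f.geometry_kind != "lines":
            raise ValueError(f"feature {f.id} is not a line")
        if f.geometry.length == 0:
            logger.warning("zero-length line %s dropped", f.id)
            continue
        if class_code is not None:
            rule = reg.rule_for(class_code)
        else:
            rule = next(
                (r for r in reg.rules if r.geometry_kind == "line" and r.matches(f.tags)),
                None,
            )
            if rule is None:
                logger.warning("line %s matches no line rule; dropped", f.id)
                continue
        if rule.buffer is None:
            raise ValueError(f"line rule {rule.class_name!r} has no buffer spec")
        width = rule.buffer.width_for(f.tags)
        poly = f.geometry.buffer(width / 2.0, cap_style="flat", join_style="mitre")
        if poly.is_empty:
            logger.warning("buffering produced empty polygon for %s; dropped", f.id)
            continue
        out.append(TaggedFeature(id=f.id, geometry=poly, tags=dict(f.tags)))
    return TaggedFeatureCollection(features=out, crs=lines.crs)
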