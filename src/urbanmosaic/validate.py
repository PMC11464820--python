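"""Completeness, accuracy (confusion matrix / Kappa / precision), and
paired-area regression.

Completeness asks how much of the study area the tagged features alone
explain before global-map backfill; accuracy cross-validates stratified
random cells against reference labels; the paired-area regression mirrors
the comparison of per-layer building surface areas against a reference
footprint layer.

Confusion-matrix orientation is fixed: predicted on rows, reference on
columns, so per-class precision is the row-normalized diagonal
(TP / (TP + FP)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .raster import CategoricalRaster
from .registry import DEVELOPED_UNKNOWN, ClassRegistry

logger = logging.getLogger(__name__)

__all__ = [
    "CompletenessReport",
    "ConfusionMatrix",
    "completeness",
    "urban_proportion",
    "stratified_sample",
    "confusion",
    "kappa",
    "precision",
    "area_regression",
]

#: codes whose sub-categorization is unknown: protected-area vegetation,
#: roads of unknown type, developed-unknown
UNKNOWN_SUBCATEGORY_CODES = (7, 17, DEVELOPED_UNKNOWN)


@dataclass
class CompletenessReport:
    overall_completeness: float
    per_class_area_diff: dict[int, float]
    per_class_area_ratio: dict[int, float]
    unknown_subcategory_share: dict[int, float]
    urban_proportion: float


@dataclass
class ConfusionMatrix:
    """Square count matrix over class labels; rows predicted, cols reference."""

    labels: list[int]
    counts: np.ndarray = field(default=None)

    def __post_init__(self):
        k = len(self.labels)
        if self.counts is None:
            self.counts = np.zeros((k, k), dtype=np.int64)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def completeness(
    osm_r: CategoricalRaster, global_r: CategoricalRaster, reg: ClassRegistry
) -> CompletenessReport:
    """Coverage of the feature-derived raster against the global raster.

    Overall completeness is the fraction of cells the tagged features
    explain (1 - nodata fraction). Per class, the absolute difference in
    total area between the feature-only layer and the global layer is
    reported, alongside a normalized ratio min(1, area_osm/area_global)
    for cross-study comparability.
    """
    if not osm_r.same_grid(global_r):
        raise ValueError("rasters are not on a common grid")
    total_cells = osm_r.values.size
    void = int(np.count_nonzero(osm_r.values == osm_r.nodata))
    overall = 1.0 - void / total_cells

    codes = sorted(
        (set(np.unique(osm_r.values)) | set(np.unique(global_r.values)))
        - {osm_r.nodata, global_r.nodata}
    )
    diffs, ratios = {}, {}
    for c in codes:
        a_osm = osm_r.area_of(c)
        a_glob = global_r.area_of(c)
        diffs[c] = abs(a_osm - a_glob)
        ratios[c] = min(1.0, a_osm / a_glob) if a_glob > 0 else (1.0 if a_osm == 0 else float("inf"))

    total_area = total_cells * osm_r.cell_area
    unknown = {c: osm_r.area_of(c) / total_area for c in UNKNOWN_SUBCATEGORY_CODES}
    return CompletenessReport(
        overall_completeness=overall,
        per_class_area_diff=diffs,
        per_class_area_ratio=ratios,
        unknown_subcategory_share=unknown,
        urban_proportion=urban_proportion(osm_r, reg),
    )


def urban_proportion(r: CategoricalRaster, reg: ClassRegistry) -> float:
    """Fraction of the study area under land-use or infrastructure classes."""
    urban = reg.urban_codes()
    return float(np.count_nonzero(np.isin(r.values, list(urban)))) / r.values.size


def stratified_sample(
    r: CategoricalRaster, n_per_class: int, seed: int
) -> list[tuple[tuple[int, int], int]]:
    """Sample cells uniformly without replacement within each class.

    Returns ``((row, col), predicted_code)`` pairs; classes with fewer
    than ``n_per_class`` cells are exhausted. Reproducible under ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    present = sorted(set(np.unique(r.values)) - {r.nodata})
    if not present:
        raise ValueError("raster holds no classified cells")
    rng = np.random.default_rng(seed)
    out = []
    for code in present:
        rows, cols = np.nonzero(r.values == code)
        k = min(n_per_class, rows.size)
        pick = rng.choice(rows.size, size=k, replace=False)
        for i in pick:
            out.append(((int(rows[i]), int(cols[i])), int(code)))
    return out


def confusion(pairs, labels=None) -> ConfusionMatrix:
    """Tally (predicted, reference) pairs into a confusion matrix."""
    pairs = list(pairs)
    if labels is None:
        labels = sorted({p for p, _ in pairs} | {q for _, q in pairs})
    labels = list(labels)
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for pred, ref in pairs:
        if pred not in index or ref not in index:
            raise ValueError(f"code outside label set: ({pred}, {ref})")
        counts[index[pred], index[ref]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's Kappa: agreement corrected for chance coincidence.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement rate
    (trace/N) and p_e the agreement expected from the marginals. Returns
    1.0 in the degenerate single-class case where p_o = p_e = 1.
    """
    n = cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    p_o = np.trace(c) / n
    p_e = float(c.sum(axis=1) @ c.sum(axis=0)) / n**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def precision(cm: ConfusionMatrix) -> dict[int, float | None]:
    """Per-class precision: diagonal over row sum (TP / (TP + FP)).

    Classes never predicted (zero row sum) are reported as None, not 0.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    out: dict[int, float | None] = {}
    row_sums = cm.counts.sum(axis=1)
    for i, code in enumerate(cm.labels):
        out[code] = float(cm.counts[i, i] / row_sums[i]) if row_sums[i] > 0 else None
    return out


def area_regression(x, y) -> tuple[float, float, float]:
    """OLS fit y = a + b*x between paired per-study-area totals.

    Returns (slope, intercept, r_squared). Mirrors regressing reference
    building surface areas on areas estimated from another layer.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; slope undefined")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    return float(slope), float(intercept), float(model.rsquared)
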