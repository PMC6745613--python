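"""Decision products from a predicted coverage surface.

Coldspots — contiguous pockets of low coverage that sustain transmission —
are classed by within-map quantile cutpoints (lowest 20%, 50% and 80% of
cells).  District-style aggregates are unweighted means of the cell
predictions inside each unit (a population-weighted variant is available),
which feed the 80%-coverage attainment check of the WHO Global Vaccine
Action Plan.  Unvaccinated-count integration multiplies cell-level
non-coverage by a matching population surface; when the coverage surface
refers to 12-23-month-olds used as a proxy for under-5 coverage, say so in
the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import block_average_weighted
from .inference import GridPrediction

__all__ = [
    "ColdspotMap",
    "aggregate_to_units",
    "coldspot_classes",
    "threshold_attainment",
    "unvaccinated_counts",
]

_CLASS_LABELS = ("lowest20", "lowest50", "lowest80", "above")


@dataclass
class ColdspotMap:
    """Cell classes (nested lowest-20/50/80 sets) and the cutpoints used."""

    classes: np.ndarray  # per-cell label from _CLASS_LABELS
    cutpoints: tuple  # the three coverage values at the class boundaries
    quantiles: tuple = (0.2, 0.5, 0.8)

    def counts(self) -> dict:
        vals, cnts = np.unique(self.classes, return_counts=True)
        out = {label: 0 for label in _CLASS_LABELS}
        out.update(dict(zip(vals.tolist(), cnts.tolist())))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": self.classes})


def aggregate_to_units(
    pred, unit_membership: np.ndarray, n_units: int = None, weights: np.ndarray = None
) -> np.ndarray:
    """Mean predicted coverage per unit (district), cells averaged unweighted.

    ``pred`` may be a :class:`GridPrediction` or a plain cell-mean vector.
    Pass ``weights`` (e.g. population) for a weighted variant.  Every unit
    must contain at least one predicted cell.
    """
    values = pred.mean if isinstance(pred, GridPrediction) else np.asarray(pred, float)
    return block_average_weighted(values, unit_membership, n_areas=n_units, weights=weights)


def coldspot_classes(pred, quantiles=(0.2, 0.5, 0.8)) -> ColdspotMap:
    """Class cells by coverage quantile: lowest 20%, lowest 50%, lowest 80%.

    Cutpoints are linear-interpolation (type-7) quantiles of the cell-mean
    distribution; a cell at or below a cutpoint belongs to that class (ties
    inclusive downward), so the classes are nested by construction.
    """
    values = pred.mean if isinstance(pred, GridPrediction) else np.asarray(pred, float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty prediction")
    qs = tuple(sorted(quantiles))
    cuts = tuple(float(np.quantile(values, q)) for q in qs)  # numpy default = type 7
    full = pred.mean if isinstance(pred, GridPrediction) else np.asarray(pred, float)
    classes = np.full(full.shape, "above", dtype=object)
    for label, cut in zip(("lowest80", "lowest50", "lowest20"), reversed(cuts)):
        classes[np.isfinite(full) & (full <= cut)] = label
    classes[~np.isfinite(full)] = "nodata"
    return ColdspotMap(classes=classes.astype(str), cutpoints=cuts, quantiles=qs)


def threshold_attainment(unit_means, threshold: float = 0.80):
    """Flag units attaining a coverage target (closed threshold: mean >= target).

    Returns ``(flags, percent_attaining)``.
    """
    unit_means = np.asarray(unit_means, dtype=float)
    flags = unit_means >= threshold
    pct = 100.0 * float(flags.sum()) / len(flags) if len(flags) else float("nan")
    return flags, pct


def unvaccinated_counts(
    pred, population: np.ndarray, level: str = "national", unit_membership=None, n_units=None
):
    """Integrate non-coverage with a population surface: sum pop * (1 - p).

    ``level`` is one of 'cell', 'unit' or 'national'; 'unit' needs
    ``unit_membership``.  The population raster must already be aligned to
    the prediction grid (same cell order).
    """
    values = pred.mean if isinstance(pred, GridPrediction) else np.asarray(pred, float)
    population = np.asarray(population, dtype=float)
    if population.shape != values.shape:
        raise ValueError("population raster is not aligned to the prediction grid")
    cell = population * (1.0 - values)
    if level == "cell":
        return cell
    if level == "unit":
        if unit_membership is None:
            raise ValueError("unit_membership is required at level='unit'")
        unit_membership = np.asarray(unit_membership, dtype=int)
        if n_units is None:
            n_units = int(unit_membership.max()) + 1
        inside = unit_membership >= 0
        return np.bincount(unit_membership[inside], weights=cell[inside], minlength=n_units)
    if level == "national":
        return float(np.nansum(cell))
    raise ValueError("level must be 'cell', 'unit' or 'national'")
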