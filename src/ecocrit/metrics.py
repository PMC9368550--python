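"""Class-level landscape metrics and the landscape structure security index.

The landscape ecological structure security index (LESSI) scores each
analysis unit (county) of a categorical land-cover raster by how intact its
landscape mosaic is:

    LESSI = 1 - [(PD + ED) x 2.5 V],    V = 0.5 AWMSI + 0.3 F + 0.2 D

where PD is patch density (patches per km^2), ED edge density (km of
inter-class edge per km^2), AWMSI the area-weighted mean shape index, F the
area-weighted mean patch fractal dimension and D the landscape division
index.  PD, ED, AWMSI, F and D follow the FRAGSTATS-standard raster
definitions; because the raw quantities are not commensurable inside the
bracket, each component is min-max rescaled across units within a period and
the bracket is normalised by its cross-unit maximum so that LESSI lies in
[0, 1] (1 = fully intact, 0 = most fragmented unit).

Patch perimeters include exposed edges on the unit border (so a square patch
filling its unit has shape index 1), while edge density counts only edges
interior to the unit, which keeps units independent of their neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Patch",
    "DEFAULT_V_WEIGHTS",
    "delineate_patches",
    "compute_metrics",
    "fragmentation_v",
    "lessi_from_metrics",
    "lessi_values",
    "lessi_raster",
    "lessi_moving_window",
]

DEFAULT_V_WEIGHTS = (0.5, 0.3, 0.2)

_METRIC_COLS = ["PD", "ED", "AWMSI", "F", "D"]


@dataclass
class Patch:
    """A maximal connected set of same-class cells."""

    id: int
    klass: int
    n_cells: int
    area: float  # km^2
    perimeter: float  # km, exposed cell edges incl. raster/unit boundary
    cells: np.ndarray = field(repr=False)  # (n, 2) array of (row, col)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _label_classes(landcover: np.ndarray, connectivity: int) -> np.ndarray:
    """Label maximal same-class components; 0 marks background/nodata."""
    labels = np.zeros(landcover.shape, dtype=np.int64)
    offset = 0
    for klass in np.unique(landcover):
        if klass <= 0:
            continue
        lab, n = ndimage.label(landcover == klass, structure=_structure(connectivity))
        labels[lab > 0] = lab[lab > 0] + offset
        offset += n
    return labels


def _perimeter_counts(labels: np.ndarray, n_labels: int) -> np.ndarray:
    """Exposed-edge count per label (4-neighbour edges, boundary included)."""
    areas = np.bincount(labels.ravel(), minlength=n_labels + 1)
    same_h = (labels[:, 1:] == labels[:, :-1]) & (labels[:, 1:] > 0)
    same_v = (labels[1:, :] == labels[:-1, :]) & (labels[1:, :] > 0)
    internal = np.bincount(labels[:, 1:][same_h].ravel(), minlength=n_labels + 1)
    internal += np.bincount(labels[1:, :][same_v].ravel(), minlength=n_labels + 1)
    return 4 * areas - 2 * internal


def delineate_patches(
    landcover: np.ndarray,
    connectivity: int = 8,
    cell_size: float = 1.0,
) -> tuple[list[Patch], np.ndarray]:
    """Partition a categorical raster into maximal same-class patches.

    Returns the patch list and a label raster (labels 1..n, 0 = nodata).
    Cells with class code <= 0 are treated as nodata.
    """
    lc = np.asarray(landcover)
    if lc.size == 0 or not np.any(lc > 0):
        raise ValueError("cannot delineate patches on an empty raster")
    labels = _label_classes(lc, connectivity)
    n = int(labels.max())
    perim = _perimeter_counts(labels, n)
    patches: list[Patch] = []
    # index cells per label in one pass
    order = np.argsort(labels, axis=None, kind="stable")
    flat = labels.ravel()[order]
    starts = np.searchsorted(flat, np.arange(1, n + 1))
    ends = np.searchsorted(flat, np.arange(1, n + 1), side="right")
    rows, cols = np.unravel_index(order, lc.shape)
    for lab in range(1, n + 1):
        sel = slice(starts[lab - 1], ends[lab - 1])
        cells = np.column_stack([rows[sel], cols[sel]])
        r, c = cells[0]
        patches.append(
            Patch(
                id=lab,
                klass=int(lc[r, c]),
                n_cells=cells.shape[0],
                area=cells.shape[0] * cell_size**2,
                perimeter=perim[lab] * cell_size,
                cells=cells,
            )
        )
    return patches, labels


def _fractal_dim(perimeter: float, area: float) -> float:
    # 2 ln(0.25 p) / ln a, with the removable singularity at a = 1 km^2
    # (single 1-km cell) set to the minimum dimension 1; clipped to [1, 2].
    if area <= 1.0:
        return 1.0
    f = 2.0 * np.log(0.25 * perimeter) / np.log(area)
    return float(np.clip(f, 1.0, 2.0))


def _unit_metrics(
    lc: np.ndarray,
    connectivity: int,
    cell_size: float,
    ed_level: str,
    unit_cells: int | None = None,
) -> dict[str, float]:
    """Metrics for one unit; ``lc`` has 0 outside the unit.

    ``unit_cells`` is the unit's total cell count (nodata included), the
    reference area A for PD/ED/D; defaults to the valid-cell count.
    """
    inside = lc > 0
    n_valid = int(inside.sum())
    area_total = (unit_cells if unit_cells is not None else n_valid) * cell_size**2
    labels = _label_classes(lc, connectivity)
    n = int(labels.max())
    areas_cells = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    perim = _perimeter_counts(labels, n)[1:] * cell_size
    areas = areas_cells * cell_size**2

    # interior inter-class edges (unit border excluded from ED)
    diff_h = (lc[:, 1:] != lc[:, :-1]) & (lc[:, 1:] > 0) & (lc[:, :-1] > 0)
    diff_v = (lc[1:, :] != lc[:-1, :]) & (lc[1:, :] > 0) & (lc[:-1, :] > 0)
    interior_edge_len = (int(diff_h.sum()) + int(diff_v.sum())) * cell_size

    pd_ = n / area_total
    # class-level ED sums count each inter-class edge once per adjoining
    # class; the landscape-mosaic variant counts each edge once.
    ed = (2.0 if ed_level == "class" else 1.0) * interior_edge_len / area_total

    w = areas / areas.sum()
    shape_idx = 0.25 * perim / np.sqrt(areas)
    awmsi = float(np.sum(shape_idx * w))
    frac = float(np.sum([_fractal_dim(p, a) * wi for p, a, wi in zip(perim, areas, w)]))
    division = float(1.0 - np.sum((areas / area_total) ** 2))
    return {
        "n_cells": n_valid,
        "area": area_total,
        "n_patches": n,
        "PD": pd_,
        "ED": ed,
        "AWMSI": awmsi,
        "F": frac,
        "D": division,
    }


def compute_metrics(
    landcover: np.ndarray,
    zones: np.ndarray,
    connectivity: int = 8,
    cell_size: float = 1.0,
    ed_level: str = "class",
) -> pd.DataFrame:
    """Per-unit class-level landscape metrics.

    Patches are clipped to their unit before measurement.  Units with no
    valid cell are flagged ``missing`` and excluded from downstream
    rescaling.  ``ed_level`` selects class-level edge sums (``"class"``,
    default) or the landscape-mosaic count (``"mosaic"``).
    """
    lc = np.asarray(landcover)
    zn = np.asarray(zones)
    if lc.shape != zn.shape:
        raise ValueError(f"landcover {lc.shape} and zones {zn.shape} shapes differ")
    if ed_level not in {"class", "mosaic"}:
        raise ValueError(f"ed_level must be 'class' or 'mosaic', got {ed_level!r}")
    records = []
    for unit in np.unique(zn):
        sel = zn == unit
        clipped = np.where(sel, lc, 0)
        if not np.any(clipped > 0):
            rec = {"unit": int(unit), "missing": True}
            rec.update({k: np.nan for k in ["n_cells", "area", "n_patches", *_METRIC_COLS]})
            records.append(rec)
            continue
        rec = {"unit": int(unit), "missing": False}
        rec.update(
            _unit_metrics(clipped, connectivity, cell_size, ed_level, int(sel.sum()))
        )
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("unit")


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(x), np.nanmax(x)
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def fragmentation_v(
    awmsi: np.ndarray | float,
    f: np.ndarray | float,
    d: np.ndarray | float,
    weights: tuple[float, float, float] = DEFAULT_V_WEIGHTS,
) -> np.ndarray | float:
    """Fragmentation composite V from rescaled-to-[0,1] components."""
    if not np.isclose(sum(weights), 1.0, atol=1e-9):
        raise ValueError(f"V weights must sum to 1, got {weights}")
    a, b, g = weights
    return a * np.asarray(awmsi) + b * np.asarray(f) + g * np.asarray(d)


def lessi_values(
    pd_ed_scaled: np.ndarray | float,
    v: np.ndarray | float,
    bracket_scale: float = 1.0,
) -> np.ndarray | float:
    """LESSI from a rescaled (PD'+ED') term, V and the bracket normaliser."""
    bracket = np.asarray(pd_ed_scaled) * 2.5 * np.asarray(v)
    if bracket_scale > 0:
        bracket = bracket / bracket_scale
    return 1.0 - bracket


def lessi_from_metrics(
    metrics: pd.DataFrame,
    weights: tuple[float, float, float] = DEFAULT_V_WEIGHTS,
) -> pd.DataFrame:
    """Attach rescaled components, V and LESSI to a per-unit metrics table.

    Min-max rescaling is done across the non-missing units of the table
    (i.e. within one period); the bracket (PD'+ED') x 2.5 V is then divided
    by its cross-unit maximum, guaranteeing LESSI in [0, 1].
    """
    out = metrics.copy()
    ok = ~out["missing"]
    scaled = {c: _minmax(out.loc[ok, c].to_numpy(float)) for c in _METRIC_COLS}
    v = fragmentation_v(scaled["AWMSI"], scaled["F"], scaled["D"], weights)
    bracket = (scaled["PD"] + scaled["ED"]) * 2.5 * v
    bmax = bracket.max() if len(bracket) else 0.0
    lessi = 1.0 - (bracket / bmax if bmax > 0 else bracket)
    for c in _METRIC_COLS:
        out.loc[ok, c + "_s"] = scaled[c]
    out.loc[ok, "V"] = v
    out.loc[ok, "LESSI"] = lessi
    return out


def lessi_raster(zones: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """Broadcast per-unit LESSI onto the grid (NaN for missing units)."""
    zn = np.asarray(zones)
    out = np.full(zn.shape, np.nan)
    for unit, row in table.iterrows():
        if not row["missing"]:
            out[zn == unit] = row["LESSI"]
    return out


def lessi_moving_window(
    landcover: np.ndarray,
    window: int = 32,
    step: int = 16,
    connectivity: int = 8,
    cell_size: float = 1.0,
) -> np.ndarray:
    """Moving-window LESSI variant.

    Metrics are computed in square windows on a coarse grid of centres and
    each cell takes the value of its nearest centre; rescaling is across
    windows.  Provided as the alternative to per-unit (county) analysis.
    """
    lc = np.asarray(landcover)
    half = window // 2
    rows = np.arange(half, lc.shape[0], step)
    cols = np.arange(half, lc.shape[1], step)
    recs = []
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            sub = lc[max(0, r - half): r + half, max(0, c - half): c + half]
            rec = {"unit": i * len(cols) + j, "missing": not np.any(sub > 0)}
            if not rec["missing"]:
                rec.update(_unit_metrics(sub, connectivity, cell_size, "class", sub.size))
            recs.append(rec)
    table = lessi_from_metrics(pd.DataFrame.from_records(recs).set_index("unit"))
    out = np.full(lc.shape, np.nan)
    rr, cc = np.meshgrid(np.arange(lc.shape[0]), np.arange(lc.shape[1]), indexing="ij")
    ri = np.clip(np.round((rr - half) / step).astype(int), 0, len(rows) - 1)
    ci = np.clip(np.round((cc - half) / step).astype(int), 0, len(cols) - 1)
    vals = table["LESSI"].to_numpy()
    out[:] = vals[ri * len(cols) + ci]
    return out
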