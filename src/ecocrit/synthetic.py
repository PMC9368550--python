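"""Seeded synthetic multi-period landscapes with known ground truth.

The generator emulates the study conditions of a gridded (1 km) ecological
barrier analysis: a 7-class land-cover mosaic, four co-registered ecosystem
-service surfaces, continuous driver surfaces, a rectangular tiling of
analysis units (counties), and a multi-period sequence in which ecologically
critical area (ECA) expands or degrades at planted locations with known
geometry (edge rings, isolated blobs, interior holes/cores).

Planted criticality is specified in ECI units and back-solved to service
values through each unit's landscape-structure security index (LESSI),
which the generator computes with the same metrics code the analysis
pipeline uses.  The resulting ECI distribution has three strata:

* background cells (class means x unit LESSI), well below criticality;
* a near-critical *shoulder* population on the fringe of critical areas,
  normally distributed just below the critical onset — this narrow mode is
  the terminal peak of the ECI frequency curve and therefore anchors the
  extracted threshold;
* critical cells at ``eci_floor`` plus a steep truncated-exponential tail,
  monotone enough that it contributes no further histogram peak.

Each service layer carries two calibration cells holding the fixed dynamic
range [0, ``anchor_high``] so min-max normalisation is exact and planted
ECI targets are realised to within the cell-noise level.  All randomness
derives from per-operation substreams of one scenario seed, so outputs are
bit-identical for identical configurations and adding an operation never
perturbs earlier draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .metrics import compute_metrics, lessi_from_metrics, lessi_raster

__all__ = [
    "LAND_CLASSES", "CLASS_CODES", "SERVICE_NAMES", "DRIVER_NAMES",
    "ChangeRule", "ScenarioConfig", "PlantedChange", "SyntheticTruth",
    "SyntheticScenario", "DEFAULT_CHANGE_RULES", "make_zones",
    "generate_landcover", "generate_services", "generate_drivers",
    "generate_timeseries",
]

LAND_CLASSES = {
    1: "cropland",
    2: "forest",
    3: "grassland",
    4: "water",
    5: "wetland",
    6: "impervious",
    7: "other",
}
CLASS_CODES = {v: k for k, v in LAND_CLASSES.items()}

SERVICE_NAMES = ("carbon", "water_yield", "soil_conservation", "habitat_quality")

# generated driver surfaces; forest/grass/cropland shares and the distance
# layers are derived downstream from the land cover itself
DRIVER_NAMES = (
    "dem", "slope", "temperature", "precipitation",
    "gdp", "population", "nightlight",
)

# class-conditioned service means (service units); forest > grassland >
# cropland > impervious for every service, all well below the criticality
# range so the background leaves the near-critical bands clear
_BASE_MEANS = {
    "forest": 0.33, "wetland": 0.31, "grassland": 0.27, "water": 0.24,
    "cropland": 0.20, "other": 0.16, "impervious": 0.12,
}
_SERVICE_TWEAK = {  # small deterministic per-service offsets
    "carbon": 0.000, "water_yield": -0.008, "soil_conservation": 0.006,
    "habitat_quality": -0.004,
}

# relative class abundance used when sowing land-cover seeds
_CLASS_WEIGHTS = {
    "forest": 0.30, "grassland": 0.20, "cropland": 0.18, "impervious": 0.10,
    "other": 0.09, "water": 0.07, "wetland": 0.06,
}

_MODES = ("expansion", "degradation")
_KINDS = ("edge", "isolated", "interior")

# rng substream codes, one per operation
_S_LANDCOVER, _S_SERVICES, _S_DRIVERS, _S_TRUTH, _S_TAIL, _S_SHOULDER, _S_PLANT = range(1, 8)


@dataclass(frozen=True)
class ChangeRule:
    """One planted change: (period pair, mode, geometric kind, magnitude).

    ``magnitude`` is the planted cell count as a fraction of the current
    true-ECA cell count.
    """

    period_pair: tuple[str, str]
    mode: str
    kind: str
    magnitude: float

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if not 0.0 < self.magnitude < 1.0:
            raise ValueError(f"magnitude must lie in (0, 1), got {self.magnitude}")


DEFAULT_CHANGE_RULES: tuple[ChangeRule, ...] = (
    # degradation-expansion-degradation sequence covering all six types
    ChangeRule(("2005", "2010"), "degradation", "edge", 0.015),
    ChangeRule(("2005", "2010"), "degradation", "isolated", 0.002),
    ChangeRule(("2005", "2010"), "expansion", "edge", 0.005),
    ChangeRule(("2010", "2015"), "expansion", "edge", 0.012),
    ChangeRule(("2010", "2015"), "expansion", "interior", 0.003),
    ChangeRule(("2010", "2015"), "expansion", "isolated", 0.004),
    ChangeRule(("2010", "2015"), "degradation", "edge", 0.005),
    ChangeRule(("2015", "2019"), "degradation", "edge", 0.015),
    ChangeRule(("2015", "2019"), "degradation", "interior", 0.006),
    ChangeRule(("2015", "2019"), "expansion", "edge", 0.005),
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of one synthetic scenario.

    The defaults are the conditions under which the pipeline's recovery
    guarantees were established; see the methods note for the calibration
    analysis behind the planted-signal parameters.
    """

    seed: int = 0
    shape: tuple[int, int] = (256, 256)
    cell_size: float = 1.0  # km
    n_zones: int = 25
    periods: tuple[str, ...] = ("2005", "2010", "2015", "2019")
    change_rules: tuple[ChangeRule, ...] = DEFAULT_CHANGE_RULES
    driver_effect: tuple[str, int, float] | None = ("precipitation", 1, 2.0)
    # service surfaces
    n_services: int = 4
    service_noise_sd: float = 0.003  # service units; surfaces are smooth
    noise_corr_length: float = 3.0  # cells
    anchor_high: float = 1.5  # fixed dynamic range of each service layer
    # planted criticality signal (ECI units; see module docstring)
    eci_floor: float = 1.3
    tail_scale: float = 0.9
    tail_max: float = 1.0
    margin_offset: float = -0.15  # sub-critical margin band, rings 1..margin_width
    margin_sd: float = 0.03
    margin_width: int = 4
    anchor_offset: float = -0.04  # near-critical anchor band, the terminal peak
    anchor_sd: float = 0.05
    anchor_width: int = 13  # outer reach (cells) of the anchor band
    truth_cover: float = 0.14  # of all grid cells (capped by host area)
    # planted geometry
    isolation_distance: float = 3.0  # km; "isolated" means beyond this
    n_satellites: int = 4
    n_holes: int = 6

    def __post_init__(self):
        rows, cols = self.shape
        if rows < 16 or cols < 16:
            raise ValueError(
                f"shape {self.shape} is too small to host all land classes (min 16x16)"
            )
        if len(set(self.periods)) != len(self.periods) or len(self.periods) < 1:
            raise ValueError("periods must be a non-empty sequence of unique labels")
        valid_pairs = set(zip(self.periods, self.periods[1:]))
        for rule in self.change_rules:
            if tuple(rule.period_pair) not in valid_pairs:
                raise ValueError(
                    f"change rule {rule} does not reference a consecutive period pair"
                )
        if self.n_zones < 1:
            raise ValueError("n_zones must be >= 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedChange:
    """One planted patch with its intended geometric kind."""

    period_pair: tuple[str, str]
    mode: str
    kind: str
    cells: np.ndarray = field(repr=False)  # (n, 2) of (row, col)


@dataclass
class SyntheticTruth:
    """Ground truth the generator guarantees."""

    true_eca_masks: dict[str, np.ndarray]
    planted_patches: list[PlantedChange]
    planted_driver: str | None
    host_units: list[int]
    expansion_units: list[int]
    degradation_units: list[int]


@dataclass
class SyntheticScenario:
    """All generated inputs plus the ground truth."""

    config: ScenarioConfig
    landcover: np.ndarray
    zones: np.ndarray
    lessi_table: "object"  # per-unit metrics + LESSI (pandas DataFrame)
    lessi: np.ndarray
    services: dict[str, np.ndarray]  # period -> (n_services, rows, cols)
    drivers: dict[str, np.ndarray]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# primitive fields and zones

def _gaussian_field(shape, corr_length, rng) -> np.ndarray:
    """Smooth zero-mean, unit-sd Gaussian random field."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma=corr_length, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_zones(shape: tuple[int, int], n_zones: int) -> np.ndarray:
    """Tile the grid into ``n_zones`` contiguous rectangular blocks."""
    rows, cols = shape
    nr = max(1, int(round(np.sqrt(n_zones))))
    while n_zones % nr:
        nr -= 1
    nc = n_zones // nr
    zones = np.zeros(shape, dtype=np.int64)
    row_edges = np.array_split(np.arange(rows), nr)
    col_edges = np.array_split(np.arange(cols), nc)
    unit = 0
    for rblock in row_edges:
        for cblock in col_edges:
            zones[np.ix_(rblock, cblock)] = unit
            unit += 1
    return zones


# ---------------------------------------------------------------------------
# land cover

def generate_landcover(config: ScenarioConfig) -> np.ndarray:
    """Cluster-grown categorical raster over the 7 land classes.

    Class seeds are sown with deliberately heterogeneous density across
    units — a few units get dense seeding (fragmented mosaics), the rest
    sparse seeding (large coherent patches) — and every cell takes the
    class of its nearest seed under a smooth coordinate wobble.  The
    density contrast gives the unit-level fragmentation gradient that the
    LESSI rescaling needs to resolve.
    """
    rows, cols = config.shape
    rng = config.rng(_S_LANDCOVER)
    zones = make_zones(config.shape, config.n_zones)
    units = np.unique(zones)
    n_frag = max(1, len(units) // 4)
    frag_units = set(rng.choice(units, size=n_frag, replace=False).tolist())

    seed_rows, seed_cols, seed_cls = [], [], []
    class_codes = np.array(sorted(LAND_CLASSES))
    weights = np.array([_CLASS_WEIGHTS[LAND_CLASSES[c]] for c in class_codes])
    weights = weights / weights.sum()
    for unit in units:
        cells = np.argwhere(zones == unit)
        dense = unit in frag_units
        n_seeds = max(7, cells.shape[0] // 8) if dense else max(2, cells.shape[0] // 256)
        idx = rng.choice(cells.shape[0], size=min(n_seeds, cells.shape[0]), replace=False)
        seed_rows.extend(cells[idx, 0])
        seed_cols.extend(cells[idx, 1])
        seed_cls.extend(rng.choice(class_codes, size=len(idx), p=weights))
    seed_cls = np.array(seed_cls)
    # guarantee global presence of every class
    force = rng.choice(len(seed_cls), size=len(class_codes), replace=False)
    seed_cls[force] = class_codes

    tree = cKDTree(np.column_stack([seed_rows, seed_cols]))
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    amp = 2.5
    wob_r = amp * _gaussian_field(config.shape, 4.0, rng)
    wob_c = amp * _gaussian_field(config.shape, 4.0, rng)
    query = np.column_stack([(rr + wob_r).ravel(), (cc + wob_c).ravel()])
    _, nearest = tree.query(query)
    lc = seed_cls[nearest].reshape(config.shape).astype(np.int64)

    for code in class_codes:  # wobble can orphan a forced seed; re-stamp
        if not np.any(lc == code):
            r = rng.integers(0, rows - 1)
            c = rng.integers(0, cols - 1)
            lc[r: r + 2, c: c + 2] = code
    return lc


# ---------------------------------------------------------------------------
# services and drivers

def _class_mean_stack(landcover: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    lut = np.zeros((len(SERVICE_NAMES), max(LAND_CLASSES) + 1))
    for s, sname in enumerate(SERVICE_NAMES[: config.n_services]):
        for code, cname in LAND_CLASSES.items():
            lut[s, code] = _BASE_MEANS[cname] + _SERVICE_TWEAK[sname]
    return lut[: config.n_services, landcover]


def generate_services(
    landcover: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Class-conditioned service stack plus smooth Gaussian-field noise.

    Returns an ``(n_services, rows, cols)`` stack of finite values.  With
    ``noise_sd=0`` the stack is exactly the class-mean surface.
    """
    lc = np.asarray(landcover)
    if lc.shape != config.shape:
        raise ValueError(f"landcover shape {lc.shape} does not match config {config.shape}")
    rng = rng if rng is not None else config.rng(_S_SERVICES)
    sd = config.service_noise_sd if noise_sd is None else noise_sd
    stack = _class_mean_stack(lc, config)
    if sd > 0:
        for s in range(stack.shape[0]):
            stack[s] += sd * _gaussian_field(config.shape, config.noise_corr_length, rng)
    return stack


def slope_from_dem(dem: np.ndarray, cell_size: float = 1.0) -> np.ndarray:
    """Slope in degrees from a DEM in metres on a grid of ``cell_size`` km."""
    cell_m = cell_size * 1000.0
    gy, gx = np.gradient(np.asarray(dem, dtype=float), cell_m)
    return np.degrees(np.arctan(np.hypot(gy, gx)))


def generate_drivers(
    landcover: np.ndarray, config: ScenarioConfig
) -> dict[str, np.ndarray]:
    """Continuous driver surfaces (Table-style environment/socioeconomic set).

    Slope is derived from the DEM, temperature is anti-correlated with it
    through a lapse rate, precipitation follows a west-east gradient, and
    GDP / population / nightlight decay with distance from impervious
    cells.  Distances to impervious and cropland are *not* produced here;
    the driver-table assembly computes them by distance transform.
    """
    lc = np.asarray(landcover)
    rng = config.rng(_S_DRIVERS)
    shape = lc.shape
    relief = _gaussian_field(shape, max(shape) / 6, rng)
    relief = (relief - relief.min()) / (relief.max() - relief.min() + 1e-12)
    dem = 600.0 + 3400.0 * relief
    slope = slope_from_dem(dem, config.cell_size)
    temperature = 26.0 - 6.5 * (dem - 600.0) / 1000.0 + 0.8 * _gaussian_field(shape, 6, rng)
    east = np.linspace(0.0, 1.0, shape[1])[None, :] * np.ones(shape)
    precipitation = 600.0 + 800.0 * east + 80.0 * _gaussian_field(shape, 8, rng)

    imperv = lc == CLASS_CODES["impervious"]
    if imperv.any():
        dist = ndimage.distance_transform_edt(~imperv) * config.cell_size
    else:
        dist = np.full(shape, float(np.hypot(*shape)) * config.cell_size)
    gdp = 12.0 * np.exp(-dist / 4.0) + 0.4 * np.abs(_gaussian_field(shape, 4, rng))
    population = 800.0 * np.exp(-dist / 5.0) + 20.0 * np.abs(_gaussian_field(shape, 4, rng))
    nightlight = np.clip(
        60.0 * np.exp(-dist / 3.0) + 2.0 * np.abs(_gaussian_field(shape, 4, rng)), 0.0, 63.0
    )
    return {
        "dem": dem, "slope": slope, "temperature": temperature,
        "precipitation": precipitation, "gdp": gdp,
        "population": population, "nightlight": nightlight,
    }


# ---------------------------------------------------------------------------
# planted change geometry

_CROSS = ndimage.generate_binary_structure(2, 1)


def _tapered_texp(rng, n, scale, cutoff):
    """Right-skewed magnitudes: truncated exponential with a linear taper
    to zero density at ``cutoff`` (steep everywhere, no terminal cliff)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = (n - filled) * 2 + 16
        u = rng.uniform(0.0, 1.0, m)
        x = -scale * np.log1p(-u * (1.0 - np.exp(-cutoff / scale)))
        keep = x[rng.uniform(0.0, 1.0, m) < (1.0 - x / cutoff)]
        take = min(keep.size, n - filled)
        out[filled: filled + take] = keep[:take]
        filled += take
    return out


def _pick_arcs(rng, candidates: np.ndarray, k: int) -> np.ndarray:
    """Choose ~k candidate cells grouped into contiguous arcs/blobs."""
    n = candidates.shape[0]
    n_anchor = max(1, int(round(k / 15)))
    anchors = candidates[rng.choice(n, size=min(n_anchor, n), replace=False)]
    tree = cKDTree(anchors)
    dist, _ = tree.query(candidates)
    order = np.argsort(dist, kind="stable")
    return candidates[order[:k]]


def _whole_components(rng, comp_labels: np.ndarray, k: int) -> np.ndarray:
    """Accumulate whole labelled components (smallest spread first) to >= k cells."""
    ids = np.arange(1, int(comp_labels.max()) + 1)
    rng.shuffle(ids)
    chosen = []
    total = 0
    for cid in ids:
        cells = np.argwhere(comp_labels == cid)
        chosen.append(cells)
        total += cells.shape[0]
        if total >= k:
            break
    return np.concatenate(chosen, axis=0)


def _plant_rule(
    rule: ChangeRule,
    mask: np.ndarray,
    regime_elig: np.ndarray,
    rng: np.random.Generator,
    cell_size: float,
    isolation_distance: float,
) -> np.ndarray:
    """Select the cell set for one change rule; returns an (n, 2) array."""
    k = max(1, int(round(rule.magnitude * int(mask.sum()))))
    if rule.mode == "expansion":
        if rule.kind == "edge":
            ring = ndimage.binary_dilation(mask, _CROSS) & ~mask & regime_elig
            nbr = ndimage.convolve(mask.astype(np.int8), _CROSS.astype(np.int8), mode="constant")
            cand = np.argwhere(ring & (nbr <= 2))
            if cand.shape[0] < k:
                cand = np.argwhere(ring)
        elif rule.kind == "isolated":
            far = (
                ndimage.distance_transform_edt(~mask) * cell_size
                > isolation_distance + 2.0
            )
            cand = np.argwhere(far & regime_elig & ~mask)
        else:  # interior: fill holes
            holes = ndimage.binary_fill_holes(mask) & ~mask & regime_elig
            labels, n = ndimage.label(holes, structure=_CROSS)
            if n == 0 or holes.sum() < k:
                raise ValueError(
                    f"change rule {rule}: requested {k} cells but only "
                    f"{int(holes.sum())} interior hole cells are available"
                )
            return _whole_components(rng, labels, k)
    else:  # degradation
        if rule.kind == "edge":
            ring = mask & ~ndimage.binary_erosion(mask, _CROSS) & regime_elig
            nbr = ndimage.convolve(mask.astype(np.int8), _CROSS.astype(np.int8), mode="constant")
            cand = np.argwhere(ring & (nbr <= 3))
            if cand.shape[0] < k:
                cand = np.argwhere(ring)
        elif rule.kind == "isolated":
            labels, n = ndimage.label(mask, structure=_CROSS)
            size_cap = max(30, 2 * k)  # whole small patches only, never a core blob
            sat_ids = []
            for cid in range(1, n + 1):
                comp = labels == cid
                if int(comp.sum()) > size_cap:
                    continue
                if not (comp & regime_elig).any():
                    continue
                others = mask & ~comp
                if not others.any():
                    continue
                gap = ndimage.distance_transform_edt(~others)[comp].min() * cell_size
                if gap > isolation_distance:
                    sat_ids.append(cid)
            if not sat_ids:
                raise ValueError(
                    f"change rule {rule}: no isolated true-ECA patch beyond "
                    f"{isolation_distance} km is available"
                )
            sat = np.isin(labels, sat_ids)
            lab2 = np.where(sat, labels, 0)
            return _whole_components(rng, lab2, k)
        else:  # interior cores
            core = ndimage.binary_erosion(mask, _CROSS, iterations=2) & regime_elig
            cand = np.argwhere(core)
    if cand.shape[0] < k:
        raise ValueError(
            f"change rule {rule}: requested {k} cells but only {cand.shape[0]} "
            f"candidate cells are available"
        )
    return _pick_arcs(rng, cand, k)


# ---------------------------------------------------------------------------
# the multi-period scenario

def _truth_seed_mask(config, zones, lessi_vals, host_units, rng):
    """Initial true-ECA blobs inside host units, with satellites and holes."""
    rows, cols = config.shape
    host_mask = np.isin(zones, host_units)
    eligible = ndimage.binary_erosion(host_mask, _CROSS, iterations=3)
    field = _gaussian_field(config.shape, max(rows, cols) / 16, rng)
    target = int(min(config.truth_cover * rows * cols, 0.45 * eligible.sum()))
    vals = field[eligible]
    q = np.quantile(vals, 1.0 - target / vals.size) if target < vals.size else vals.min() - 1
    truth = eligible & (field > q)
    return truth, eligible


def _punch_holes(truth, regime_mask, config, rng):
    core = ndimage.binary_erosion(truth & regime_mask, _CROSS, iterations=3)
    centers = np.argwhere(core)
    if centers.shape[0] == 0:
        return truth
    idx = rng.choice(centers.shape[0], size=min(config.n_holes, centers.shape[0]), replace=False)
    rr, cc = np.meshgrid(np.arange(truth.shape[0]), np.arange(truth.shape[1]), indexing="ij")
    out = truth.copy()
    for r, c in centers[idx]:
        out &= (rr - r) ** 2 + (cc - c) ** 2 > 2.0**2
    return out


def _add_satellites(truth, eligible, regime_mask, config, rng):
    """Stamp small blobs far from existing truth (for 'departed' rules).

    Returns the augmented truth and the satellite mask itself.  Satellites
    sit beyond the fringe-band reach so their surroundings carry no
    near-critical cells.
    """
    out = truth.copy()
    sats = np.zeros_like(truth)
    clearance = config.isolation_distance + 2.0
    placed = 0
    for _ in range(200):
        if placed >= config.n_satellites:
            break
        room = (
            eligible & regime_mask & ~out
            & (ndimage.distance_transform_edt(~out) * config.cell_size > clearance)
        )
        cells = np.argwhere(room)
        if cells.shape[0] == 0:
            break
        r, c = cells[rng.integers(0, cells.shape[0])]
        rr, cc = np.meshgrid(np.arange(out.shape[0]), np.arange(out.shape[1]), indexing="ij")
        disk = ((rr - r) ** 2 + (cc - c) ** 2 <= 2.0**2) & eligible
        out |= disk
        sats |= disk
        placed += 1
    return out, sats


def _band_masks(truth, feasible, exclusion, config):
    """Sub-critical margin and near-critical anchor fringe bands.

    The margin band (rings 1..margin_width) is clearly sub-threshold, so
    boundary transitions are unambiguous; the anchor band (rings up to
    anchor_width) holds the narrow near-critical mode that pins the
    extracted threshold.  Satellite surroundings (``exclusion``) carry
    neither band, keeping their isolation geometrically exact.
    """
    inner = ndimage.binary_dilation(truth, _CROSS, iterations=config.margin_width) & ~truth
    outer = (
        ndimage.binary_dilation(truth, _CROSS, iterations=config.anchor_width)
        & ~truth & ~inner
    )
    return inner & feasible & ~exclusion, outer & feasible & ~exclusion


def generate_timeseries(config: ScenarioConfig) -> SyntheticScenario:
    """Generate the full multi-period scenario with ground truth.

    Raises ``ValueError`` when a change rule asks for more cells than its
    geometric candidate set offers, or when too few structurally secure
    units exist to host the requested critical cover.
    """
    rows, cols = config.shape
    n_cells = rows * cols
    lc = generate_landcover(config)
    zones = make_zones(config.shape, config.n_zones)
    table = lessi_from_metrics(compute_metrics(lc, zones, 8, config.cell_size))
    lessi = lessi_raster(zones, table)

    n_s = config.n_services
    l_req = (config.eci_floor + config.tail_max) / (0.97 * n_s)
    lvals = table.loc[~table["missing"], "LESSI"]
    host_units = lvals[lvals >= l_req].sort_values(ascending=False).index.tolist()
    host_area = int(np.isin(zones, host_units).sum())
    if host_area < config.truth_cover * n_cells / 0.7:
        raise ValueError(
            f"only {len(host_units)} structurally secure units "
            f"(LESSI >= {l_req:.2f}) covering {host_area} cells; cannot host "
            f"critical cover {config.truth_cover:.0%} of {n_cells} cells"
        )
    rng_truth = config.rng(_S_TRUTH)
    # split hosts into expansion / degradation regimes (alternating by rank)
    exp_units = host_units[0::2]
    deg_units = host_units[1::2]
    exp_mask = np.isin(zones, exp_units)
    deg_mask = np.isin(zones, deg_units)

    truth0, eligible = _truth_seed_mask(config, zones, lvals, host_units, rng_truth)
    truth0 = _punch_holes(truth0, exp_mask, config, rng_truth)
    truth0, satellites = _add_satellites(truth0, eligible, deg_mask, config, rng_truth)
    isolated_blobs = satellites.copy()  # isolated plantings accumulate here

    # per-cell static draws (streams fixed so a no-change scenario is static)
    rng_tail = config.rng(_S_TAIL)
    e_map = _tapered_texp(
        rng_tail, n_cells, config.tail_scale, config.tail_max
    ).reshape(config.shape)
    rng_sh = config.rng(_S_SHOULDER)
    margin_map = rng_sh.normal(
        config.eci_floor + config.margin_offset, config.margin_sd, config.shape
    )
    anchor_map = rng_sh.normal(
        config.eci_floor + config.anchor_offset, config.anchor_sd, config.shape
    )

    # walk the period sequence applying rules
    from .evolution import build_patches, lei as lei_of  # local import avoids cycle

    rng_plant = config.rng(_S_PLANT)
    masks = {config.periods[0]: truth0}
    planted: list[PlantedChange] = []
    current = truth0
    for p_from, p_to in zip(config.periods, config.periods[1:]):
        nxt = current.copy()
        for rule in config.change_rules:
            if tuple(rule.period_pair) != (p_from, p_to):
                continue
            regime = exp_mask & eligible if rule.mode == "expansion" else deg_mask
            cells = _plant_rule(
                rule, current, regime, rng_plant, config.cell_size,
                config.isolation_distance,
            )
            sel = np.zeros(config.shape, dtype=bool)
            sel[cells[:, 0], cells[:, 1]] = True
            sel &= ~current if rule.mode == "expansion" else current
            # planted-type fidelity: keep only buffer-groups whose LEI
            # against the true masks matches the intended geometric kind
            labels = build_patches(sel, 1.0, config.cell_size)
            kept = np.zeros_like(sel)
            for lab in range(1, int(labels.max()) + 1):
                pmask = labels == lab
                ref = current & ~sel if rule.mode == "degradation" else current
                value, *_ = lei_of(pmask, ref & ~pmask, 1.0, config.cell_size)
                ok = (
                    value == 0.0 if rule.kind == "isolated"
                    else 0.0 < value <= 50.0 if rule.kind == "edge"
                    else value > 50.0
                )
                if not ok:
                    continue
                kept |= pmask
                planted.append(
                    PlantedChange(
                        period_pair=(p_from, p_to), mode=rule.mode,
                        kind=rule.kind, cells=np.argwhere(pmask),
                    )
                )
            if rule.mode == "expansion":
                nxt |= kept
                if rule.kind == "isolated":
                    isolated_blobs |= kept
            else:
                nxt &= ~kept
        masks[p_to] = nxt
        current = nxt

    # isolated patches carry no near-critical fringe, keeping their
    # surroundings criticality-free (their isolation is the planted signal)
    iso_exclusion = ndimage.binary_dilation(
        isolated_blobs, _CROSS, iterations=config.anchor_width + 1
    ) & ~isolated_blobs

    # service stacks per period: background + compensated planted strata
    base = generate_services(lc, config)
    class_means = _class_mean_stack(lc, config)
    eps = base - class_means
    sh_feasible = lessi * (0.97 * n_s) >= (
        config.eci_floor + config.anchor_offset + 3 * config.anchor_sd
    )
    calib_unit = lvals.idxmin() if len(lvals) else 0
    calib_cells = np.argwhere(zones == calib_unit)[:2]
    # a single fixed maximally-critical cell in the most secure unit pins
    # the ECI range, so histogram bin edges are identical across periods
    calib_top = tuple(np.argwhere(zones == host_units[0])[0])
    safe_l = np.where(np.isfinite(lessi) & (lessi > 1e-6), lessi, 1.0)

    # bands are frozen at the initial truth geometry so the strata are
    # static: only planted transitions change a cell's stratum, never a
    # band reassignment around a moved boundary
    margin_band0, anchor_band0 = _band_masks(truth0, sh_feasible, iso_exclusion, config)

    services: dict[str, np.ndarray] = {}
    for period, mask in masks.items():
        stack = base.copy()
        margin_band = margin_band0 & ~mask
        anchor_band = anchor_band0 & ~mask
        t_target = np.zeros(config.shape)
        t_target[mask] = (config.eci_floor + e_map[mask]) / (n_s * safe_l[mask])
        t_target[margin_band] = margin_map[margin_band] / (n_s * safe_l[margin_band])
        t_target[anchor_band] = anchor_map[anchor_band] / (n_s * safe_l[anchor_band])
        t_target = np.clip(t_target, 0.0, 0.97)
        overwrite = mask | margin_band | anchor_band
        for s in range(n_s):
            layer = stack[s]
            layer[overwrite] = (
                config.anchor_high * t_target[overwrite] + eps[s][overwrite]
            )
            for i, (r, c) in enumerate(calib_cells):
                layer[r, c] = 0.0 if i == 0 else config.anchor_high
            layer[calib_top] = 0.97 * config.anchor_high
        services[period] = stack

    drivers = generate_drivers(lc, config)
    planted_driver = None
    if config.driver_effect is not None:
        name, direction, strength = config.driver_effect
        if name not in drivers:
            raise ValueError(f"driver_effect names unknown driver {name!r}")
        delta = direction * strength * float(np.std(drivers[name]))
        drivers[name] = drivers[name] + delta * exp_mask.astype(float) \
            - delta * deg_mask.astype(float)
        planted_driver = name

    truth = SyntheticTruth(
        true_eca_masks=masks,
        planted_patches=planted,
        planted_driver=planted_driver,
        host_units=[int(u) for u in host_units],
        expansion_units=[int(u) for u in exp_units],
        degradation_units=[int(u) for u in deg_units],
    )
    return SyntheticScenario(
        config=config, landcover=lc, zones=zones, lessi_table=table,
        lessi=lessi, services=services, drivers=drivers, truth=truth,
    )
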