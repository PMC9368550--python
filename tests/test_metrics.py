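"""Landscape-metric checks against analytic values and a brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from ecocrit import metrics as lm


# ---------------------------------------------------------------------------
# independent flood-fill + per-patch-sum oracle

def _flood_fill_patches(lc, connectivity):
    """Brute-force patch delineation by iterative flood fill."""
    rows, cols = lc.shape
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros(lc.shape, dtype=bool)
    patches = []
    for r in range(rows):
        for c in range(cols):
            if seen[r, c] or lc[r, c] <= 0:
                continue
            stack, cells = [(r, c)], set()
            seen[r, c] = True
            while stack:
                y, x = stack.pop()
                cells.add((y, x))
                for dy, dx in steps:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < rows and 0 <= nx < cols and not seen[ny, nx] \
                            and lc[ny, nx] == lc[r, c]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            patches.append((int(lc[r, c]), frozenset(cells)))
    return patches


def _cell_perimeter(cells, rows, cols):
    p = 0
    for (y, x) in cells:
        for dy, dx in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            if (y + dy, x + dx) not in cells:
                p += 1
    return p


def _oracle_metrics(lc, connectivity, cell_size, unit_cells):
    patches = _flood_fill_patches(lc, connectivity)
    A = unit_cells * cell_size**2
    areas = np.array([len(cells) for _, cells in patches]) * cell_size**2
    perims = np.array(
        [_cell_perimeter(cells, *lc.shape) for _, cells in patches]
    ) * cell_size
    # interior inter-class edges only
    edge = 0
    for y in range(lc.shape[0]):
        for x in range(lc.shape[1]):
            if lc[y, x] <= 0:
                continue
            for dy, dx in [(1, 0), (0, 1)]:
                ny, nx = y + dy, x + dx
                if ny < lc.shape[0] and nx < lc.shape[1] and lc[ny, nx] > 0 \
                        and lc[ny, nx] != lc[y, x]:
                    edge += 1
    w = areas / areas.sum()
    awmsi = float(np.sum(0.25 * perims / np.sqrt(areas) * w))
    f = float(sum(
        (1.0 if a <= 1.0 else min(2.0, max(1.0, 2 * np.log(0.25 * p) / np.log(a)))) * wi
        for p, a, wi in zip(perims, areas, w)
    ))
    return {
        "PD": len(patches) / A,
        "ED": 2 * edge * cell_size / A,
        "AWMSI": awmsi,
        "F": f,
        "D": 1.0 - float(np.sum((areas / A) ** 2)),
    }


# ---------------------------------------------------------------------------

def test_uniform_raster_is_one_patch_with_analytic_geometry():
    lc = np.full((10, 10), 3)
    patches, labels = lm.delineate_patches(lc, connectivity=8)
    assert len(patches) == 1
    assert patches[0].area == 100.0
    assert patches[0].perimeter == 40.0
    assert labels.max() == 1 and (labels == 1).all()


def test_checkerboard_under_4_connectivity_is_one_patch_per_cell():
    lc = np.indices((8, 8)).sum(axis=0) % 2 + 1
    patches, _ = lm.delineate_patches(lc, connectivity=4)
    assert len(patches) == 64
    assert all(p.n_cells == 1 and p.perimeter == 4.0 for p in patches)


def test_empty_raster_fails():
    with pytest.raises(ValueError, match="empty"):
        lm.delineate_patches(np.zeros((5, 5), dtype=int))


@pytest.mark.parametrize("seed", range(6))
@pytest.mark.parametrize("connectivity", [4, 8])
def test_patch_delineation_matches_flood_fill_oracle(seed, connectivity):
    rng = np.random.default_rng(seed)
    lc = rng.integers(1, 4, size=(16, 16))
    patches, labels = lm.delineate_patches(lc, connectivity=connectivity)
    got = {(p.klass, frozenset(map(tuple, p.cells))) for p in patches}
    expected = set(_flood_fill_patches(lc, connectivity))
    assert got == expected
    for p in patches:
        cells = frozenset(map(tuple, p.cells))
        assert p.perimeter == _cell_perimeter(cells, *lc.shape)


def test_hand_worked_single_patch_unit():
    # one 2x2 patch alone in a 10x10 (100 km^2) unit
    lc = np.zeros((10, 10), dtype=int)
    lc[4:6, 4:6] = 2
    zones = np.zeros((10, 10), dtype=int)
    rec = lm.compute_metrics(lc, zones).loc[0]
    assert rec["AWMSI"] == pytest.approx(0.25 * 8 / np.sqrt(4))  # = 1.0
    assert rec["D"] == pytest.approx(1 - (4 / 100) ** 2)  # = 0.9984
    assert rec["PD"] == pytest.approx(0.01)


def test_square_patch_filling_its_unit():
    lc = np.full((12, 12), 5)
    rec = lm.compute_metrics(lc, np.zeros((12, 12), dtype=int)).loc[0]
    assert rec["AWMSI"] == pytest.approx(1.0)
    assert rec["D"] == pytest.approx(0.0)
    assert rec["ED"] == pytest.approx(0.0)  # unit-border edges excluded


@pytest.mark.parametrize("seed", range(5))
def test_unit_metrics_match_brute_force_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    lc = rng.integers(1, 5, size=(24, 24))
    zones = np.zeros_like(lc)
    zones[:, 12:] = 1
    table = lm.compute_metrics(lc, zones)
    for unit in (0, 1):
        sub = np.where(zones == unit, lc, 0)
        expected = _oracle_metrics(sub, 8, 1.0, int((zones == unit).sum()))
        for key, val in expected.items():
            assert table.loc[unit, key] == pytest.approx(val, rel=1e-9), key


def test_scale_covariance_of_patch_geometry():
    rng = np.random.default_rng(3)
    lc = rng.integers(1, 4, size=(12, 12))
    p1, _ = lm.delineate_patches(lc, cell_size=1.0)
    p2, _ = lm.delineate_patches(lc, cell_size=2.0)
    for a, b in zip(p1, p2):
        assert b.area == pytest.approx(4 * a.area)
        assert b.perimeter == pytest.approx(2 * a.perimeter)


def test_shape_metrics_invariant_to_class_relabeling():
    rng = np.random.default_rng(9)
    lc = rng.integers(1, 4, size=(20, 20))
    relabeled = np.select([lc == 1, lc == 2, lc == 3], [7, 5, 2])
    zones = np.zeros_like(lc)
    a = lm.compute_metrics(lc, zones).loc[0]
    b = lm.compute_metrics(relabeled, zones).loc[0]
    for key in ("PD", "ED", "AWMSI", "F", "D"):
        assert a[key] == pytest.approx(b[key])


def test_fragmentation_v_arithmetic_and_weight_check():
    assert lm.fragmentation_v(0.0, 0.0, 0.0) == 0.0
    assert lm.fragmentation_v(1.0, 1.0, 1.0) == pytest.approx(1.0)
    assert lm.fragmentation_v(0.5, 0.2, 0.9) == pytest.approx(0.49)
    with pytest.raises(ValueError, match="sum to 1"):
        lm.fragmentation_v(0.5, 0.2, 0.9, weights=(0.5, 0.3, 0.3))


def test_lessi_boundary_values_and_monotonicity():
    assert lm.lessi_values(0.0, 0.7) == pytest.approx(1.0)
    assert lm.lessi_values(1.0, 0.4, bracket_scale=1.0) == pytest.approx(0.0)
    # raising V with the (PD'+ED') term fixed never increases LESSI
    grid = np.linspace(0.0, 1.0, 21)
    for pd_ed in (0.2, 0.6, 1.0):
        vals = lm.lessi_values(pd_ed, grid, bracket_scale=2.5)
        assert np.all(np.diff(vals) <= 1e-12)


def test_lessi_in_unit_interval_and_uniform_unit_is_most_secure():
    rng = np.random.default_rng(5)
    lc = rng.integers(1, 8, size=(40, 40))
    lc[:20, :20] = 2  # one intact single-class unit
    zones = np.repeat(np.arange(2), 20)[:, None] * 2 + np.repeat(np.arange(2), 20)[None, :]
    table = lm.lessi_from_metrics(lm.compute_metrics(lc, zones))
    ok = table[~table["missing"]]
    assert ((ok["LESSI"] >= 0) & (ok["LESSI"] <= 1)).all()
    assert table.loc[0, "LESSI"] == pytest.approx(1.0)


def test_missing_unit_is_flagged_and_excluded():
    lc = np.zeros((10, 10), dtype=int)
    lc[:, :5] = 1
    zones = np.zeros_like(lc)
    zones[:, 5:] = 1
    table = lm.lessi_from_metrics(lm.compute_metrics(lc, zones))
    assert bool(table.loc[1, "missing"])
    assert pd.isna(table.loc[1, "LESSI"])


def test_lessi_raster_broadcasts_unit_values(small_scenario):
    arr = lm.lessi_raster(small_scenario.zones, small_scenario.lessi_table)
    table = small_scenario.lessi_table
    unit = table.index[0]
    assert np.allclose(
        arr[small_scenario.zones == unit], table.loc[unit, "LESSI"], equal_nan=True
    )


def test_moving_window_lessi_is_bounded(small_scenario):
    out = lm.lessi_moving_window(small_scenario.landcover, window=32, step=16)
    assert out.shape == small_scenario.landcover.shape
    assert np.nanmin(out) >= 0.0 and np.nanmax(out) <= 1.0
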