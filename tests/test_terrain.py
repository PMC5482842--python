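import numpy as np
import pytest

from n15scape.raster import RasterGrid
from n15scape.terrain import (LANDFORM_LEGEND, classify_landforms, fill_pits,
                              mean_filter_circular, mfd_flow_accumulation,
                              slope, tpi, twi)


def grid(vals, cs=1.0, origin=None):
    vals = np.asarray(vals, dtype=float)
    if origin is None:
        origin = (0.0, vals.shape[0] * cs)
    return RasterGrid(vals, cs, origin)


# -- mean filter -----------------------------------------------------------

def test_mean_filter_constant_identity():
    g = grid(np.full((9, 9), 3.7))
    out = mean_filter_circular(g, 3)
    assert np.allclose(out.values, 3.7)


def test_mean_filter_radius_zero_identity(rng):
    g = grid(rng.normal(size=(6, 8)))
    assert np.array_equal(mean_filter_circular(g, 0).values, g.values)


def test_mean_filter_cross_window():
    # single 1.0 at centre of a 5x5 zero grid, radius 1: the <=1-cell window
    # is the 5-cell cross, so the centre and its 4 neighbours read 0.2
    vals = np.zeros((5, 5))
    vals[2, 2] = 1.0
    out = mean_filter_circular(grid(vals), 1).values
    expect = np.zeros((5, 5))
    for i, j in [(2, 2), (1, 2), (3, 2), (2, 1), (2, 3)]:
        expect[i, j] = 0.2
    assert np.allclose(out, expect)


def test_mean_filter_negative_radius():
    with pytest.raises(ValueError):
        mean_filter_circular(grid(np.zeros((3, 3))), -1)


def test_mean_filter_nodata_excluded():
    vals = np.ones((5, 5))
    vals[0, 0] = np.nan
    out = mean_filter_circular(grid(vals), 1)
    assert np.isnan(out.values[0, 0])  # nodata centre stays nodata
    assert np.allclose(out.values[0, 1], 1.0)  # neighbour mean skips the hole


def test_mean_filter_translation_invariant(rng):
    vals = rng.normal(size=(8, 8))
    a = mean_filter_circular(grid(vals, origin=(0.0, 8.0)), 2).values
    b = mean_filter_circular(grid(vals, origin=(100.0, 250.0)), 2).values
    assert np.array_equal(a, b)


# -- slope -----------------------------------------------------------------

def test_slope_flat():
    assert np.allclose(slope(grid(np.full((5, 5), 2.0))).values, 0.0)


def test_slope_plane_x():
    X, Y = np.meshgrid(np.arange(7) + 0.5, np.arange(7) + 0.5)
    s = slope(grid(0.1 * X)).values
    assert np.allclose(s[1:-1, 1:-1], 0.1)


def test_slope_plane_pythagoras():
    X, Y = np.meshgrid(np.arange(9) + 0.5, np.arange(9)[::-1] + 0.5)
    s = slope(grid(0.3 * X + 0.4 * Y)).values
    assert np.allclose(s[1:-1, 1:-1], 0.5)


# -- MFD accumulation ------------------------------------------------------

def test_mfd_single_cell_padded():
    # 3x3 with strictly highest centre: centre keeps only its own area
    z = np.array([[0., 0., 0.], [0., 5., 0.], [0., 0., 0.]])
    acc = mfd_flow_accumulation(grid(z)).values
    assert acc[1, 1] == 1.0


def test_mfd_descending_ramp_chain():
    z = np.array([[5., 4., 3., 2., 1.]])
    acc = mfd_flow_accumulation(grid(z)).values[0]
    assert np.allclose(acc, [1, 2, 3, 4, 5])


def brute_force_mfd(z, cell_size=1.0, p=1.1):
    """Independent fixed-point oracle: repeatedly propagate area along the
    slope-weighted MFD rule until convergence."""
    nr, nc = z.shape
    area = cell_size ** 2
    acc = np.full(z.shape, area)
    for _ in range(10_000):
        new = np.full(z.shape, area)
        for i in range(nr):
            for j in range(nc):
                ws, nbrs = [], []
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < nr and 0 <= jj < nc and z[ii, jj] < z[i, j]:
                            d = cell_size * np.hypot(di, dj)
                            ws.append(((z[i, j] - z[ii, jj]) / d) ** p)
                            nbrs.append((ii, jj))
                if ws:
                    tot = sum(ws)
                    for (ii, jj), w in zip(nbrs, ws):
                        new[ii, jj] += acc[i, j] * w / tot
        if np.max(np.abs(new - acc)) < 1e-12:
            return new
        acc = new
    raise RuntimeError("oracle did not converge")


def test_mfd_matches_bruteforce_oracle(rng):
    for _ in range(3):
        z = rng.normal(size=(6, 6))
        got = mfd_flow_accumulation(grid(z)).values
        want = brute_force_mfd(z)
        assert np.allclose(got, want, atol=1e-9)


def test_mfd_pure_python_fallback_matches(rng):
    from n15scape.terrain import _mfd_accumulate

    z = rng.normal(size=(8, 8))
    order = np.lexsort((np.arange(z.size), -z.ravel()))
    py = _mfd_accumulate(z, order, 1.0, 1.1)
    assert np.allclose(py, mfd_flow_accumulation(grid(z)).values, atol=1e-12)


def test_mfd_conservation_lower_bound(rng):
    z = rng.normal(size=(10, 10))
    acc = mfd_flow_accumulation(grid(z)).values
    assert np.all(acc >= 1.0 - 1e-12)


def test_mfd_rejects_nodata():
    z = np.ones((4, 4))
    z[1, 1] = np.nan
    with pytest.raises(ValueError):
        mfd_flow_accumulation(grid(z))


# -- TWI -------------------------------------------------------------------

def test_twi_formula_values():
    acc = grid(np.full((3, 3), 10.0))
    sl = grid(np.full((3, 3), 0.1))
    out = twi(acc, sl, smooth_radius_cells=0)
    assert np.allclose(out.values, np.log(100.0))

    out = twi(grid(np.ones((3, 3))), grid(np.ones((3, 3))),
              smooth_radius_cells=0)
    assert np.allclose(out.values, 0.0)


def test_twi_zero_slope_eps_guard():
    out = twi(grid(np.ones((3, 3))), grid(np.zeros((3, 3))),
              smooth_radius_cells=0)
    assert np.allclose(out.values, np.log(1 / 0.001))


def test_twi_nonpositive_accumulation_error():
    with pytest.raises(ValueError):
        twi(grid(np.zeros((3, 3))), grid(np.ones((3, 3))))


def test_twi_monotone_decreasing_in_slope():
    acc = grid(np.full((3, 3), 5.0))
    vals = [twi(acc, grid(np.full((3, 3), t)), smooth_radius_cells=0).values[1, 1]
            for t in (0.05, 0.1, 0.2, 0.5, 1.0)]
    assert np.all(np.diff(vals) < 0)


# -- TPI -------------------------------------------------------------------

def test_tpi_constant_zero():
    out = tpi(grid(np.full((60, 60), 4.0)), 5, 20)
    assert np.allclose(out.values, 0.0, atol=1e-8)


def test_tpi_plane_interior_zero():
    X, Y = np.meshgrid(np.arange(80) + 0.5, np.arange(80) + 0.5)
    out = tpi(grid(0.05 * X + 0.02 * Y), 5, 15).values
    # cells with a complete annulus: symmetric window -> mean equals centre
    assert np.allclose(out[20:-20, 20:-20], 0.0, atol=1e-8)


def test_tpi_gaussian_hill_against_bruteforce():
    n = 151
    X, Y = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5)
    c = n / 2
    z = 5.0 * np.exp(-(((X - c) ** 2 + (Y - c) ** 2) / (2 * 15.0 ** 2)))
    dem = grid(z)
    out = tpi(dem, 10, 50).values
    ic = n // 2
    assert out[ic, ic] > 0

    def brute(i, j):
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        d = np.hypot(ii - i, jj - j)
        sel = (d > 10) & (d <= 50)
        return z[i, j] - z[sel].mean()

    assert np.isclose(out[ic, ic], brute(ic, ic), atol=1e-6)
    moat = ic + 35  # inside the annulus-depressed ring
    assert np.isclose(out[ic, moat], brute(ic, moat), atol=1e-6)
    assert out[ic, moat] < 0


def test_tpi_antisymmetry(rng):
    z = rng.normal(size=(40, 40)).cumsum(axis=0)
    a = tpi(grid(z), 3, 10).values
    b = tpi(grid(-z), 3, 10).values
    assert np.allclose(a, -b, atol=1e-8)


def test_tpi_bad_radii():
    with pytest.raises(ValueError):
        tpi(grid(np.zeros((10, 10))), 10, 5)


# -- landform classification ----------------------------------------------

def test_landforms_constant_all_plain():
    dem = grid(np.full((30, 30), 1.0))
    with pytest.warns(UserWarning):
        lf = classify_landforms(tpi(dem, 3, 10), slope(dem))
    assert np.all(lf.grid.values == 3)  # plain
    assert lf.legend[3] == "plain"


def test_landforms_only_legend_classes(rng):
    z = rng.normal(size=(50, 50)).cumsum(axis=1)
    dem = grid(z)
    lf = classify_landforms(tpi(dem, 3, 15), slope(dem))
    codes = np.unique(lf.grid.values[np.isfinite(lf.grid.values)])
    assert set(codes.astype(int)) <= set(LANDFORM_LEGEND)


def test_landforms_partition_counts(rng):
    z = rng.normal(size=(40, 40)).cumsum(axis=0)
    dem = grid(z)
    lf = classify_landforms(tpi(dem, 3, 12), slope(dem))
    valid = np.isfinite(lf.grid.values)
    counts = [int(np.sum(lf.grid.values == c)) for c in LANDFORM_LEGEND]
    assert sum(counts) == int(valid.sum())


def test_landforms_sinusoid_ridge_valley_slope():
    # ridge-valley sinusoid, wavelength 80 m, amplitude 5 m along rows
    n = 240
    X, Y = np.meshgrid(np.arange(n) + 0.5, np.arange(n) + 0.5)
    z = 5.0 * np.sin(2 * np.pi * Y / 80.0)
    dem = grid(z)
    t = tpi(dem, 10, 40)
    lf = classify_landforms(t, slope(dem))

    # independent z-score classification oracle on interior rows
    tv = t.values
    zsc = (tv - tv[np.isfinite(tv)].mean()) / tv[np.isfinite(tv)].std()
    interior = slice(60, n - 60)
    crest_rows = np.where(np.isclose(np.sin(2 * np.pi * (np.arange(n) + 0.5) / 80.0), 1, atol=0.01))[0]
    trough_rows = np.where(np.isclose(np.sin(2 * np.pi * (np.arange(n) + 0.5) / 80.0), -1, atol=0.01))[0]
    for r in crest_rows:
        if 60 <= r < n - 60:
            assert np.all(zsc[r, interior] >= 1.0)
            assert np.all(lf.grid.values[r, interior] == 1)  # ridge
    for r in trough_rows:
        if 60 <= r < n - 60:
            assert np.all(lf.grid.values[r, interior] == 5)  # valley
    # mid-flank rows (sin ~ 0) are steep: tan = 5*2pi/80 = 0.39 >> tan(5 deg)
    flank_rows = [r for r in range(60, n - 60)
                  if abs(np.sin(2 * np.pi * (r + 0.5) / 80.0)) < 0.05]
    assert flank_rows
    flank_codes = lf.grid.values[np.ix_(flank_rows, range(60, n - 60))]
    assert np.mean(flank_codes == 2) > 0.95  # slope


# -- pit filling -----------------------------------------------------------

def test_fill_pits_removes_depression():
    z = np.full((7, 7), 5.0)
    z[3, 3] = 1.0  # closed pit
    filled = fill_pits(grid(z)).values
    assert filled[3, 3] == 5.0
    assert np.all(filled >= z)
    # already-drained DEM untouched
    ramp = np.tile(np.arange(7.0), (7, 1))
    assert np.array_equal(fill_pits(grid(ramp)).values, ramp)
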