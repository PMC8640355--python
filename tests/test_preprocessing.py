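"""Preprocessing chain: baseline removal, spline regridding, normalization."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ramanembryo import (
    BaselineParams,
    GridSpectrum,
    PreprocessParams,
    RawSpectrum,
    SimConfig,
    extract_fingerprint,
    generate_dataset,
    preprocess_dataset,
    remove_baseline,
    resample_to_grid,
    subtract_background,
    vector_normalize,
)


# ---------------------------------------------------------------------------
# independent not-a-knot cubic spline oracle (dense piecewise-polynomial solve)


def natural_knot_spline_oracle(x, y, xq):
    """Piecewise cubic with not-a-knot ends, built from the dense linear system.

    Unknowns are the 4 polynomial coefficients of each of the n-1 intervals
    (in the local variable t = w - x_i); equations are interpolation at both
    interval ends, C1/C2 continuity at interior knots, and third-derivative
    continuity at the first and last interior knots (not-a-knot).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    m = n - 1
    A = np.zeros((4 * m, 4 * m))
    b = np.zeros(4 * m)
    row = 0
    for i in range(m):
        h = x[i + 1] - x[i]
        A[row, 4 * i] = 1.0
        b[row] = y[i]
        row += 1
        A[row, 4 * i : 4 * i + 4] = [1.0, h, h**2, h**3]
        b[row] = y[i + 1]
        row += 1
    for i in range(m - 1):
        h = x[i + 1] - x[i]
        A[row, 4 * i : 4 * i + 4] = [0.0, 1.0, 2 * h, 3 * h**2]
        A[row, 4 * (i + 1) + 1] = -1.0
        row += 1
        A[row, 4 * i : 4 * i + 4] = [0.0, 0.0, 2.0, 6 * h]
        A[row, 4 * (i + 1) + 2] = -2.0
        row += 1
    # not-a-knot: d''' continuous across the first and last interior knots
    A[row, 3] = 6.0
    A[row, 4 + 3] = -6.0
    row += 1
    A[row, 4 * (m - 2) + 3] = 6.0
    A[row, 4 * (m - 1) + 3] = -6.0
    row += 1
    assert row == 4 * m
    coef = np.linalg.solve(A, b)
    out = np.empty_like(np.asarray(xq, float))
    for j, q in enumerate(np.asarray(xq, float)):
        i = min(max(np.searchsorted(x, q) - 1, 0), m - 1)
        t = q - x[i]
        c = coef[4 * i : 4 * i + 4]
        out[j] = c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3
    return out


# ---------------------------------------------------------------------------
# baseline removal


def test_pure_quadratic_baseline_removed():
    w = np.arange(200.0, 2001.0)
    base = 5.0 + 0.003 * (w - 200) - 1e-6 * (w - 200) ** 2
    spec = RawSpectrum(w, base)
    out = remove_baseline(spec)
    assert np.abs(out.intensities).max() < 0.01 * (base.max() - base.min())


def test_zero_spectrum_stays_zero():
    w = np.arange(200.0, 2001.0)
    out = remove_baseline(RawSpectrum(w, np.zeros_like(w)))
    np.testing.assert_allclose(out.intensities, 0.0, atol=1e-12)


def test_peak_apex_preserved_within_5_percent():
    w = np.arange(200.0, 2001.0)
    apex = 1.0
    peak = apex * (5.0**2) / ((w - 1008.0) ** 2 + 5.0**2)
    base = 4.0 * np.exp(-(w - 200.0) / 400.0) + 1.0
    out = remove_baseline(RawSpectrum(w, base + peak))
    i = int(np.argmin(np.abs(w - 1008.0)))
    assert out.intensities[i] == pytest.approx(apex, rel=0.05)


def test_baseline_parameter_validation():
    spec = RawSpectrum(np.arange(10.0) + 200, np.ones(10))
    with pytest.raises(ValueError):
        remove_baseline(spec, lam=0.0)
    with pytest.raises(ValueError):
        remove_baseline(spec, p=1.0)


# ---------------------------------------------------------------------------
# regridding


def test_spline_exact_on_linear_function():
    w = np.arange(199.5, 2001.0)  # half-integer sampling
    spec = RawSpectrum(w, 2 * w + 1)
    grid = resample_to_grid(spec)
    np.testing.assert_allclose(grid.intensities, 2 * grid.wavenumbers + 1, atol=1e-8)


def test_spline_exact_on_cubic_polynomial():
    w = np.arange(199.5, 2001.0)
    poly = lambda t: 1.0 + 1e-3 * t - 2e-6 * t**2 + 3e-10 * t**3
    grid = resample_to_grid(RawSpectrum(w, poly(w)))
    np.testing.assert_allclose(grid.intensities, poly(grid.wavenumbers), atol=1e-8)


def test_spline_identity_on_integer_grid():
    w = np.arange(200.0, 2001.0)
    y = np.sin(w / 50.0)
    grid = resample_to_grid(RawSpectrum(w, y))
    np.testing.assert_allclose(grid.intensities, y, atol=1e-12)


@given(st.integers(0, 1000))
def test_spline_matches_independent_oracle_on_small_inputs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 21))
    x = np.sort(rng.uniform(0.0, 20.0, size=n))
    while np.min(np.diff(x)) < 1e-3:
        x = np.sort(rng.uniform(0.0, 20.0, size=n))
    y = rng.normal(size=n)
    xq = np.linspace(x[0], x[-1], 37)
    from scipy.interpolate import CubicSpline

    ours = CubicSpline(x, y, bc_type="not-a-knot")(xq)
    oracle = natural_knot_spline_oracle(x, y, xq)
    np.testing.assert_allclose(ours, oracle, atol=1e-8)


def test_no_extrapolation():
    spec = RawSpectrum(np.arange(300.0, 1500.0), np.ones(1200))
    with pytest.raises(ValueError, match="extrapolate"):
        resample_to_grid(spec)


# ---------------------------------------------------------------------------
# normalization / subtraction / fingerprint


def test_vector_normalize_three_four_five():
    g = GridSpectrum(200, 201, [3.0, 4.0])
    out = vector_normalize(g)
    np.testing.assert_allclose(out.intensities, [0.6, 0.8])


def test_vector_normalize_unit_norm_and_scale_invariance(rng):
    y = rng.normal(size=1801)
    g = GridSpectrum(200, 2000, y)
    out = vector_normalize(g)
    assert np.linalg.norm(out.intensities) == pytest.approx(1.0, abs=1e-12)
    out7 = vector_normalize(GridSpectrum(200, 2000, 7.0 * y))
    np.testing.assert_allclose(out7.intensities, out.intensities, atol=1e-12)


def test_vector_normalize_zero_norm_rejected():
    with pytest.raises(ValueError, match="zero-norm"):
        vector_normalize(GridSpectrum(200, 201, [0.0, 0.0]))


def test_subtract_background_identities(rng):
    y = rng.normal(size=1801)
    g = GridSpectrum(200, 2000, y)
    self_sub = subtract_background(g, g)
    np.testing.assert_allclose(self_sub.intensities, 0.0)
    zero = GridSpectrum(200, 2000, np.zeros(1801))
    np.testing.assert_allclose(subtract_background(g, zero).intensities, y)
    with pytest.raises(ValueError, match="grid mismatch"):
        subtract_background(g, GridSpectrum(600, 1800, np.zeros(1201)))


def test_fingerprint_extraction(rng):
    g = GridSpectrum(200, 2000, rng.normal(size=1801))
    fp = extract_fingerprint(g)
    assert fp.intensities.shape == (1201,)
    assert fp.intensities[0] == g.intensities[400]
    assert fp.intensities[-1] == g.intensities[1600]
    again = extract_fingerprint(fp)
    np.testing.assert_array_equal(again.intensities, fp.intensities)
    with pytest.raises(ValueError, match="does not cover"):
        extract_fingerprint(GridSpectrum(700, 1800, rng.normal(size=1101)))


# ---------------------------------------------------------------------------
# full chain


def test_preprocess_dataset_shape(tiny_config):
    fm = preprocess_dataset(generate_dataset(tiny_config))
    assert fm.X.shape == (25, 1201)
    assert fm.wavenumbers[0] == 600.0 and fm.wavenumbers[-1] == 1800.0
    assert fm.medium_fingerprint is not None


def test_preprocess_requires_medium(tiny_config):
    ds = generate_dataset(tiny_config)
    ds.medium = None
    with pytest.raises(ValueError, match="medium"):
        preprocess_dataset(ds)


def test_preprocess_error_names_spectrum(tiny_config):
    ds = generate_dataset(tiny_config)
    bad = ds.spectra[3]
    bad.intensities = bad.intensities.copy()
    ds.spectra[3] = RawSpectrum(
        np.linspace(300, 1500, 100), np.ones(100), spectrum_id=bad.spectrum_id,
        sample_id=bad.sample_id, group=bad.group, replicate=bad.replicate,
    )
    with pytest.raises(ValueError, match=bad.spectrum_id):
        preprocess_dataset(ds)


def test_quiet_generator_gives_identical_groups(tiny_config):
    quiet_baseline = replace(tiny_config.baseline, amplitude_jitter_sd=0.0)
    cfg = replace(
        tiny_config,
        group_effects=(),
        noise_sd=0.0,
        sample_sd=0.0,
        bulk_sd=0.0,
        factor_sd=0.0,
        replicate_sd=0.0,
        axis_jitter=0.0,
        baseline=quiet_baseline,
    )
    fm = preprocess_dataset(generate_dataset(cfg))
    bl = fm.X[fm.groups == "blastula"]
    nb = fm.X[fm.groups == "non_blastula"]
    np.testing.assert_allclose(bl.mean(axis=0), nb.mean(axis=0), atol=1e-10)


def test_chain_scale_invariance(tiny_config):
    """Multiplying a raw spectrum by 7 leaves its fingerprint unchanged."""
    ds = generate_dataset(tiny_config)
    params = PreprocessParams()
    spec = ds.spectra[0]
    from ramanembryo.preprocessing import _process_one

    a = _process_one(spec, params)
    scaled = RawSpectrum(
        spec.wavenumbers, 7.0 * spec.intensities, spectrum_id="s", group="blastula",
        sample_id="x",
    )
    b = _process_one(scaled, params)
    np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-9)


def test_feature_matrix_csv_round_trip(tmp_path, tiny_config):
    fm = preprocess_dataset(generate_dataset(tiny_config))
    fm.to_csv(tmp_path / "f.csv")
    from ramanembryo import FeatureMatrix

    back = FeatureMatrix.from_csv(tmp_path / "f.csv")
    np.testing.assert_allclose(back.X, fm.X, atol=1e-12)
    assert list(back.sample_ids) == list(fm.sample_ids)
    assert list(back.groups) == list(fm.groups)
    np.testing.assert_allclose(back.medium_fingerprint, fm.medium_fingerprint, atol=1e-12)
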