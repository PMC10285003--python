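"""Corruption operators: sampled-parameter supports, locality, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

import octood as o
from octood.corruptions import (
    CONTRAST_FACTORS,
    corrupt_contrast,
    corrupt_dataset,
    corrupt_intensity,
    corrupt_noise,
    corrupt_rectangle,
    corrupt_shift,
    corrupt_smoothing,
    corrupt_stripes,
    corrupt_zoom,
    round_half_up,
)


@pytest.fixture(scope="module")
def mscan():
    m, _ = o.generate_mscan(o.PhantomParams(), np.random.default_rng(1))
    return m


def test_type_sampling_uniform_and_deterministic():
    rng = np.random.default_rng(0)
    draws = [o.sample_corruption_type(rng) for _ in range(80_000)]
    assert set(draws) == set(o.CORRUPTION_TYPES)
    assert len(o.CORRUPTION_TYPES) == 8
    for ct in o.CORRUPTION_TYPES:
        assert abs(draws.count(ct) / 80_000 - 1 / 8) < 0.01
    r1, r2 = np.random.default_rng(42), np.random.default_rng(42)
    assert [o.sample_corruption_type(r1) for _ in range(100)] == [
        o.sample_corruption_type(r2) for _ in range(100)
    ]


def test_noise_statistics():
    """Additive noise recovers sigma=50 and zero mean before clipping."""
    const = np.full((10, 67_400), 128.0)  # > 1e5 pixels
    out, spec = corrupt_noise(const, np.random.default_rng(3), clip=False)
    delta = out - const
    assert spec.params["sigma"] == 50.0
    assert abs(delta.std() - 50.0) < 1.0
    assert abs(delta.mean()) < 0.5
    out0, _ = corrupt_noise(const, np.random.default_rng(3), sigma=0.0)
    assert (out0 == const).all()


def test_smoothing_impulse_and_constants(mscan):
    field = np.zeros((101, 401))
    field[50, 200] = 255.0
    sm, spec = corrupt_smoothing(field, np.random.default_rng(0))
    assert spec.params["sigma"] == 5.0
    profile = sm[50]
    popt, _ = curve_fit(
        lambda x, a, mu, s: a * np.exp(-0.5 * ((x - mu) / s) ** 2),
        np.arange(401.0), profile, p0=[profile.max(), 200.0, 4.0],
    )
    assert abs(popt[2] - 5.0) < 0.1
    # constants are preserved and kernel mass is conserved away from clipping
    const = np.full((10, 674), 77.0)
    out, _ = corrupt_smoothing(const, np.random.default_rng(0))
    np.testing.assert_allclose(out, const, atol=1e-9)
    mid = np.clip(mscan, 50, 200)  # keep away from the clip boundaries
    out, _ = corrupt_smoothing(mid, np.random.default_rng(0))
    assert abs(out.sum() / mid.sum() - 1.0) < 1e-3


def test_contrast_support_and_scaling(mscan):
    rng = np.random.default_rng(5)
    factors = [corrupt_contrast(mscan[:2, :4], rng)[1].params["factor"]
               for _ in range(6000)]
    assert set(factors) == set(CONTRAST_FACTORS)
    for f in CONTRAST_FACTORS:
        assert abs(factors.count(f) / 6000 - 1 / 6) < 0.03
    out, _ = corrupt_contrast(mscan, rng, factor=1.0)
    np.testing.assert_array_equal(out, mscan)
    # low contrast compresses the spread linearly (no clipping can engage)
    out, _ = corrupt_contrast(mscan, rng, factor=0.1)
    assert abs(out.std() / mscan.std() - 0.1) < 0.005


def test_intensity_shift_support(mscan):
    rng = np.random.default_rng(6)
    tiny = mscan[:2, :4]
    shifts = np.array(
        [corrupt_intensity(tiny, rng)[1].params["shift"] for _ in range(10_000)]
    )
    assert ((np.abs(shifts) >= 25.0) & (np.abs(shifts) <= 50.0)).all()
    assert abs((shifts > 0).mean() - 0.5) < 0.02
    const = np.full((10, 674), 128.0)
    out, _ = corrupt_intensity(const, rng, shift=40.0)
    assert (out == 168.0).all()
    out, _ = corrupt_intensity(mscan, rng, shift=0.0)
    np.testing.assert_array_equal(out, mscan)


def test_stripes_locality(mscan):
    rng = np.random.default_rng(7)
    for _ in range(50):
        out, spec = corrupt_stripes(mscan, rng)
        rows = spec.params["rows"]
        assert len(rows) in (1, 2)
        changed = [t for t in range(10) if not (out[t] == mscan[t]).all()]
        assert set(changed) <= set(rows)
        for r, v in zip(rows, spec.params["values"]):
            assert (out[r] == v).all()
            assert 100.0 <= v <= 200.0
        untouched = [t for t in range(10) if t not in rows]
        np.testing.assert_array_equal(out[untouched], mscan[untouched])


def test_rectangle_geometry(mscan):
    rng = np.random.default_rng(8)
    for _ in range(300):
        out, spec = corrupt_rectangle(mscan, rng)
        p = spec.params
        assert 6 <= p["width"] <= 10 and 15 <= p["depth"] <= 30
        r0, c0, w, d = p["row"], p["col"], p["width"], p["depth"]
        assert r0 + w <= 10 and c0 + d <= 674
        assert (out[r0 : r0 + w, c0 : c0 + d] == p["value"]).all()
        mask = np.zeros_like(mscan, bool)
        mask[r0 : r0 + w, c0 : c0 + d] = True
        np.testing.assert_array_equal(out[~mask], mscan[~mask])
        # pixels differing from the input are confined to the rectangle
        assert ((out != mscan) <= mask).all()
    with pytest.raises(ValueError):
        corrupt_rectangle(mscan[:5], rng)  # fewer than 6 A-scans


def test_shift_is_a_suffix_roll(mscan):
    rng = np.random.default_rng(9)
    for _ in range(200):
        out, spec = corrupt_shift(mscan, rng)
        s, split = spec.params["shift"], spec.params["split"]
        assert 25 <= abs(s) <= 100
        np.testing.assert_array_equal(out[:split], mscan[:split])
        for t in range(split, 10):
            np.testing.assert_array_equal(np.sort(out[t]), np.sort(mscan[t]))
            np.testing.assert_array_equal(out[t], np.roll(mscan[t], s))
    # a delta marker relocates by s mod P under the same roll
    marker = np.zeros((10, 674))
    marker[:, 300] = 255.0
    out, spec = corrupt_shift(marker, np.random.default_rng(1))
    s, split = spec.params["shift"], spec.params["split"]
    assert out[split].argmax() == (300 + s) % 674


def test_zoom_factor_and_edge_geometry():
    rng = np.random.default_rng(10)
    tiny = np.linspace(0, 255, 674)[None, :].repeat(2, axis=0)
    zs = [corrupt_zoom(tiny, rng)[1].params["factor"] for _ in range(2000)]
    assert all(1.5 <= z <= 1.75 for z in zs)
    out, _ = corrupt_zoom(tiny, rng, factor=1.0)
    np.testing.assert_allclose(out, tiny, atol=1e-9)
    # a step edge at depth d moves to round(z*d) - (round(z*P)-P)//2
    step = np.zeros((3, 674))
    step[:, 400:] = 200.0
    out, spec = corrupt_zoom(step, rng, factor=1.6)
    predicted = round(1.6 * 400) - spec.params["offset"]
    edge = int(np.argmax(out[0] > 100.0))
    assert abs(edge - predicted) <= 1


def test_corrupt_dataset_counts():
    mscans = np.full((2000, 10, 40), 60.0)
    rng = np.random.default_rng(11)
    out, labels, specs = corrupt_dataset(mscans, 0.0, rng)
    assert labels.sum() == 0 and (out == mscans).all()
    out, labels, specs = corrupt_dataset(mscans, 0.9, rng)
    assert labels.sum() == 1800
    counts = {ct: sum(1 for s in specs if s and s.ctype == ct)
              for ct in o.CORRUPTION_TYPES}
    # 1800 corruptions over 8 equiprobable types: 225 each, binomial 3-sigma
    for ct, c in counts.items():
        assert abs(c - 225) <= 42, (ct, c)
    out, labels, _ = corrupt_dataset(mscans, 0.5, rng)
    assert labels.sum() == 1000
    assert round_half_up(0.5 * 2000) == 1000


def test_corrupt_dataset_deterministic():
    mscans = np.full((40, 10, 40), 60.0)
    a = corrupt_dataset(mscans, 0.5, np.random.default_rng(3))
    b = corrupt_dataset(mscans, 0.5, np.random.default_rng(3))
    np.testing.assert_array_equal(a[0], b[0])
    np.testing.assert_array_equal(a[1], b[1])
    assert [s.ctype if s else None for s in a[2]] == [
        s.ctype if s else None for s in b[2]
    ]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    ctype=st.sampled_from(o.CORRUPTION_TYPES),
    seed=st.integers(0, 2**20),
    t=st.integers(6, 12),
)
def test_operators_preserve_shape_and_range(ctype, seed, t):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0, 255, size=(t, 80))
    out, spec = o.apply_corruption(m, ctype, rng)
    assert out.shape == m.shape
    assert out.min() >= 0.0 and out.max() <= 255.0
    assert spec.ctype == ctype
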