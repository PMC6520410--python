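import numpy as np
import pandas as pd
import pytest

from cortilam.model_io import ImageStack, NeuronTable
from cortilam.slice_features import (
    FeatureParams,
    SomaMeasurement,
    build_features,
    classify_neuron_types,
    mean_size_shape_per_slice,
    measure_soma,
    neuron_density,
    robust_mean,
    texture_features,
)

from conftest import gaussian_blob_stack


def table(xyz_rows, days=None):
    df = pd.DataFrame(xyz_rows, columns=["x", "y", "z"])
    if days is not None:
        df["day"] = days
    return NeuronTable(df)


class TestDensity:
    def test_counts_normalized_by_slice_area(self):
        # 2601 neurons in one 510 µm x 510 µm slice -> 10000 per mm²
        rows = [(i % 51, i // 51, 0) for i in range(2601)]
        t = table(rows)
        d = neuron_density(t, (1, 0.2601))
        assert d[0] == pytest.approx(10000.0)

    def test_empty_table_gives_zero_vector(self):
        t = NeuronTable(pd.DataFrame(columns=["x", "y", "z"]))
        assert np.array_equal(neuron_density(t, (5, 0.25)), np.zeros(5))

    def test_invariant_to_day_duplication(self, rng):
        rows = [(int(x), int(y), int(z)) for x, y, z in
                rng.integers(0, 10, size=(50, 3))]
        single = neuron_density(table(rows), (10, 0.1))
        dup = table(rows * 2, days=[0] * 50 + [1] * 50)
        assert np.allclose(neuron_density(dup, (10, 0.1)), single)

    def test_out_of_depth_neuron_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            neuron_density(table([(0, 0, 7)]), (5, 0.1))


class TestMeasureSoma:
    def test_gaussian_blob_half_max_area(self):
        # analytic half-max disc of a Gaussian: r = sigma * sqrt(2 ln 2)
        sigma = 3.0
        stack = gaussian_blob_stack(peak=200, background=20, sigma_px=sigma)
        m = measure_soma(stack, (32, 32, 1))
        assert m.valid
        expected = np.pi * (sigma * np.sqrt(2 * np.log(2))) ** 2
        assert m.area == pytest.approx(expected, rel=0.15)

    def test_disc_region_shape_near_one(self):
        # hard-edged disc of radius 5 px on black background
        vox = np.zeros((3, 32, 32))
        yy, xx = np.mgrid[0:32, 0:32]
        disc = (yy - 16) ** 2 + (xx - 16) ** 2 <= 25
        vox[1][disc] = 100.0
        m = measure_soma(ImageStack(vox, spacing=(1, 1, 2)), (16, 16, 1))
        assert m.valid
        # rasterized-disc oracle with the package's diameter convention
        # (max pairwise pixel-centre distance plus one pixel pitch)
        pts = np.column_stack([xx[disc], yy[disc]]).astype(float)
        d2 = ((pts[:, None] - pts[None, :]) ** 2).sum(-1)
        d_oracle = np.sqrt(d2.max()) + 1.0
        shape_oracle = np.pi * d_oracle**2 / (4 * disc.sum())
        assert m.shape == pytest.approx(shape_oracle, rel=1e-9)
        assert 0.9 <= m.shape <= 1.2

    def test_flat_slice_is_invalid(self, flat_stack):
        m = measure_soma(flat_stack, (16, 16, 1))
        assert not m.valid

    def test_shape_identity_holds(self):
        stack = gaussian_blob_stack()
        m = measure_soma(stack, (32, 32, 1))
        assert m.shape == pytest.approx(
            np.pi * m.max_diameter**2 / (4 * m.area), rel=1e-9
        )

    def test_single_pixel_region_gets_pixel_diameter(self):
        # one bright pixel: d = pixel pitch, not 0
        vox = np.full((2, 33, 33), 1.0)
        vox[0, 16, 16] = 100.0
        m = measure_soma(ImageStack(vox, spacing=(1, 1, 2)), (16, 16, 0))
        assert m.valid
        assert m.max_diameter == pytest.approx(1.0)
        assert m.area == pytest.approx(1.0)

    def test_region_capped_at_r_cap(self):
        vox = np.zeros((2, 101, 101))
        vox[0] = 0.0
        vox[0, 20:81, 20:81] = 100.0  # huge bright square
        vox[0, 50, 50] = 120.0
        m = measure_soma(
            ImageStack(vox, spacing=(1, 1, 2)), (50, 50, 0),
            FeatureParams(annulus=(45, 49), r_cap=10),
        )
        assert m.valid
        assert m.area <= np.pi * 11**2  # bounded by the cap radius


class TestRobustMean:
    def test_constant_data(self):
        assert robust_mean([5, 5, 5, 5]) == 5

    def test_outlier_downweighted(self):
        got = robust_mean([10, 10, 10, 10, 10, 1000])
        assert got == pytest.approx(10, rel=0.01)

    def test_matches_direct_irls_iteration(self, rng):
        v = np.concatenate([rng.normal(50, 5, 30), [500.0]])
        # independent direct IRLS with bisquare weights
        mu = np.median(v)
        for _ in range(200):
            r = v - mu
            s = np.median(np.abs(r)) / 0.6745
            u = r / (4.685 * s)
            w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
            mu = np.sum(w * v) / np.sum(w)
        assert robust_mean(v) == pytest.approx(mu, abs=1e-6)

    def test_short_list_median_fallback(self):
        assert robust_mean([3, 9]) == 6

    def test_empty_signalled(self):
        with pytest.raises(ValueError):
            robust_mean([])


def meas(z, area, shape=1.0, valid=True, day=0):
    d = np.sqrt(4 * area * shape / np.pi)
    return SomaMeasurement(0, z, area if valid else 0.0,
                           d if valid else 0.0, shape if valid else 0.0,
                           day, valid)


class TestPerSliceAverages:
    def test_near_constant_slice_is_mean(self):
        ms = [meas(0, a) for a in (50, 52, 48)]
        size, _ = mean_size_shape_per_slice(ms, 1)
        assert size[0] == pytest.approx(50, abs=0.5)

    def test_gap_imputed_by_interpolation(self):
        ms = [meas(0, 40), meas(2, 60)]
        size, _ = mean_size_shape_per_slice(ms, 3)
        assert size[1] == pytest.approx(50)

    def test_endpoints_extended_constantly(self):
        ms = [meas(1, 40)]
        size, _ = mean_size_shape_per_slice(ms, 3)
        assert np.allclose(size, 40)

    def test_single_slice_single_soma(self):
        size, shape = mean_size_shape_per_slice([meas(0, 30.0)], 1)
        assert size[0] == 30.0

    def test_all_invalid_signalled(self):
        with pytest.raises(ValueError):
            mean_size_shape_per_slice([meas(0, 0, valid=False)], 1)


class TestNeuronTyping:
    def test_well_separated_populations_recovered(self, rng):
        small = rng.normal(40, 4, 500)
        large = rng.normal(120, 10, 500)
        ms = [meas(0, a, 1.05) for a in small] + [meas(0, a, 1.2) for a in large]
        classes, per_slice = classify_neuron_types(ms, 1, seed=0)
        truth = np.array([1] * 500 + [2] * 500)
        assert np.mean(classes == truth) >= 0.99

    def test_class_one_is_smaller_population(self, rng):
        # larger population listed first must still become class 2
        ms = [meas(0, a) for a in rng.normal(120, 10, 100)] + [
            meas(0, a) for a in rng.normal(40, 4, 100)
        ]
        classes, _ = classify_neuron_types(ms, 1, seed=0)
        assert classes[0] == 2 and classes[-1] == 1

    def test_proportions_sum_to_one(self, rng):
        ms = [meas(z % 3, a) for z, a in enumerate(np.abs(rng.normal(80, 30, 300)) + 1)]
        _, per_slice = classify_neuron_types(ms, 3, seed=0)
        total = per_slice["prop_class1"] + per_slice["prop_class2"]
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_degenerate_data_signalled(self):
        ms = [meas(0, 50.0) for _ in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            classify_neuron_types(ms, 1)


def brute_force_texture(img, n_levels=8):
    """Independent double-loop co-occurrence computation."""
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        q = np.clip(np.floor((img - lo) / (hi - lo) * n_levels), 0, n_levels - 1)
    else:
        q = np.zeros_like(img)
    q = q.astype(int)
    P = np.zeros((n_levels, n_levels))
    ny, nx = q.shape
    for y in range(ny):
        for x in range(nx - 1):
            P[q[y, x], q[y, x + 1]] += 1
            P[q[y, x + 1], q[y, x]] += 1
    P /= P.sum()
    contrast = corr = energy = homog = 0.0
    mu_i = sum(i * P[i, j] for i in range(n_levels) for j in range(n_levels))
    mu_j = sum(j * P[i, j] for i in range(n_levels) for j in range(n_levels))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(n_levels) for j in range(n_levels))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(n_levels) for j in range(n_levels))
    for i in range(n_levels):
        for j in range(n_levels):
            contrast += (i - j) ** 2 * P[i, j]
            energy += P[i, j] ** 2
            homog += P[i, j] / (1 + abs(i - j))
            if var_i > 0 and var_j > 0:
                corr += (i - mu_i) * (j - mu_j) * P[i, j] / np.sqrt(var_i * var_j)
    return contrast, corr, energy, homog


class TestTexture:
    def test_constant_slice(self):
        c, r, e, h = texture_features(np.full((8, 8), 7.0))
        assert (c, r, e, h) == (0.0, 0.0, 1.0, 1.0)

    def test_two_level_checkerboard(self):
        img = np.indices((8, 8)).sum(axis=0) % 2 * 10.0
        c, r, e, h = texture_features(img)
        assert c == pytest.approx(49.0)
        assert r == pytest.approx(-1.0)
        assert e == pytest.approx(0.5)
        assert h == pytest.approx(0.125)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((16, 16)) * 100
        got = texture_features(img)
        want = brute_force_texture(img)
        assert np.allclose(got, want, atol=1e-12)


@pytest.fixture(scope="module")
def data():
    rng = np.random.default_rng(7)
    vox = np.clip(rng.normal(20, 3, size=(6, 64, 64)), 0, None)
    yy, xx = np.mgrid[0:64, 0:64]
    rows = []
    for z in range(6):
        for _ in range(8):
            x, y = rng.integers(8, 56, 2)
            vox[z] += 180 * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2 * 2.0**2)
            )
            rows.append((x, y, z))
    stack = ImageStack(vox, spacing=(1, 1, 2))
    return stack, table(rows)


class TestBuildFeatures:
    @pytest.mark.parametrize(
        "fset,ncols",
        [("F1", 1), ("F2", 2), ("F3", 5), ("F4", 6), ("F5", 6), ("F6", 4)],
    )
    def test_column_counts(self, data, fset, ncols):
        stack, neurons = data
        fm = build_features(stack, neurons, fset, FeatureParams(annulus=(5, 8)))
        assert fm.values.shape == (6, ncols)

    def test_f1_is_unstandardized_density(self, data):
        stack, neurons = data
        fm = build_features(stack, neurons, "F1")
        assert fm.feature_names == ["density"]
        assert not fm.standardized
        assert np.allclose(fm.values[:, 0], neuron_density(neurons, stack))

    def test_multifeature_standardized_by_default(self, data):
        stack, neurons = data
        fm = build_features(stack, neurons, "F6")
        assert fm.standardized
        # standardized non-constant columns have zero mean
        assert np.allclose(fm.values.mean(axis=0), 0, atol=1e-9)

    def test_unknown_set_rejected(self, data):
        stack, neurons = data
        with pytest.raises(ValueError, match="unknown feature set"):
            build_features(stack, neurons, "F7")

    def test_tsv_round_trip(self, data, tmp_path):
        from cortilam.slice_features import SliceFeatureMatrix

        stack, neurons = data
        fm = build_features(stack, neurons, "F1")
        p = tmp_path / "f.tsv"
        fm.write_tsv(p)
        back = SliceFeatureMatrix.read_tsv(p, "F1")
        assert np.allclose(back.values, fm.values)
        assert back.feature_names == fm.feature_names
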