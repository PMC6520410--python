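"""Per-slice feature extraction for the laminar clustering.

Six feature sets are supported, combining

* neuron density (detections per slice, normalized by slice area),
* rough soma size/shape measures obtained by half-maximum thresholding
  around each detected neuron centre,
* a two-class Gaussian-mixture typing of neurons on (size, shape),
  a proxy for granule vs. pyramidal populations, and
* four gray-level co-occurrence texture measures of the slice image
  (contrast, correlation, energy, homogeneity).

Feature sets:
  F1 density; F2 density+mean size; F3 density+class proportions+class
  mean sizes; F4 = F3 + overall mean size; F5 density+mean size+textures;
  F6 textures only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.ndimage import label as cc_label
from skimage.feature import graycomatrix
from sklearn.mixture import GaussianMixture

from .model_io import ImageStack, NeuronTable

__all__ = [
    "SomaMeasurement",
    "SliceFeatureMatrix",
    "FeatureParams",
    "FEATURE_SETS",
    "neuron_density",
    "measure_soma",
    "measure_all_somata",
    "robust_mean",
    "mean_size_shape_per_slice",
    "classify_neuron_types",
    "texture_features",
    "build_features",
]

FEATURE_SETS = ("F1", "F2", "F3", "F4", "F5", "F6")

TEXTURE_NAMES = ("contrast", "correlation", "energy", "homogeneity")


@dataclass
class FeatureParams:
    """Tunable parameters of feature extraction.

    ``annulus`` (inner, outer radius in px) bounds the local background
    ring for soma thresholding; ``r_cap`` (px) caps soma region growth;
    ``n_levels``/``offset`` parameterize the co-occurrence matrix;
    ``standardize`` is True/False or "auto" (on for multi-feature sets,
    off for the single-feature F1).
    """

    annulus: tuple[int, int] = (8, 14)
    r_cap: int = 20
    n_levels: int = 8
    offset: int = 1
    standardize: bool | str = "auto"
    seed: int = 0


@dataclass(frozen=True)
class SomaMeasurement:
    """Half-maximum soma delineation summary for one detected neuron.

    ``area`` in µm², ``max_diameter`` in µm, ``shape`` = pi*d^2 / (4*A)
    (1 for a disc, larger for elongated somata).  ``valid`` is False when
    the centre intensity does not rise above local background.
    """

    neuron_index: int
    z: int
    area: float
    max_diameter: float
    shape: float
    day: int
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid:
            if self.area <= 0 or self.max_diameter < 0:
                raise ValueError("valid measurement needs area > 0 and d >= 0")
            expect = np.pi * self.max_diameter**2 / (4 * self.area)
            if not np.isclose(self.shape, expect, rtol=1e-9, atol=1e-12):
                raise ValueError("shape must equal pi*d^2/(4A)")


@dataclass
class SliceFeatureMatrix:
    """z_max x n_features matrix whose rows align 1:1 with slices."""

    values: np.ndarray
    feature_names: list[str]
    feature_set_id: str
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match matrix columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def z_max(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "z", np.arange(1, self.z_max + 1))
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, feature_set_id="", standardized=False):
        df = pd.read_csv(path, sep="\t")
        names = [c for c in df.columns if c != "z"]
        return cls(df[names].to_numpy(float), names, feature_set_id, standardized)


# ---------------------------------------------------------------------------
# Individual features


def neuron_density(neurons: NeuronTable, stack_geometry) -> np.ndarray:
    """Detections per slice per mm², averaged over scan days.

    ``stack_geometry`` is an :class:`ImageStack` or a ``(z_max,
    slice_area_mm2)`` pair.
    """
    if isinstance(stack_geometry, ImageStack):
        z_max, area = stack_geometry.z_max, stack_geometry.slice_area_mm2()
    else:
        z_max, area = stack_geometry
    density = np.zeros(z_max, dtype=float)
    if not len(neurons):
        return density
    df = neurons.records
    days = neurons.days
    counts = np.zeros((len(days), z_max), dtype=float)
    for i, day in enumerate(days):
        zs = df.loc[df["day"] == day, "z"].to_numpy()
        if np.any(zs >= z_max):
            raise ValueError("neuron z outside stack depth")
        counts[i] = np.bincount(zs, minlength=z_max)
    return counts.mean(axis=0) / area


def _annulus_median(img: np.ndarray, x: int, y: int, r_in: int, r_out: int) -> float:
    ny, nx = img.shape
    y0, y1 = max(0, y - r_out), min(ny, y + r_out + 1)
    x0, x1 = max(0, x - r_out), min(nx, x + r_out + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rr2 = (yy - y) ** 2 + (xx - x) ** 2
    ring = img[y0:y1, x0:x1][(rr2 >= r_in**2) & (rr2 <= r_out**2)]
    if ring.size == 0:  # degenerate geometry near a tiny image corner
        ring = img[y0:y1, x0:x1].ravel()
    return float(np.median(ring))


def _max_pairwise_distance(pts: np.ndarray) -> float:
    """Maximum pairwise Euclidean distance between points (via convex hull)."""
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # collinear points: brute force on the full (small) set
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def measure_soma(
    stack: ImageStack,
    centre: tuple[int, int, int],
    params: FeatureParams | None = None,
    neuron_index: int = 0,
    day: int = 0,
) -> SomaMeasurement:
    """Delineate one soma by half-maximum thresholding around its centre.

    Background is the median intensity in an annulus around the centre;
    the threshold sits halfway between background and centre intensity.
    The soma is the connected above-threshold region containing the
    centre, grown at most ``r_cap`` pixels out.
    """
    params = params or FeatureParams()
    x, y, z = (int(v) for v in centre)
    img = np.asarray(stack.voxels[z], dtype=float)
    dx, dy, _ = stack.spacing
    centre_val = img[y, x]
    bg = _annulus_median(img, x, y, *params.annulus)
    if centre_val <= bg:
        return SomaMeasurement(neuron_index, z, 0.0, 0.0, 0.0, day, valid=False)
    thr = bg + (centre_val - bg) / 2.0

    r = params.r_cap
    ny, nx = img.shape
    y0, y1 = max(0, y - r), min(ny, y + r + 1)
    x0, x1 = max(0, x - r), min(nx, x + r + 1)
    win = img[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask = (win >= thr) & (((yy - y) ** 2 + (xx - x) ** 2) <= r * r)
    lab, _ = cc_label(mask, structure=np.ones((3, 3), dtype=int))
    region = lab == lab[y - y0, x - x0]
    n_px = int(region.sum())
    area = n_px * dx * dy
    pts = np.column_stack([xx[region] * dx, yy[region] * dy])
    d = _max_pairwise_distance(pts) + dx
    shape = np.pi * d**2 / (4 * area)
    return SomaMeasurement(neuron_index, z, area, d, shape, day)


def measure_all_somata(
    stack: ImageStack, neurons: NeuronTable, params: FeatureParams | None = None
) -> list[SomaMeasurement]:
    neurons.check_bounds(stack)
    df = neurons.records
    return [
        measure_soma(
            stack,
            (row.x, row.y, row.z),
            params,
            neuron_index=i,
            day=int(row.day),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def robust_mean(values) -> float:
    """Outlier-resistant location estimate.

    Intercept-only iteratively reweighted least squares with bisquare
    weights (tuning constant 4.685, scale = MAD/0.6745).  Lists shorter
    than 3 fall back to the median.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("robust_mean of an empty list is undefined")
    if v.size < 3:
        return float(np.median(v))
    mu = float(np.median(v))
    for _ in range(100):
        r = v - mu
        s = float(np.median(np.abs(r))) / 0.6745
        if s <= np.finfo(float).eps * max(1.0, abs(mu)):
            return mu
        u = r / (4.685 * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            return mu
        new = float(np.sum(w * v) / w.sum())
        if abs(new - mu) < 1e-10 * max(1.0, abs(mu)):
            return new
        mu = new
    return mu


def _interpolate_missing(per_slice: np.ndarray) -> np.ndarray:
    """Fill NaN slices by linear interpolation, constant at the ends."""
    out = per_slice.astype(float).copy()
    good = np.flatnonzero(~np.isnan(out))
    if good.size == 0:
        raise ValueError("no slice has a measured value to interpolate from")
    idx = np.arange(out.size)
    out = np.interp(idx, good, out[good])
    return out


def mean_size_shape_per_slice(
    measurements: list[SomaMeasurement], z_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice robust mean soma size (µm²) and shape, pooled across days.

    Slices without any valid measurement are imputed by linear
    interpolation from the nearest measured slices.
    """
    size = np.full(z_max, np.nan)
    shape = np.full(z_max, np.nan)
    by_slice: dict[int, list[SomaMeasurement]] = {}
    for m in measurements:
        if m.valid:
            by_slice.setdefault(m.z, []).append(m)
    if not by_slice:
        raise ValueError("no valid soma measurement in any slice")
    for z, ms in by_slice.items():
        size[z] = robust_mean([m.area for m in ms])
        shape[z] = robust_mean([m.shape for m in ms])
    return _interpolate_missing(size), _interpolate_missing(shape)


def classify_neuron_types(
    measurements: list[SomaMeasurement], z_max: int, seed: int = 0
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Two-class Gaussian-mixture typing of neurons on (size, shape).

    Returns per-measurement class labels (1 or 2, 0 for invalid
    measurements) and per-slice summary vectors: proportions of each
    class and robust mean sizes of each class, imputed where a class is
    absent from a slice.  Class 1 is the smaller-soma population.
    """
    valid = [m for m in measurements if m.valid]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid measurements for typing")
    X = np.array([[m.area, m.shape] for m in valid])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate measurements: all identical")
    gmm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        init_params="kmeans",
        n_init=1,
        random_state=seed,
    )
    raw = gmm.fit_predict(X)
    # class 1 = smaller mean soma size
    mean_area = [X[raw == k, 0].mean() if np.any(raw == k) else np.inf for k in (0, 1)]
    small = int(np.argmin(mean_area))
    cls_valid = np.where(raw == small, 1, 2)

    classes = np.zeros(len(measurements), dtype=int)
    vi = 0
    for i, m in enumerate(measurements):
        if m.valid:
            classes[i] = cls_valid[vi]
            vi += 1

    prop1 = np.full(z_max, np.nan)
    msize = {1: np.full(z_max, np.nan), 2: np.full(z_max, np.nan)}
    by_slice: dict[int, list[tuple[int, float]]] = {}
    for m, c in zip(measurements, classes):
        if m.valid:
            by_slice.setdefault(m.z, []).append((c, m.area))
    for z, items in by_slice.items():
        cs = np.array([c for c, _ in items])
        areas = np.array([a for _, a in items])
        prop1[z] = np.mean(cs == 1)
        for k in (1, 2):
            if np.any(cs == k):
                msize[k][z] = robust_mean(areas[cs == k])
    prop1 = _interpolate_missing(prop1)
    per_slice = {
        "prop_class1": prop1,
        "prop_class2": 1.0 - prop1,
        "mean_size_class1": _interpolate_missing(msize[1]),
        "mean_size_class2": _interpolate_missing(msize[2]),
    }
    return classes, per_slice


def _quantize(img: np.ndarray, n_levels: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros(img.shape, dtype=np.uint8)
    q = np.floor((img - lo) / (hi - lo) * n_levels).astype(int)
    return np.clip(q, 0, n_levels - 1).astype(np.uint8)


def texture_features(
    slice_image: np.ndarray, params: FeatureParams | None = None
) -> tuple[float, float, float, float]:
    """Co-occurrence texture measures of one slice.

    The image is linearly quantized to ``n_levels`` gray levels between
    its min and max; the co-occurrence matrix uses the horizontal
    neighbour offset at the given distance, symmetric and normalized.
    Returns (contrast, correlation, energy, homogeneity); correlation of
    a zero-variance co-occurrence distribution is defined as 0.
    """
    params = params or FeatureParams()
    n = params.n_levels
    q = _quantize(slice_image, n)
    P = graycomatrix(
        q, distances=[params.offset], angles=[0.0], levels=n, symmetric=True,
        normed=True,
    )[:, :, 0, 0]
    i = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    contrast = float(np.sum((ii - jj) ** 2 * P))
    mu_i = float(np.sum(ii * P))
    mu_j = float(np.sum(jj * P))
    var_i = float(np.sum((ii - mu_i) ** 2 * P))
    var_j = float(np.sum((jj - mu_j) ** 2 * P))
    if var_i * var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum((ii - mu_i) * (jj - mu_j) * P) / np.sqrt(var_i * var_j)
        )
    energy = float(np.sum(P**2))
    homogeneity = float(np.sum(P / (1.0 + np.abs(ii - jj))))
    return contrast, correlation, energy, homogeneity


# ---------------------------------------------------------------------------
# Feature-set assembly


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def build_features(
    stack: ImageStack | None,
    neurons: NeuronTable | None,
    feature_set_id: str,
    params: FeatureParams | None = None,
    seed: int | None = None,
    z_max: int | None = None,
    slice_area_mm2: float | None = None,
) -> SliceFeatureMatrix:
    """Assemble the per-slice feature matrix for one feature set.

    F1 needs only the neuron table and stack geometry (a stack, or
    explicit ``z_max`` + ``slice_area_mm2``); all other sets need the
    stack, and F2-F5 additionally the neuron table.
    """
    if feature_set_id not in FEATURE_SETS:
        raise ValueError(f"unknown feature set {feature_set_id!r}")
    params = params or FeatureParams()
    if seed is None:
        seed = params.seed
    if stack is not None:
        z_max = stack.z_max
        slice_area_mm2 = stack.slice_area_mm2()
    if z_max is None or slice_area_mm2 is None:
        raise ValueError("need a stack or explicit z_max and slice_area_mm2")

    cols: list[np.ndarray] = []
    names: list[str] = []

    def add(name: str, vec: np.ndarray) -> None:
        names.append(name)
        cols.append(np.asarray(vec, dtype=float))

    needs_density = feature_set_id in ("F1", "F2", "F3", "F4", "F5")
    needs_somata = feature_set_id in ("F2", "F3", "F4", "F5")
    needs_texture = feature_set_id in ("F5", "F6")

    if needs_density:
        if neurons is None:
            raise ValueError("feature set needs a neuron table")
        add("density", neuron_density(neurons, (z_max, slice_area_mm2)))

    if needs_somata:
        if stack is None:
            raise ValueError(f"feature set {feature_set_id} needs the image stack")
        measurements = measure_all_somata(stack, neurons, params)
        mean_size, _mean_shape = mean_size_shape_per_slice(measurements, z_max)
        if feature_set_id in ("F3", "F4"):
            _, per_slice = classify_neuron_types(measurements, z_max, seed)
            add("prop_class1", per_slice["prop_class1"])
            add("prop_class2", per_slice["prop_class2"])
            add("mean_size_class1", per_slice["mean_size_class1"])
            add("mean_size_class2", per_slice["mean_size_class2"])
            if feature_set_id == "F4":
                add("mean_size", mean_size)
        else:
            add("mean_size", mean_size)

    if needs_texture:
        if stack is None:
            raise ValueError(f"feature set {feature_set_id} needs the image stack")
        tex = np.array(
            [texture_features(stack.voxels[z], params) for z in range(z_max)]
        )
        for k, name in enumerate(TEXTURE_NAMES):
            add(name, tex[:, k])

    values = np.column_stack(cols)
    standardize = params.standardize
    if standardize == "auto":
        standardize = feature_set_id != "F1"
    if standardize:
        values = _standardize(values)
    return SliceFeatureMatrix(values, names, feature_set_id, bool(standardize))
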