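"""Synthetic laminar stacks with ground truth.

Emulates the statistical structure the discrimination method assumes: a
pile of x-y slices along cortical depth, flat layer boundaries, per-layer
neuron density (Poisson placement), two soma-size subpopulations per
layer (a small granule-like and a large pyramidal-like class), and slice
images rendered as Gaussian blobs whose half-maximum area equals the
drawn soma size, over a noisy background with optional depth attenuation.

Defaults follow typical 2-photon mouse-cortex geometry: a 510 µm x 510
µm field at 0.996 µm in-plane / 2 µm axial spacing, and layer densities
in the 10^4-10^5 neurons/mm^3 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_io import ImageStack, Labeling, NeuronTable

__all__ = [
    "LayerSpec",
    "LaminarSpec",
    "SyntheticLocation",
    "default_laminar_spec",
    "generate_neurons",
    "render_stack",
    "ground_truth_labeling",
    "make_location",
    "make_paired_locations",
]


@dataclass
class LayerSpec:
    """Statistical description of one cortical layer.

    ``density``: neurons per mm^3.  ``small_frac``: mixture weight of the
    small-soma class.  Size means/SDs in µm^2 and shape means/SDs
    (dimensionless, >= 1) are given per class as (small, large) pairs.
    """

    density: float
    small_frac: float = 0.5
    size_mean: tuple[float, float] = (40.0, 120.0)
    size_sd: tuple[float, float] = (6.0, 15.0)
    shape_mean: tuple[float, float] = (1.1, 1.25)
    shape_sd: tuple[float, float] = (0.05, 0.08)

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("layer density must be >= 0")
        if not 0 <= self.small_frac <= 1:
            raise ValueError("mixture weight must be in [0, 1]")


@dataclass
class LaminarSpec:
    """Full description of a synthetic location.

    ``boundaries`` are layer edges in slice indices, starting at 0 and
    ending at z_max, strictly increasing; ``layers`` has one entry per
    interval between consecutive edges.
    """

    boundaries: list[int]
    layers: list[LayerSpec]
    x_px: int = 512
    y_px: int = 512
    spacing: tuple[float, float, float] = (0.996, 0.996, 2.0)
    blob_amplitude: float = 150.0
    background: float = 20.0
    noise_sd: float = 5.0
    depth_attenuation: float = 0.0  # per-slice exponential decay coefficient

    def __post_init__(self) -> None:
        b = self.boundaries
        if len(b) < 2 or b[0] != 0 or any(x >= y for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing from 0 to z_max")
        if len(self.layers) != len(b) - 1:
            raise ValueError("need one layer spec per boundary interval")

    @property
    def z_max(self) -> int:
        return self.boundaries[-1]

    def slice_area_mm2(self) -> float:
        dx, dy, _ = self.spacing
        return self.x_px * dx * self.y_px * dy / 1e6

    def layer_volume_mm3(self, i: int) -> float:
        _, _, dz = self.spacing
        thick = self.boundaries[i + 1] - self.boundaries[i]
        return self.slice_area_mm2() * thick * dz / 1e3


@dataclass
class SyntheticLocation:
    """One generated location: stack (may be None when unrendered),
    detected-neuron table, per-neuron truth, and true layer labeling."""

    spec: LaminarSpec
    neurons: NeuronTable
    truth: pd.DataFrame  # per-neuron: layer, neuron_class, size, shape
    labeling: Labeling
    stack: ImageStack | None = None


def default_laminar_spec(
    slices_per_layer: int = 40,
    counts_per_slice: tuple[float, ...] = (100, 500, 300, 900, 700),
    small_fracs: tuple[float, ...] = (0.9, 0.5, 0.7, 0.2, 0.4),
    x_px: int = 512,
    y_px: int = 512,
    **render_kwargs,
) -> LaminarSpec:
    """Canonical five-layer test bed.

    Layer densities are stated as expected detections per slice and
    converted to per-mm^3 rates for the given field.  The default profile
    is non-monotone in depth (as cortical densities are: a dense
    granular layer over a sparser layer V) with adjacent-layer count gaps
    of at least five Poisson standard deviations, so per-slice density
    alone separates neighbouring layers.  Mixture weights of the
    small-soma class vary per layer as well.
    """
    if len(counts_per_slice) != len(small_fracs):
        raise ValueError("need one mixture weight per layer")
    n_layers = len(counts_per_slice)
    boundaries = [i * slices_per_layer for i in range(n_layers + 1)]
    spacing = render_kwargs.pop("spacing", (0.996, 0.996, 2.0))
    dx, dy, dz = spacing
    slice_vol_mm3 = x_px * dx * y_px * dy * dz / 1e9
    layers = [
        LayerSpec(density=c / slice_vol_mm3, small_frac=f)
        for c, f in zip(counts_per_slice, small_fracs)
    ]
    return LaminarSpec(
        boundaries=boundaries,
        layers=layers,
        x_px=x_px,
        y_px=y_px,
        spacing=spacing,
        **render_kwargs,
    )


def generate_neurons(
    spec: LaminarSpec, seed: int = 0
) -> tuple[NeuronTable, pd.DataFrame]:
    """Place neurons layer by layer.

    Counts are Poisson(density x layer volume); positions uniform within
    the layer; class Bernoulli(small_frac); sizes and shapes from
    class-specific normals truncated to positive (shape >= 1).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for li, layer in enumerate(spec.layers):
        vol = spec.layer_volume_mm3(li)
        if vol <= 0:
            raise ValueError(f"layer {li + 1} has zero volume")
        n = rng.poisson(layer.density * vol)
        if n == 0:
            continue
        z = rng.integers(spec.boundaries[li], spec.boundaries[li + 1], size=n)
        x = rng.integers(0, spec.x_px, size=n)
        y = rng.integers(0, spec.y_px, size=n)
        small = rng.random(n) < layer.small_frac
        cls = np.where(small, 1, 2)
        size = np.where(
            small,
            rng.normal(layer.size_mean[0], layer.size_sd[0], size=n),
            rng.normal(layer.size_mean[1], layer.size_sd[1], size=n),
        )
        size = np.maximum(size, 1.0)
        shp = np.where(
            small,
            rng.normal(layer.shape_mean[0], layer.shape_sd[0], size=n),
            rng.normal(layer.shape_mean[1], layer.shape_sd[1], size=n),
        )
        shp = np.maximum(shp, 1.0)
        for k in range(n):
            rows.append((x[k], y[k], z[k], 0, li + 1, cls[k], size[k], shp[k]))
    cols = ["x", "y", "z", "day", "layer", "neuron_class", "size", "shape"]
    df = pd.DataFrame(rows, columns=cols)
    table = NeuronTable(df[["x", "y", "z", "day"]])
    return table, df[["layer", "neuron_class", "size", "shape"]].copy()


def render_stack(
    neurons: NeuronTable,
    sizes_um2: np.ndarray,
    spec: LaminarSpec,
    seed: int = 0,
) -> ImageStack:
    """Render neurons as 2D Gaussian blobs into a noisy background stack.

    Each blob's half-maximum area equals the drawn soma size, so the
    half-maximum soma delineation recovers it.  Intensities are clipped
    at zero (the sensor reports non-negative counts).
    """
    rng = np.random.default_rng(seed)
    dx, dy, _ = spec.spacing
    z_max = spec.z_max
    vox = rng.normal(
        spec.background, spec.noise_sd, size=(z_max, spec.y_px, spec.x_px)
    )
    sizes = np.asarray(sizes_um2, dtype=float)
    if len(sizes) != len(neurons):
        raise ValueError("need one soma size per neuron")
    df = neurons.records
    ln2 = np.log(2.0)
    for (x, y, z), area in zip(df[["x", "y", "z"]].to_numpy(), sizes):
        # half-max radius r: area = pi r^2; FWHM = 2r => sigma = r/sqrt(2 ln 2)
        r_um = np.sqrt(area / np.pi)
        sig_x = r_um / np.sqrt(2 * ln2) / dx
        sig_y = r_um / np.sqrt(2 * ln2) / dy
        half = int(np.ceil(4 * max(sig_x, sig_y)))
        if 2 * half + 1 > min(spec.x_px, spec.y_px):
            raise ValueError("soma blob larger than the field of view")
        x0, x1 = max(0, x - half), min(spec.x_px, x + half + 1)
        y0, y1 = max(0, y - half), min(spec.y_px, y + half + 1)
        xs = np.arange(x0, x1) - x
        ys = np.arange(y0, y1) - y
        amp = spec.blob_amplitude * np.exp(-spec.depth_attenuation * z)
        blob = amp * np.exp(
            -(ys[:, None] ** 2) / (2 * sig_y**2) - (xs[None, :] ** 2) / (2 * sig_x**2)
        )
        vox[z, y0:y1, x0:x1] += blob
    return ImageStack(np.clip(vox, 0, None), spec.spacing)


def ground_truth_labeling(spec: LaminarSpec) -> Labeling:
    labels: list[str] = []
    for li, (s, e) in enumerate(zip(spec.boundaries, spec.boundaries[1:]), start=1):
        labels.extend([str(li)] * (e - s))
    return Labeling(labels, label_set_name="ground truth")


def make_location(
    spec: LaminarSpec, seed: int = 0, render: bool = True
) -> SyntheticLocation:
    neurons, truth = generate_neurons(spec, seed)
    stack = None
    if render:
        stack = render_stack(neurons, truth["size"].to_numpy(), spec, seed + 1)
    return SyntheticLocation(
        spec=spec,
        neurons=neurons,
        truth=truth,
        labeling=ground_truth_labeling(spec),
        stack=stack,
    )


def _jitter_boundaries(
    spec: LaminarSpec, jitter: int, rng: np.random.Generator
) -> LaminarSpec:
    if jitter == 0:
        return spec
    b = list(spec.boundaries)
    new = [b[0]]
    for i in range(1, len(b) - 1):
        shifted = b[i] + int(rng.integers(-jitter, jitter + 1))
        new.append(shifted)
    new.append(b[-1])
    if any(x >= y for x, y in zip(new, new[1:])):
        raise ValueError("thickness jitter collapsed a layer")
    return replace(spec, boundaries=new)


def make_paired_locations(
    spec: LaminarSpec,
    thickness_jitter: int = 0,
    seed: int = 0,
    render: bool = True,
) -> tuple[SyntheticLocation, SyntheticLocation]:
    """Reference/target pair sharing per-layer feature distributions.

    The target's layer boundaries are jittered by up to
    ``thickness_jitter`` slices; neuron draws are independent.
    """
    rng = np.random.default_rng(seed)
    s_ref, s_tgt = int(rng.integers(2**31)), int(rng.integers(2**31))
    target_spec = _jitter_boundaries(spec, thickness_jitter, rng)
    ref = make_location(spec, s_ref, render)
    tgt = make_location(target_spec, s_tgt, render)
    return ref, tgt
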