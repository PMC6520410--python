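"""Similarity metrics between laminar hierarchies and labelings.

Three comparison procedures:

* hierarchy vs hierarchy — boundary arrays: for each consecutive slice
  pair, the first hierarchy level on which the two slices share a
  c-layer; Gaussian-smoothed arrays are compared by Pearson correlation
  (kappa).
* hierarchy vs single-level (manual) labeling — the manual labeling's
  boundary array is a 0/1 indicator; the hierarchy is binarized per
  level and the maximum per-level correlation is kappa_m.
* labeling vs labeling — slice-wise agreement after mapping both label
  sets into a common set; the mean of the 0/1 agreement array gives the
  f-indices (f_c=B, f_d=B, f_d=c^ref, f_d1=d2).

Arrays of unequal length (different scan depths) are compared by sliding
the shorter over the longer and taking the best value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

from .model_io import Labeling, LayerHierarchy

__all__ = [
    "BoundaryArray",
    "LabelMap",
    "boundary_array",
    "manual_boundary_array",
    "binary_boundary_array",
    "smooth",
    "kappa",
    "kappa_m",
    "similarity_labelings",
    "sliding_max",
    "reference_quality",
    "perturb_boundaries",
    "cross_location_matrix",
]

DEFAULT_SPAN = 5
DEFAULT_SIGMA = 1.0


@dataclass
class BoundaryArray:
    """Per consecutive-slice-pair values; length = z_max - 1."""

    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError("boundary array must have at least one element")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class LabelMap:
    """Maps two label sets into a common label set.

    ``x_map``/``y_map`` send labels of the first/second labeling to
    common labels; labels absent from a map pass through unchanged
    (identity default).
    """

    x_map: dict = field(default_factory=dict)
    y_map: dict = field(default_factory=dict)

    def map_x(self, label: str) -> str:
        return str(self.x_map.get(label, self.x_map.get(str(label), label)))

    def map_y(self, label: str) -> str:
        return str(self.y_map.get(label, self.y_map.get(str(label), label)))


def boundary_array(h: LayerHierarchy) -> BoundaryArray:
    """First hierarchy level (1-based) at which each consecutive slice
    pair shares a c-layer; the final single-c-layer level guarantees a
    finite value everywhere."""
    out = np.zeros(h.z_max - 1, dtype=float)
    remaining = np.ones(h.z_max - 1, dtype=bool)
    for level in range(1, h.n_levels + 1):
        labels = h.slice_labels(level)
        same = labels[:-1] == labels[1:]
        newly = remaining & same
        out[newly] = level
        remaining &= ~same
    if remaining.any():
        raise ValueError("hierarchy never merges some consecutive slices")
    return BoundaryArray(out)


def manual_boundary_array(labeling: Labeling) -> BoundaryArray:
    """0/1 indicator of a label change between consecutive slices."""
    labs = labeling.labels
    vals = np.array(
        [1.0 if a != b else 0.0 for a, b in zip(labs, labs[1:])]
    )
    return BoundaryArray(vals)


def binary_boundary_array(h: LayerHierarchy, level: int) -> BoundaryArray:
    """Indicator that the pair merges only above the given level
    (1 iff boundary value > level)."""
    if not 0 <= level <= h.n_levels:
        raise ValueError(f"level {level} out of range 0..{h.n_levels}")
    raw = boundary_array(h).values
    return BoundaryArray((raw > level).astype(float))


def _gaussian_kernel(span: int, sigma: float) -> np.ndarray:
    half = span // 2
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def smooth(
    b: BoundaryArray, span: int = DEFAULT_SPAN, sigma: float = DEFAULT_SIGMA
) -> BoundaryArray:
    """Gaussian smoothing (normalized discrete kernel, reflect padding).

    Arrays shorter than the span fall back to the largest odd kernel that
    fits (down to the identity).
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be a positive odd integer")
    n = len(b)
    eff = min(span, n if n % 2 == 1 else n - 1)
    if eff < 3:
        return BoundaryArray(b.values.copy(), smoothed=True)
    kernel = _gaussian_kernel(eff, sigma)
    vals = correlate1d(b.values, kernel, mode="reflect")
    return BoundaryArray(vals, smoothed=True)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size != b.size:
        raise ValueError("arrays must have equal length")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def kappa(
    a: BoundaryArray,
    b: BoundaryArray,
    span: int = DEFAULT_SPAN,
    sigma: float = DEFAULT_SIGMA,
) -> float:
    """Pearson correlation of the (smoothed) boundary arrays; 0 when
    either array is constant."""
    if len(a) != len(b):
        raise ValueError("boundary arrays differ in length; use sliding_max")
    av = a.values if a.smoothed else smooth(a, span, sigma).values
    bv = b.values if b.smoothed else smooth(b, span, sigma).values
    return _pearson(av, bv)


def kappa_m(
    h: LayerHierarchy,
    manual: Labeling,
    span: int = DEFAULT_SPAN,
    sigma: float = DEFAULT_SIGMA,
) -> tuple[float, int]:
    """Maximum over hierarchy levels of the correlation between the
    smoothed manual 0/1 boundary array and the smoothed per-level binary
    boundary arrays; returns (kappa_m, best level)."""
    if len(manual) != h.z_max:
        raise ValueError("manual labeling does not match hierarchy depth")
    man = smooth(manual_boundary_array(manual), span, sigma)
    best, best_level = -np.inf, 1
    for level in range(1, h.n_levels + 1):
        k = kappa(man, smooth(binary_boundary_array(h, level), span, sigma))
        if k > best:
            best, best_level = k, level
    return float(best), best_level


def similarity_labelings(
    x: Labeling, y: Labeling, label_map: LabelMap | None = None
) -> tuple[np.ndarray, float]:
    """Slice-wise 0/1 agreement after mapping into the common label set,
    and its mean f."""
    if len(x) != len(y):
        raise ValueError("labelings differ in length; use sliding_max")
    label_map = label_map or LabelMap()
    dM = np.array(
        [
            1.0 if label_map.map_x(a) == label_map.map_y(b) else 0.0
            for a, b in zip(x.labels, y.labels)
        ]
    )
    return dM, float(dM.mean())


def sliding_max(short, long, measure) -> tuple[float, int]:
    """Best value of ``measure(short, chunk_of_long)`` over all offsets.

    ``short``/``long`` are sequences (numpy arrays or lists); inputs are
    swapped internally if needed.  Returns (max value, offset of the best
    chunk within the longer sequence).
    """
    a, b = list(short), list(long)
    swapped = False
    if len(a) > len(b):
        a, b = b, a
        swapped = True
    n, m = len(a), len(b)
    best, best_off = -np.inf, 0
    for off in range(m - n + 1):
        val = measure(a, b[off : off + n])
        if val > best:
            best, best_off = val, off
    del swapped  # offset is always within the longer sequence
    return float(best), best_off


def reference_quality(
    ref_clayers: Labeling, manual: Labeling, label_map: LabelMap | None = None
) -> tuple[int, float]:
    """(n_B, f_c=B): number of distinct manual layers present and the
    slice-agreement fraction between reference c-layers and manual layers."""
    n_B = len(set(manual.labels))
    _, f = similarity_labelings(ref_clayers, manual, label_map)
    return n_B, f


def perturb_boundaries(labeling: Labeling, nsa: int, seed: int = 0) -> Labeling:
    """Shift each internal layer boundary by a uniform integer in
    [-Nsa, Nsa], clipped so layer order is preserved and no layer empties.

    This is the control used to translate kappa values into an equivalent
    boundary-position uncertainty in slices.
    """
    if nsa < 0:
        raise ValueError("Nsa must be >= 0")
    if not labeling.is_contiguous():
        raise ValueError("can only perturb a contiguous labeling")
    labs = labeling.labels
    z_max = len(labs)
    bounds = [i for i in range(1, z_max) if labs[i] != labs[i - 1]]
    if nsa == 0 or not bounds:
        return Labeling(list(labs), labeling.label_set_name)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(-nsa, nsa + 1, size=len(bounds))
    new_bounds: list[int] = []
    prev = 0
    nb = len(bounds)
    for i, (b, s) in enumerate(zip(bounds, shifts)):
        lo = prev + 1
        hi = z_max - (nb - 1 - i) - 1
        new_bounds.append(int(np.clip(b + s, lo, hi)))
        prev = new_bounds[-1]
    layer_labels = [labs[0]] + [labs[b] for b in bounds]
    edges = [0] + new_bounds + [z_max]
    out: list[str] = []
    for lab, s, e in zip(layer_labels, edges, edges[1:]):
        out.extend([lab] * (e - s))
    return Labeling(out, labeling.label_set_name + " perturbed")


def cross_location_matrix(
    items: list,
    mode: str = "hierarchy-kappa",
    span: int = DEFAULT_SPAN,
    sigma: float = DEFAULT_SIGMA,
    label_map: LabelMap | None = None,
) -> np.ndarray:
    """Pairwise similarity between locations.

    ``mode='hierarchy-kappa'``: items are hierarchies, compared by kappa
    of smoothed boundary arrays.  ``mode='dlayer-f'``: items are slice
    labelings, compared by the agreement fraction f.  Unequal depths are
    handled by the sliding-window maximum.  Diagonal is 1.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 locations")
    n = len(items)
    out = np.eye(n)

    if mode == "hierarchy-kappa":
        arrays = [smooth(boundary_array(h), span, sigma).values for h in items]

        def pair(i: int, j: int) -> float:
            a, b = arrays[i], arrays[j]
            if a.size == b.size:
                return _pearson(a, b)
            val, _ = sliding_max(
                a, b, lambda u, v: _pearson(np.asarray(u), np.asarray(v))
            )
            return val

    elif mode == "dlayer-f":

        def pair(i: int, j: int) -> float:
            x, y = items[i], items[j]
            if len(x) == len(y):
                return similarity_labelings(x, y, label_map)[1]

            def f_chunks(u, v):
                lm = label_map or LabelMap()
                return float(
                    np.mean([lm.map_x(a) == lm.map_y(b) for a, b in zip(u, v)])
                )

            val, _ = sliding_max(x.labels, y.labels, f_chunks)
            return val

    else:
        raise ValueError(f"unknown mode {mode!r}")

    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pair(i, j)
    return out
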