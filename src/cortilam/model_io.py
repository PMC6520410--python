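"""Core domain types and file IO.

The pipeline works on four kinds of objects:

* :class:`ImageStack` — a 3D intensity volume, an ordered pile of x-y
  slices along cortical depth z.
* :class:`NeuronTable` — detected neuron centre coordinates (in pixels),
  optionally tagged with the scan day they were detected on.  Detection
  itself is upstream of this package.
* :class:`Labeling` — a single-level assignment of every z-slice to a
  layer label (manual Brodmann-style labels, c-layers at one hierarchy
  level, or transferred d-layers).
* :class:`LayerHierarchy` — the nested per-iteration partitions of the
  slices into contiguous c-layers produced by the iterative clustering.

Slice indices are 0-based half-open ``[z_start, z_end)`` internally;
every human-facing file format reports them 1-based inclusive.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "NeuronTable",
    "Labeling",
    "CLayer",
    "HierarchyLevel",
    "LayerHierarchy",
    "read_stack",
    "write_stack",
    "read_neurons",
    "write_neurons",
    "read_labeling",
    "write_labeling",
    "read_hierarchy",
    "write_hierarchy",
]

DEFAULT_SPACING = (0.996, 0.996, 2.0)  # (dx, dy, dz) in micrometres


@dataclass
class ImageStack:
    """3D intensity volume.

    ``voxels`` has shape ``(z_max, ny, nx)`` so that ``voxels[z]`` is the
    x-y slice at depth index ``z``.  ``spacing`` is ``(dx, dy, dz)`` in µm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("stack voxels must be a 3D array (z, y, x)")
        if self.z_max < 2:
            raise ValueError("a stack needs at least 2 slices")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all voxel spacings must be positive")
        if np.any(np.asarray(self.voxels, dtype=float) < 0):
            raise ValueError("stack intensities must be non-negative")

    @property
    def z_max(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape_xy(self) -> tuple[int, int]:
        ny, nx = self.voxels.shape[1:]
        return nx, ny

    def slice_area_mm2(self) -> float:
        nx, ny = self.shape_xy
        dx, dy, _ = self.spacing
        return nx * dx * ny * dy / 1e6


@dataclass
class NeuronTable:
    """Detected neuron centres in pixel coordinates.

    ``records`` is a DataFrame with integer columns ``x``, ``y``, ``z``
    and ``day``.  A table without scan-day information carries a single
    pseudo-day 0 so across-day averaging degenerates gracefully.
    """

    records: pd.DataFrame

    REQUIRED = ("x", "y", "z")

    def __post_init__(self) -> None:
        df = self.records
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"neuron table misses required column {col!r}")
        if "day" not in df.columns:
            df = df.assign(day=0)
        df = df[["x", "y", "z", "day"]].copy()
        for col in df.columns:
            vals = df[col].to_numpy()
            as_int = np.asarray(vals).astype(np.int64, casting="unsafe")
            if not np.all(as_int == np.asarray(vals, dtype=float)):
                raise ValueError(f"non-integer value in column {col!r}")
            df[col] = as_int
        if len(df) and (df[["x", "y", "z"]].to_numpy() < 0).any():
            raise ValueError("neuron coordinates must be non-negative")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def days(self) -> list[int]:
        if not len(self.records):
            return []
        return sorted(self.records["day"].unique().tolist())

    def check_bounds(self, stack: ImageStack) -> None:
        nx, ny = stack.shape_xy
        df = self.records
        ok = (
            (df["x"] < nx).all()
            and (df["y"] < ny).all()
            and (df["z"] < stack.z_max).all()
        )
        if not ok:
            raise ValueError("neuron coordinates exceed stack bounds")


@dataclass
class Labeling:
    """Assignment of each z-slice to one layer label.

    Labels are stored as strings so file round trips are lossless;
    integer layer indices are stringified on construction.  Contiguity is
    not required in general (only d-layer labelings derived from c-layers
    are contiguous by construction).
    """

    labels: list[str]
    label_set_name: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(v) for v in self.labels]
        if not self.labels:
            raise ValueError("labeling must cover at least one slice")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def label_order(self) -> list[str]:
        """Distinct labels in order of first appearance (superficial first)."""
        seen: dict[str, None] = {}
        for v in self.labels:
            seen.setdefault(v)
        return list(seen)

    def is_contiguous(self) -> bool:
        runs = 1 + sum(
            1 for a, b in zip(self.labels, self.labels[1:]) if a != b
        )
        return runs == len(set(self.labels))


@dataclass(frozen=True)
class CLayer:
    """One contiguous run of slices at one hierarchy level."""

    z_start: int
    z_end: int  # half-open
    cluster_id: int
    clayer_index: int  # 1-based, numbered superficial -> deep

    def __post_init__(self) -> None:
        if self.z_end <= self.z_start:
            raise ValueError("c-layer interval must be non-empty")


@dataclass(frozen=True)
class HierarchyLevel:
    mc: int
    clayers: tuple[CLayer, ...]

    @property
    def n_clayers(self) -> int:
        return len(self.clayers)


@dataclass
class LayerHierarchy:
    """Nested partitions of the slice range into contiguous c-layers.

    Level 1 is the first clustering iteration (largest cluster budget);
    the final level is a single c-layer covering the whole stack.
    """

    z_max: int
    levels: list[HierarchyLevel] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_hierarchy(self)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_counts(self) -> list[int]:
        return [lv.n_clayers for lv in self.levels]

    def slice_labels(self, level: int) -> np.ndarray:
        """Per-slice c-layer index (1-based) at a 1-based level."""
        if not 1 <= level <= self.n_levels:
            raise ValueError(f"level {level} out of range 1..{self.n_levels}")
        out = np.empty(self.z_max, dtype=int)
        for cl in self.levels[level - 1].clayers:
            out[cl.z_start : cl.z_end] = cl.clayer_index
        return out


def validate_hierarchy(h: LayerHierarchy) -> None:
    """Check partition, nestedness, monotonicity and final-singleton invariants."""
    if not h.levels:
        raise ValueError("hierarchy must have at least one level")
    if h.z_max < 2:
        raise ValueError("hierarchy must span at least 2 slices")
    prev_bounds: set[int] | None = None
    prev_count = None
    for li, lv in enumerate(h.levels, start=1):
        cls = lv.clayers
        if not cls:
            raise ValueError(f"level {li} has no c-layers")
        pos = 0
        bounds = set()
        for idx, cl in enumerate(cls, start=1):
            if cl.z_start != pos:
                raise ValueError(
                    f"level {li}: intervals do not partition the slice range"
                )
            if cl.clayer_index != idx:
                raise ValueError(
                    f"level {li}: c-layer indices must run 1..n superficial to deep"
                )
            pos = cl.z_end
            bounds.add(cl.z_end)
        if pos != h.z_max:
            raise ValueError(f"level {li}: intervals do not cover all slices")
        n_ids = len({cl.cluster_id for cl in cls})
        if len(cls) < n_ids:
            raise ValueError(f"level {li}: fewer c-layers than cluster ids")
        if prev_bounds is not None and not bounds <= prev_bounds:
            raise ValueError(f"level {li}: partition is not nested in level {li - 1}")
        if prev_count is not None and len(cls) > prev_count:
            raise ValueError(f"level {li}: c-layer count increased")
        prev_bounds, prev_count = bounds, len(cls)
    if h.levels[-1].n_clayers != 1:
        raise ValueError("final level must be a single c-layer")


# ---------------------------------------------------------------------------
# Readers / writers


def read_stack(path: str | os.PathLike, spacing=DEFAULT_SPACING) -> ImageStack:
    """Read a multi-page TIFF, or a directory of per-slice TIFFs in lexical order."""
    path = os.fspath(path)
    if os.path.isdir(path):
        names = sorted(
            f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff"))
        )
        if not names:
            raise FileNotFoundError(f"no TIFF slices in directory {path}")
        pages = [tifffile.imread(os.path.join(path, n)) for n in names]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError("slice TIFFs have unequal x-y shapes")
        vox = np.stack(pages, axis=0)
    else:
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        vox = tifffile.imread(path)
        if vox.ndim == 2:
            vox = vox[None]
    return ImageStack(vox, spacing)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    tifffile.imwrite(os.fspath(path), stack.voxels)


def read_neurons(path: str | os.PathLike) -> NeuronTable:
    """Read a delimited text table with header columns x, y, z and optional day."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    return NeuronTable(df)


def write_neurons(table: NeuronTable, path: str | os.PathLike) -> None:
    table.records.to_csv(path, index=False)


def write_labeling(labeling: Labeling, path: str | os.PathLike) -> None:
    """Write a labeling as TSV with 1-based z and label columns."""
    with open(path, "w") as fh:
        fh.write("z\tlabel\n")
        for z, lab in enumerate(labeling.labels, start=1):
            fh.write(f"{z}\t{lab}\n")


def read_labeling(path: str | os.PathLike, label_set_name: str = "") -> Labeling:
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    if "z" not in df.columns or "label" not in df.columns:
        raise ValueError("labeling file needs columns z and label")
    zs = df["z"].to_numpy()
    if len(np.unique(zs)) != len(zs):
        raise ValueError("duplicate z in labeling file")
    expected = np.arange(1, len(zs) + 1)
    if not np.array_equal(np.sort(zs), expected):
        raise ValueError("labeling file has a gap in z coverage")
    order = np.argsort(zs)
    labels = df["label"].to_numpy()[order].tolist()
    return Labeling(labels, label_set_name)


def write_hierarchy(h: LayerHierarchy, path: str | os.PathLike) -> None:
    doc = {
        "z_max": h.z_max,
        "levels": [
            {
                "mc": lv.mc,
                "clayers": [
                    {
                        "z_start": cl.z_start,
                        "z_end": cl.z_end,
                        "cluster_id": cl.cluster_id,
                        "clayer_index": cl.clayer_index,
                    }
                    for cl in lv.clayers
                ],
            }
            for lv in h.levels
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_hierarchy(path: str | os.PathLike) -> LayerHierarchy:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        levels = [
            HierarchyLevel(
                mc=int(lv["mc"]),
                clayers=tuple(
                    CLayer(
                        int(c["z_start"]),
                        int(c["z_end"]),
                        int(c["cluster_id"]),
                        int(c["clayer_index"]),
                    )
                    for c in lv["clayers"]
                ),
            )
            for lv in doc["levels"]
        ]
        z_max = int(doc["z_max"])
    except (KeyError, TypeError) as exc:
        raise ValueError(f"hierarchy file schema violation: {exc}") from exc
    return LayerHierarchy(z_max=z_max, levels=levels)
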