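"""SVM-ensemble transfer of reference c-layer labels to target c-layers.

An ensemble of m linear SVMs is trained on randomly sampled slices of a
reference location (features + its c-layer labels at a chosen hierarchy
level).  Applied to every slice of a target c-layer t (n_t slices), the
ensemble casts n_t * m votes over the reference layers r; the vote share
p(r) = n_r / (n_t * m) is read as a similarity between target c-layer t
and reference c-layer r, and the argmax defines the transferred d-layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .model_io import Labeling, LayerHierarchy
from .slice_features import SliceFeatureMatrix

__all__ = [
    "EnsembleParams",
    "MergeSpec",
    "SvmEnsemble",
    "TransferResult",
    "merge_reference_clayers",
    "train_ensemble",
    "transfer",
    "relabel_reference",
    "select_target_level",
]


@dataclass
class EnsembleParams:
    """m linear SVMs (cost C), each trained on a stratified random
    ``sample_fraction`` of the reference slices, without replacement."""

    m: int = 200
    cost: float = 1.0
    sample_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("ensemble size m must be >= 1")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")


@dataclass
class MergeSpec:
    """Groups of adjacent reference c-layers to merge, with an optional
    rename into evaluation labels (e.g. Brodmann names)."""

    groups: list[list] = field(default_factory=list)
    rename: dict | None = None


@dataclass
class SvmEnsemble:
    members: list[SVC]
    classes: list[str]  # reference labels, superficial -> deep
    feature_names: list[str]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    params: EnsembleParams

    def apply_scaling(self, values: np.ndarray) -> np.ndarray:
        return (values - self.scale_mean) / self.scale_std


@dataclass
class ClayerTransfer:
    target_label: str
    n_slices: int
    votes: dict[str, int]
    probabilities: dict[str, float]
    d_layer: str


@dataclass
class TransferResult:
    clayers: list[ClayerTransfer]
    labeling: Labeling  # per-slice d-layer assignment
    ref_labels: list[str]
    m: int

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "ref_labels": self.ref_labels,
            "clayers": [
                {
                    "target_label": c.target_label,
                    "n_slices": c.n_slices,
                    "votes": c.votes,
                    "probabilities": c.probabilities,
                    "d_layer": c.d_layer,
                }
                for c in self.clayers
            ],
            "slice_d_layers": self.labeling.labels,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def merge_reference_clayers(labeling: Labeling, spec: MergeSpec) -> Labeling:
    """Merge groups of adjacent reference c-layers into single layers.

    Members of each group must be adjacent in the depth order of the
    labeling; the merged labeling is re-indexed 1..k superficial to deep,
    then optionally renamed.
    """
    order = labeling.label_order
    pos = {lab: i for i, lab in enumerate(order)}
    group_of: dict[str, int] = {}
    for gi, group in enumerate(spec.groups):
        members = [str(g) for g in group]
        for mlab in members:
            if mlab not in pos:
                raise ValueError(f"merge group references unknown label {mlab!r}")
            if mlab in group_of:
                raise ValueError("merge groups must be disjoint")
            group_of[mlab] = gi
        idxs = sorted(pos[mlab] for mlab in members)
        if idxs != list(range(idxs[0], idxs[-1] + 1)):
            raise ValueError(f"merge group {group!r} members are not adjacent in depth")
    # new label per original label: collapse each group onto its most
    # superficial member, then re-index 1..k in depth order
    rep: dict[str, str] = {}
    for lab in order:
        if lab in group_of:
            gi = group_of[lab]
            first = min(
                (l for l in group_of if group_of[l] == gi), key=lambda l: pos[l]
            )
            rep[lab] = first
        else:
            rep[lab] = lab
    new_order: list[str] = []
    for lab in order:
        if rep[lab] not in new_order:
            new_order.append(rep[lab])
    index = {lab: str(i) for i, lab in enumerate(new_order, start=1)}
    labels = [index[rep[lab]] for lab in labeling.labels]
    if spec.rename:
        rename = {str(k): str(v) for k, v in spec.rename.items()}
        labels = [rename.get(lab, lab) for lab in labels]
    return Labeling(labels, label_set_name=labeling.label_set_name + " merged")


def train_ensemble(
    ref_features: SliceFeatureMatrix,
    ref_labeling: Labeling,
    params: EnsembleParams | None = None,
) -> SvmEnsemble:
    """Train m linear SVMs on stratified random samples of reference slices.

    Feature scaling (z-score) is learned on the full reference and stored
    for reuse on targets.  Multiclass handling is one-vs-one (SVC default).
    """
    params = params or EnsembleParams()
    if len(ref_labeling) != ref_features.z_max:
        raise ValueError("labeling and feature matrix cover different slice counts")
    y = np.asarray(ref_labeling.labels)
    classes = ref_labeling.label_order
    if len(classes) < 2:
        raise ValueError("need at least 2 reference labels to train")
    mean = ref_features.values.mean(axis=0)
    std = ref_features.values.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    X = (ref_features.values - mean) / std

    rng = np.random.default_rng(params.seed)
    class_idx = {c: np.flatnonzero(y == c) for c in classes}
    for c, idx in class_idx.items():
        if max(1, int(np.floor(params.sample_fraction * idx.size))) < 1:
            raise ValueError(f"label {c!r} has no slice to sample")
    members: list[SVC] = []
    for _ in range(params.m):
        sel: list[np.ndarray] = []
        for c in classes:
            idx = class_idx[c]
            k = max(1, int(np.floor(params.sample_fraction * idx.size)))
            sel.append(rng.choice(idx, size=k, replace=False))
        train = np.concatenate(sel)
        svm = SVC(kernel="linear", C=params.cost)
        svm.fit(X[train], y[train])
        members.append(svm)
    return SvmEnsemble(
        members=members,
        classes=classes,
        feature_names=list(ref_features.feature_names),
        scale_mean=mean,
        scale_std=std,
        params=params,
    )


def transfer(
    ensemble: SvmEnsemble,
    target_features: SliceFeatureMatrix,
    target_clayer_labeling: Labeling,
) -> TransferResult:
    """Vote reference labels onto target c-layers and assign d-layers.

    Ties at the vote maximum resolve to the most superficial reference
    layer.  The returned labeling assigns each slice the d-layer of its
    target c-layer.
    """
    if list(target_features.feature_names) != ensemble.feature_names:
        raise ValueError("target feature columns differ from reference")
    if len(target_clayer_labeling) != target_features.z_max:
        raise ValueError("target labeling and features cover different slice counts")
    X = ensemble.apply_scaling(target_features.values)
    # votes[i, z] = reference label voted by member i for slice z
    votes = np.stack([svm.predict(X) for svm in ensemble.members])

    ref_labels = ensemble.classes
    tlabels = np.asarray(target_clayer_labeling.labels)
    clayers: list[ClayerTransfer] = []
    slice_d = np.empty(len(tlabels), dtype=object)
    for tlab in target_clayer_labeling.label_order:
        zsel = np.flatnonzero(tlabels == tlab)
        n_t = zsel.size
        block = votes[:, zsel]
        counts = {r: int(np.sum(block == r)) for r in ref_labels}
        total = n_t * len(ensemble.members)
        probs = {r: counts[r] / total for r in ref_labels}
        best = max(ref_labels, key=lambda r: (probs[r], -ref_labels.index(r)))
        clayers.append(
            ClayerTransfer(
                target_label=str(tlab),
                n_slices=int(n_t),
                votes=counts,
                probabilities=probs,
                d_layer=best,
            )
        )
        slice_d[zsel] = best
    labeling = Labeling(list(slice_d), label_set_name="d-layers")
    return TransferResult(
        clayers=clayers,
        labeling=labeling,
        ref_labels=list(ref_labels),
        m=len(ensemble.members),
    )


def relabel_reference(
    ensemble: SvmEnsemble,
    ref_features: SliceFeatureMatrix,
    ref_labeling: Labeling,
) -> TransferResult:
    """Transfer with the reference serving as its own target; the
    agreement of d-layers with the original c-layers feeds f_d=c^ref."""
    return transfer(ensemble, ref_features, ref_labeling)


def select_target_level(h: LayerHierarchy, n_ref_layers: int) -> int:
    """Deepest (latest-iteration) level whose c-layer count >= n_ref_layers."""
    if n_ref_layers < 1:
        raise ValueError("n_ref_layers must be >= 1")
    counts = h.level_counts()
    qualifying = [i for i, c in enumerate(counts, start=1) if c >= n_ref_layers]
    if not qualifying:
        raise ValueError(
            f"no hierarchy level has >= {n_ref_layers} c-layers (max {max(counts)})"
        )
    return qualifying[-1]
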