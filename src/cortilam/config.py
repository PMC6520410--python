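"""Pipeline configuration and end-to-end orchestration.

Defaults mirror the method's published operating point: initial cluster
budget mc0 = 10, ensemble size m = 200 linear SVMs at cost 1, and a
5-element Gaussian smoothing span for boundary arrays.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from . import evaluation as ev
from .label_transfer import (
    EnsembleParams,
    MergeSpec,
    merge_reference_clayers,
    relabel_reference,
    select_target_level,
    train_ensemble,
    transfer,
)
from .laminar_clustering import (
    ClusteringParams,
    build_hierarchy,
    get_level_labeling,
)
from .model_io import (
    Labeling,
    read_labeling,
    read_neurons,
    read_stack,
    write_hierarchy,
    write_labeling,
)
from .slice_features import FeatureParams, build_features

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class EvalParams:
    span: int = 5
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.span < 3 or self.span % 2 == 0:
            raise ValueError("smoothing span must be an odd integer >= 3")
        if self.sigma <= 0:
            raise ValueError("smoothing sigma must be positive")


@dataclass
class TransferConfig(EnsembleParams):
    # fixed-level overrides for the reference/target hierarchy levels;
    # None selects the deepest level with enough c-layers automatically
    ref_level: int | None = None
    target_level: int | None = None


@dataclass
class PipelineConfig:
    features: FeatureParams = field(default_factory=FeatureParams)
    feature_set: str = "F1"
    transfer_feature_set: str | None = None  # defaults to feature_set
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    evaluation: EvalParams = field(default_factory=EvalParams)
    merge_groups: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "features": FeatureParams,
    "clustering": ClusteringParams,
    "transfer": TransferConfig,
    "evaluation": EvalParams,
}


def validate_config(source) -> PipelineConfig:
    """Build a config from a YAML path or a dict; unknown keys are
    rejected and defaults injected for everything unspecified."""
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            doc = yaml.safe_load(fh) or {}
    else:
        doc = dict(source or {})
    if not isinstance(doc, dict):
        raise ValueError("config must be a mapping")
    cfg = PipelineConfig()
    for key, val in doc.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            allowed = set(cls.__dataclass_fields__)
            extra = set(val or {}) - allowed
            if extra:
                raise ValueError(f"unknown config keys in {key}: {sorted(extra)}")
            kwargs = dict(val or {})
            for name in ("annulus",):
                if name in kwargs and isinstance(kwargs[name], list):
                    kwargs[name] = tuple(kwargs[name])
            setattr(cfg, key, cls(**kwargs))
        elif key == "feature_set":
            cfg.feature_set = str(val)
        elif key == "transfer_feature_set":
            cfg.transfer_feature_set = None if val is None else str(val)
        elif key == "merge_groups":
            cfg.merge_groups = list(val or [])
        else:
            raise ValueError(f"unknown config key {key!r}")
    if cfg.feature_set not in ("F1", "F2", "F3", "F4", "F5", "F6"):
        raise ValueError(f"unknown feature set {cfg.feature_set!r}")
    return cfg


def _load_inputs(entry: dict):
    stack = read_stack(entry["stack"]) if entry.get("stack") else None
    neurons = read_neurons(entry["neurons"]) if entry.get("neurons") else None
    manual = None
    if entry.get("manual"):
        manual = read_labeling(entry["manual"], label_set_name="B-layers")
    return stack, neurons, manual


def run_pipeline(
    config: PipelineConfig,
    reference: dict,
    targets: list[dict],
    out_dir: str | os.PathLike,
) -> dict:
    """Full run: features -> hierarchies -> reference labels (optionally
    merged) -> SVM ensemble -> transfer to each target -> indices.

    ``reference`` and each target entry are dicts with keys ``name``,
    ``stack``, ``neurons`` and optional ``manual`` (file paths).  Returns
    the run report (also written to ``out_dir/report.json``).
    """
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {"config": config.to_dict(), "targets": []}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[stage {name}] {exc}") from exc

    tf_set = config.transfer_feature_set or config.feature_set

    ref_stack, ref_neurons, ref_manual = stage("load-reference", _load_inputs, reference)
    ref_cluster_feats = stage(
        "reference-features",
        build_features,
        ref_stack,
        ref_neurons,
        config.feature_set,
        config.features,
    )
    ref_h = stage("reference-clustering", build_hierarchy, ref_cluster_feats.values,
                  config.clustering)
    write_hierarchy(ref_h, os.path.join(out_dir, "reference_hierarchy.json"))

    ref_level = config.transfer.ref_level
    if ref_level is None:
        # default convention: pick the level whose c-layer count is closest
        # to the manual layer count when a manual labeling is available
        if ref_manual is not None:
            want = len(set(ref_manual.labels))
            counts = ref_h.level_counts()
            ref_level = int(
                min(range(1, len(counts) + 1), key=lambda i: (abs(counts[i - 1] - want), -i))
            )
        else:
            ref_level = min(8, ref_h.n_levels)
    ref_labeling = get_level_labeling(ref_h, ref_level)
    if config.merge_groups:
        ref_labeling = stage(
            "merge-reference",
            merge_reference_clayers,
            ref_labeling,
            MergeSpec(groups=config.merge_groups),
        )
    write_labeling(ref_labeling, os.path.join(out_dir, "reference_clayers.tsv"))
    report["reference"] = {
        "name": reference.get("name", "reference"),
        "level": ref_level,
        "n_ref_layers": len(ref_labeling.label_order),
        "ref_labels": list(ref_labeling.label_order),
    }
    if ref_manual is not None:
        n_B, f_cB = ev.reference_quality(ref_labeling, ref_manual)
        km, klev = ev.kappa_m(
            ref_h, ref_manual, config.evaluation.span, config.evaluation.sigma
        )
        report["reference"].update(
            {"n_B": n_B, "f_c_eq_B": f_cB, "kappa_m": km, "kappa_m_level": klev}
        )

    ref_tf_feats = (
        ref_cluster_feats
        if tf_set == config.feature_set
        else stage(
            "reference-transfer-features",
            build_features,
            ref_stack,
            ref_neurons,
            tf_set,
            config.features,
        )
    )
    ensemble = stage("train-ensemble", train_ensemble, ref_tf_feats, ref_labeling,
                     config.transfer)
    self_res = stage("relabel-reference", relabel_reference, ensemble, ref_tf_feats,
                     ref_labeling)
    _, f_self = ev.similarity_labelings(self_res.labeling, ref_labeling)
    report["reference"]["f_d_eq_c_ref"] = f_self

    n_ref = len(ref_labeling.label_order)
    for entry in targets:
        name = entry.get("name", "target")
        t_stack, t_neurons, t_manual = stage(f"load-{name}", _load_inputs, entry)
        t_cluster_feats = stage(
            f"features-{name}",
            build_features,
            t_stack,
            t_neurons,
            config.feature_set,
            config.features,
        )
        t_h = stage(f"clustering-{name}", build_hierarchy, t_cluster_feats.values,
                    config.clustering)
        write_hierarchy(t_h, os.path.join(out_dir, f"{name}_hierarchy.json"))
        t_level = config.transfer.target_level or select_target_level(t_h, n_ref)
        t_clayers = get_level_labeling(t_h, t_level)
        t_tf_feats = (
            t_cluster_feats
            if tf_set == config.feature_set
            else stage(
                f"transfer-features-{name}",
                build_features,
                t_stack,
                t_neurons,
                tf_set,
                config.features,
            )
        )
        res = stage(f"transfer-{name}", transfer, ensemble, t_tf_feats, t_clayers)
        res.write_json(os.path.join(out_dir, f"{name}_transfer.json"))
        write_labeling(res.labeling, os.path.join(out_dir, f"{name}_dlayers.tsv"))
        trec = {
            "name": name,
            "level": t_level,
            "n_target_clayers": len(t_clayers.label_order),
            "d_layers": [c.d_layer for c in res.clayers],
        }
        if t_manual is not None:
            _, f_dB = ev.similarity_labelings(res.labeling, t_manual)
            km, klev = ev.kappa_m(
                t_h, t_manual, config.evaluation.span, config.evaluation.sigma
            )
            trec.update({"f_d_eq_B": f_dB, "kappa_m": km, "kappa_m_level": klev})
        report["targets"].append(trec)

    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
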