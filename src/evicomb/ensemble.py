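"""The evidence-based combining classifier and reference combiners.

The evidential path: each feature-space view is confidence-relabeled, an
MLP expert is trained on its relabeled samples, and at test time the
experts' softmax outputs are read as basic belief assignments whose focal
elements are the views' crisp/soft classes.  Dempster's rule fuses the
per-view evidence and the pignistic transformation yields the decision.

Also provided: the fixed-rule combiners (average / product / maximum /
minimum over decision profiles), the decision-templates combiner, and the
KNN-relabeling evidential variant — all operating on per-view experts of
the same architecture, trained on the original crisp labels (fixed rules)
or KNN-relabeled data (the variant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ds_core import Frame, MassFunction, NotCombinableError, combine, pignistic, \
    PignisticDistribution
from .experts import ExpertModel, MLPConfig, expert_bba, train_mlp_expert
from .relabeling import RelabelConfig, RelabeledDataset, TemplateVector, \
    knn_relabel, relabel_dataset
from .views import FeatureSpaceView

__all__ = [
    "EvidenceEnsemble",
    "DecisionTemplates",
    "fit_evidence_ensemble",
    "fit_knn_evidence_ensemble",
    "fit_plain_experts",
    "predict",
    "predict_batch",
    "decision_profile",
    "fixed_rule_combine",
    "decision_templates_fit",
    "decision_templates_predict",
]

FIXED_RULES = ("average", "product", "maximum", "minimum")


@dataclass
class ViewState:
    """Per-view training artifacts: relabeling state plus the trained expert."""

    expert: ExpertModel
    relabeled: RelabeledDataset | None = None
    template: TemplateVector | None = None
    relabel_net: ExpertModel | None = None


@dataclass
class EvidenceEnsemble:
    """The fitted combining classifier: one expert per feature-space view."""

    frame: Frame
    views: list[ViewState]
    relabel_cfg: RelabelConfig | None = None

    def __post_init__(self):
        if not self.views:
            raise ValueError("an ensemble needs at least one view")
        for vs in self.views:
            if tuple(vs.expert.frame_classes) != self.frame.classes:
                raise ValueError("all experts must share the ensemble frame")


def _check_views(views: Sequence[FeatureSpaceView]) -> None:
    n = len(views[0])
    labels = views[0].labels
    for v in views[1:]:
        if len(v) != n:
            raise ValueError("views must index the same samples (length mismatch)")
        if not np.array_equal(v.labels, labels):
            raise ValueError("views must share the same labels")


def fit_evidence_ensemble(
    views: Sequence[FeatureSpaceView],
    val_views: Sequence[FeatureSpaceView] | None,
    relabel_cfg: RelabelConfig,
    relabel_mlp: MLPConfig | None = None,
    expert_mlp: MLPConfig | None = None,
) -> EvidenceEnsemble:
    """Confidence-relabel each view and train an expert on the relabeled data."""
    _check_views(views)
    relabel_mlp = relabel_mlp or MLPConfig()
    expert_mlp = expert_mlp or MLPConfig()
    frame = Frame(views[0].classes)
    states = []
    for i, view in enumerate(views):
        vX = val_views[i].features if val_views else None
        vy = val_views[i].labels if val_views else None
        rcfg = MLPConfig(**{**relabel_mlp.__dict__, "seed": relabel_mlp.seed + i,
                            "monitor": "loss"})
        ds, net, template = relabel_dataset(view.features, view.labels, relabel_cfg,
                                            rcfg, vX, vy)
        ecfg = MLPConfig(**{**expert_mlp.__dict__, "seed": expert_mlp.seed + 1000 + i,
                            "monitor": "accuracy"})
        val_labs = [(int(c),) for c in vy] if vy is not None else None
        # validation labels stay crisp; crisp singletons are always in the
        # expanded class list, so early stopping scores original-label accuracy
        expert = train_mlp_expert(ds.features, ds.labels, vX, val_labs, ecfg,
                                  class_list=ds.expanded_classes)
        states.append(ViewState(expert, ds, template, net))
    return EvidenceEnsemble(frame, states, relabel_cfg)


def fit_knn_evidence_ensemble(
    views: Sequence[FeatureSpaceView],
    val_views: Sequence[FeatureSpaceView] | None,
    k: int = 5,
    threshold: float = 0.3,
    expert_mlp: MLPConfig | None = None,
) -> EvidenceEnsemble:
    """The KNN-relabeling evidential baseline: same fusion, local relabeler."""
    _check_views(views)
    expert_mlp = expert_mlp or MLPConfig()
    frame = Frame(views[0].classes)
    states = []
    for i, view in enumerate(views):
        ds = knn_relabel(view.features, view.labels, k=k, threshold=threshold)
        vX = val_views[i].features if val_views else None
        val_labs = [(int(c),) for c in val_views[i].labels] if val_views else None
        ecfg = MLPConfig(**{**expert_mlp.__dict__, "seed": expert_mlp.seed + 2000 + i,
                            "monitor": "accuracy"})
        expert = train_mlp_expert(ds.features, ds.labels, vX, val_labs, ecfg,
                                  class_list=ds.expanded_classes)
        states.append(ViewState(expert, ds))
    return EvidenceEnsemble(frame, states)


def fit_plain_experts(
    views: Sequence[FeatureSpaceView],
    val_views: Sequence[FeatureSpaceView] | None,
    expert_mlp: MLPConfig | None = None,
) -> list[ExpertModel]:
    """Train per-view experts on the original crisp labels (fixed-rule path)."""
    _check_views(views)
    expert_mlp = expert_mlp or MLPConfig()
    experts = []
    for i, view in enumerate(views):
        vX = val_views[i].features if val_views else None
        val_labs = [(int(c),) for c in val_views[i].labels] if val_views else None
        cfg = MLPConfig(**{**expert_mlp.__dict__, "seed": expert_mlp.seed + 3000 + i,
                           "monitor": "accuracy"})
        experts.append(train_mlp_expert(view.features, [(int(c),) for c in view.labels],
                                        vX, val_labs, cfg))
    return experts


def predict(ens: EvidenceEnsemble, x_views: Sequence[np.ndarray],
            on: str = "raw") -> tuple[int, PignisticDistribution]:
    """Fuse per-view evidence for one sample and decide pignistically.

    BBAs are combined left to right; a BBA whose inclusion would make the
    running conflict total (K within 1e-12 of 1) is skipped with a warning
    rather than failing the prediction.  Ties in the pignistic argmax go to
    the lowest class index.
    """
    if len(x_views) != len(ens.views):
        raise ValueError(f"expected {len(ens.views)} view inputs, got {len(x_views)}")
    bbas = [expert_bba(vs.expert, np.asarray(x), on=on)
            for vs, x in zip(ens.views, x_views)]
    out: MassFunction | None = None
    for i, m in enumerate(bbas):
        if out is None:
            out = m
            continue
        try:
            out = combine(out, m)
        except NotCombinableError as exc:
            warnings.warn(f"skipping totally conflicting evidence from view {i} "
                          f"(K = {exc.k:.6f})", stacklevel=2)
    if out is None:
        raise NotCombinableError(1.0, "no combinable evidence")
    betp = pignistic(out)
    return int(betp.argmax_class()), betp


def predict_batch(ens: EvidenceEnsemble, view_matrices: Sequence[np.ndarray],
                  on: str = "raw") -> np.ndarray:
    """Vectorized convenience wrapper: one prediction per row across views."""
    n = len(view_matrices[0])
    preds = np.empty(n, dtype=int)
    for j in range(n):
        preds[j], _ = predict(ens, [X[j] for X in view_matrices], on=on)
    return preds


# ---------------------------------------------------------------------------
# baseline combiners over decision profiles


def decision_profile(experts: Sequence[ExpertModel], x_views: Sequence[np.ndarray]) -> np.ndarray:
    """Stack per-expert class supports (logistic outputs) into an L x C matrix."""
    rows = []
    for expert, x in zip(experts, x_views):
        if any(len(c) != 1 for c in expert.class_list):
            raise ValueError("decision profiles need experts over the original classes")
        rows.append(expert.output(np.asarray(x)))
    return np.vstack(rows)


def fixed_rule_combine(profile: np.ndarray, rule: str) -> int:
    """Aggregate an L x C decision profile by a fixed rule and take argmax.

    Returns the 0-based column index of the winning class (ties toward the
    lowest index); callers map it onto their class identifiers.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 2:
        raise ValueError("decision profile must be 2-D (classifiers x classes)")
    if rule == "average":
        agg = profile.mean(axis=0)
    elif rule == "product":
        agg = profile.prod(axis=0)
    elif rule == "maximum":
        agg = profile.max(axis=0)
    elif rule == "minimum":
        agg = profile.min(axis=0)
    else:
        raise ValueError(f"unknown rule {rule!r}; expected one of {FIXED_RULES}")
    return int(np.argmax(agg))


@dataclass
class DecisionTemplates:
    """Per-class mean decision profiles for template matching."""

    classes: tuple[int, ...]
    templates: np.ndarray  # (C, L, C)


def decision_templates_fit(profiles: np.ndarray, labels: Sequence[int]) -> DecisionTemplates:
    """Mean decision profile per class over the training samples."""
    profiles = np.asarray(profiles, dtype=float)
    y = np.asarray(labels)
    classes = tuple(sorted(int(c) for c in np.unique(y)))
    templates = []
    for c in classes:
        sel = y == c
        if not sel.any():
            raise ValueError(f"class {c} has no training profiles")
        templates.append(profiles[sel].mean(axis=0))
    return DecisionTemplates(classes, np.stack(templates))


def decision_templates_predict(dt: DecisionTemplates, profile: np.ndarray) -> int:
    """Class whose template is nearest (squared Euclidean); ties to lowest index."""
    profile = np.asarray(profile, dtype=float)
    d = ((dt.templates - profile[None]) ** 2).sum(axis=(1, 2))
    return dt.classes[int(np.argmin(d))]
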