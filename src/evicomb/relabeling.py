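"""Confidence-based relabeling of crisp training labels into crisp/soft labels.

The relabeling step models label uncertainty before any expert is trained:
a network with one output node per original class is fit on the crisply
labeled data, a per-class *template* of its mean own-class confidence is
computed, and each training sample is then compared against the template.
Samples the network places confidently keep a crisp label; samples whose
confidences fall well short of the template for two or more classes receive
a *soft* label naming all plausible classes.  A KNN-based relabeler (local
class prototypes among a sample's nearest neighbors) is provided as the
baseline alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .experts import ExpertModel, MLPConfig, train_mlp_expert
from .labels import expand_class_list, format_label, parse_label, soft_label

__all__ = [
    "TemplateVector",
    "RelabelConfig",
    "RelabeledDataset",
    "fit_confidence_template",
    "confidence_relabel",
    "relabel_dataset",
    "knn_relabel",
    "write_relabeled",
    "read_relabeled",
]


def default_confidence(D: np.ndarray, epsilon: float) -> np.ndarray:
    """Per-class confidence v from the template gap D.

    ``v_i = (d_min + eps) / (D_i + eps)``: equals 1 at the smallest gap,
    stays strictly positive at ``D_i = 0`` thanks to ``eps``, and decreases
    monotonically as the gap grows.
    """
    d_min = float(np.min(D))
    return (d_min + epsilon) / (D + epsilon)


@dataclass(frozen=True)
class TemplateVector:
    """Mean own-node confidence of the relabeling network, one entry per class."""

    classes: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.classes),) or not np.isfinite(v).all():
            raise ValueError("template must hold one finite value per class")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class RelabelConfig:
    """Uncertainty threshold theta and the division guard epsilon.

    Classes whose confidence v exceeds ``theta`` join the soft label; with
    ``theta >= 1`` every label stays crisp (v never exceeds 1).  ``epsilon``
    defaults to 0.01.  ``confidence_fn`` maps the clamped gap vector D to
    the confidences v and may be swapped for an alternative form.
    """

    theta: float = 0.5
    epsilon: float = 0.01
    confidence_fn: Callable[[np.ndarray, float], np.ndarray] = field(
        default=default_confidence, compare=False
    )

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class RelabeledDataset:
    """Feature matrix with per-sample (soft) labels and the expanded class list."""

    features: np.ndarray
    labels: list[tuple[int, ...]]
    expanded_classes: tuple[tuple[int, ...], ...]
    original_labels: np.ndarray | None = None

    def __post_init__(self):
        missing = set(self.labels) - set(self.expanded_classes)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from expanded_classes")

    @property
    def soft_fraction(self) -> float:
        return float(np.mean([len(l) > 1 for l in self.labels]))


def fit_confidence_template(
    network: ExpertModel, features: np.ndarray, labels: Sequence[int]
) -> TemplateVector:
    """Average output node i of *network* over the class-i training samples."""
    y = np.asarray(labels)
    classes = network.frame_classes
    node = {c: network.class_list.index((c,)) for c in classes}
    out = network.outputs(np.asarray(features, dtype=float))
    values = np.empty(len(classes))
    for j, c in enumerate(classes):
        sel = y == c
        if not sel.any():
            raise ValueError(f"class {c} has no training samples")
        values[j] = out[sel, node[c]].mean()
    return TemplateVector(classes, values)


def confidence_relabel(
    network: ExpertModel,
    template: TemplateVector,
    x: np.ndarray,
    cfg: RelabelConfig,
) -> tuple[int, ...]:
    """Assign a crisp or soft label to one sample from its template gaps.

    The gap ``D = T - O`` is clamped at zero wherever the network exceeds
    its template (a confident assignment), converted to confidences v, and
    thresholded at theta.  Two or more above-threshold classes form a soft
    label; otherwise the crisp label is the smallest-gap class (ties toward
    the lowest class index).
    """
    O = network.output(np.asarray(x, dtype=float))
    if O.shape != template.values.shape:
        raise ValueError("network output length does not match the template")
    D = template.values - O
    D[D < 0] = 0.0
    v = cfg.confidence_fn(D, cfg.epsilon)
    S = [c for c, vi in zip(template.classes, v) if vi > cfg.theta]
    if len(S) > 1:
        return soft_label(S)
    return (template.classes[int(np.argmin(D))],)


def relabel_dataset(
    features: np.ndarray,
    labels: Sequence[int],
    cfg: RelabelConfig,
    mlp_config: MLPConfig | None = None,
    val_features: np.ndarray | None = None,
    val_labels: Sequence[int] | None = None,
) -> tuple[RelabeledDataset, ExpertModel, TemplateVector]:
    """Train the relabeling network and relabel every training sample.

    Returns the relabeled dataset together with the fitted network and its
    template (both are needed to relabel further data consistently).
    Deterministic given ``mlp_config.seed``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("relabeling needs at least two classes")
    mlp_config = mlp_config or MLPConfig()
    crisp = [(int(c),) for c in y]
    net = train_mlp_expert(X, crisp, val_features,
                           None if val_labels is None else [(int(c),) for c in val_labels],
                           mlp_config)
    template = fit_confidence_template(net, X, y)
    new_labels = [confidence_relabel(net, template, x, cfg) for x in X]
    ds = RelabeledDataset(X, new_labels, expand_class_list(new_labels), original_labels=y)
    return ds, net, template


def knn_relabel(
    features: np.ndarray,
    labels: Sequence[int],
    k: int = 5,
    threshold: float = 0.3,
    similarity: Callable[[np.ndarray], np.ndarray] | None = None,
) -> RelabeledDataset:
    """KNN relabeling baseline: local class prototypes among k neighbors.

    For each sample, the mean of its k nearest neighbors (self excluded)
    belonging to each class is that class's local prototype; the classes
    whose prototype similarity ``1/(1 + Euclidean distance)`` exceeds
    *threshold* form the soft label, else the crisp label is the
    nearest-prototype class.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = len(X)
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    if similarity is None:
        similarity = lambda dist: 1.0 / (1.0 + dist)
    tree = cKDTree(X)
    _, idx = tree.query(X, k=k + 1)
    new_labels: list[tuple[int, ...]] = []
    for i in range(n):
        neigh = [j for j in idx[i] if j != i][:k]
        protos: dict[int, np.ndarray] = {}
        for c in np.unique(y[neigh]):
            protos[int(c)] = X[[j for j in neigh if y[j] == c]].mean(axis=0)
        cls = sorted(protos)
        dists = np.array([np.linalg.norm(X[i] - protos[c]) for c in cls])
        sims = similarity(dists)
        S = [c for c, s in zip(cls, sims) if s > threshold]
        if len(S) > 1:
            new_labels.append(soft_label(S))
        else:
            new_labels.append((cls[int(np.argmax(sims))],))
    return RelabeledDataset(X, new_labels, expand_class_list(new_labels),
                            original_labels=y)


# ---------------------------------------------------------------------------
# delimited-text serialization: feature columns then a label column "i|j|k"


def write_relabeled(ds: RelabeledDataset, path) -> None:
    d = ds.features.shape[1]
    with open(path, "w") as fh:
        fh.write("\t".join(f"f{j}" for j in range(d)) + "\tlabel\n")
        for x, lab in zip(ds.features, ds.labels):
            fh.write("\t".join(repr(float(v)) for v in x) + "\t" + format_label(lab) + "\n")


def read_relabeled(path, valid_classes: Sequence[int] | None = None) -> RelabeledDataset:
    rows, labs = [], []
    with open(path) as fh:
        header = fh.readline()
        if "label" not in header:
            raise ValueError("missing header with a label column")
        for line in fh:
            if not line.strip():
                continue
            *vals, lab = line.rstrip("\n").split("\t")
            rows.append([float(v) for v in vals])
            labs.append(parse_label(lab, valid_classes))
    X = np.asarray(rows, dtype=float)
    return RelabeledDataset(X, labs, expand_class_list(labs))
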