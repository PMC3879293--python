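"""One-hidden-layer MLP experts and their reading as basic belief assignments.

Each expert is a classic feed-forward network — logistic hidden and output
units, trained by plain (full-batch) gradient descent on a sum-of-squares
loss against 0/1 targets, with early stopping on validation accuracy.  An
expert trained on relabeled data has one output node per crisp *or soft*
class; at test time its raw output activations are pushed through a softmax
and read as the masses of a basic belief assignment whose focal elements
are exactly those classes (each soft class being a non-singleton subset of
the original frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ds_core import Frame, MassFunction
from .labels import expand_class_list, format_label, parse_label, soft_label

__all__ = ["MLPConfig", "ExpertModel", "train_mlp_expert", "expert_bba",
           "write_expert", "read_expert"]


@dataclass(frozen=True)
class MLPConfig:
    """Hyperparameters of a one-hidden-layer expert.

    ``patience`` counts consecutive validation checks (one per epoch) with
    no improvement above ``tol`` before training stops; the best weights
    seen are restored.  ``monitor`` selects the early-stopping quantity:
    ``"loss"`` (validation mean squared error — keeps training while the
    output confidences sharpen, which the confidence-relabeling template
    depends on) or ``"accuracy"`` (stops once the decision quality
    plateaus, appropriate for decision experts).
    """

    hidden_units: int = 10
    learning_rate: float = 0.1
    max_epochs: int = 1000
    patience: int = 30
    tol: float = 1e-4
    seed: int = 0
    monitor: str = "loss"

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not (0 < self.learning_rate <= 1):
            raise ValueError("learning_rate must be in (0, 1]")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.monitor not in ("loss", "accuracy"):
            raise ValueError(f"unknown early-stopping monitor {self.monitor!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ExpertModel:
    """A trained expert: weights plus the class list its output nodes mean.

    ``class_list`` is the ordered tuple of (soft) labels the network was
    trained against; output node ``i`` carries the confidence for
    ``class_list[i]``.  ``frame_classes`` are the original crisp classes
    referenced by those labels.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    class_list: tuple[tuple[int, ...], ...]
    frame_classes: tuple[int, ...]
    config: MLPConfig
    epochs_run: int = 0
    val_accuracy: float = float("nan")

    @property
    def n_inputs(self) -> int:
        return self.w1.shape[1]

    def _check_x(self, x: np.ndarray, batch: bool) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        want = 2 if batch else 1
        if x.ndim != want or x.shape[-1] != self.n_inputs:
            raise ValueError(
                f"input dimension mismatch: expected (*, {self.n_inputs}), got {x.shape}"
            )
        return x

    def raw_outputs(self, X: np.ndarray) -> np.ndarray:
        """Pre-activation values of the output nodes for a batch of samples."""
        X = self._check_x(X, batch=True)
        a1 = _sigmoid(X @ self.w1.T + self.b1)
        return a1 @ self.w2.T + self.b2

    def outputs(self, X: np.ndarray) -> np.ndarray:
        """Logistic confidences in [0, 1], one column per class-list entry."""
        return _sigmoid(self.raw_outputs(X))

    def raw_output(self, x: np.ndarray) -> np.ndarray:
        return self.raw_outputs(self._check_x(x, batch=False)[None, :])[0]

    def output(self, x: np.ndarray) -> np.ndarray:
        return _sigmoid(self.raw_output(x))

    def predict_labels(self, X: np.ndarray) -> list[tuple[int, ...]]:
        idx = np.argmax(self.outputs(X), axis=1)
        return [self.class_list[i] for i in idx]


def train_mlp_expert(
    features: np.ndarray,
    labels: Sequence,
    val_features: np.ndarray | None,
    val_labels: Sequence | None,
    cfg: MLPConfig,
    class_list: Sequence[tuple[int, ...]] | None = None,
) -> ExpertModel:
    """Train an expert on (possibly soft-) labeled data.

    Targets are one-hot over the expanded class list (zeros except at the
    sample's own class node).  Training is deterministic given ``cfg.seed``.
    When no validation set is given, early stopping is disabled with a
    warning and training runs to ``max_epochs``.
    """
    X = np.asarray(features, dtype=float)
    labs = [soft_label(l) for l in labels]
    if class_list is None:
        class_list = expand_class_list(labs)
    else:
        class_list = tuple(soft_label(c) for c in class_list)
        missing = set(labs) - set(class_list)
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from the class list")
    node = {c: i for i, c in enumerate(class_list)}
    frame_classes = tuple(sorted({m for c in class_list for m in c}))
    n, d = X.shape
    k = len(class_list)
    T = np.zeros((n, k))
    T[np.arange(n), [node[l] for l in labs]] = 1.0

    has_val = val_features is not None and val_labels is not None and len(val_labels) > 0
    # pignistic-style spread matrix: node j contributes its support equally to
    # the original classes its (soft) label names; validation accuracy is then
    # scored against crisp classes even when a crisp node was relabeled away
    frame_idx = {c: i for i, c in enumerate(frame_classes)}
    spread = np.zeros((k, len(frame_classes)))
    for j, c in enumerate(class_list):
        for m in c:
            spread[j, frame_idx[m]] = 1.0 / len(c)
    if has_val:
        Xv = np.asarray(val_features, dtype=float)
        val_labs = [soft_label(l) for l in val_labels]
        val_members = [frozenset(frame_idx[m] for m in l) for l in val_labs]
        # early stopping monitors the validation error (mean squared error
        # against one-hot targets), not accuracy: accuracy saturates long
        # before the output confidences are calibrated, and the relabeling
        # stage depends on calibrated confidences.  Samples whose label has
        # no output node (a crisp class relabeled away) are excluded.
        val_has_node = np.array([l in node for l in val_labs])
        if val_has_node.any():
            Xv_loss = Xv[val_has_node]
            Tv = np.zeros((int(val_has_node.sum()), k))
            Tv[np.arange(len(Xv_loss)),
               [node[l] for l, ok in zip(val_labs, val_has_node) if ok]] = 1.0
        else:
            has_val = False
            warnings.warn("no validation label maps to an output node: "
                          "early stopping disabled", stacklevel=2)
    else:
        warnings.warn("no validation set: early stopping disabled", stacklevel=2)

    rng = np.random.default_rng(cfg.seed)
    # fan-in-scaled uniform init keeps logistic units in their linear range
    w1 = rng.uniform(-0.5, 0.5, size=(cfg.hidden_units, d)) / np.sqrt(max(d, 1))
    b1 = np.zeros(cfg.hidden_units)
    w2 = rng.uniform(-0.5, 0.5, size=(k, cfg.hidden_units)) / np.sqrt(cfg.hidden_units)
    b2 = np.zeros(k)

    best = (w1.copy(), b1.copy(), w2.copy(), b2.copy())
    best_loss, best_acc, bad, epochs = np.inf, -np.inf, 0, 0
    lr = cfg.learning_rate
    for epoch in range(1, cfg.max_epochs + 1):
        a1 = _sigmoid(X @ w1.T + b1)
        a2 = _sigmoid(a1 @ w2.T + b2)
        err = a2 - T
        if not np.isfinite(err).all():
            raise FloatingPointError("non-finite training loss")
        # epoch-summed gradient (classic accumulated backprop): step sizes
        # comparable to the per-sample rule at the same learning rate
        dz2 = err * a2 * (1.0 - a2)
        dz1 = (dz2 @ w2) * a1 * (1.0 - a1)
        w2 -= lr * dz2.T @ a1
        b2 -= lr * dz2.sum(axis=0)
        w1 -= lr * dz1.T @ X
        b1 -= lr * dz1.sum(axis=0)
        epochs = epoch
        if has_val:
            if cfg.monitor == "loss":
                av = _sigmoid(_sigmoid(Xv_loss @ w1.T + b1) @ w2.T + b2)
                loss = float(np.mean((av - Tv) ** 2))
                improved = loss < best_loss * (1.0 - cfg.tol)
                best_loss = min(loss, best_loss)
            else:
                av = _sigmoid(_sigmoid(Xv @ w1.T + b1) @ w2.T + b2)
                win = np.argmax(av @ spread, axis=1)
                acc = float(np.mean([w in mem
                                     for w, mem in zip(win, val_members)]))
                improved = acc > best_acc + cfg.tol
                best_acc = max(acc, best_acc)
            if improved:
                bad = 0
                best = (w1.copy(), b1.copy(), w2.copy(), b2.copy())
            else:
                bad += 1
                if bad >= cfg.patience:
                    break
    if has_val:
        w1, b1, w2, b2 = best
        # pignistic-style spread projects (soft) node supports back onto the
        # original classes for the reported validation accuracy
        av = _sigmoid(_sigmoid(Xv @ w1.T + b1) @ w2.T + b2)
        win = np.argmax(av @ spread, axis=1)
        val_acc = float(np.mean([w in mem for w, mem in zip(win, val_members)]))
    else:
        val_acc = float("nan")
    return ExpertModel(w1, b1, w2, b2, tuple(class_list), frame_classes, cfg,
                       epochs_run=epochs, val_accuracy=val_acc)


def expert_bba(model: ExpertModel, x: np.ndarray, on: str = "raw") -> MassFunction:
    """Read an expert's outputs for one sample as a basic belief assignment.

    Masses are the softmax of the output activations; each output node's
    (soft) class is one focal subset of the original frame.  ``on="raw"``
    (default) applies the softmax to the pre-activation values; ``on=
    "logistic"`` applies it to the logistic confidences instead.
    """
    if on == "raw":
        z = model.raw_output(x)
    elif on == "logistic":
        z = model.output(x)
    else:
        raise ValueError(f"unknown softmax input {on!r}")
    z = z - z.max()  # shift invariance; guards overflow
    w = np.exp(z)
    masses = w / w.sum()
    frame = Frame(model.frame_classes)
    focal = {}
    for label, mass in zip(model.class_list, masses):
        focal[frame.to_mask(label)] = focal.get(frame.to_mask(label), 0.0) + float(mass)
    return MassFunction(frame, focal)


# ---------------------------------------------------------------------------
# structured-text serialization (exact round trip via float reprs)


def write_expert(model: ExpertModel, path) -> None:
    cfg = model.config
    with open(path, "w") as fh:
        fh.write("# evicomb expert v1\n")
        fh.write("classes\t" + "\t".join(format_label(c) for c in model.class_list) + "\n")
        fh.write("frame\t" + ",".join(str(c) for c in model.frame_classes) + "\n")
        fh.write(f"config\t{cfg.hidden_units}\t{cfg.learning_rate!r}\t{cfg.max_epochs}"
                 f"\t{cfg.patience}\t{cfg.tol!r}\t{cfg.seed}\n")
        fh.write(f"meta\t{model.epochs_run}\t{model.val_accuracy!r}\n")
        for name in ("w1", "b1", "w2", "b2"):
            arr = np.atleast_2d(getattr(model, name))
            fh.write(f"array\t{name}\t{arr.shape[0]}\t{arr.shape[1]}\n")
            for row in arr:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_expert(path) -> ExpertModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("# evicomb expert"):
        raise ValueError("not an expert model file")
    class_list = tuple(parse_label(tok) for tok in lines[1].split("\t")[1:])
    frame_classes = tuple(int(c) for c in lines[2].split("\t")[1].split(","))
    _, h, lr, me, pat, tol, seed = lines[3].split("\t")
    cfg = MLPConfig(int(h), float(lr), int(me), int(pat), float(tol), int(seed))
    _, epochs, vacc = lines[4].split("\t")
    arrays = {}
    i = 5
    while i < len(lines):
        _, name, r, c = lines[i].split("\t")
        r, c = int(r), int(c)
        arrays[name] = np.array(
            [[float(v) for v in lines[i + 1 + j].split("\t")] for j in range(r)]
        )
        i += 1 + r
    return ExpertModel(
        arrays["w1"], arrays["b1"].ravel(), arrays["w2"], arrays["b2"].ravel(),
        class_list, frame_classes, cfg,
        epochs_run=int(epochs), val_accuracy=float(vacc),
    )
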