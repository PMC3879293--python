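"""Synthetic benchmarks: the rotating-triangle Gaussian dataset and EEG-like trials.

``make_triangle_views`` builds the three-class, two-dimensional benchmark
used to study classification under controlled label uncertainty: class
means sit on the vertices of an equilateral triangle (identity covariance),
and two complementary feature spaces are obtained by advancing each class
mean one vertex clockwise.  Shrinking the side length increases class
overlap, i.e. uncertainty: side 1/2/3 give high/medium/low uncertainty.

``make_synthetic_trials`` builds band-limited multichannel oscillatory
trials with class-specific spatial variance patterns, for exercising the
spatial-filtering and spectral feature stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .eeg_features import TrialSet
from .views import FeatureSpaceView

__all__ = ["TriangleSpec", "make_triangle_views", "make_synthetic_trials"]

CLASSES = (1, 2, 3)


@dataclass(frozen=True)
class TriangleSpec:
    """Parameters of the triangle benchmark.

    ``side`` is the triangle edge length d (1, 2 and 3 in the reference
    conditions); totals are per-set sample counts split as evenly as
    possible among the three classes (remainder to the lowest indices);
    the reference totals are 150/300/500 train/validation/test.
    """

    side: float = 1.0
    n_train: int = 150
    n_val: int = 300
    n_test: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("side length must be positive")
        for name in ("n_train", "n_val", "n_test"):
            if getattr(self, name) < 3:
                raise ValueError(f"{name} must be at least 3")


def triangle_vertices(side: float) -> np.ndarray:
    """Vertices of an equilateral triangle, centroid at the origin,
    vertex 1 on the positive y-axis, numbered clockwise."""
    r = side / np.sqrt(3.0)
    angles = np.deg2rad([90.0, -30.0, -150.0])  # clockwise from the top
    return np.column_stack([r * np.cos(angles), r * np.sin(angles)])


def _split_counts(total: int) -> np.ndarray:
    base, rem = divmod(total, 3)
    counts = np.full(3, base)
    counts[:rem] += 1  # remainder to the lowest class indices
    return counts


def make_triangle_views(spec: TriangleSpec):
    """Generate the three complementary views of the triangle benchmark.

    Returns ``(views, truth)`` where ``views`` is a dict with keys
    ``"train"``, ``"val"``, ``"test"``, each a list of three
    :class:`FeatureSpaceView` sharing labels, and ``truth`` records the
    class means per view.  In view v, class i's mean sits at vertex
    ``(i-1+v) mod 3`` — each view advances every class one vertex
    clockwise.  Coordinates are drawn independently per view (unit
    covariance) while labels are common, so the views carry complementary
    information about each sample.
    """
    verts = triangle_vertices(spec.side)
    rng = np.random.default_rng(spec.seed)
    means = {v: verts[(np.arange(3) + v) % 3] for v in range(3)}
    out = {}
    for split, total in (("train", spec.n_train), ("val", spec.n_val), ("test", spec.n_test)):
        counts = _split_counts(total)
        labels = np.repeat(CLASSES, counts)
        views = []
        for v in range(3):
            X = np.empty((total, 2))
            for ci in range(3):
                sel = labels == CLASSES[ci]
                X[sel] = means[v][ci] + rng.standard_normal((counts[ci], 2))
            views.append(FeatureSpaceView(
                X, labels.copy(),
                provenance={"generator": "triangle", "side": spec.side,
                            "view": v + 1, "split": split, "seed": spec.seed},
            ))
        out[split] = views
    truth = {"vertices": verts, "means_per_view": means, "classes": CLASSES}
    return out, truth


def make_synthetic_trials(
    n_classes: int,
    n_channels: int,
    fs: float,
    duration_s: float,
    spatial_patterns: np.ndarray | None = None,
    band_powers: np.ndarray | None = None,
    n_trials_per_class: int = 20,
    seed: int = 0,
    band: tuple[float, float] = (8.0, 13.0),
    noise_std: float = 1.0,
):
    """Band-limited oscillatory trials with class-specific spatial variance.

    Each class ``c`` drives band-limited Gaussian sources along the rows of
    ``spatial_patterns`` with standard deviations ``sqrt(band_powers[c])``,
    on top of white sensor noise.  Returns ``(TrialSet, truth)`` with the
    generating patterns for filter-recovery tests.  Defaults: one random
    orthonormal pattern per class, with class ``c`` strong on pattern ``c``
    and weak elsewhere.
    """
    rng = np.random.default_rng(seed)
    if spatial_patterns is None:
        raw = rng.standard_normal((n_channels, n_classes))
        q, _ = np.linalg.qr(raw)
        spatial_patterns = q[:, :n_classes].T  # one orthonormal pattern per class
    spatial_patterns = np.asarray(spatial_patterns, dtype=float)
    n_patterns = spatial_patterns.shape[0]
    if np.linalg.matrix_rank(spatial_patterns) < n_patterns:
        raise ValueError("spatial patterns must be linearly independent")
    if band_powers is None:
        band_powers = np.full((n_classes, n_patterns), 0.5)
        band_powers[np.arange(n_classes), np.arange(min(n_classes, n_patterns))] = 8.0
    band_powers = np.asarray(band_powers, dtype=float)
    if (band_powers < 0).any():
        raise ValueError("band powers must be nonnegative")

    n_samp = int(round(duration_s * fs))
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    trials, labels = [], []
    for c in range(n_classes):
        for _ in range(n_trials_per_class):
            src = sosfiltfilt(sos, rng.standard_normal((n_patterns, n_samp)), axis=1)
            src /= src.std(axis=1, keepdims=True) + 1e-12
            src *= np.sqrt(band_powers[c])[:, None]
            x = spatial_patterns.T @ src + noise_std * rng.standard_normal((n_channels, n_samp))
            trials.append(x)
            labels.append(c + 1)
    trials = np.asarray(trials)
    order = rng.permutation(len(trials))
    ts = TrialSet(trials[order], fs=fs, labels=np.asarray(labels)[order],
                  channel_names=tuple(f"ch{i}" for i in range(n_channels)))
    truth = {"spatial_patterns": spatial_patterns, "band_powers": band_powers,
             "band": band}
    return ts, truth
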