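"""Feature-space views: one representation of a common sample set."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureSpaceView", "write_view", "read_view"]


@dataclass
class FeatureSpaceView:
    """A feature matrix over the common samples, with their original labels.

    ``provenance`` records where the view came from — a feature-index
    subset of a parent space, or the generator parameters that produced it.
    """

    features: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must have the same length")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def classes(self) -> tuple[int, ...]:
        return tuple(sorted(int(c) for c in np.unique(self.labels)))


def write_view(view: FeatureSpaceView, path) -> None:
    d = view.features.shape[1]
    with open(path, "w") as fh:
        fh.write("\t".join(f"f{j}" for j in range(d)) + "\tlabel\n")
        for x, y in zip(view.features, view.labels):
            fh.write("\t".join(repr(float(v)) for v in x) + f"\t{int(y)}\n")


def read_view(path) -> FeatureSpaceView:
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
            labs.append(int(lab))
    return FeatureSpaceView(np.asarray(rows), np.asarray(labs),
                            provenance={"source": str(path)})
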