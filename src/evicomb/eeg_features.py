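"""EEG preprocessing and feature extraction for motor-imagery classification.

Stages mirror a standard offline BCI pipeline: a surface-Laplacian spatial
filter (each channel minus the mean of its four neighbours), a zero-phase
Butterworth band-pass over the mu/beta band where ERD/ERS occurs, epoch
extraction relative to stimulus onset, one-versus-rest Common Spatial
Patterns with log-variance features, and Welch-style band power spectral
density features with the unit-length normalization / first-of-k
downsampling used for precomputed PSD data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, signal

__all__ = [
    "TrialSet",
    "CSPModel",
    "surface_laplacian",
    "butterworth_bandpass",
    "extract_epoch",
    "fit_csp_ovr",
    "csp_features",
    "psd_features",
    "unit_normalize",
    "downsample_first_of_k",
    "write_trialset",
    "read_trialset",
]


@dataclass
class TrialSet:
    """Multichannel trials (trial x channel x time, µV) with labels and rate."""

    trials: np.ndarray
    fs: float
    labels: np.ndarray
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.trials.ndim != 3:
            raise ValueError("trials must be a (n_trials, n_channels, n_samples) array")
        if len(self.labels) != len(self.trials):
            raise ValueError("one label per trial required")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.trials.shape[1]))
        elif len(self.channel_names) != self.trials.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    def replace_trials(self, trials: np.ndarray) -> "TrialSet":
        return TrialSet(trials, self.fs, self.labels.copy(), self.channel_names)


def surface_laplacian(trials: TrialSet, neighbor_map: Mapping[str, Sequence[str]]) -> TrialSet:
    """Subtract from each mapped channel the mean of its four neighbours.

    Channels without an entry in ``neighbor_map`` pass through unchanged
    (with a warning); a neighbour name outside the montage is an error.
    """
    name_to_idx = {n: i for i, n in enumerate(trials.channel_names)}
    out = trials.trials.copy()
    unmapped = [n for n in trials.channel_names if n not in neighbor_map]
    if unmapped:
        warnings.warn(f"channels without a neighbor map pass through: {unmapped}",
                      stacklevel=2)
    for name, neighbors in neighbor_map.items():
        if name not in name_to_idx:
            raise ValueError(f"mapped channel {name!r} not in the montage")
        if len(neighbors) != 4:
            raise ValueError(f"channel {name!r} needs exactly 4 neighbors, got {len(neighbors)}")
        try:
            idx = [name_to_idx[nb] for nb in neighbors]
        except KeyError as exc:
            raise ValueError(f"neighbor {exc.args[0]!r} of {name!r} not in the montage") from None
        out[:, name_to_idx[name]] = (
            trials.trials[:, name_to_idx[name]] - trials.trials[:, idx].mean(axis=1)
        )
    return trials.replace_trials(out)


def butterworth_bandpass(trials: TrialSet, low_hz: float, high_hz: float,
                         order: int = 6) -> TrialSet:
    """Zero-phase Butterworth band-pass (forward-backward) per channel."""
    if not (0 < low_hz < high_hz < trials.fs / 2):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) at fs={trials.fs}")
    sos = signal.butter(order, (low_hz, high_hz), btype="bandpass",
                        fs=trials.fs, output="sos")
    return trials.replace_trials(signal.sosfiltfilt(sos, trials.trials, axis=2))


def extract_epoch(trials: TrialSet, t_start_s: float, t_end_s: float) -> TrialSet:
    """Keep samples in the half-open window [t_start, t_end) seconds from onset."""
    i0 = int(round(t_start_s * trials.fs))
    i1 = int(round(t_end_s * trials.fs))
    if not (0 <= i0 < i1 <= trials.n_samples):
        raise ValueError(
            f"epoch [{t_start_s}, {t_end_s}) s maps to samples [{i0}, {i1}) "
            f"outside the trial length {trials.n_samples}"
        )
    return trials.replace_trials(trials.trials[:, :, i0:i1])


@dataclass
class CSPModel:
    """One-versus-rest CSP filters: 2m per class sub-problem, C*2m in total."""

    filters: np.ndarray  # (C*2m, n_channels)
    classes: tuple[int, ...]
    m: int
    eigenvalues: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.filters.shape[0]


def _trace_normalized_cov(x: np.ndarray) -> np.ndarray:
    c = x @ x.T
    return c / np.trace(c)


def fit_csp_ovr(trials: TrialSet, m: int = 3, ridge: float = 1e-8) -> CSPModel:
    """Fit one-versus-rest Common Spatial Patterns.

    Per class: average the trace-normalized spatial covariance of that
    class's trials and of the rest, solve the generalized eigenproblem
    ``S_c w = lambda (S_c + S_rest) w``, and keep the first and last *m*
    eigenvectors (largest/smallest variance ratio).  A small trace-scaled
    ridge stabilizes near-singular composite covariances.
    """
    classes = tuple(sorted(int(c) for c in np.unique(trials.labels)))
    if len(classes) < 2:
        raise ValueError("CSP needs at least two classes")
    if not (1 <= m <= trials.n_channels // 2):
        raise ValueError(f"m={m} out of range for {trials.n_channels} channels")
    covs = {}
    for c in classes:
        sel = trials.labels == c
        if sel.sum() < 2:
            raise ValueError(f"class {c} needs at least 2 trials")
        covs[c] = np.mean([_trace_normalized_cov(x) for x in trials.trials[sel]], axis=0)
    filters, eigvals = [], []
    for c in classes:
        s_c = covs[c]
        s_rest = np.mean([covs[o] for o in classes if o != c], axis=0)
        composite = s_c + s_rest
        composite = composite + ridge * np.trace(composite) * np.eye(len(composite))
        try:
            w, v = linalg.eigh(s_c, composite)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                f"singular composite covariance for class {c}; "
                f"increase the ridge regularization"
            ) from exc
        if np.all(np.abs(w - 0.5) < 0.05):
            warnings.warn(f"class {c}: eigenvalues all near 0.5 — no discriminative "
                          "spatial structure", stacklevel=2)
        # eigh returns ascending eigenvalues; ends are the discriminative filters
        keep = list(range(m)) + list(range(len(w) - m, len(w)))
        filters.append(v[:, keep].T)
        eigvals.append(w[keep])
    return CSPModel(np.vstack(filters), classes, m, eigenvalues=eigvals)


def csp_features(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Log-normalized variance of one trial along each spatial filter.

    ``f_j = log(var_j / sum_k var_k)`` with the variance taken across time
    after projecting on filter j; ``style="plain"`` is available via
    :func:`csp_features_plain` for an unnormalized elementwise log.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[0] != model.filters.shape[1]:
        raise ValueError(
            f"trial must be (n_channels={model.filters.shape[1]}, n_samples), "
            f"got {trial.shape}"
        )
    proj = model.filters @ trial
    var = proj.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance along the CSP filters")
    return np.log(var / total)


def csp_features_plain(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Elementwise ``log(var_j)`` variant of the CSP feature map."""
    proj = model.filters @ np.asarray(trial, dtype=float)
    var = proj.var(axis=1)
    if (var <= 0).any():
        raise ValueError("zero variance along a CSP filter")
    return np.log(var)


def psd_features(trials: TrialSet, band: tuple[float, float] = (8.0, 30.0),
                 resolution_hz: float = 2.0, window_s: float = 1.0) -> np.ndarray:
    """Band power-spectral-density features over the last ``window_s`` seconds.

    A Welch/periodogram estimate at the window's natural frequency grid is
    sampled at multiples of ``resolution_hz`` within ``band`` (inclusive),
    per channel, and the channel blocks are concatenated.  The reference
    recipe — 8–30 Hz at 2 Hz resolution over a 1 s window — yields 12 bins
    per channel.
    """
    n_win = int(round(window_s * trials.fs))
    if n_win > trials.n_samples:
        raise ValueError(f"trials of {trials.n_samples} samples are shorter than the "
                         f"{n_win}-sample window")
    tail = trials.trials[:, :, -n_win:]
    freqs, pxx = signal.welch(tail, fs=trials.fs, nperseg=n_win, axis=2,
                              window="hann", detrend=False)
    lo, hi = band
    n_bins = int(round((hi - lo) / resolution_hz)) + 1
    targets = lo + resolution_hz * np.arange(n_bins)
    cols = [int(np.argmin(np.abs(freqs - f))) for f in targets]
    feats = pxx[:, :, cols]  # (n_trials, n_channels, n_bins)
    return feats.reshape(trials.n_trials, -1)


def unit_normalize(x: np.ndarray) -> np.ndarray:
    """Scale a vector to unit Euclidean length."""
    x = np.asarray(x, dtype=float)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("cannot unit-normalize a zero vector")
    return x / norm


def downsample_first_of_k(seq, k: int = 8):
    """Keep the first element of every k consecutive elements (index 0, k, 2k...)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    arr = np.asarray(seq)
    return arr[::k]


# ---------------------------------------------------------------------------
# on-disk TrialSet: one TSV per trial (rows = channels) plus a manifest TSV


def write_trialset(trials: TrialSet, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
        fh.write(f"# fs\t{trials.fs!r}\n")
        fh.write("# channels\t" + ",".join(trials.channel_names) + "\n")
        fh.write("file\tlabel\n")
        for i, (x, y) in enumerate(zip(trials.trials, trials.labels)):
            name = f"trial_{i:04d}.tsv"
            fh.write(f"{name}\t{int(y)}\n")
            np.savetxt(os.path.join(outdir, name), x, delimiter="\t")


def read_trialset(indir) -> TrialSet:
    import os

    with open(os.path.join(indir, "manifest.tsv")) as fh:
        fs = float(fh.readline().split("\t")[1])
        channels = tuple(fh.readline().split("\t")[1].strip().split(","))
        fh.readline()  # column header
        files, labels = [], []
        for line in fh:
            if not line.strip():
                continue
            name, lab = line.rstrip("\n").split("\t")
            files.append(name)
            labels.append(int(lab))
    trials = np.stack([np.loadtxt(os.path.join(indir, f), delimiter="\t", ndmin=2)
                       for f in files])
    return TrialSet(trials, fs, np.asarray(labels), channels)
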