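"""Forward (inverted) encoding of orientation from multichannel EEG.

The model expresses the sensor data ``B`` (sensors x trials) at one time
point as a linear mixture of nine hypothetical orientation channels,

    B = W C,

where ``C`` (channels x trials) holds the basis-function activation of each
trial's presented orientation and ``W`` (sensors x channels) is a spatial
weight matrix.  ``W`` is estimated by ordinary least squares on training
trials,

    W = B C' (C C')^-1,

and inverted on held-out trials to reconstruct their channel responses,

    C2 = (W' W)^-1 W' B2.

Responses are reconstructed in a sliding window over the epoch with
cross-validation so that no trial contributes to the weights used to
reconstruct it, then circularly shifted ("centered") so each trial's
presented orientation sits at 0 deg offset, which allows averaging over
orientations.  Cross-temporal generalisation trains the weights at one time
point and applies them at every other, mapping the stability of the
orientation code.

The basis is the half-cosine raised to the 8th power: non-negative,
180-deg periodic, unit peak, zero at 90 deg orientation distance, and with
a channel sum that is constant in orientation (315/128 for nine channels),
so the basis tiles orientation space without bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import LeaveOneOut

from ._utils import ORIENTATION_GRID, circ_dist_deg, logger
from .design import ExperimentDesign
from .epochs import EpochsArray


class RankDeficientError(np.linalg.LinAlgError):
    """Design or weight matrix is numerically rank deficient."""


# ---------------------------------------------------------------------------
# basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSet:
    """Half-cosine^exponent orientation channel basis."""

    centers: np.ndarray
    exponent: int

    @property
    def n_channels(self) -> int:
        return len(self.centers)

    @property
    def channel_sum(self) -> float:
        """The orientation-independent sum over channels.

        For an even exponent ``e`` the profile's harmonics stop at order
        ``e/2``; with more channels than that the harmonic sums vanish and
        the channel sum equals ``n * C(e, e/2) / 2**e`` everywhere
        (315/128 for nine channels, exponent 8).
        """
        e = self.exponent
        return self.n_channels * comb(e, e // 2) / 2**e

    def evaluate(self, theta) -> np.ndarray:
        """Channel activations for orientation(s) theta (degrees).

        Returns shape (n_channels,) for scalar input, else
        (n_channels, n_orientations).
        """
        theta = np.asarray(theta, dtype=float)
        scalar = theta.ndim == 0
        d = circ_dist_deg(np.atleast_1d(theta)[None, :], self.centers[:, None])
        act = np.cos(np.pi * d / 180.0) ** self.exponent
        return act[:, 0] if scalar else act


def make_basis(n_channels: int = 9, exponent: int = 8) -> BasisSet:
    """Construct the orientation basis with evenly spaced channel centers."""
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if exponent < 2 or exponent % 2:
        raise ValueError(
            "exponent must be an even integer >= 2 (odd powers break the "
            "180-degree periodicity of this parameterisation)"
        )
    centers = np.arange(n_channels) * (180.0 / n_channels)
    return BasisSet(centers=centers, exponent=exponent)


def build_design_matrix(orientations, basis: BasisSet) -> np.ndarray:
    """Basis activations of each trial's orientation: C (channels x trials)."""
    orientations = np.asarray(orientations, dtype=float)
    if orientations.size == 0:
        raise ValueError("empty trial list")
    if np.any((orientations < 0) | (orientations >= 180)):
        logger.info("orientations outside [0, 180) normalised mod 180")
        orientations = orientations % 180.0
    return basis.evaluate(orientations)


# ---------------------------------------------------------------------------
# weight estimation and inversion
# ---------------------------------------------------------------------------

_COND_MAX = 1e10


def fit_weights(B_train: np.ndarray, C_train: np.ndarray) -> np.ndarray:
    """OLS estimate of the sensor weights: W = B C' (C C')^-1."""
    B = np.asarray(B_train, dtype=float)
    C = np.asarray(C_train, dtype=float)
    if B.shape[1] != C.shape[1]:
        raise ValueError("B and C must have the same number of trials")
    if C.shape[1] < C.shape[0]:
        raise RankDeficientError(
            f"underdetermined: {C.shape[1]} training trials for {C.shape[0]} channels"
        )
    gram = C @ C.T
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > _COND_MAX:
        raise RankDeficientError(
            f"design matrix rank deficient (condition number {cond:.3g})"
        )
    return np.linalg.solve(gram, C @ B.T).T


def invert_model(W: np.ndarray, B_test: np.ndarray) -> np.ndarray:
    """Reconstruct channel responses on test data: C2 = (W'W)^-1 W' B2."""
    W = np.asarray(W, dtype=float)
    B = np.asarray(B_test, dtype=float)
    gram = W.T @ W
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > _COND_MAX:
        raise RankDeficientError(
            f"weight matrix rank deficient (condition number {cond:.3g})"
        )
    return np.linalg.solve(gram, W.T @ B)


class ForwardEncoder(BaseEstimator, TransformerMixin):
    """Scikit-learn estimator wrapping the encode/invert pair at one time point.

    ``fit(X, y)`` takes sensor features X (n_trials, n_sensors) and presented
    orientations y (degrees); ``transform(X)`` returns reconstructed channel
    responses (n_trials, n_channels).  An optional ridge penalty stabilises
    the weight regression in noisy regimes (off by default: the canonical
    model is pure OLS).
    """

    def __init__(self, n_channels: int = 9, exponent: int = 8, ridge: float = 0.0):
        self.n_channels = n_channels
        self.exponent = exponent
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be (n_trials, n_sensors) aligned with y")
        self.basis_ = make_basis(self.n_channels, self.exponent)
        C = build_design_matrix(y, self.basis_)
        if self.ridge:
            gram = C @ C.T + self.ridge * np.eye(C.shape[0])
            self.weights_ = np.linalg.solve(gram, C @ X).T
        else:
            self.weights_ = fit_weights(X.T, C)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise RuntimeError("ForwardEncoder is not fitted")
        return invert_model(self.weights_, np.asarray(X, dtype=float).T).T


# ---------------------------------------------------------------------------
# sliding-window cross-validated reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ChannelResponseTensor:
    """Reconstructed channel responses per trial and time point."""

    responses: np.ndarray          # (n_trials_used, n_channels, n_times)
    time_axis: np.ndarray          # seconds, relative to first-Gabor onset
    basis: BasisSet
    design: "object"               # pandas.DataFrame of the used trials
    centered: bool = False
    channel_offsets: np.ndarray = None  # degrees, set when centered

    @property
    def channel_centers(self) -> np.ndarray:
        return self.basis.centers

    def labels(self, grouping: str):
        from .design import expectation_of

        if grouping == "expectation":
            return expectation_of(self.design["condition"].to_numpy())
        if grouping == "repetition":
            return self.design["trial_type"].to_numpy()
        return self.design[grouping].to_numpy()


def _sliding_features(epochs: EpochsArray, window_ms: float, step_ms: float,
                      tmin: float = None, tmax: float = None):
    """Window-averaged sensor features: (n_trials, n_sensors, n_windows).

    The feature at each window position is the average of the samples it
    spans (16 ms at 256 Hz -> 4 samples), keeping the per-window regression
    at sensors x channels.
    """
    fs = epochs.sample_rate
    wlen = max(1, int(round(window_ms * fs / 1000.0)))
    step = max(1, int(round(step_ms * fs / 1000.0)))
    times = epochs.times
    lo = 0 if tmin is None else int(np.searchsorted(times, tmin - 1e-9))
    hi = epochs.n_samples if tmax is None else int(np.searchsorted(times, tmax + 1e-9))
    starts = np.arange(lo, hi - wlen + 1, step)
    if starts.size == 0:
        raise ValueError("analysis window shorter than the sliding window")
    data = epochs.data[:, :, lo : starts[-1] + wlen].astype(np.float64)
    csum = np.concatenate(
        [np.zeros(data.shape[:2] + (1,)), np.cumsum(data, axis=-1)], axis=-1
    )
    feats = (csum[:, :, starts - lo + wlen] - csum[:, :, starts - lo]) / wlen
    centers = times[starts] + (wlen - 1) / (2 * fs)
    return feats, centers


def _make_folds(design_table, cv, seed: int):
    """Cross-validation folds stratified by orientation x condition.

    K-fold assignment deals the (shuffled) trials of every orientation x
    condition cell round-robin over folds with a rotating offset, so each
    fold's cell composition is proportional within one trial even when
    cells are smaller than the fold count.  This keeps every training set
    full rank and its condition mixture (hence its mean tuning gain)
    essentially constant across folds.
    """
    n = len(design_table)
    if cv in ("loo", "leave_one_out"):
        return list(LeaveOneOut().split(np.arange(n)))
    n_folds = 10 if cv in (None, "kfold10") else int(cv)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > n:
        raise ValueError(f"{n_folds} folds for {n} trials")
    strata = (
        design_table["orientation_second"].astype(str)
        + "|"
        + design_table["condition"].astype(str)
    ).to_numpy()
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    offset = 0
    for cell in np.unique(strata):
        idx = np.flatnonzero(strata == cell)
        rng.shuffle(idx)
        assignment[idx] = (offset + np.arange(len(idx))) % n_folds
        offset = (offset + len(idx)) % n_folds
    folds = []
    for f in range(n_folds):
        test = np.flatnonzero(assignment == f)
        train = np.flatnonzero(assignment != f)
        folds.append((train, test))
    return folds


def _batched_pinv_apply(W_t: np.ndarray, F_test: np.ndarray) -> np.ndarray:
    """Apply the least-squares inverse of each W_t to its test features.

    W_t: (T, n_sensors, n_channels); F_test: (n_test, n_sensors, T).
    Returns (n_test, n_channels, T).  Uses a pseudoinverse so that windows
    with (numerically) zero weights yield zero responses instead of blowing
    up -- the strict :func:`invert_model` is the single-time-point contract.
    """
    Winv = np.linalg.pinv(W_t, rcond=1e-10)          # (T, n_ch, n_sens)
    out = np.einsum("tcs,nst->nct", Winv, F_test, optimize=True)
    return out


def encode_timecourse(
    epochs: EpochsArray,
    basis: BasisSet = None,
    window_ms: float = 16.0,
    step_ms: float = 4.0,
    cv="kfold10",
    tmin: float = None,
    tmax: float = None,
    seed: int = 0,
    ridge: float = 0.0,
) -> ChannelResponseTensor:
    """Cross-validated sliding-window reconstruction of channel responses.

    For every window position, weights are fitted on the training folds and
    inverted on the held-out trials until every retained trial has a test
    response.  Rejected trials are excluded throughout.
    """
    basis = basis or make_basis()
    used = epochs.retained()
    table = epochs.design.table.iloc[used].reset_index(drop=True)
    feats, centers = _sliding_features(epochs, window_ms, step_ms, tmin, tmax)
    feats = feats[used]
    folds = _make_folds(table, cv, seed)
    for train_idx, _ in folds:
        if len(train_idx) < basis.n_channels:
            raise ValueError(
                f"training fold of {len(train_idx)} trials is smaller than "
                f"the {basis.n_channels}-channel basis"
            )
    C_all = build_design_matrix(table["orientation_second"].to_numpy(), basis)
    n_trials, _, T = feats.shape
    responses = np.empty((n_trials, basis.n_channels, T))
    eye = np.eye(basis.n_channels)
    for train_idx, test_idx in folds:
        C = C_all[:, train_idx]
        gram = C @ C.T + ridge * eye
        # W_t = B_t C' (C C')^-1 for every window at once
        BCt = np.einsum("nst,cn->tsc", feats[train_idx], C, optimize=True)
        W_t = np.linalg.solve(gram[None], BCt.transpose(0, 2, 1)).transpose(0, 2, 1)
        responses[test_idx] = _batched_pinv_apply(W_t, feats[test_idx])
    return ChannelResponseTensor(
        responses=responses, time_axis=centers, basis=basis, design=table
    )


def center_responses(tensor: ChannelResponseTensor) -> ChannelResponseTensor:
    """Circularly shift each trial's channel axis so its presented orientation
    maps to 0 deg offset (middle index)."""
    if tensor.centered:
        raise ValueError("tensor is already centered")
    centers = tensor.channel_centers
    n_ch = len(centers)
    mid = n_ch // 2
    ori = tensor.design["orientation_second"].to_numpy(dtype=float)
    # channel index of each trial's presented orientation
    chan_idx = np.array([int(np.argmin(np.abs(circ_dist_deg(o, centers)))) for o in ori])
    shifts = (mid - chan_idx) % n_ch
    rows = (np.arange(n_ch)[None, :] - shifts[:, None]) % n_ch
    centered = np.take_along_axis(tensor.responses, rows[:, :, None], axis=1)
    offsets = (centers - centers[mid])
    return ChannelResponseTensor(
        responses=centered,
        time_axis=tensor.time_axis,
        basis=tensor.basis,
        design=tensor.design,
        centered=True,
        channel_offsets=offsets,
    )


def write_responses(tensor: ChannelResponseTensor, path) -> Path:
    """Persist a ChannelResponseTensor in the header+binary container format
    (JSON header with time axis and channel offsets, float32 payload,
    design CSV sidecar)."""
    import json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = np.ascontiguousarray(tensor.responses, dtype="<f4")
    header = {
        "format_version": 1,
        "kind": "channel_responses",
        "shape": list(tensor.responses.shape),
        "dtype": "<f4",
        "n_bytes": int(payload.nbytes),
        "time_axis": [float(t) for t in tensor.time_axis],
        "centered": bool(tensor.centered),
        "channel_centers": [float(c) for c in tensor.basis.centers],
        "basis_exponent": int(tensor.basis.exponent),
        "channel_offsets": None if tensor.channel_offsets is None
        else [float(o) for o in tensor.channel_offsets],
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    (path / "data.bin").write_bytes(payload.tobytes())
    tensor.design.to_csv(path / "design.csv", index=False)
    return path


def read_responses(path) -> ChannelResponseTensor:
    """Read a container written by :func:`write_responses`."""
    import json

    import pandas as pd

    from .epochs import EpochsFormatError

    path = Path(path)
    header = json.loads((path / "header.json").read_text())
    if header.get("kind") != "channel_responses":
        raise EpochsFormatError(f"kind: expected channel_responses, found {header.get('kind')}")
    raw = (path / "data.bin").read_bytes()
    if len(raw) != header["n_bytes"]:
        raise EpochsFormatError(
            f"data.bin: expected {header['n_bytes']} bytes, found {len(raw)}"
        )
    responses = np.frombuffer(raw, dtype=header["dtype"]).reshape(header["shape"]).copy()
    basis = BasisSet(centers=np.asarray(header["channel_centers"], dtype=float),
                     exponent=int(header["basis_exponent"]))
    offsets = header["channel_offsets"]
    return ChannelResponseTensor(
        responses=responses,
        time_axis=np.asarray(header["time_axis"], dtype=float),
        basis=basis,
        design=pd.read_csv(path / "design.csv"),
        centered=bool(header["centered"]),
        channel_offsets=None if offsets is None else np.asarray(offsets, dtype=float),
    )


# ---------------------------------------------------------------------------
# cross-temporal generalisation
# ---------------------------------------------------------------------------

@dataclass
class GeneralizationMap:
    """Orientation selectivity for every (train time, test time) pair."""

    selectivity: np.ndarray      # (n_train_times, n_test_times)
    train_times: np.ndarray
    test_times: np.ndarray
    metric: str = "contrast"

    def to_csv(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# train_times_s: " + ",".join(f"{t:.6f}" for t in self.train_times) + "\n")
            fh.write("# test_times_s: " + ",".join(f"{t:.6f}" for t in self.test_times) + "\n")
            fh.write(f"# metric: {self.metric}\n")
            np.savetxt(fh, self.selectivity, delimiter=",")
        return path


def _profile_selectivity(mean_centered: np.ndarray, offsets: np.ndarray,
                         metric: str) -> np.ndarray:
    """Selectivity of centered mean profiles, vectorised over trailing axes.

    ``contrast`` is the basis-weighted contrast of the profile (response at
    0 deg offset minus the mean of the two most distant offsets); ``gaussian``
    fits the tuning Gaussian and returns its amplitude.
    """
    if metric == "contrast":
        mid = int(np.argmin(np.abs(offsets)))
        far = np.argsort(np.abs(circ_dist_deg(offsets, 0)))[-2:]
        return mean_centered[mid] - mean_centered[far].mean(axis=0)
    if metric == "gaussian":
        from .tuning import fit_tuning_curve

        shape = mean_centered.shape[1:]
        flat = mean_centered.reshape(len(offsets), -1)
        amps = np.array(
            [fit_tuning_curve(flat[:, j], offsets=offsets).A for j in range(flat.shape[1])]
        )
        return amps.reshape(shape)
    raise ValueError(f"unknown selectivity metric {metric!r}")


def cross_temporal_generalise(
    epochs: EpochsArray,
    basis: BasisSet = None,
    window_ms: float = 16.0,
    step_ms: float = 16.0,
    cv="kfold10",
    tmin: float = None,
    tmax: float = None,
    seed: int = 0,
    metric: str = "contrast",
    grouping: str = None,
) -> "GeneralizationMap | dict":
    """Train weights at each time point, apply them at every other.

    Returns a :class:`GeneralizationMap` of the selectivity of the centered
    mean response for every train/test time pair (or a dict of maps keyed by
    group level when ``grouping`` is given).  The diagonal reproduces the
    sliding-window selectivity up to fold bookkeeping.
    """
    basis = basis or make_basis()
    used = epochs.retained()
    table = epochs.design.table.iloc[used].reset_index(drop=True)
    feats, centers = _sliding_features(epochs, window_ms, step_ms, tmin, tmax)
    feats = feats[used]
    folds = _make_folds(table, cv, seed)
    C_all = build_design_matrix(table["orientation_second"].to_numpy(), basis)
    n_trials, _, T = feats.shape
    n_ch = basis.n_channels
    mid = n_ch // 2
    ori = table["orientation_second"].to_numpy(dtype=float)
    chan_idx = np.array(
        [int(np.argmin(np.abs(circ_dist_deg(o, basis.centers)))) for o in ori]
    )
    shifts = (mid - chan_idx) % n_ch
    rows = (np.arange(n_ch)[None, :] - shifts[:, None]) % n_ch

    if grouping is None:
        group_labels = np.zeros(n_trials, dtype=int)
        levels = [None]
    else:
        lab = (
            table["trial_type"].to_numpy()
            if grouping == "repetition"
            else np.asarray(
                ["expected" if c.startswith("expected") else "unexpected" for c in table["condition"]]
            )
            if grouping == "expectation"
            else table[grouping].to_numpy()
        )
        levels = list(dict.fromkeys(lab))
        group_labels = np.array([levels.index(v) for v in lab])

    sums = np.zeros((len(levels), n_ch, T, T))
    counts = np.zeros(len(levels))
    for train_idx, test_idx in folds:
        C = C_all[:, train_idx]
        gram = C @ C.T
        BCt = np.einsum("nst,cn->tsc", feats[train_idx], C, optimize=True)
        W_t = np.linalg.solve(gram[None], BCt.transpose(0, 2, 1)).transpose(0, 2, 1)
        Winv = np.linalg.pinv(W_t, rcond=1e-10)     # (T_train, n_ch, n_sens)
        # responses for every train x test time: (n_test, n_ch, T_train, T_test)
        resp = np.einsum("tcs,nsu->nctu", Winv, feats[test_idx], optimize=True)
        centered = np.take_along_axis(resp, rows[test_idx][:, :, None, None], axis=1)
        for g in range(len(levels)):
            sel = group_labels[test_idx] == g
            sums[g] += centered[sel].sum(axis=0)
            counts[g] += sel.sum()
    offsets = basis.centers - basis.centers[mid]
    maps = {}
    for g, level in enumerate(levels):
        mean_centered = sums[g] / counts[g]
        sel = _profile_selectivity(mean_centered, offsets, metric)
        maps[level] = GeneralizationMap(
            selectivity=sel, train_times=centers, test_times=centers, metric=metric
        )
    return maps[None] if grouping is None else maps
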