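"""Quantitative readouts for learned representations.

Selectivity ratios, participation-ratio dimensionality, linear readout,
L1-regularized signal reconstruction, representational similarity and the
majority-vote disentanglement score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.metrics import r2_score

__all__ = [
    "RepresentationMatrix",
    "cluster_selectivity",
    "participation_ratio",
    "linear_readout_accuracy",
    "signal_selectivity",
    "relative_tuning",
    "reconstruct_inputs",
    "representational_similarity",
    "disentanglement_score",
]


@dataclass
class RepresentationMatrix:
    """B samples x N units of activity, with optional labels."""

    values: np.ndarray
    labels: Optional[np.ndarray] = None
    bin_width: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("representation matrix contains non-finite entries")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length must match the number of samples")


def cluster_selectivity(mean_z1: float, mean_z2: float, z_max: float, z_min: float) -> float:
    """Normalized mean-response difference ``|<z1> - <z2>| / (z_max - z_min)``.

    Returns 0 for a dead neuron (``z_max == z_min``) by convention.
    """
    if z_max < z_min:
        raise ValueError("z_max must be >= z_min")
    rng = z_max - z_min
    if rng == 0:
        return 0.0
    return abs(mean_z1 - mean_z2) / rng


def participation_ratio(reps, center: bool = True) -> float:
    """Effective dimensionality ``(sum lambda)^2 / sum lambda^2``.

    ``lambda`` are the eigenvalues of ``Z^T Z``.  By default ``Z`` is
    mean-centered first (the uncentered variant is what the bare formula
    reads as; centering is the default because the uncentered value is
    dominated by the mean response).  An all-zero matrix yields 1 with a
    warning.
    """
    Z = reps.values if isinstance(reps, RepresentationMatrix) else np.atleast_2d(np.asarray(reps, float))
    if Z.shape[0] < 2:
        raise ValueError("participation ratio needs at least 2 samples")
    if center:
        Z = Z - Z.mean(axis=0)
    if not np.any(Z):
        warnings.warn("all-zero representation; participation ratio defined as 1")
        return 1.0
    # eigenvalues of Z^T Z via singular values (stable for tall/thin Z)
    s = np.linalg.svd(Z, compute_uv=False)
    lam = s**2
    return float(lam.sum() ** 2 / np.sum(lam**2))


def linear_readout_accuracy(
    train_reps: np.ndarray,
    train_labels: np.ndarray,
    test_reps: np.ndarray,
    test_labels: np.ndarray,
    C: float = 1.0,
    max_iter: int = 2000,
    seed: int = 0,
) -> float:
    """Accuracy of an L2-regularized multinomial linear classifier.

    The readout is trained on frozen representations only; accuracy is
    reported on the held-out set.
    """
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("need at least two classes to train a readout")
    clf = LogisticRegression(C=C, max_iter=max_iter, random_state=seed)
    clf.fit(np.atleast_2d(train_reps), train_labels)
    return float(clf.score(np.atleast_2d(test_reps), np.asarray(test_labels)))


def _relative_ratio(a: float, b: float, what: str) -> float:
    if a < 0 or b < 0:
        raise ValueError(f"{what} expects nonnegative mean weights")
    s = a + b
    if s == 0:
        warnings.warn(f"{what}: both weights zero; returning 0")
        return 0.0
    return (a - b) / s


def signal_selectivity(w_signal, w_control):
    """Relative weight difference ``(w_P - w_ctl) / (w_P + w_ctl)`` in [-1, 1]."""
    w_signal = np.asarray(w_signal, dtype=float)
    w_control = np.asarray(w_control, dtype=float)
    if w_signal.ndim == 0:
        return _relative_ratio(float(w_signal), float(w_control), "signal_selectivity")
    return np.array(
        [_relative_ratio(a, b, "signal_selectivity") for a, b in zip(w_signal, w_control)]
    )


def relative_tuning(w_p2, w_p1):
    """Relative tuning ``(w_P2 - w_P1) / (w_P2 + w_P1)`` in [-1, 1]."""
    w_p2 = np.asarray(w_p2, dtype=float)
    w_p1 = np.asarray(w_p1, dtype=float)
    if w_p2.ndim == 0:
        return _relative_ratio(float(w_p2), float(w_p1), "relative_tuning")
    return np.array(
        [_relative_ratio(a, b, "relative_tuning") for a, b in zip(w_p2, w_p1)]
    )


def reconstruct_inputs(
    network_raster,
    target_traces: Dict[str, np.ndarray],
    bin_width: float = 0.025,
    train_span: float = 95.0,
    test_span: float = 5.0,
    alpha: float = 1.0,
    seed: int = 0,
) -> Dict[str, float]:
    """Held-out R^2 of L1-regularized decoding of targets from binned rates.

    Network spikes are binned (25-ms bins by default) and a Lasso
    regression maps binned rates to each target trace; the model is fit on
    the first ``train_span`` seconds and scored on the final
    ``test_span`` seconds.  Targets must be sampled on the same bin grid.
    """
    if network_raster.duration + 1e-9 < train_span + test_span:
        raise ValueError("raster shorter than train + test span")
    X = network_raster.binned_counts(bin_width) / bin_width  # rates in Hz
    n_train = int(round(train_span / bin_width))
    n_test = int(round(test_span / bin_width))
    out: Dict[str, float] = {}
    for name, y in target_traces.items():
        y = np.asarray(y, dtype=float)
        if len(y) != X.shape[0]:
            raise ValueError(
                f"target {name!r} has {len(y)} bins, raster has {X.shape[0]}"
            )
        model = Lasso(alpha=alpha, random_state=seed, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[:n_train], y[:n_train])
        pred = model.predict(X[n_train : n_train + n_test])
        out[name] = float(r2_score(y[n_train : n_train + n_test], pred))
    return out


def representational_similarity(
    reps: np.ndarray,
    factor_labels: np.ndarray,
    factor: int,
    eps: float = 1e-12,
) -> np.ndarray:
    """Per-factor averaged cosine-similarity matrix.

    Groups samples by the level of ``factor`` (column of
    ``factor_labels``), holding every combination of the remaining
    factors fixed, computes the cosine similarity between mean
    representations across the levels of the chosen factor, and averages
    over the settings of the other factors.  Cells with no data raise.
    """
    reps = np.atleast_2d(np.asarray(reps, dtype=float))
    labels = np.atleast_2d(np.asarray(factor_labels))
    levels = np.unique(labels[:, factor])
    others = [c for c in range(labels.shape[1]) if c != factor]
    if others:
        other_keys = [tuple(row) for row in labels[:, others]]
    else:
        other_keys = [()] * len(labels)
    uniq = sorted(set(other_keys))
    L = len(levels)
    acc = np.zeros((L, L))
    n_used = 0
    for key in uniq:
        sel = np.array([k == key for k in other_keys])
        means = []
        for lv in levels:
            m = sel & (labels[:, factor] == lv)
            if not np.any(m):
                means = None
                break
            means.append(reps[m].mean(axis=0))
        if means is None:
            continue
        V = np.stack(means)
        norms = np.linalg.norm(V, axis=1)
        sim = (V @ V.T) / np.maximum(np.outer(norms, norms), eps)
        acc += sim
        n_used += 1
    if n_used == 0:
        raise ValueError("no complete factor cell found")
    return acc / n_used


def disentanglement_score(
    reps: np.ndarray,
    factor_labels: np.ndarray,
    n_votes: int = 400,
    batch: int = 64,
    train_frac: float = 0.5,
    seed: int = 0,
) -> float:
    """Majority-vote disentanglement metric.

    For each vote, one factor is fixed: a batch of samples sharing that
    factor's value is drawn, each unit's responses are normalized by its
    global standard deviation, and the unit with the lowest variance in
    the batch votes for the fixed factor.  A majority-vote classifier
    (most frequent factor per unit, fit on the training votes) is scored
    on the held-out votes.  Factors with a single observed level are
    excluded with a warning.
    """
    reps = np.atleast_2d(np.asarray(reps, dtype=float))
    labels = np.atleast_2d(np.asarray(factor_labels))
    rng = np.random.default_rng(seed)
    n_units = reps.shape[1]
    std = reps.std(axis=0)
    std[std == 0] = 1.0
    norm = reps / std

    factors = []
    for f in range(labels.shape[1]):
        if len(np.unique(labels[:, f])) < 2:
            warnings.warn(f"factor {f} has a single level; excluded from the score")
        else:
            factors.append(f)
    if not factors:
        raise ValueError("no factor with more than one level")

    votes = np.zeros(n_votes, dtype=int)  # winning unit per vote
    truth = np.zeros(n_votes, dtype=int)  # fixed factor per vote
    for v in range(n_votes):
        f = factors[rng.integers(len(factors))]
        lv = rng.choice(np.unique(labels[:, f]))
        pool = np.flatnonzero(labels[:, f] == lv)
        take = rng.choice(pool, size=min(batch, len(pool)), replace=len(pool) < batch)
        var = norm[take].var(axis=0)
        votes[v] = int(np.argmin(var))
        truth[v] = f
    n_train = int(round(train_frac * n_votes))
    # majority-vote classifier: most frequent factor per winning unit
    table = np.zeros((n_units, labels.shape[1]))
    np.add.at(table, (votes[:n_train], truth[:n_train]), 1.0)
    unit_to_factor = np.argmax(table, axis=1)
    pred = unit_to_factor[votes[n_train:]]
    return float(np.mean(pred == truth[n_train:]))
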