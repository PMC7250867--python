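"""Classifier-derived neural decision variable (DV) from sensor epochs.

Per-timepoint linear support-vector decoders are trained on the
pre-decision phase to predict the initial choice (left vs. right) from
whole-sensor activity, then reapplied at the corresponding timepoint of the
post-decision phase.  The signed distance to the separating hyperplane is a
graded, time-resolved readout of choice evidence (positive = rightward);
an ordinary least-squares line through each trial's DV timeseries yields a
neural starting point (intercept) and drift (slope).  The module also
provides sensor-subset contribution maps and train-time x test-time
temporal generalization with per-condition AUC.

All feature extraction uses 100 ms boxcar windows stepped every 10 ms,
right-aligned to the nominal timepoint, and all standardization statistics
are estimated on training trials only (no leakage into held-out trials).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import rankdata
from sklearn.svm import LinearSVC

logger = logging.getLogger(__name__)

DEFAULT_C = 1.0  # SVM regularization constant


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class EpochSet:
    """Sensor-space epochs: trials x channels x samples, with metadata.

    ``times`` are milliseconds relative to the alignment event and must be
    uniform at 1000/sampling_rate; ``labels`` carries one row per trial.
    """

    data: np.ndarray
    sampling_rate: float
    times: np.ndarray
    labels: pd.DataFrame
    channels: list[str]
    alignment: str = "trial_onset"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be trials x channels x samples")
        n, c, s = self.data.shape
        if len(self.labels) != n:
            raise ValueError(f"label rows ({len(self.labels)}) != trials ({n})")
        if len(self.channels) != c:
            raise ValueError("channel name count mismatch")
        if len(self.times) != s:
            raise ValueError("times length mismatch")
        dt = np.diff(self.times)
        expected = 1000.0 / self.sampling_rate
        if len(dt) and not np.allclose(dt, expected, rtol=1e-6, atol=1e-6):
            raise ValueError("times must be strictly increasing and uniform at 1/sampling_rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochSet":
        """Restrict to samples with tmin_ms <= t <= tmax_ms."""
        m = (self.times >= tmin_ms - 1e-9) & (self.times <= tmax_ms + 1e-9)
        if not m.any():
            raise ValueError("crop window contains no samples")
        return EpochSet(
            data=self.data[:, :, m],
            sampling_rate=self.sampling_rate,
            times=self.times[m],
            labels=self.labels,
            channels=self.channels,
            alignment=self.alignment,
        )

    def realign(self, event_ms: float, alignment: str) -> "EpochSet":
        """Shift the time axis so ``event_ms`` becomes 0 (e.g. re-reference
        to post-decision evidence onset)."""
        return EpochSet(
            data=self.data,
            sampling_rate=self.sampling_rate,
            times=self.times - event_ms,
            labels=self.labels,
            channels=self.channels,
            alignment=alignment,
        )


@dataclass
class SlidingFeatures:
    """Windowed-mean features: X has shape (timepoints, trials, channels)."""

    X: np.ndarray
    times_ms: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]


@dataclass
class DecoderEnsemble:
    """One linear decision rule per training timepoint.

    scheme 'all': ``weights`` (T, channels), ``intercepts`` (T,).
    scheme 'loo': leading axis indexes the left-out trial —
    ``weights`` (trials, T, channels) — so that the rule used to score a
    trial was trained without it.  Standardization statistics (means/sds
    of the training trials' *pre-phase* features) are stored alongside;
    post-phase features are standardized with statistics computed over the
    same training trials at decode time.
    """

    weights: np.ndarray
    intercepts: np.ndarray
    scheme: str
    times_ms: np.ndarray
    C: float = DEFAULT_C
    n_train: int = 0


@dataclass
class DVSeries:
    """Per-trial, per-timepoint signed hyperplane distance (+ = rightward)."""

    dv: np.ndarray  # (trials, timepoints)
    times_ms: np.ndarray


@dataclass
class TGMatrix:
    """Temporal generalization: AUC for every (train-time, test-time) pair.

    ``overall`` is computed over all trials; ``by_cell`` holds the four
    confidence x change-of-mind cells.  AUC is for predicting the *initial*
    decision from the continuous DV.
    """

    overall: np.ndarray
    by_cell: dict[str, np.ndarray]
    train_times_ms: np.ndarray
    test_times_ms: np.ndarray
    folds: int = 4
    reps: int = 1


@dataclass
class SensorContributionMap:
    """Mean held-out accuracy over all random sensor subsets containing
    each channel."""

    contribution: np.ndarray
    counts: np.ndarray
    subset_size: int
    reps: int


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------


def preprocess(
    raw: EpochSet,
    target_rate: float = 100.0,
    highpass_hz: float = 0.5,
    realign_to_ms: float | None = None,
    alignment: str | None = None,
) -> EpochSet:
    """Resample epochs to ``target_rate`` and high-pass filter.

    Resampling is polyphase (scipy ``resample_poly``); the high-pass is a
    4th-order zero-phase Butterworth (``sosfiltfilt``), removing slow drift
    while leaving the task band untouched.  An 8200 ms segment recorded at
    600 Hz (4921 samples) becomes a 821-sample epoch at 100 Hz.
    """
    if raw.data.shape[2] < 8:
        raise ValueError("segments too short to preprocess")
    frac = Fraction(target_rate / raw.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = raw.data.astype(float)
    if (up, down) != (1, 1):
        data = signal.resample_poly(data, up, down, axis=2)
    n_out = data.shape[2]
    times = raw.times[0] + 1000.0 / target_rate * np.arange(n_out)
    if highpass_hz and highpass_hz > 0:
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=target_rate, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=2)
    out = EpochSet(
        data=data,
        sampling_rate=target_rate,
        times=times,
        labels=raw.labels,
        channels=raw.channels,
        alignment=raw.alignment,
    )
    if realign_to_ms is not None:
        out = out.realign(realign_to_ms, alignment or "realigned")
    return out


def highpass_response(freq_hz: float, highpass_hz: float = 0.5, fs: float = 100.0) -> float:
    """Designed zero-phase amplitude response of the high-pass at ``freq_hz``
    (forward-backward filtering squares the one-pass magnitude)."""
    sos = signal.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------


def sliding_features(
    epochs: EpochSet,
    window_ms: float = 100.0,
    step_ms: float = 10.0,
    tmin_ms: float | None = None,
    tmax_ms: float | None = None,
    standardize: bool = False,
) -> SlidingFeatures:
    """Windowed-mean sensor features on a regular timepoint grid.

    Each nominal timepoint t carries the mean activity over the window
    (t - window_ms, t], clipped at the epoch edge.  With
    ``standardize=True`` each (timepoint, channel) column is z-scored
    across trials (use only where no train/test split applies; decoders
    standardize per training fold instead).
    """
    if step_ms <= 0:
        raise ValueError("step must be positive")
    times = epochs.times
    if window_ms > times[-1] - times[0] + 1000.0 / epochs.sampling_rate:
        raise ValueError("window longer than epoch")
    lo = times[0] if tmin_ms is None else tmin_ms
    hi = times[-1] if tmax_ms is None else tmax_ms
    grid = np.arange(lo, hi + step_ms / 2, step_ms)
    X = np.empty((len(grid), epochs.n_trials, len(epochs.channels)))
    for k, t in enumerate(grid):
        # half-open window (t - window, t]: 100 ms at 100 Hz = 10 samples
        m = (times - (t - window_ms) > 1e-9) & (times <= t + 1e-9)
        if not m.any():
            m = np.abs(times - t) == np.abs(times - t).min()
        X[k] = epochs.data[:, :, m].mean(axis=2)
    if standardize:
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    return SlidingFeatures(X=X, times_ms=grid)


def _standardize(train: np.ndarray, *apply_to: np.ndarray):
    """Z-score using training-set statistics; returns scaled copies."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return [(a - mu) / sd for a in apply_to]


def _labels_to_signs(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        known = {"right": 1, "left": -1, "high": 1, "low": -1}
        try:
            y = np.array([known[str(v)] for v in y])
        except KeyError as e:
            raise ValueError(f"unknown class label {e.args[0]!r}") from None
    y = y.astype(int)
    u = np.unique(y)
    if len(u) != 2:
        raise ValueError(f"need exactly two classes, got {u}")
    return np.where(y == u.max(), 1, -1)


# ---------------------------------------------------------------------------
# Decoders and the decision variable
# ---------------------------------------------------------------------------


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, normalize: bool = False) -> tuple[np.ndarray, float]:
    clf = LinearSVC(C=C, dual="auto", max_iter=5000, tol=1e-5, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X, y)
    w, b = clf.coef_[0].copy(), float(clf.intercept_[0])
    if normalize:
        nrm = float(np.linalg.norm(w))
        if nrm > 0:  # geometric (unit-norm) distance to the hyperplane
            w, b = w / nrm, b / nrm
    return w, b


def train_decoders(
    pre: SlidingFeatures,
    labels,
    scheme: str = "loo",
    C: float = DEFAULT_C,
) -> DecoderEnsemble:
    """Train one linear SVM (C = 1 by default) per pre-decision timepoint.

    ``scheme='loo'`` implements the leave-one-out protocol: for every trial
    a full ensemble is trained on the remaining trials, so downstream DV
    scores for that trial never saw it during training.  ``scheme='all'``
    trains a single ensemble on all trials (for application to independent
    data).
    """
    y = _labels_to_signs(labels)
    T, n, c = pre.X.shape
    if scheme == "all":
        W = np.empty((T, c))
        b = np.empty(T)
        for t in range(T):
            Xs, = _standardize(pre.X[t], pre.X[t])
            W[t], b[t] = _fit_svc(Xs, y, C, normalize=True)
        return DecoderEnsemble(W, b, "all", pre.times_ms, C, n)
    if scheme != "loo":
        raise ValueError("scheme must be 'loo' or 'all'")
    W = np.empty((n, T, c))
    b = np.empty((n, T))
    idx = np.arange(n)
    for i in range(n):
        tr = idx != i
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training set after leaving one out")
        for t in range(T):
            Xs, = _standardize(pre.X[t][tr], pre.X[t][tr])
            W[i, t], b[i, t] = _fit_svc(Xs, y[tr], C, normalize=True)
    return DecoderEnsemble(W, b, "loo", pre.times_ms, C, n)


def decode_dv(
    ensemble: DecoderEnsemble,
    post: SlidingFeatures,
    train_post: SlidingFeatures | None = None,
) -> DVSeries:
    """Reapply the pre-decision rules to the post-decision phase.

    Timepoint t of the post phase is scored with the rule trained at
    timepoint t of the pre phase; the output is the signed geometric
    distance to the hyperplane (positive = rightward prediction).

    Post-phase features are normalized per channel with statistics pooled
    over the analysis window and estimated on training trials only
    (``train_post`` for scheme 'all', defaulting to ``post`` itself; the
    remaining trials for 'loo').  Pooling keeps the whole DV timeseries in
    one unit system so that a within-trial linear trend is meaningful —
    per-timepoint scaling would give every timepoint its own unit and
    distort trial-wise slopes.
    """
    T, n, c = post.X.shape
    if T != len(ensemble.times_ms):
        raise ValueError(
            f"timepoint count mismatch: ensemble has {len(ensemble.times_ms)}, features {T}"
        )
    dv = np.empty((n, T))
    if ensemble.scheme == "all":
        ref = post.X if train_post is None else train_post.X
        mu = ref.mean(axis=(0, 1))
        sd = ref.std(axis=(0, 1))
        sd = np.where(sd > 0, sd, 1.0)
        for t in range(T):
            Xs = (post.X[t] - mu) / sd
            dv[:, t] = Xs @ ensemble.weights[t] + ensemble.intercepts[t]
        return DVSeries(dv=dv, times_ms=post.times_ms)
    # leave-one-out: trial i uses rule i and pooled stats from the others
    if ensemble.weights.shape[0] != n:
        raise ValueError("trial count mismatch between ensemble and features")
    per_trial_sum = post.X.sum(axis=0).astype(float)        # (n, c) over timepoints
    per_trial_sum2 = (post.X.astype(float) ** 2).sum(axis=0)
    tot = per_trial_sum.sum(axis=0)                          # (c,)
    tot2 = per_trial_sum2.sum(axis=0)
    m = T * (n - 1)
    mu = (tot[None, :] - per_trial_sum) / m                  # (n, c) LOO means
    var = (tot2[None, :] - per_trial_sum2) / m - mu**2
    sd = np.sqrt(np.maximum(var, 0.0))
    sd = np.where(sd > 0, sd, 1.0)
    for t in range(T):
        Xs = (post.X[t] - mu) / sd
        dv[:, t] = np.einsum("ic,ic->i", Xs, ensemble.weights[:, t, :]) + ensemble.intercepts[:, t]
    return DVSeries(dv=dv, times_ms=post.times_ms)


def dv_trend(series: DVSeries, tmin_ms: float | None = None, tmax_ms: float | None = None) -> pd.DataFrame:
    """Per-trial OLS intercept and slope of the DV over the given window.

    Time is in seconds from the window start (post-stimulus onset), so the
    intercept is the DV at onset (starting-point analogue) and the slope is
    in DV units per second (drift analogue).
    """
    t = series.times_ms
    lo = t[0] if tmin_ms is None else tmin_ms
    hi = t[-1] if tmax_ms is None else tmax_ms
    m = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if m.sum() < 3:
        raise ValueError("trend window must contain at least 3 timepoints")
    ts = (t[m] - lo) / 1000.0
    Y = series.dv[:, m]
    A = np.vstack([np.ones_like(ts), ts]).T
    coef, *_ = np.linalg.lstsq(A, Y.T, rcond=None)
    return pd.DataFrame({"intercept": coef[0], "slope": coef[1]})


def unsign(summary: pd.DataFrame, direction) -> pd.DataFrame:
    """Flip slope/intercept sign on leftward-motion trials so positive
    means 'toward the presented direction'.  Involutive."""
    d = np.asarray(direction)
    if d.dtype.kind in "OUS":
        bad = ~np.isin(d, ["left", "right"])
        if bad.any():
            raise ValueError(f"unknown direction label {d[bad][0]!r}")
        s = np.where(d == "right", 1.0, -1.0)
    else:
        s = np.where(d > 0, 1.0, -1.0)
    out = summary.copy()
    for col in ("intercept", "slope"):
        if col in out.columns:
            out[col] = out[col].to_numpy() * s
    return out


# ---------------------------------------------------------------------------
# Temporal generalization and derived quantities
# ---------------------------------------------------------------------------


def _auc_matrix(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rank-based AUC of ``y`` (+1/-1) from scores of shape (trials, ...)."""
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return np.full(scores.shape[1:], np.nan)
    r = rankdata(scores, axis=0)
    return (r[pos].sum(axis=0) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _stratified_folds(strata: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign each trial a fold, balancing every stratum across folds."""
    assign = np.empty(len(strata), dtype=int)
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % n_folds
    return assign


def temporal_generalization(
    pre: SlidingFeatures,
    post: SlidingFeatures,
    labels,
    cells,
    folds: int = 4,
    reps: int = 100,
    seed: int = 0,
    C: float = DEFAULT_C,
    stratify_cells=None,
) -> TGMatrix:
    """Train-time x test-time AUC of predicting the initial decision.

    Stratified ``folds``-fold cross-validation, repeated ``reps`` times
    with reshuffled folds; stratification balances decision x condition
    cells across folds.  AUC is reported over all trials and separately
    for the four confidence x change-of-mind cells.

    ``stratify_cells`` optionally replaces ``cells`` for fold
    stratification only (e.g. coarser strata when a condition cell holds
    fewer trials than folds); AUC grouping still follows ``cells``.
    """
    y = _labels_to_signs(labels)
    cells = np.asarray(cells).astype(str)
    strat = cells if stratify_cells is None else np.asarray(stratify_cells).astype(str)
    strata = np.char.add(np.where(y > 0, "R|", "L|"), strat)
    counts = pd.Series(strata).value_counts()
    too_small = counts[counts < folds]
    if len(too_small):
        raise ValueError(
            f"condition cell too small to stratify into {folds} folds: "
            + ", ".join(f"{k} (n={v})" for k, v in too_small.items())
        )
    Tt, n, c = pre.X.shape
    Tu = post.X.shape[0]
    rng = np.random.default_rng(seed)
    auc_sum = np.zeros((Tt, Tu))
    cell_names = sorted(np.unique(cells))
    cell_sums = {k: np.zeros((Tt, Tu)) for k in cell_names}
    scores = np.empty((n, Tt, Tu))
    for _ in range(reps):
        fold_of = _stratified_folds(strata, folds, rng)
        for f in range(folds):
            te = fold_of == f
            tr = ~te
            for t in range(Tt):
                Xtr, = _standardize(pre.X[t][tr], pre.X[t][tr])
                w, b = _fit_svc(Xtr, y[tr], C)
                # standardize every post timepoint with training-trial stats
                mu = post.X[:, tr, :].mean(axis=1)  # (Tu, c)
                sd = post.X[:, tr, :].std(axis=1)
                sd = np.where(sd > 0, sd, 1.0)
                Xte = (post.X[:, te, :] - mu[:, None, :]) / sd[:, None, :]
                scores[te, t, :] = (Xte @ w).T + b
        auc_sum += _auc_matrix(scores, y)
        for k in cell_names:
            m = cells == k
            cell_sums[k] += _auc_matrix(scores[m], y[m])
    return TGMatrix(
        overall=auc_sum / reps,
        by_cell={k: v / reps for k, v in cell_sums.items()},
        train_times_ms=pre.times_ms,
        test_times_ms=post.times_ms,
        folds=folds,
        reps=reps,
    )


def peak_decodability(tg: TGMatrix | np.ndarray) -> int:
    """Index of the timepoint maximizing diagonal (corresponding-timepoint)
    accuracy; ties break toward the earlier timepoint."""
    mat = tg.overall if isinstance(tg, TGMatrix) else np.asarray(tg)
    k = min(mat.shape)
    if k < 1:
        raise ValueError("diagonal undefined")
    diag = np.diagonal(mat)[:k]
    if np.allclose(diag, diag[0]):
        warnings.warn("flat diagonal: peak decodability defaults to the earliest timepoint")
        return 0
    return int(np.argmax(diag))  # argmax returns the first maximum


def sensor_contributions(
    features: np.ndarray,
    labels,
    subset_size: int = 30,
    reps: int = 2500,
    seed: int = 0,
    folds: int = 4,
    C: float = DEFAULT_C,
) -> SensorContributionMap:
    """Mean held-out accuracy of random ``subset_size``-sensor decoders.

    ``features`` is the (trials, channels) matrix at the peak-decodability
    timepoint.  Each repetition draws a random sensor subset, estimates
    its cross-validated accuracy, and credits that accuracy to every
    sensor in the subset; a sensor's contribution is the mean over all
    subsets containing it.
    """
    X = np.asarray(features, dtype=float)
    y = _labels_to_signs(labels)
    n, c = X.shape
    if c < subset_size:
        raise ValueError(f"need at least {subset_size} channels, got {c}")
    rng = np.random.default_rng(seed)
    acc_sum = np.zeros(c)
    counts = np.zeros(c)
    strata = np.where(y > 0, "R", "L")
    for _ in range(reps):
        sub = rng.choice(c, size=subset_size, replace=False)
        fold_of = _stratified_folds(strata, folds, rng)
        correct = 0
        for f in range(folds):
            te = fold_of == f
            tr = ~te
            Xtr, Xte = _standardize(X[tr][:, sub], X[tr][:, sub], X[te][:, sub])
            w, b = _fit_svc(Xtr, y[tr], C)
            correct += int(np.sum(np.sign(Xte @ w + b) == y[te]))
        acc = correct / n
        acc_sum[sub] += acc
        counts[sub] += 1
    if (counts == 0).any():
        warnings.warn(
            f"{int((counts == 0).sum())} channels never sampled in {reps} subsets; "
            "increase reps for full coverage"
        )
    contribution = np.divide(acc_sum, counts, out=np.zeros(c), where=counts > 0)
    return SensorContributionMap(contribution, counts, subset_size, reps)
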