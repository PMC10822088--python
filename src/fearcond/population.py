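"""Population-level analyses of simultaneously recorded neurons.

Baseline Z-scoring, the moment-by-moment T x T population-vector
correlation (PCC) matrix, epoch-wise mean PCC with the diagonal factored
out, PCA state-space trajectories, the Mahalanobis distance between the
baseline and post-shock centroids, a repeated stratified logistic
classifier of state-space coordinates, and epoch-wise comparisons of
per-cell mean activity distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .containers import ActivityMatrix
from .synthetic import SessionSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "EpochLabels",
    "PopulationCorrelationMatrix",
    "StateSpaceResult",
    "ClassifierResult",
    "baseline_zscore",
    "label_epochs",
    "population_correlation_matrix",
    "epoch_mean_pcc",
    "cross_trial_similarity",
    "pca_state_space",
    "mahalanobis_shift",
    "state_space_classifier",
    "epoch_z_distribution",
    "compare_distributions",
]

FINE_EPOCHS = ("baseline", "tone", "shock", "post_shock_window", "iti")


# ---------------------------------------------------------------------------
# normalization and epoch labeling
# ---------------------------------------------------------------------------

def baseline_zscore(activity: ActivityMatrix, baseline_duration: float = 300.0) -> ActivityMatrix:
    """Z-score each neuron against the session's opening baseline period.

    Default baseline is the first 5 minutes. Neurons with zero baseline
    variance cannot be standardized and are excluded with a logged ID.
    """
    n_base = int(round(baseline_duration / activity.bin_width))
    if n_base < 2:
        raise ValueError("baseline must contain at least two bins")
    base = activity.values[:, :n_base]
    mu = base.mean(axis=1)
    sd = base.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [nid for nid, k in zip(activity.neuron_ids, keep) if not k]
        logger.warning("excluding %d zero-baseline-variance neurons: %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("no neurons with nonzero baseline variance")
    z = (activity.values[keep] - mu[keep, None]) / sd[keep, None]
    ids = [nid for nid, k in zip(activity.neuron_ids, keep) if k]
    return ActivityMatrix(z, activity.bin_width, ids, units_tag="zscored")


@dataclass
class EpochLabels:
    """Per-bin fine epoch labels and the baseline/post-baseline dichotomy.

    ``fine`` is one of baseline / tone / shock / post_shock_window / iti.
    ``coarse`` splits the session at the first shock onset: every bin from
    that onset (inclusive) is post-baseline, everything before it baseline.
    """

    time_axis: np.ndarray
    fine: np.ndarray
    coarse: np.ndarray

    def bins(self, epoch: str) -> np.ndarray:
        source = self.coarse if epoch == "post" else self.fine
        return np.flatnonzero(source == epoch)


def label_epochs(
    schedule: SessionSchedule,
    time_axis: np.ndarray | None = None,
    post_shock_window: float = 5.0,
    iti_convention: str = "shock_off",
) -> EpochLabels:
    """Label every time bin with its session epoch.

    Fine labels follow precedence shock > tone > post-shock window > ITI,
    with all pre-first-tone time labeled baseline. Coarse labels implement
    the baseline / post-baseline dichotomy at the first shock onset; in a
    shock-free session everything is coarse-baseline.
    """
    if time_axis is None:
        time_axis = schedule.bin_times
    mid = np.asarray(time_axis, float) + schedule.bin_width / 2.0
    fine = np.full(mid.size, "iti", dtype=object)
    first_tone = schedule.trials[0].tone_on if schedule.trials else schedule.session_end
    fine[mid < first_tone] = "baseline"
    for s, e in schedule.iti_windows(convention=iti_convention):
        fine[(mid >= s) & (mid < e)] = "iti"
        post_end = min(s + post_shock_window, e)
        fine[(mid >= s) & (mid < post_end)] = "post_shock_window"
    for tr in schedule.trials:
        fine[(mid >= tr.tone_on) & (mid < tr.tone_off)] = "tone"
        if tr.has_shock:
            fine[(mid >= tr.shock_on) & (mid < tr.shock_off)] = "shock"
    first = schedule.first_shock_onset
    coarse = np.full(mid.size, "baseline", dtype=object)
    if first is not None:
        # the bin containing the first shock onset, and everything after, is post-baseline
        onset_bin = int(np.floor(first / schedule.bin_width + 1e-9))
        coarse[onset_bin:] = "post"
    return EpochLabels(np.asarray(time_axis, float), fine.astype(str), coarse.astype(str))


# ---------------------------------------------------------------------------
# correlation structure
# ---------------------------------------------------------------------------

@dataclass
class PopulationCorrelationMatrix:
    """T x T Pearson correlations between population vectors."""

    values: np.ndarray
    time_axis: np.ndarray
    epoch_labels: EpochLabels | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")


def population_correlation_matrix(
    activity: ActivityMatrix, labels: EpochLabels | None = None
) -> PopulationCorrelationMatrix:
    """Correlate every population vector with every other time point's.

    Entry (s, t) is the Pearson correlation across neurons between the
    population vectors at bins s and t. Bins whose population vector is
    constant across neurons have undefined correlations; their row/column
    is set to NaN with a warning.
    """
    if activity.n_neurons < 3:
        raise ValueError("need at least 3 neurons for population correlations")
    V = activity.values  # neurons x T
    sd = V.std(axis=0)
    const = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.corrcoef(V, rowvar=False)
    if const.any():
        logger.warning("%d constant population vectors set to missing", int(const.sum()))
        M[const, :] = np.nan
        M[:, const] = np.nan
    M = (M + M.T) / 2.0
    di = np.arange(M.shape[0])
    M[di, di] = np.where(const, np.nan, 1.0)
    return PopulationCorrelationMatrix(M, activity.time_axis, labels)


def _window_bins(matrix: PopulationCorrelationMatrix, window) -> np.ndarray:
    if isinstance(window, str):
        if matrix.epoch_labels is None:
            raise ValueError("named windows need epoch labels on the matrix")
        idx = matrix.epoch_labels.bins(window)
    elif isinstance(window, tuple) and len(window) == 2 and np.isscalar(window[0]):
        start, end = window
        t = matrix.time_axis
        if start < t[0] - 1e-9 or end > t[-1] + (t[1] - t[0]) + 1e-9:
            raise ValueError("window outside the session")
        idx = np.flatnonzero((t >= start - 1e-9) & (t < end - 1e-9))
    else:
        idx = np.asarray(window, dtype=int)
    if idx.size == 0:
        raise ValueError("window selects no time bins")
    return idx


def epoch_mean_pcc(matrix: PopulationCorrelationMatrix, window_a, window_b=None) -> float:
    """Mean PCC within or across windows with the diagonal factored out.

    Windows are epoch names, (start, end) second pairs, or bin indices.
    Within-window means count each unordered bin pair once; diagonal
    entries (and NaN rows from constant vectors) are excluded.
    """
    a = _window_bins(matrix, window_a)
    if window_b is None or (np.isscalar(window_b) and window_b == window_a):
        vals = matrix.values[np.ix_(a, a)][np.triu_indices(a.size, k=1)]
    else:
        b = _window_bins(matrix, window_b)
        sub = matrix.values[np.ix_(a, b)]
        mask = a[:, None] != b[None, :]
        vals = sub[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def cross_trial_similarity(
    matrix: PopulationCorrelationMatrix,
    schedule: SessionSchedule,
    epoch: str = "shock",
    reference_trial: int = 1,
    window_length: float | None = None,
) -> np.ndarray:
    """Mean PCC between the reference trial's epoch bins and every other trial's.

    ``epoch`` is tone / shock / iti; ``window_length`` optionally truncates
    each trial's epoch to its first that-many seconds. Missing epochs on a
    trial yield NaN.
    """
    if schedule.n_trials < 2:
        raise ValueError("need at least two trials")
    t = matrix.time_axis
    bw = schedule.bin_width

    def trial_window(k: int):
        tr = schedule.trials[k - 1]
        if epoch == "tone":
            s, e = tr.tone_on, tr.tone_off
        elif epoch == "shock":
            if not tr.has_shock:
                return None
            s, e = tr.shock_on, tr.shock_off
        elif epoch == "iti":
            wins = schedule.iti_windows()
            if k - 1 >= len(wins):
                return None
            s, e = wins[k - 1]
        else:
            raise ValueError(f"unknown epoch {epoch!r}")
        if window_length is not None:
            e = min(e, s + window_length)
        return np.flatnonzero((t >= s - 1e-9) & (t < e - 1e-9))

    ref = trial_window(reference_trial)
    if ref is None or ref.size == 0:
        raise ValueError("reference trial has no bins for this epoch")
    out = []
    for k in range(1, schedule.n_trials + 1):
        if k == reference_trial:
            continue
        w = trial_window(k)
        if w is None or w.size == 0:
            out.append(np.nan)
            continue
        out.append(epoch_mean_pcc(matrix, ref, w))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# state space: PCA, Mahalanobis shift, classification
# ---------------------------------------------------------------------------

@dataclass
class StateSpaceResult:
    pc_coordinates: np.ndarray          # T x 2 scores
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray                # neurons x 2
    labels: EpochLabels
    covariance_mode: str | None = None
    mahalanobis: float | None = None


def pca_state_space(activity: ActivityMatrix, labels: EpochLabels, n_components: int = 2) -> StateSpaceResult:
    """Project the time-points x neurons matrix onto its first two PCs.

    Neurons are mean-centered (inputs are typically already baseline
    Z-scored; no further per-neuron rescaling). Component signs follow a
    deterministic convention: the largest-magnitude loading is positive.
    """
    V = activity.values
    nz = V.std(axis=1) > 0
    if nz.sum() < 2:
        raise ValueError("need at least two nonzero-variance neurons")
    X = V[nz].T  # time x neurons
    if X.shape[0] <= 2:
        raise ValueError("need more than two time bins")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # neurons x k
    for c in range(scores.shape[1]):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    full_loadings = np.zeros((activity.n_neurons, scores.shape[1]))
    full_loadings[nz] = loadings
    return StateSpaceResult(scores, pca.explained_variance_ratio_, full_loadings, labels)


def mahalanobis_shift(result: StateSpaceResult, mode: str = "pooled", ridge: float = 1e-8) -> float:
    """Mahalanobis distance between baseline and post-baseline centroids.

    d_M = sqrt((x - y)^T S^-1 (x - y)) with S the pooled within-group
    covariance of the PC coordinates by default (``mode='baseline'`` uses
    the baseline-group covariance alone). A singular S is ridge-regularized
    with a logged epsilon.
    """
    coarse = result.labels.coarse
    a = result.pc_coordinates[coarse == "baseline"]
    b = result.pc_coordinates[coarse == "post"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both baseline and post-baseline groups must be non-empty")
    diff = a.mean(axis=0) - b.mean(axis=0)
    if mode == "pooled":
        ca, cb = np.cov(a, rowvar=False), np.cov(b, rowvar=False)
        S = ((len(a) - 1) * ca + (len(b) - 1) * cb) / (len(a) + len(b) - 2)
    elif mode == "baseline":
        S = np.cov(a, rowvar=False)
    else:
        raise ValueError("mode must be 'pooled' or 'baseline'")
    S = np.atleast_2d(S)
    try:
        sol = np.linalg.solve(S, diff)
    except np.linalg.LinAlgError:
        eps = ridge * max(np.trace(S) / S.shape[0], 1.0)
        logger.warning("singular covariance; ridge-regularizing with eps=%.3g", eps)
        sol = np.linalg.solve(S + eps * np.eye(S.shape[0]), diff)
    d2 = float(diff @ sol)
    result.covariance_mode = mode
    result.mahalanobis = float(np.sqrt(max(d2, 0.0)))
    return result.mahalanobis


def mahalanobis_distance(x: np.ndarray, y: np.ndarray, S: np.ndarray) -> float:
    """d_M = sqrt((x-y)^T S^-1 (x-y)) for explicit centroids and covariance."""
    diff = np.asarray(x, float) - np.asarray(y, float)
    sol = np.linalg.solve(np.atleast_2d(np.asarray(S, float)), diff)
    return float(np.sqrt(max(diff @ sol, 0.0)))


@dataclass
class ClassifierResult:
    accuracies: np.ndarray
    mean_accuracy: float
    chance_level: float          # majority-class proportion
    class_proportions: dict
    iterations: int
    mode: str


def state_space_classifier(
    pc_coordinates: np.ndarray,
    labels: np.ndarray | EpochLabels,
    iterations: int = 10,
    train_fraction: float = 0.75,
    seed: int = 0,
    mode: str = "shuffle",
) -> ClassifierResult:
    """Classify state-space coordinates as baseline vs post-baseline.

    Default (``mode='shuffle'``): ``iterations`` repeated stratified
    shuffled splits training a linear logistic model on ``train_fraction``
    of the time bins and scoring held-out accuracy on the rest; the mean
    of the held-out accuracies is reported alongside the majority-class
    proportion as the chance level. ``mode='kfold'`` runs literal
    stratified K-fold cross-validation with K = ``iterations``.
    """
    X = np.asarray(pc_coordinates, dtype=float)
    y = labels.coarse if isinstance(labels, EpochLabels) else np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if len(y) < 20:
        raise ValueError("need at least 20 time bins to split")
    if mode == "shuffle":
        splitter = StratifiedShuffleSplit(
            n_splits=iterations, train_size=train_fraction, random_state=seed
        )
    elif mode == "kfold":
        splitter = StratifiedKFold(n_splits=iterations, shuffle=True, random_state=seed)
    else:
        raise ValueError("mode must be 'shuffle' or 'kfold'")
    accs = []
    for train, test in splitter.split(X, y):
        clf = LogisticRegression(max_iter=1000)
        clf.fit(X[train], y[train])
        accs.append(float(clf.score(X[test], y[test])))
    accs = np.asarray(accs)
    return ClassifierResult(
        accuracies=accs,
        mean_accuracy=float(accs.mean()),
        chance_level=float(counts.max() / counts.sum()),
        class_proportions={c: float(n / counts.sum()) for c, n in zip(classes, counts)},
        iterations=iterations,
        mode=mode,
    )


# ---------------------------------------------------------------------------
# epoch-wise activity distributions
# ---------------------------------------------------------------------------

def epoch_z_distribution(activity: ActivityMatrix, labels: EpochLabels, epoch: str) -> np.ndarray:
    """One mean-Z value per cell over the bins of an epoch."""
    idx = labels.bins(epoch)
    if idx.size == 0:
        raise ValueError(f"epoch {epoch!r} selects no time bins")
    return activity.values[:, idx].mean(axis=1)


def compare_distributions(a: np.ndarray, b: np.ndarray):
    """Two-sample Kolmogorov-Smirnov comparison of per-cell mean activity."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
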