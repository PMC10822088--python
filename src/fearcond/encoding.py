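"""Time-kernel linear encoding model for single-neuron task tuning.

Each neuron's binned calcium trace is regressed on lagged, trial-split
task indicators (tone, footshock, ITI), lagged speed, and its own
one-bin-lagged signal (autoregressive term):

    y_t = b0 * y_{t-1}
        + sum_n sum_i b1[n,i] * tone_n(t-i)
        + sum_n sum_i b2[n,i] * shock_n(t-i)
        + sum_n sum_i b3[n,i] * iti_n(t-i)
        + sum_i b4[i] * speed(t-i) + eps_t

A task variable is "encoded" by a neuron when dropping all of its columns
(all trials, all lags) significantly reduces explained variance — assessed
with a partial F-test on the extra sum of squares. Trial-level encoding
drops only that trial's lag columns. Collinearity diagnostics (VIF,
condition index, minimum-eigenvalue path) support predictor selection.

The printed model carries no intercept; fits append one internally (it is
retained, like the autoregressive column, in every reduced model) so that
explained variance is a proper coefficient of determination in [0, 1].
Rows whose lag history would reach before the session start are dropped
from the fit rather than zero-padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ActivityMatrix
from .synthetic import SessionSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "EncoderFit",
    "VariableTest",
    "CollinearityReport",
    "PopulationEncoder",
    "bin_activity",
    "build_design_matrix",
    "fit_encoder",
    "test_variable_encoding",
    "test_trial_encoding",
    "collinearity_diagnostics",
    "summarize_encoders",
    "reactivation_probability",
    "speed_tuning",
]

TASK_VARIABLES = ("tone", "footshock", "iti")
_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# binning and design construction
# ---------------------------------------------------------------------------

def bin_activity(trace: np.ndarray, bin_width: float, sampling_rate: float) -> np.ndarray:
    """Aggregate a sampled trace into bins of ``bin_width`` s by the mean.

    ``bin_width`` must be a (near-)integer multiple of the sample interval;
    a partial trailing bin is dropped.
    """
    trace = np.asarray(trace, dtype=float)
    spb = bin_width * sampling_rate
    if spb < 1 - 1e-9:
        raise ValueError("bin_width must not be smaller than the sample interval")
    if abs(spb - round(spb)) > 1e-6:
        raise ValueError("bin_width must be an integer multiple of the sample interval")
    spb = int(round(spb))
    n_bins = trace.size // spb
    return trace[: n_bins * spb].reshape(n_bins, spb).mean(axis=1)


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    out = np.zeros_like(x)
    if lag == 0:
        return x.copy()
    out[lag:] = x[:-lag]
    return out


@dataclass
class DesignMatrix:
    """Time-bins x predictors matrix with labeled columns.

    Column labels are ``(variable, trial, lag)``; the autoregressive column
    is ``("autoregressive", None, None)`` and continuous columns (speed)
    carry ``trial=None``. Task columns are binary indicators.
    """

    X: np.ndarray
    labels: list[tuple]
    kernel_length: int
    bin_width: float
    continuous_label: str = "speed"

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def n_bins(self) -> int:
        return self.X.shape[0]

    @property
    def n_trials(self) -> int:
        return max((lab[1] for lab in self.labels if lab[1] is not None), default=0)

    @property
    def test_variables(self) -> list[str]:
        """Variables subject to the nested encoding test (AR excluded)."""
        seen = []
        for lab in self.labels:
            if lab[0] != "autoregressive" and lab[0] not in seen:
                seen.append(lab[0])
        return seen

    def columns_of(self, variable: str, trial: int | None = None) -> np.ndarray:
        idx = [
            j
            for j, lab in enumerate(self.labels)
            if lab[0] == variable and (trial is None or lab[1] == trial)
        ]
        if not idx:
            if variable not in {lab[0] for lab in self.labels}:
                raise ValueError(f"variable {variable!r} not in design")
            raise ValueError(f"trial {trial} out of range for variable {variable!r}")
        return np.asarray(idx)

    @property
    def fit_rows(self) -> slice:
        """Rows with complete lag history (and an available AR lag)."""
        return slice(max(self.kernel_length - 1, 1), None)


def _task_columns(schedule: SessionSchedule, speed: np.ndarray, kernel_length: int,
                  continuous_label: str = "speed"):
    """All design columns except the autoregressive one."""
    n_bins = schedule.n_bins
    speed = np.asarray(speed, dtype=float)
    if speed.size != n_bins:
        raise ValueError("speed must be binned to the schedule's bin grid")
    cols, labels = [], []
    for var in TASK_VARIABLES:
        for n in range(1, schedule.n_trials + 1):
            ind = schedule.indicator(var, trial=n)
            for i in range(kernel_length):
                cols.append(_lagged(ind, i))
                labels.append((var, n, i))
    for i in range(kernel_length):
        cols.append(_lagged(speed, i))
        labels.append((continuous_label, None, i))
    return np.column_stack(cols), labels


def build_design_matrix(
    schedule: SessionSchedule,
    speed: np.ndarray,
    trace: np.ndarray,
    kernel_length: int = 5,
    continuous_label: str = "speed",
) -> DesignMatrix:
    """Construct the full design matrix for one neuron.

    ``speed`` and ``trace`` must already be on the schedule's bin grid.
    The continuous predictor is not split by trial; task indicators are
    dummy-coded per trial and lag.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size != schedule.n_bins:
        raise ValueError("trace must be binned to the schedule's bin grid")
    F, labels = _task_columns(schedule, speed, kernel_length, continuous_label)
    ar = _lagged(trace, 1)
    X = np.column_stack([ar, F])
    return DesignMatrix(X, [("autoregressive", None, None)] + labels, kernel_length,
                        schedule.bin_width, continuous_label)


# ---------------------------------------------------------------------------
# fitting and nested tests
# ---------------------------------------------------------------------------

@dataclass
class VariableTest:
    variable: str
    trial: int | None
    f_stat: float
    p_value: float
    significant: bool
    ev_full: float
    ev_reduced: float
    q: int


@dataclass
class EncoderFit:
    coefficients: np.ndarray
    column_labels: list[tuple]
    intercept: float | None
    r_squared: float
    residual_variance: float
    n_obs: int
    n_params: int
    alpha: float
    variable_tests: dict = field(default_factory=dict)
    trial_tests: dict = field(default_factory=dict)
    rank_warning: bool = False

    def coefficient(self, variable: str, trial: int | None = None, lag: int | None = None):
        vals = [
            c
            for c, lab in zip(self.coefficients, self.column_labels)
            if lab[0] == variable
            and (trial is None or lab[1] == trial)
            and (lag is None or lab[2] == lag)
        ]
        return vals[0] if len(vals) == 1 else np.asarray(vals)

    def encodes(self, variable: str) -> bool:
        return self.variable_tests[variable].significant


def _sse(X: np.ndarray, y: np.ndarray):
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid), rank


def _partial_f(sse_red: float, sse_full: float, q: int, dof_resid: int):
    """Partial F on the extra sum of squares.

    ``q`` must be the rank gained by the dropped columns (not their count):
    the lagged dummy coding is structurally rank-deficient — e.g. a shock
    column lagged past the shock window falls inside the ITI support — and
    column counts would deflate the statistic.
    """
    if dof_resid <= 0:
        raise ValueError("invalid residual degrees of freedom for partial F-test")
    if q <= 0:
        return 0.0, 1.0
    extra = max(sse_red - sse_full, 0.0)
    if sse_full <= _RANK_TOL * max(sse_red, 1.0):
        # (near-)perfect full fit: significant iff the variable buys anything
        return (np.inf, 0.0) if extra > _RANK_TOL else (0.0, 1.0)
    f = (extra / q) / (sse_full / dof_resid)
    return f, float(stats.f.sf(f, q, dof_resid))


def fit_encoder(
    trace: np.ndarray,
    design: DesignMatrix,
    alpha: float = 0.05,
    add_intercept: bool = True,
    trial_tests: bool = False,
    bonferroni: bool = False,
) -> EncoderFit:
    """OLS fit of one neuron plus nested per-variable (and per-trial) tests.

    Rank-deficient designs are fitted via the pseudoinverse with a rank
    warning recorded on the fit. ``bonferroni`` corrects the per-variable
    p-values across the tested variables before flagging.
    """
    trace = np.asarray(trace, dtype=float)
    rows = design.fit_rows
    y = trace[rows]
    X = design.X[rows]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
    n, k = X.shape
    if n <= k:
        raise ValueError("need more time bins than design columns")
    coef, sse_full, rank = _sse(X, y)
    rank_warning = rank < k
    if rank_warning:
        logger.warning("design is rank-deficient (rank %d < %d columns); pseudoinverse fit", rank, k)
    sst = float(np.sum((y - y.mean()) ** 2)) if add_intercept else float(y @ y)
    r2 = 1.0 - sse_full / sst if sst > 0 else 0.0
    dof = n - rank
    fit = EncoderFit(
        coefficients=coef[1:] if add_intercept else coef,
        column_labels=list(design.labels),
        intercept=float(coef[0]) if add_intercept else None,
        r_squared=r2,
        residual_variance=sse_full / dof if dof > 0 else np.nan,
        n_obs=n,
        n_params=k,
        alpha=alpha,
        rank_warning=rank_warning,
    )
    variables = design.test_variables
    n_tests = len(variables)

    def nested(drop):
        keep = np.setdiff1d(np.arange(k), drop)
        _, sse_red, rank_red = _sse(X[:, keep], y)
        f, p = _partial_f(sse_red, sse_full, rank - rank_red, dof)
        ev_red = 1.0 - sse_red / sst if sst > 0 else 0.0
        return f, p, ev_red, rank - rank_red

    for var in variables:
        drop = design.columns_of(var) + (1 if add_intercept else 0)
        f, p, ev_red, q = nested(drop)
        p_eff = min(p * n_tests, 1.0) if bonferroni else p
        fit.variable_tests[var] = VariableTest(var, None, f, p, p_eff < alpha, r2, ev_red, q)
    if trial_tests:
        for var in TASK_VARIABLES:
            if var not in variables:
                continue
            for tr in range(1, design.n_trials + 1):
                drop = design.columns_of(var, trial=tr) + (1 if add_intercept else 0)
                f, p, ev_red, q = nested(drop)
                fit.trial_tests[(var, tr)] = VariableTest(var, tr, f, p, p < alpha, r2, ev_red, q)
    return fit


def test_variable_encoding(
    trace: np.ndarray,
    design: DesignMatrix,
    variable: str,
    alpha: float = 0.05,
    method: str = "ftest",
    n_shifts: int = 1000,
    seed: int = 0,
) -> VariableTest:
    """Nested test of one task variable (all trials, all lags dropped).

    ``method='permutation'`` replaces the F reference distribution with the
    explained-variance gain under circular shifts of the trace (the design's
    autoregressive column is rebuilt for every shift).
    """
    if method == "ftest":
        fit = fit_encoder(trace, design, alpha=alpha)
        return fit.variable_tests[variable]
    if method != "permutation":
        raise ValueError("method must be 'ftest' or 'permutation'")
    obs = _ev_gain(trace, design, variable)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, len(trace), size=n_shifts)
    null = np.array([_ev_gain(np.roll(trace, int(s)), design, variable) for s in shifts])
    p = (1.0 + np.sum(null >= obs)) / (n_shifts + 1.0)
    fit = fit_encoder(trace, design, alpha=alpha)
    base = fit.variable_tests[variable]
    return VariableTest(variable, None, np.nan, p, p < alpha, base.ev_full, base.ev_reduced, base.q)


def _ev_gain(trace: np.ndarray, design: DesignMatrix, variable: str) -> float:
    ar_idx = int(design.columns_of("autoregressive")[0])
    X = design.X.copy()
    X[:, ar_idx] = _lagged(np.asarray(trace, float), 1)
    d = DesignMatrix(X, design.labels, design.kernel_length, design.bin_width,
                     design.continuous_label)
    t = fit_encoder(trace, d)
    return t.variable_tests[variable].ev_full - t.variable_tests[variable].ev_reduced


def test_trial_encoding(
    trace: np.ndarray, design: DesignMatrix, variable: str, trial: int, alpha: float = 0.05
) -> VariableTest:
    """Nested test of one variable on one trial (kernel_length columns dropped)."""
    design.columns_of(variable, trial=trial)  # validates variable and trial bounds
    fit = fit_encoder(trace, design, alpha=alpha, trial_tests=True)
    return fit.trial_tests[(variable, trial)]


# ---------------------------------------------------------------------------
# shared-design population fitting (QR update over the per-neuron AR column)
# ---------------------------------------------------------------------------

class PopulationEncoder:
    """Fit the encoder to many neurons sharing one task design.

    All columns except the autoregressive one are identical across neurons,
    so the fixed part of every full and reduced model is factorized once
    into a rank-truncated orthonormal basis (the lagged dummy coding is
    structurally rank-deficient); each neuron then costs only projections
    of its trace and lagged trace onto the precomputed bases. Nested tests
    use rank differences as their numerator degrees of freedom, matching
    ``fit_encoder``.
    """

    def __init__(
        self,
        schedule: SessionSchedule,
        speed: np.ndarray,
        kernel_length: int = 5,
        alpha: float = 0.05,
        trial_tests: bool = False,
        continuous_label: str = "speed",
        bonferroni: bool = False,
    ):
        self.schedule = schedule
        self.kernel_length = kernel_length
        self.alpha = alpha
        self.bonferroni = bonferroni
        self.trial_tests = trial_tests
        F, labels = _task_columns(schedule, speed, kernel_length, continuous_label)
        self.labels = [("autoregressive", None, None)] + labels
        self.rows = slice(max(kernel_length - 1, 1), None)
        Fv = F[self.rows]
        n = Fv.shape[0]
        ones = np.ones((n, 1))
        self._n = n
        self.test_variable_names = []
        for lab in labels:
            if lab[0] not in self.test_variable_names:
                self.test_variable_names.append(lab[0])

        def basis(M):
            """Orthonormal basis of col(M) with numerical rank truncation."""
            U, s, Vt = np.linalg.svd(M, full_matrices=False)
            tol = s.max() * max(M.shape) * np.finfo(float).eps if s.size else 0.0
            r = int(np.sum(s > tol))
            # min-norm coefficient map: pinv factor V S^-1 (p x r)
            W = (Vt[:r].T / s[:r])
            return U[:, :r], W, r

        G_full = np.hstack([ones, Fv])
        self._U_full, self._W_full, self._rank_fixed = basis(G_full)
        self.rank_deficient = self._rank_fixed < G_full.shape[1]
        if self.rank_deficient:
            logger.info(
                "fixed design rank %d < %d columns (structural collinearity of "
                "lagged indicators); using pseudoinverse bases",
                self._rank_fixed, G_full.shape[1],
            )
        self._reduced = {}
        for var in self.test_variable_names:
            keep = [j for j, lab in enumerate(labels) if lab[0] != var]
            U, _, r = basis(np.hstack([ones, Fv[:, keep]]))
            self._reduced[var] = (U, self._rank_fixed - r)
        self._trial_bases = {}
        if trial_tests:
            for var in TASK_VARIABLES:
                if var not in self.test_variable_names:
                    continue
                for tr in range(1, schedule.n_trials + 1):
                    keep = [j for j, lab in enumerate(labels)
                            if not (lab[0] == var and lab[1] == tr)]
                    U, _, r = basis(np.hstack([ones, Fv[:, keep]]))
                    self._trial_bases[(var, tr)] = (U, self._rank_fixed - r)
        self._k_columns = G_full.shape[1] + 1  # intercept + fixed + AR

    @staticmethod
    def _sse_with_ar(U: np.ndarray, Y: np.ndarray, A: np.ndarray):
        """SSE of span(U) + per-neuron AR column; Y, A are bins x neurons."""
        UtY = U.T @ Y
        RY = Y - U @ UtY
        UtA = U.T @ A
        RA = A - U @ UtA
        na2 = np.einsum("ij,ij->j", RA, RA)
        # AR column collinear with the fixed design -> it adds no dimension
        ok = na2 > _RANK_TOL * np.einsum("ij,ij->j", A, A).clip(min=1.0)
        b = np.where(ok, np.einsum("ij,ij->j", RA, RY) / np.where(ok, na2, 1.0), 0.0)
        sse = np.einsum("ij,ij->j", RY, RY) - b**2 * na2
        return np.clip(sse, 0.0, None), b, UtY, UtA, ok

    def fit_matrix(self, activity: ActivityMatrix | np.ndarray) -> list[EncoderFit]:
        values = activity.values if isinstance(activity, ActivityMatrix) else np.asarray(activity, float)
        if values.ndim == 1:
            values = values[None, :]
        if values.shape[1] != self.schedule.n_bins:
            raise ValueError("activity must be on the schedule's bin grid")
        A_full = np.stack([_lagged(v, 1) for v in values], axis=1)[self.rows]
        Y = values.T[self.rows]
        n, n_neurons = self._n, Y.shape[1]
        if n <= self._k_columns:
            raise ValueError("need more time bins than design columns")

        sse_full, b, UtY, UtA, ok = self._sse_with_ar(self._U_full, Y, A_full)
        # min-norm coefficients of intercept+fixed part given the AR coefficient
        C = self._W_full @ (UtY - UtA * b[None, :])
        sst = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(sst > 0, 1.0 - sse_full / sst, 0.0)
        rank_full = self._rank_fixed + ok.astype(int)  # per neuron
        dof = n - rank_full

        reduced = {var: (self._sse_with_ar(U, Y, A_full)[0], q)
                   for var, (U, q) in self._reduced.items()}
        trial_sse = {key: (self._sse_with_ar(U, Y, A_full)[0], q)
                     for key, (U, q) in self._trial_bases.items()}

        n_tests = len(self.test_variable_names)
        fits = []
        for j in range(n_neurons):
            coef = np.concatenate([[b[j]], C[1:, j]])
            fit = EncoderFit(
                coefficients=coef,
                column_labels=list(self.labels),
                intercept=float(C[0, j]),
                r_squared=float(r2[j]),
                residual_variance=float(sse_full[j] / dof[j]) if dof[j] > 0 else np.nan,
                n_obs=n,
                n_params=self._k_columns,
                alpha=self.alpha,
                rank_warning=self.rank_deficient or not bool(ok[j]),
            )
            for var, (sse_r, q) in reduced.items():
                f, p = _partial_f(float(sse_r[j]), float(sse_full[j]), q, int(dof[j]))
                p_eff = min(p * n_tests, 1.0) if self.bonferroni else p
                ev_red = float(1.0 - sse_r[j] / sst[j]) if sst[j] > 0 else 0.0
                fit.variable_tests[var] = VariableTest(
                    var, None, f, p, p_eff < self.alpha, float(r2[j]), ev_red, q
                )
            for (var, tr), (sse_r, q) in trial_sse.items():
                f, p = _partial_f(float(sse_r[j]), float(sse_full[j]), q, int(dof[j]))
                ev_red = float(1.0 - sse_r[j] / sst[j]) if sst[j] > 0 else 0.0
                fit.trial_tests[(var, tr)] = VariableTest(
                    var, tr, f, p, p < self.alpha, float(r2[j]), ev_red, q
                )
            fits.append(fit)
        return fits

    def fit(self, trace: np.ndarray) -> EncoderFit:
        return self.fit_matrix(np.asarray(trace, float)[None, :])[0]


# ---------------------------------------------------------------------------
# collinearity diagnostics
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    column_labels: list[tuple]
    vif: np.ndarray
    vif_flags: np.ndarray
    condition_index: float
    condition_flag: bool
    min_eigenvalue_path: list[tuple]
    scaling: str = "correlation"

    @property
    def any_flag(self) -> bool:
        return bool(self.condition_flag or np.any(self.vif_flags))


def collinearity_diagnostics(
    design: DesignMatrix, vif_threshold: float = 10.0, condition_threshold: float = 30.0
) -> CollinearityReport:
    """VIF per column, condition index, and a minimum-eigenvalue path.

    VIF_j = 1/(1 - R^2_j) from regressing column j on all other columns;
    exactly duplicated (perfectly collinear) columns are reported as
    infinite and flagged. The condition index is sqrt(l_max/l_min) of the
    correlation-scaled cross-product matrix. The eigenvalue path adds
    predictor groups in model order (AR, tone, footshock, ITI, speed) and
    records the smallest eigenvalue after each addition.
    """
    X = design.X[design.fit_rows]
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least two columns for collinearity diagnostics")
    sd = X.std(axis=0, ddof=1)
    nonconst = sd > 0
    Z = np.zeros_like(X)
    Z[:, nonconst] = (X[:, nonconst] - X[:, nonconst].mean(axis=0)) / sd[nonconst]
    if not nonconst.all():
        logger.warning("%d constant design columns excluded from correlation scaling",
                       int((~nonconst).sum()))
    C = (Z.T @ Z) / (n - 1)
    np.fill_diagonal(C, np.where(nonconst, 1.0, 0.0))

    vif = np.full(k, np.nan)
    idx = np.flatnonzero(nonconst)
    Csub = C[np.ix_(idx, idx)]
    eigvals = np.linalg.eigvalsh(Csub)
    if eigvals.min() > 1e-10:
        vif[idx] = np.diag(np.linalg.inv(Csub))
    else:
        for j in idx:
            others = idx[idx != j]
            coef, _, _, _ = np.linalg.lstsq(Z[:, others], Z[:, j], rcond=None)
            resid = Z[:, j] - Z[:, others] @ coef
            r2 = 1.0 - (resid @ resid) / (n - 1)
            vif[j] = np.inf if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    vif_flags = np.zeros(k, dtype=bool)
    vif_flags[idx] = ~np.isfinite(vif[idx]) | (vif[idx] > vif_threshold)

    lmin, lmax = eigvals.min(), eigvals.max()
    condition_index = np.inf if lmin <= 1e-12 else float(np.sqrt(lmax / lmin))

    order = ["autoregressive"] + list(TASK_VARIABLES) + [design.continuous_label]
    path, acc = [], []
    for group in order:
        cols = [j for j, lab in enumerate(design.labels) if lab[0] == group and nonconst[j]]
        if not cols:
            continue
        acc.extend(cols)
        sub = C[np.ix_(acc, acc)]
        path.append((group, float(np.linalg.eigvalsh(sub).min())))
    return CollinearityReport(
        list(design.labels), vif, vif_flags, condition_index,
        condition_index > condition_threshold, path,
    )


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------

def _event_onsets(schedule: SessionSchedule, variable: str) -> list[float]:
    if variable == "tone":
        return [tr.tone_on for tr in schedule.trials]
    if variable == "footshock":
        return [tr.shock_on for tr in schedule.trials if tr.has_shock]
    if variable == "iti":
        return [w[0] for w in schedule.iti_windows()]
    raise ValueError(f"unknown task variable {variable!r}")


def mean_event_response(
    activity: ActivityMatrix,
    schedule: SessionSchedule,
    variable: str,
    neuron_mask: np.ndarray | None = None,
    pre: float = 5.0,
    post: float = 10.0,
):
    """Mean peri-event trace (baseline-normalized) and its AUC.

    Each neuron/event window is Z-scored against its own ``pre``-seconds
    segment (mean subtraction only when that segment has zero variance),
    then averaged over events and the selected neurons. Returns
    ``(time_axis, mean_trace, auc)`` with AUC the trapezoidal area over
    the post-onset part.
    """
    values = activity.values if neuron_mask is None else activity.values[neuron_mask]
    if values.shape[0] == 0:
        raise ValueError("no neurons selected")
    bw = activity.bin_width
    npre, npost = int(round(pre / bw)), int(round(post / bw))
    rows = []
    for onset in _event_onsets(schedule, variable):
        i0 = int(round(onset / bw))
        if i0 - npre < 0 or i0 + npost > activity.n_bins:
            continue
        seg = values[:, i0 - npre : i0 + npost]
        base = seg[:, :npre]
        mu, sd = base.mean(axis=1, keepdims=True), base.std(axis=1, keepdims=True)
        sd = np.where(sd > 0, sd, 1.0)
        rows.append((seg - mu) / sd)
    if not rows:
        raise ValueError("no event fits within the recording")
    mean_trace = np.mean([r.mean(axis=0) for r in rows], axis=0)
    time_axis = (np.arange(npre + npost) - npre) * bw
    auc = float(np.trapezoid(mean_trace[npre:], dx=bw))
    return time_axis, mean_trace, auc


def summarize_encoders(
    fits: list[EncoderFit],
    schedule: SessionSchedule,
    activity: ActivityMatrix | None = None,
) -> pd.DataFrame:
    """Fraction of significant neurons per variable and per trial.

    Rows with ``test='variable'`` use the all-trials nested test; rows with
    ``test='trial'`` use the per-trial test (present only when trial tests
    were computed). When ``activity`` is given, variable rows also carry the
    peri-event AUC of the mean response over significant neurons.
    """
    if not fits:
        raise ValueError("no fitted neurons to summarize")
    n = len(fits)
    records = []
    for var in fits[0].variable_tests:
        flags = np.array([f.variable_tests[var].significant for f in fits])
        rec = {"variable": var, "trial": None, "test": "variable",
               "n_neurons": n, "n_significant": int(flags.sum()),
               "fraction": float(flags.mean())}
        if activity is not None and var in TASK_VARIABLES and flags.any():
            try:
                _, _, auc = mean_event_response(activity, schedule, var, flags)
                rec["mean_response_auc"] = auc
            except ValueError:
                rec["mean_response_auc"] = np.nan
        records.append(rec)
    if fits[0].trial_tests:
        for (var, tr) in fits[0].trial_tests:
            flags = np.array([f.trial_tests[(var, tr)].significant for f in fits])
            records.append({"variable": var, "trial": tr, "test": "trial",
                            "n_neurons": n, "n_significant": int(flags.sum()),
                            "fraction": float(flags.mean())})
    return pd.DataFrame.from_records(records)


def reactivation_probability(trial_flags: np.ndarray, warn: bool = True) -> float:
    """Among neurons significant on trial 1, the fraction significant on all
    subsequent trials. ``trial_flags`` is a neurons x trials boolean array.
    Returns NaN (with a warning) when no neuron is flagged on trial 1.
    """
    flags = np.asarray(trial_flags, dtype=bool)
    if flags.ndim != 2 or flags.shape[1] < 2:
        raise ValueError("trial_flags must be neurons x trials with >= 2 trials")
    first = flags[:, 0]
    if not first.any():
        if warn:
            logger.warning("no neurons significant on trial 1; reactivation undefined")
        return float("nan")
    return float(flags[first, 1:].all(axis=1).mean())


def trial_flag_matrix(fits: list[EncoderFit], variable: str) -> np.ndarray:
    """Neurons x trials boolean matrix of per-trial significance flags."""
    trials = sorted({tr for (v, tr) in fits[0].trial_tests if v == variable})
    if not trials:
        raise ValueError(f"fits carry no trial tests for {variable!r}")
    return np.array([[f.trial_tests[(variable, tr)].significant for tr in trials] for f in fits])


@dataclass
class SpeedTuning:
    curves: np.ndarray          # selected neurons x speed bins, mean activity
    bin_edges: np.ndarray
    preferred_bin: np.ndarray   # argmax per neuron, lowest index wins ties
    histogram: np.ndarray       # counts of preferred bins


def speed_tuning(
    activity: ActivityMatrix,
    speed_binned: np.ndarray,
    neuron_mask: np.ndarray,
    n_speed_bins: int = 5,
) -> SpeedTuning:
    """Occupancy-matched speed tuning curves for speed-modulated neurons.

    Speed bins are equal-occupancy (quantile) bins; duplicate quantile edges
    (from ties at low speeds) merge the affected bins with a log message.
    The preferred bin is the argmax of each tuning curve.
    """
    speed_binned = np.asarray(speed_binned, dtype=float)
    if speed_binned.size != activity.n_bins:
        raise ValueError("speed must be on the activity bin grid")
    values = activity.values[np.asarray(neuron_mask, dtype=bool)]
    if values.shape[0] == 0:
        raise ValueError("no speed-modulated neurons selected")
    edges = np.quantile(speed_binned, np.linspace(0, 1, n_speed_bins + 1))
    uniq = np.unique(edges)
    if uniq.size < edges.size:
        logger.warning("empty speed bins merged: %d -> %d bins", n_speed_bins, uniq.size - 1)
        edges = uniq
    assign = np.clip(np.searchsorted(edges, speed_binned, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    curves = np.column_stack([values[:, assign == b].mean(axis=1) for b in range(n_bins)])
    preferred = curves.argmax(axis=1)
    hist = np.bincount(preferred, minlength=n_bins)
    return SpeedTuning(curves, edges, preferred, hist)
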