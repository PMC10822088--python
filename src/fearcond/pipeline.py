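"""End-to-end orchestration: simulate -> encode -> population -> report.

A ``RunConfig`` captures every tunable (including the alternative-mode
flags of each analysis decision) and serializes losslessly to YAML. Each
stage draws its randomness from a seed derived from the master seed, so
identical configs produce byte-identical reports and stages can be rerun
in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ActivityMatrix, BehaviorTrace
from .synthetic import SessionSchedule, simulate_dataset, inject_state_shift
from .encoding import (
    PopulationEncoder,
    bin_activity,
    summarize_encoders,
    reactivation_probability,
    trial_flag_matrix,
)
from .population import (
    baseline_zscore,
    label_epochs,
    population_correlation_matrix,
    epoch_mean_pcc,
    cross_trial_similarity,
    pca_state_space,
    mahalanobis_shift,
    state_space_classifier,
    epoch_z_distribution,
    compare_distributions,
)
from .photometry import correct_control_channel, session_normalize, peri_event_matrix, epoch_auc, detect_transients
from .behavior import epoch_freezing_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "compare_conditions",
           "stage_seeds"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; downstream stages were skipped."""


@dataclass
class RunConfig:
    """All knobs of a synthetic end-to-end run (defaults = documented defaults)."""

    # session / simulation
    paradigm: str = "conditioning"
    n_trials: int = 6
    iti: float = 60.0
    baseline_duration: float | None = None
    sampling_rate: float = 10.0
    bin_width: float = 0.5
    n_neurons: int = 50
    fraction_tuned: float = 0.2
    effect_size: float = 1.0
    noise_sd: float = 0.5
    ar_coef: float = 0.5
    kernel_tau: float | None = None
    freeze_prob_post_shock: float = 0.4
    shift_gain: float = 0.0
    shared_factor_sd: float = 0.0
    with_photometry: bool = False
    # encoder
    kernel_length: int = 5
    alpha: float = 0.05
    bonferroni: bool = False
    # population windows (seconds)
    cue_window: float = 28.0
    shock_window: float = 5.0
    iti_window: float = 5.0
    post_shock_window: float = 5.0
    iti_convention: str = "shock_off"
    # classifier / state space
    classifier_iterations: int = 10
    train_fraction: float = 0.75
    classifier_mode: str = "shuffle"
    mahalanobis_mode: str = "pooled"
    # photometry
    correction_mode: str = "fit-signal"
    transient_threshold: float = 2.5
    transient_refractory: float = 1.0
    # behavior surrogate
    speed_threshold: float = 0.5
    min_bout: float = 1.0
    # randomness
    seed: int = 0

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        payload = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def stage_seeds(master_seed: int, n: int = 6) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from a master seed."""
    return [int(c.generate_state(1)[0] % 2**31) for c in np.random.SeedSequence(master_seed).spawn(n)]


@dataclass
class RunReport:
    config: RunConfig
    version: str = __version__
    scalars: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    arrays: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    stage_status: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return any(v == "failed" for v in self.stage_status.values())

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.to_csv(out / f"{name}.csv", index=False)
        payload = {
            "version": self.version,
            "config": asdict(self.config),
            "scalars": self.scalars,
            "warnings": self.warnings,
            "stage_status": self.stage_status,
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2, default=float))
        return out

    @classmethod
    def load(cls, out_dir) -> "RunReport":
        out = Path(out_dir)
        payload = json.loads((out / "report.json").read_text())
        report = cls(config=RunConfig(**payload["config"]), version=payload["version"],
                     scalars=payload["scalars"], warnings=payload["warnings"],
                     stage_status=payload["stage_status"])
        for csv in out.glob("*.csv"):
            report.tables[csv.stem] = pd.read_csv(csv)
        return report


def _epoch_window_bins(schedule: SessionSchedule, time_axis: np.ndarray, cfg: RunConfig) -> dict:
    """Pooled bin indices for the cue / shock / ITI quantification windows."""
    t = np.asarray(time_axis)

    def collect(windows):
        idx = []
        for s, e in windows:
            idx.append(np.flatnonzero((t >= s - 1e-9) & (t < e - 1e-9)))
        return np.concatenate(idx) if idx else np.array([], dtype=int)

    cue = [(tr.tone_on, min(tr.tone_on + cfg.cue_window, tr.tone_off)) for tr in schedule.trials]
    shock = [(tr.shock_on, tr.shock_on + cfg.shock_window) for tr in schedule.trials if tr.has_shock]
    iti = []
    for tr in schedule.trials:
        start = (tr.shock_on + cfg.shock_window) if tr.has_shock else tr.tone_off
        iti.append((start, start + cfg.iti_window))
    base = [(0.0, schedule.trials[0].tone_on if schedule.trials else schedule.session_end)]
    return {"baseline": collect(base), "cue": collect(cue), "shock": collect(shock),
            "iti": collect(iti)}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run simulate -> behavior -> encode -> population (-> photometry).

    A failed stage is recorded in ``stage_status`` and its downstream
    stages are skipped; callers should treat ``report.failed`` as a
    nonzero exit condition.
    """
    report = RunReport(config=config)
    seeds = stage_seeds(config.seed)
    dataset = None

    # -- simulate -----------------------------------------------------------
    try:
        dataset = simulate_dataset(
            paradigm=config.paradigm, n_trials=config.n_trials, n_neurons=config.n_neurons,
            fraction_tuned=config.fraction_tuned, effect_size=config.effect_size,
            noise_sd=config.noise_sd, ar_coef=config.ar_coef,
            kernel_length=config.kernel_length, kernel_tau=config.kernel_tau,
            freeze_prob_post_shock=config.freeze_prob_post_shock,
            with_photometry=config.with_photometry, seed=seeds[0],
            iti=config.iti, baseline_duration=config.baseline_duration,
            sampling_rate=config.sampling_rate, bin_width=config.bin_width,
        )
        if config.shift_gain != 0.0 or config.shared_factor_sd != 0.0:
            dataset.activity = inject_state_shift(
                dataset.activity, dataset.schedule, config.shift_gain,
                config.shared_factor_sd, seed=seeds[1],
            )
        report.stage_status["simulate"] = "ok"
    except Exception as exc:  # noqa: BLE001 - stage boundary
        logger.exception("simulate stage failed")
        report.stage_status["simulate"] = "failed"
        report.warnings.append(f"simulate: {exc}")
        for stage in ("behavior", "encode", "population", "photometry"):
            report.stage_status[stage] = "skipped"
        return report

    schedule, activity, behavior = dataset.schedule, dataset.activity, dataset.behavior

    # -- behavior -----------------------------------------------------------
    try:
        rows = epoch_freezing_table(behavior, schedule, config.speed_threshold, config.min_bout)
        table = pd.DataFrame.from_records(rows)
        report.tables["freezing"] = table
        base = table.loc[table.epoch == "baseline", "fraction"].mean()
        iti_frac = table.loc[table.epoch == "iti", "fraction"].mean()
        report.scalars["freezing_baseline"] = float(base)
        report.scalars["freezing_iti"] = float(iti_frac) if not np.isnan(iti_frac) else float("nan")
        report.stage_status["behavior"] = "ok"
    except Exception as exc:  # noqa: BLE001
        logger.exception("behavior stage failed")
        report.stage_status["behavior"] = "failed"
        report.warnings.append(f"behavior: {exc}")

    # -- encoder ------------------------------------------------------------
    try:
        speed_binned = bin_activity(behavior.speed, config.bin_width, behavior.sampling_rate)
        speed_binned = speed_binned[: schedule.n_bins]
        encoder = PopulationEncoder(
            schedule, speed_binned, kernel_length=config.kernel_length,
            alpha=config.alpha, trial_tests=True, bonferroni=config.bonferroni,
        )
        fits = encoder.fit_matrix(activity)
        summary = summarize_encoders(fits, schedule)
        report.tables["encoder_summary"] = summary
        fit_rows = []
        for nid, f in zip(activity.neuron_ids, fits):
            row = {"neuron": nid, "r_squared": f.r_squared}
            for var, t in f.variable_tests.items():
                row[f"p_{var}"] = t.p_value
                row[f"encodes_{var}"] = t.significant
            fit_rows.append(row)
        report.tables["encoder_fits"] = pd.DataFrame.from_records(fit_rows)
        for var in fits[0].variable_tests:
            frac = summary.loc[
                (summary.variable == var) & (summary.test == "variable"), "fraction"
            ].iloc[0]
            report.scalars[f"fraction_encoding_{var}"] = float(frac)
        if schedule.first_shock_onset is not None:
            flags = trial_flag_matrix(fits, "footshock")
            report.scalars["reactivation_probability_footshock"] = reactivation_probability(flags)
        report.stage_status["encode"] = "ok"
    except Exception as exc:  # noqa: BLE001
        logger.exception("encode stage failed")
        report.stage_status["encode"] = "failed"
        report.warnings.append(f"encode: {exc}")

    # -- population state ---------------------------------------------------
    try:
        baseline_dur = schedule.baseline_duration
        z = baseline_zscore(activity, baseline_duration=baseline_dur)
        labels = label_epochs(schedule, post_shock_window=config.post_shock_window,
                              iti_convention=config.iti_convention)
        pcc = population_correlation_matrix(z, labels)
        report.arrays["pcc_matrix"] = pcc.values
        windows = _epoch_window_bins(schedule, z.time_axis, config)
        pcc_rows = []
        for name, bins in windows.items():
            if bins.size >= 2:
                pcc_rows.append({"epoch": name, "mean_pcc": epoch_mean_pcc(pcc, bins)})
        report.tables["epoch_pcc"] = pd.DataFrame.from_records(pcc_rows)
        if schedule.first_shock_onset is not None and schedule.n_trials >= 2:
            sim = cross_trial_similarity(pcc, schedule, epoch="shock",
                                         window_length=config.shock_window)
            report.tables["cross_trial_similarity"] = pd.DataFrame({
                "trial": [k for k in range(1, schedule.n_trials + 1) if k != 1],
                "mean_pcc_vs_trial1": sim,
            })

        state = pca_state_space(z, labels)
        report.tables["pc_scores"] = pd.DataFrame({
            "time": z.time_axis, "pc1": state.pc_coordinates[:, 0],
            "pc2": state.pc_coordinates[:, 1], "fine": labels.fine, "coarse": labels.coarse,
        })
        report.scalars["pc1_explained_variance"] = float(state.explained_variance_ratio[0])
        report.scalars["pc2_explained_variance"] = float(state.explained_variance_ratio[1])
        if schedule.first_shock_onset is not None:
            report.scalars["mahalanobis_shift"] = mahalanobis_shift(
                state, mode=config.mahalanobis_mode)
            clf = state_space_classifier(
                state.pc_coordinates, labels, iterations=config.classifier_iterations,
                train_fraction=config.train_fraction, seed=seeds[2], mode=config.classifier_mode,
            )
            report.scalars["classifier_accuracy"] = clf.mean_accuracy
            report.scalars["classifier_chance"] = clf.chance_level

        mean_z = {}
        for epoch in ("baseline", "tone", "shock", "iti", "post_shock_window"):
            if labels.bins(epoch).size:
                mean_z[epoch] = epoch_z_distribution(z, labels, epoch)
        report.tables["epoch_mean_z"] = pd.DataFrame(mean_z)
        report.stage_status["population"] = "ok"
    except Exception as exc:  # noqa: BLE001
        logger.exception("population stage failed")
        report.stage_status["population"] = "failed"
        report.warnings.append(f"population: {exc}")

    # -- photometry ---------------------------------------------------------
    if config.with_photometry and dataset.photometry is not None:
        try:
            rec = dataset.photometry
            corr = correct_control_channel(rec, mode=config.correction_mode)
            if corr.warning:
                report.warnings.append(f"photometry: {corr.warning}")
            normed = session_normalize(
                corr.corrected, (0.0, schedule.baseline_duration), rec.sampling_rate)
            onsets = [tr.tone_on for tr in schedule.trials]
            tensor = peri_event_matrix(normed, onsets, sampling_rate=rec.sampling_rate)
            auc_rows = []
            for name in ("early_tone", "late_tone", "footshock", "post_footshock"):
                aucs = epoch_auc(tensor, name)
                for ev, a in enumerate(aucs, start=1):
                    auc_rows.append({"window": name, "event": ev, "auc": float(a)})
            report.tables["photometry_auc"] = pd.DataFrame.from_records(auc_rows)
            events = detect_transients(normed, config.transient_threshold,
                                       config.transient_refractory, rec.sampling_rate)
            report.scalars["photometry_transient_count"] = events.count
            report.stage_status["photometry"] = "ok"
        except Exception as exc:  # noqa: BLE001
            logger.exception("photometry stage failed")
            report.stage_status["photometry"] = "failed"
            report.warnings.append(f"photometry: {exc}")
    else:
        report.stage_status["photometry"] = "skipped"
    return report


_CONDITION_FIELDS = {"shift_gain", "shared_factor_sd", "effect_size", "fraction_tuned",
                     "noise_sd", "freeze_prob_post_shock", "seed"}


def compare_conditions(report_a: RunReport, report_b: RunReport) -> pd.DataFrame:
    """Side-by-side scalars of two runs plus KS tests on mean-Z distributions.

    The two reports must share every config field except the condition
    parameters (effect sizes, state-shift gains, seeds). Scalar rows carry
    the A/B values and their difference; distribution rows carry the KS
    statistic and p-value comparing the per-cell mean-Z collections of the
    same epoch.
    """
    ca, cb = asdict(report_a.config), asdict(report_b.config)
    diffs = {k for k in ca if ca[k] != cb[k]}
    bad = diffs - _CONDITION_FIELDS
    if bad:
        raise ValueError(f"reports differ in non-condition config fields: {sorted(bad)}")
    rows = []
    for key in sorted(set(report_a.scalars) & set(report_b.scalars)):
        va, vb = report_a.scalars[key], report_b.scalars[key]
        rows.append({"metric": key, "value_a": va, "value_b": vb,
                     "difference": va - vb, "ks_stat": np.nan, "ks_p": np.nan})
    ta, tb = report_a.tables.get("epoch_mean_z"), report_b.tables.get("epoch_mean_z")
    if ta is not None and tb is not None:
        for epoch in sorted(set(ta.columns) & set(tb.columns)):
            ks, p = compare_distributions(ta[epoch].dropna().to_numpy(),
                                          tb[epoch].dropna().to_numpy())
            rows.append({"metric": f"mean_z_{epoch}", "value_a": float(ta[epoch].mean()),
                         "value_b": float(tb[epoch].mean()),
                         "difference": float(ta[epoch].mean() - tb[epoch].mean()),
                         "ks_stat": ks, "ks_p": p})
    return pd.DataFrame.from_records(rows)
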