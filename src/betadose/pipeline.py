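"""Cohort orchestration: QC -> spectra -> velocity -> stats -> report tables.

``analyze_session`` turns one merged session into per-step summaries;
``run_cohort`` aggregates a cohort of hemispheres into the report tables:
per-step band power (mean ± SD with per-cell n), per-step relative tapping
velocity, paired permutation tests of each stimulated step against the
pre-DBS baseline, the dose-response and velocity mixed models per band with
a low-vs-high-beta comparison, per-hemisphere correlations, beta peak
frequencies (OFF-pre / best effect / OFF-post) and the post-cessation
recovery table.  Group sizes may shrink toward high amplitudes because
hemispheres are only stimulated up to their individual maximum.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortError, InvalidArgumentError
from .movement import POST_OFF_KEY, MovementConfig, block_velocities, velocity_trace
from .preprocess import (DEFAULT_ALIASING_THRESHOLD, DEFAULT_ECG_THRESHOLD,
                         FilterSpec, bandpass_bandstop, qc_session)
from .session import SessionRecording
from .spectral import (BANDS, NormalizedSpectrum, SpectralConfig, band_power,
                       baseline_recovery, detect_beta_peak, morlet_tfr,
                       normalize_total_sum, rest_spectrum)
from .stats import (MixedModelResult, StatsConfig, compare_models,
                    fit_dose_model, fit_velocity_model, paired_permutation_test,
                    per_subject_correlation)


@dataclass
class RunConfig:
    """Everything one cohort run needs; see the CLI for the YAML mapping."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    movement: MovementConfig = field(default_factory=MovementConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    ecg_threshold: float = DEFAULT_ECG_THRESHOLD
    aliasing_threshold: float = DEFAULT_ALIASING_THRESHOLD
    with_velocity: bool = True


@dataclass
class SessionAnalysis:
    """Per-step summaries of one hemisphere."""

    hemisphere_id: str
    subject_id: str
    steps: pd.DataFrame  # step_mA, is_post, band powers, peak_hz, actual_window_s
    spectra: dict[float, NormalizedSpectrum]
    velocity: dict[float, float] | None
    relative_velocity: dict[float, float] | None
    recovery_rel_low_beta: np.ndarray | None
    recovery_time_s: float | None


@dataclass
class CohortReport:
    band_power_table: pd.DataFrame
    velocity_table: pd.DataFrame
    permutation_table: pd.DataFrame
    dose_models: dict[str, MixedModelResult]
    velocity_models: dict[str, MixedModelResult]
    model_comparison: dict
    correlations: pd.DataFrame
    peak_table: pd.DataFrame
    recovery_table: pd.DataFrame
    excluded: dict[str, list[str]]
    best_effect: pd.DataFrame | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        """Deterministic JSON serialization of every table."""
        doc = {
            "band_power_table": self.band_power_table.to_dict("records"),
            "velocity_table": self.velocity_table.to_dict("records"),
            "permutation_table": self.permutation_table.to_dict("records"),
            "dose_models": {k: dataclasses.asdict(v) for k, v in self.dose_models.items()},
            "velocity_models": {k: dataclasses.asdict(v)
                                for k, v in self.velocity_models.items()},
            "model_comparison": self.model_comparison,
            "correlations": self.correlations.to_dict("records"),
            "peak_table": self.peak_table.to_dict("records"),
            "recovery_table": self.recovery_table.to_dict("records"),
            "excluded": self.excluded,
            "best_effect": (self.best_effect.to_dict("records")
                            if self.best_effect is not None else None),
        }
        text = json.dumps(doc, sort_keys=True, indent=1, default=_json_default)
        if path is not None:
            Path(path).write_text(text)
        return text


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _step_schedule(session: SessionRecording) -> list[tuple[float, bool, object]]:
    """(amplitude, is_post_off, step annotation) in temporal order."""
    steps = sorted((ev for ev in session.events if ev.label.startswith("stim_step:")),
                   key=lambda ev: ev.onset_s)
    if not steps:
        raise InvalidArgumentError("session has no stim_step annotations")
    out = []
    seen_zero = False
    for ev in steps:
        amp = float(ev.label.split(":", 1)[1])
        is_post = amp == 0.0 and seen_zero
        if amp == 0.0:
            seen_zero = True
        out.append((amp, is_post, ev))
    return out


def analyze_session(session: SessionRecording, config: RunConfig = RunConfig(),
                    hemisphere_id: str | None = None) -> SessionAnalysis:
    """Filter, decompose and summarize one merged session.

    Per-step rest spectra are normalized within their own segment (so the
    reference-range bins of each step sum to 100); the washout profile is
    computed on one session-wide normalized map, where the shared
    denominator cancels from the post/baseline ratio.
    """
    cfg = config.spectral
    fs = session.sampling_rate_hz
    hemisphere_id = hemisphere_id or f"{session.subject_id}_{session.hemisphere}"
    filtered = bandpass_bandstop(session.lfp, fs, config.filter_spec)
    tfr = morlet_tfr(filtered, fs, cfg)

    schedule = _step_schedule(session)
    rests = session.events_labelled("rest")
    rows, spectra = [], {}
    baseline_spec_sessionnorm = None
    tfr_norm = normalize_total_sum(tfr, cfg)
    for amp, is_post, step_ev in schedule:
        rest = next((r for r in rests
                     if step_ev.onset_s - 1e-9 <= r.onset_s and r.end_s <= step_ev.end_s + 1e-9),
                    None)
        if rest is None:
            raise InvalidArgumentError(f"step at {step_ev.onset_s:.1f} s has no rest annotation")
        spec = rest_spectrum(tfr, rest, cfg).renormalized(cfg)
        key = POST_OFF_KEY if is_post else amp
        spectra[key] = spec
        peak = detect_beta_peak(spec, cfg=cfg)
        row = {"hemisphere_id": hemisphere_id, "subject_id": session.subject_id,
               "step_mA": key, "amplitude_mA": amp, "is_post": is_post,
               "peak_hz": peak.freq_hz if peak.found else np.nan,
               "actual_window_s": spec.actual_window_s}
        for name, band in BANDS.items():
            row[name] = band_power(spec, band)
        rows.append(row)
        if key == 0.0:
            baseline_spec_sessionnorm = rest_spectrum(tfr_norm, rest, cfg)

    # post-cessation washout, relative to the pre-DBS baseline
    recovery_rel, recovery_time = None, None
    post = [ev for amp, is_post, ev in schedule if is_post]
    if post and baseline_spec_sessionnorm is not None:
        cessation = post[0].onset_s
        if tfr_norm.times_s[-1] >= cessation + cfg.recovery_window_s:
            prof = baseline_recovery(tfr_norm, cessation, baseline_spec_sessionnorm, cfg)
            recovery_rel, recovery_time = prof.rel_low_beta, prof.recovery_time_s

    velocity = relative = None
    if config.with_velocity:
        try:
            z = session.channel(config.movement.z_axis_label)
        except KeyError:
            z = None
        if z is not None:
            vtrace = velocity_trace(z, fs, config.movement)
            summary = block_velocities(vtrace, fs, session.events, config.movement)
            velocity, relative = summary.per_step, summary.relative_to_baseline

    return SessionAnalysis(hemisphere_id=hemisphere_id, subject_id=session.subject_id,
                           steps=pd.DataFrame(rows), spectra=spectra,
                           velocity=velocity, relative_velocity=relative,
                           recovery_rel_low_beta=recovery_rel,
                           recovery_time_s=recovery_time)


def run_cohort(sessions: list[SessionRecording] | list[dict],
               config: RunConfig = RunConfig(),
               skip_qc: bool = False) -> CohortReport:
    """Analyze a cohort of merged sessions and build the report tables.

    ``sessions`` is either a list of SessionRecording or the list of dicts
    produced by :func:`betadose.synthetic.simulate_cohort`.  Hemispheres
    failing QC are excluded and listed with reasons; at least two must
    survive.
    """
    recs: list[tuple[str, SessionRecording]] = []
    for item in sessions:
        if isinstance(item, dict):
            recs.append((item.get("hemisphere_id") or
                         f"{item['session'].subject_id}_{item['session'].hemisphere}",
                         item["session"]))
        else:
            recs.append((f"{item.subject_id}_{item.hemisphere}", item))

    excluded: dict[str, list[str]] = {}
    analyses: list[SessionAnalysis] = []
    for hid, rec in recs:
        if not skip_qc:
            report = qc_session(rec, ecg_threshold=config.ecg_threshold,
                                aliasing_threshold=config.aliasing_threshold)
            if report.decision == "exclude":
                excluded[hid] = list(report.reasons)
                continue
        analyses.append(analyze_session(rec, config, hemisphere_id=hid))
    if len(analyses) < 2:
        raise CohortError(f"fewer than 2 hemispheres pass QC; excluded: {excluded}")

    steps = pd.concat([a.steps for a in analyses], ignore_index=True)

    band_rows = []
    for step_key, grp in steps.groupby("step_mA"):
        for name in BANDS:
            band_rows.append({"step_mA": step_key, "band": name,
                              "mean": float(grp[name].mean()),
                              "sd": float(grp[name].std(ddof=1)) if len(grp) > 1 else 0.0,
                              "n": int(len(grp))})
    band_power_table = pd.DataFrame(band_rows).sort_values(["band", "step_mA"],
                                                           ignore_index=True)

    vel_rows = []
    for a in analyses:
        if a.relative_velocity is None:
            continue
        for step_key, rel in a.relative_velocity.items():
            vel_rows.append({"hemisphere_id": a.hemisphere_id, "step_mA": step_key,
                             "velocity_z": a.velocity[step_key], "relative_velocity": rel})
    velocity_table = pd.DataFrame(vel_rows)

    # paired permutation tests: each stimulated step (and OFF-post) vs baseline
    perm_rows = []
    step_keys = sorted(k for k in steps["step_mA"].unique() if k != 0.0)
    for name in BANDS:
        base = steps[steps["step_mA"] == 0.0].set_index("hemisphere_id")[name]
        for key in step_keys:
            other = steps[steps["step_mA"] == key].set_index("hemisphere_id")[name]
            common = base.index.intersection(other.index)
            if len(common) < 3:
                continue
            res = paired_permutation_test(base.loc[common].to_numpy(),
                                          other.loc[common].to_numpy(), config.stats)
            perm_rows.append({"band": name, "step_mA": key, "n": len(common),
                              "mean_diff": res.observed_stat, "p": res.p_value,
                              "exhaustive": res.exhaustive})
    if config.with_velocity and len(velocity_table):
        base = velocity_table[velocity_table["step_mA"] == 0.0].set_index(
            "hemisphere_id")["velocity_z"]
        for key in sorted(k for k in velocity_table["step_mA"].unique() if k != 0.0):
            other = velocity_table[velocity_table["step_mA"] == key].set_index(
                "hemisphere_id")["velocity_z"]
            common = base.index.intersection(other.index)
            if len(common) < 3:
                continue
            res = paired_permutation_test(other.loc[common].to_numpy(),
                                          base.loc[common].to_numpy(), config.stats)
            perm_rows.append({"band": "velocity", "step_mA": key, "n": len(common),
                              "mean_diff": res.observed_stat, "p": res.p_value,
                              "exhaustive": res.exhaustive})
    permutation_table = pd.DataFrame(perm_rows)

    # mixed models over the stimulated sequence (OFF-post excluded: washout
    # hysteresis would contaminate the dose-response)
    stim_steps = steps[steps["step_mA"] != POST_OFF_KEY]
    dose_models = {}
    for name in BANDS:
        ok = stim_steps[stim_steps[name] > 0]
        try:
            dose_models[name] = fit_dose_model(ok[name], ok["amplitude_mA"],
                                               ok["hemisphere_id"])
        except InvalidArgumentError:
            continue

    velocity_models: dict[str, MixedModelResult] = {}
    correlations = pd.DataFrame()
    model_comparison: dict = {}
    if config.with_velocity and len(velocity_table):
        merged = stim_steps.merge(velocity_table, on=["hemisphere_id", "step_mA"])
        for name in BANDS:
            try:
                velocity_models[name] = fit_velocity_model(
                    merged[name], merged["relative_velocity"], merged["hemisphere_id"])
            except InvalidArgumentError:
                continue
        if {"low_beta", "high_beta"} <= set(velocity_models):
            cmp = compare_models(velocity_models["low_beta"],
                                 velocity_models["high_beta"], config.stats)
            model_comparison = {"a": "low_beta", "b": "high_beta",
                                "delta_bic": cmp.delta_bic, "label": cmp.label,
                                "preferred": {"a": "low_beta", "b": "high_beta",
                                              "neither": "neither"}[cmp.preferred]}
        corr_rows = []
        for hid, grp in merged.groupby("hemisphere_id"):
            if len(grp) < 4:
                continue
            c = per_subject_correlation(grp["low_beta"], grp["relative_velocity"])
            corr_rows.append({"hemisphere_id": hid, "method": c.method, "r": c.r,
                              "p": c.p, "n": len(grp)})
        correlations = pd.DataFrame(corr_rows)

    peak_rows = [{"hemisphere_id": a.hemisphere_id,
                  "off_pre_peak_hz": _peak_of(a, 0.0),
                  "off_post_peak_hz": _peak_of(a, POST_OFF_KEY)} for a in analyses]
    peak_table = pd.DataFrame(peak_rows)

    recovery_table = pd.DataFrame(
        [{"hemisphere_id": a.hemisphere_id, "recovery_time_s": a.recovery_time_s,
          "recovered": a.recovery_time_s is not None} for a in analyses
         if a.recovery_rel_low_beta is not None])

    report = CohortReport(band_power_table=band_power_table,
                          velocity_table=velocity_table,
                          permutation_table=permutation_table,
                          dose_models=dose_models, velocity_models=velocity_models,
                          model_comparison=model_comparison, correlations=correlations,
                          peak_table=peak_table, recovery_table=recovery_table,
                          excluded=excluded)
    if config.with_velocity and len(velocity_table):
        report.best_effect = best_effect_grouping(analyses)
        best = report.best_effect.set_index("hemisphere_id")["best_step_mA"]
        report.peak_table["best_effect_peak_hz"] = [
            _peak_of(a, float(best[a.hemisphere_id])) if a.hemisphere_id in best.index
            else np.nan for a in analyses]
    return report


def _peak_of(analysis: SessionAnalysis, step_key: float) -> float:
    row = analysis.steps[analysis.steps["step_mA"] == step_key]
    return float(row["peak_hz"].iloc[0]) if len(row) else np.nan


def best_effect_grouping(analyses: list[SessionAnalysis]) -> pd.DataFrame:
    """Per hemisphere: the stimulated step with maximal mean tap velocity.

    Ties break toward the lower amplitude.  Band powers at the best-effect
    step are carried along so OFF-pre / best-effect / OFF-post spectra can
    be averaged across hemispheres.
    """
    rows = []
    for a in analyses:
        if a.velocity is None:
            continue
        candidates = [(amp, v) for amp, v in a.velocity.items()
                      if amp not in (0.0, POST_OFF_KEY)]
        if not candidates:
            continue
        best_v = max(v for _, v in candidates)
        best_amp = min(amp for amp, v in candidates if v >= best_v - 1e-12)
        row = {"hemisphere_id": a.hemisphere_id, "best_step_mA": best_amp,
               "best_velocity_z": best_v}
        step = a.steps[a.steps["step_mA"] == best_amp].iloc[0]
        off = a.steps[a.steps["step_mA"] == 0.0].iloc[0]
        for name in BANDS:
            row[f"{name}_best"] = float(step[name])
            row[f"{name}_off"] = float(off[name])
        rows.append(row)
    return pd.DataFrame(rows)
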