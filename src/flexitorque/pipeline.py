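"""End-to-end study replica: simulate a cohort, train, predict, evaluate.

Per subject: passive calibration, two isokinetic sets at each of three
velocities and two isotonic sets at each of two impedance fractions; the
averaged torque-per-strain curve is trained from the 1st isokinetic sets and
evaluated on the 2nd isokinetic sets and all isotonic sets.  ANOVA across
velocities tests the velocity independence of the fitted log-linear
parameters.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DegenerateDataError
from .model import compute_eta, fit_log_eta, predict_torque, train_torque_model
from .preprocess import calibrate_connatural, extract_strain
from .stats import cohort_report, error_metrics, mean_report, velocity_anova
from .synthetic import (
    ProtocolConfig,
    SubjectParams,
    make_subject,
    power_velocity_gain,
    simulate_isokinetic_trial,
    simulate_isotonic_trial,
    simulate_passive_trial,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of a full synthetic study run."""

    n_subjects: int = 13
    seed: int = 0
    velocities: tuple = (60.0, 90.0, 120.0)
    impedance_fractions: tuple = (0.30, 0.40)
    rom: tuple = (30.0, 120.0)
    fit_range: tuple = (50.0, 100.0)
    min_strain: float = 0.005
    sample_rate: float = 100.0
    n_cycles: int = 4
    n_passive: int = 2
    sets_per_condition: int = 2
    flexion_index: int = 2
    window_deg: float = 1.0
    noise_scale: float = 1.0
    drift_scale: float = 1.0
    velocity_gain_ratio: float | None = None
    include_isotonic: bool = True
    evaluate_predictions: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.rom
        flo, fhi = self.fit_range
        if not (lo <= flo < fhi <= hi):
            raise ValueError("fit_range must lie within the ROM")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def scaled_subject(subject: SubjectParams, noise_scale: float,
                   drift_scale: float) -> SubjectParams:
    if noise_scale == 1.0 and drift_scale == 1.0:
        return subject
    return replace(subject,
                   noise_torque_sd=subject.noise_torque_sd * noise_scale,
                   noise_circ_sd=subject.noise_circ_sd * noise_scale,
                   drift_amp=subject.drift_amp * drift_scale)


def study_subject(config: StudyConfig, index: int,
                  seed_seq: np.random.SeedSequence) -> tuple[SubjectParams, "object"]:
    """Deterministically derive subject ``index`` and its trial-seed iterator.

    One top-level seed fans out via SeedSequence.spawn: child ``index`` is
    split into a parameter stream and a trial-seed stream.
    """
    params_seq, trials_seq = seed_seq.spawn(2)
    overrides = {"subject_id": str(index + 1)}
    if config.velocity_gain_ratio is not None:
        overrides["velocity_gain"] = power_velocity_gain(config.velocity_gain_ratio)
    subject = make_subject(params_seq, overrides=overrides)
    subject = scaled_subject(subject, config.noise_scale, config.drift_scale)
    trial_seeds = iter(int(s) for s in trials_seq.generate_state(256))
    return subject, trial_seeds


def generate_subject_trials(subject: SubjectParams, config: StudyConfig,
                            trial_seeds) -> dict:
    """Simulate all trials of one subject, keyed by a descriptive label."""
    trials: dict = {}
    for i in range(config.n_passive):
        proto = ProtocolConfig("passive", rom=config.rom, velocity=90.0,
                               n_cycles=min(config.n_cycles, 2),
                               sample_rate=config.sample_rate,
                               seed=next(trial_seeds))
        trials[f"passive_{i + 1}"] = simulate_passive_trial(subject, proto)
    for v in config.velocities:
        for s in range(1, config.sets_per_condition + 1):
            proto = ProtocolConfig("isokinetic", rom=config.rom, velocity=v,
                                   n_cycles=config.n_cycles,
                                   sample_rate=config.sample_rate,
                                   seed=next(trial_seeds))
            trials[f"isokinetic_{int(v)}_set{s}"] = \
                simulate_isokinetic_trial(subject, proto)
    if config.include_isotonic:
        # the impedance is a fraction of T_120, capped by what the subject can
        # produce at rest so that a velocity-gain effect cannot make the
        # protocol infeasible at break-away
        reference = min(subject.t120_max, subject.peak_torque(0.0, config.rom))
        for frac in config.impedance_fractions:
            impedance = frac * reference
            for s in range(1, config.sets_per_condition + 1):
                proto = ProtocolConfig("isotonic", rom=config.rom,
                                       impedance=impedance,
                                       n_cycles=config.n_cycles,
                                       sample_rate=config.sample_rate,
                                       seed=next(trial_seeds))
                trials[f"isotonic_{int(round(frac * 100))}_set{s}"] = \
                    simulate_isotonic_trial(subject, proto)
    return trials


def analyze_subject(subject: SubjectParams, trials: dict,
                    config: StudyConfig) -> dict:
    """Calibrate, fit, train and evaluate one subject's trials."""
    passive = [t for k, t in trials.items() if k.startswith("passive")]
    profile = calibrate_connatural(passive)

    def strain_of(trial):
        return extract_strain(trial, profile,
                              flexion_index=config.flexion_index,
                              window_deg=config.window_deg)

    fits: dict = {}
    curves: dict = {}
    for v in config.velocities:
        for s in range(1, config.sets_per_condition + 1):
            trial = trials[f"isokinetic_{int(v)}_set{s}"]
            curve = compute_eta(strain_of(trial), min_strain=config.min_strain)
            curve.meta["set"] = s
            curves[(v, s)] = curve
            fits[(v, s)] = fit_log_eta(curve, config.fit_range)
    torque_model = train_torque_model([curves[(v, 1)] for v in config.velocities])

    result: dict = {
        "subject_id": subject.subject_id,
        "truth": {"a1_true": subject.a1_true, "a2_true": subject.a2_true,
                  "s_max": subject.s_max, "t120_max": subject.t120_max},
        "fits": {f"{int(v)}_set{s}": asdict(f)
                 for (v, s), f in fits.items()},
    }

    if config.sets_per_condition >= 2:
        for param in ("a1", "a2"):
            groups = {v: [getattr(fits[(v, s)], param)
                          for s in range(1, config.sets_per_condition + 1)]
                      for v in config.velocities}
            try:
                anova = velocity_anova(groups, param)
            except DegenerateDataError:
                # zero-noise runs leave no variance to partition
                result[f"anova_{param}"] = {"p": float("nan"),
                                            "F": float("nan"),
                                            "eta_squared": float("nan"),
                                            "effect": "undefined"}
                continue
            result[f"anova_{param}"] = {"p": anova.p_value,
                                        "F": anova.f_statistic,
                                        "eta_squared": anova.eta_squared,
                                        "effect": anova.effect_label}

    if config.evaluate_predictions:
        per_mode: dict = {"isokinetic": [], "isotonic": []}
        for key, trial in trials.items():
            is_test_isokinetic = (key.startswith("isokinetic") and
                                  not key.endswith("set1"))
            if not (is_test_isokinetic or key.startswith("isotonic")):
                continue
            series = strain_of(trial)
            predicted = predict_torque(series, torque_model, outside="mask")
            report = error_metrics(series.torque, predicted, series.angle,
                                   eval_range=config.fit_range)
            mode = "isokinetic" if key.startswith("isokinetic") else "isotonic"
            per_mode[mode].append((key, report))
        result["trial_errors"] = {
            key: rep.as_dict() for mode in per_mode.values() for key, rep in mode}
        result["mode_errors"] = {
            mode: mean_report([rep for _, rep in entries]).as_dict()
            for mode, entries in per_mode.items() if entries}
    return result, fits, torque_model


def run_study(config: StudyConfig) -> dict:
    """Run the full study replica; fully reproducible from (config, seed)."""
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_subjects)
    subjects: list[dict] = []
    set1_fits: dict = {}
    for i, child in enumerate(children):
        subject, trial_seeds = study_subject(config, i, child)
        logger.info("subject %s: simulating trials", subject.subject_id)
        trials = generate_subject_trials(subject, config, trial_seeds)
        try:
            result, fits, _ = analyze_subject(subject, trials, config)
        except Exception as exc:
            raise type(exc)(
                f"subject {subject.subject_id}: {exc}") from exc
        subjects.append(result)
        for v in config.velocities:
            set1_fits.setdefault(v, []).append(fits[(v, 1)])

    study: dict = {"config": asdict(config), "subjects": subjects}

    # cohort-level ANOVA: one 1st-set fit per subject per velocity group
    cohort_anova = {}
    if config.n_subjects >= 2:
        for param in ("a1", "a2"):
            groups = {v: [getattr(f, param) for f in fs]
                      for v, fs in set1_fits.items()}
            res = velocity_anova(groups, param)
            cohort_anova[param] = {"p": res.p_value, "F": res.f_statistic,
                                   "eta_squared": res.eta_squared,
                                   "effect": res.effect_label}
    study["anova"] = cohort_anova

    if config.sets_per_condition >= 2:
        study["table1"] = [
            {"subject_id": s["subject_id"],
             "p_a1": s["anova_a1"]["p"], "p_a2": s["anova_a2"]["p"]}
            for s in subjects]

    if config.evaluate_predictions:
        by_mode: dict = {}
        for s in subjects:
            for mode, rep in s.get("mode_errors", {}).items():
                by_mode.setdefault(mode, []).append((s["subject_id"], _Rep(rep)))
        study["table2"] = cohort_report(by_mode)
    return study


class _Rep:
    """Lightweight adapter exposing dict error entries as attributes."""

    def __init__(self, d: dict):
        self.__dict__.update(d)


def render_table1(study: dict) -> str:
    rows = study.get("table1", [])
    lines = ["Subject No.  p_a1      p_a2",
             "---------------------------"]
    for r in rows:
        lines.append(f"{r['subject_id']:>11}  {r['p_a1']:<8.4f}  {r['p_a2']:<8.4f}")
    return "\n".join(lines) + "\n"


def render_table2(study: dict) -> str:
    table2 = study.get("table2", {})
    modes = [m for m in ("isokinetic", "isotonic") if m in table2]
    header = "Subject No."
    for m in modes:
        header += f"  {m}:r_rms(N*m)  {m}:r_m"
    lines = [header, "-" * len(header)]
    ids = [r["subject_id"] for r in table2[modes[0]]["rows"]] if modes else []
    for i, sid in enumerate(ids):
        line = f"{sid:>11}"
        for m in modes:
            row = table2[m]["rows"][i]
            line += f"  {row['r_rms']:>13.4f}  {row['r_m']:>8.4f}"
        lines.append(line)
    line = f"{'Mean ± Std':>11}"
    for m in modes:
        t = table2[m]
        line += (f"  {t['mean_r_rms']:.4f} ± {t['sd_r_rms']:.4f}"
                 f"  {t['mean_r_m']:.4f} ± {t['sd_r_m']:.4f}")
    lines.append(line)
    return "\n".join(lines) + "\n"


def write_study(study: dict, out_dir) -> None:
    from .io import write_json
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(out / "report.json", study)
    (out / "table1.txt").write_text(render_table1(study))
    if "table2" in study:
        (out / "table2.txt").write_text(render_table2(study))
    write_json(out / "manifest.json", {
        "files": ["report.json", "table1.txt"] +
                 (["table2.txt"] if "table2" in study else []),
        "seed": study["config"]["seed"],
        "n_subjects": study["config"]["n_subjects"],
    })
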