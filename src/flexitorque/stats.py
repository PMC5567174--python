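"""One-way ANOVA with effect size, and the five torque-error indicators."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError, ParameterError

COHEN_BANDS = ((0.14, "large"), (0.06, "medium"), (0.01, "small"))
DEFAULT_EVAL_RANGE = (50.0, 100.0)
DEFAULT_TM_FLOOR = 0.5  # N*m; guards the relative-error denominator


def cohen_label(eta_squared: float) -> str:
    """Cohen's qualitative band for an eta-squared effect size."""
    for threshold, label in COHEN_BANDS:
        if eta_squared >= threshold:
            return label
    return "negligible"


@dataclass
class AnovaResult:
    """Single-factor fixed-effects ANOVA across velocity groups."""

    parameter: str
    groups: dict
    f_statistic: float
    p_value: float
    eta_squared: float
    effect_label: str
    df_between: int
    df_within: int


def _as_groups(groups) -> dict:
    if isinstance(groups, dict):
        return {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    return {i: np.asarray(v, dtype=float) for i, v in enumerate(groups)}


def _sums_of_squares(groups: dict):
    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    # computed per group (not by subtraction) to avoid cancellation when the
    # within-group variance is tiny relative to the between-group one
    ss_within = sum(float(np.sum((v - v.mean()) ** 2)) for v in groups.values())
    return float(ss_between), float(ss_within), float(ss_between + ss_within)


def effect_size(groups) -> tuple[float, str]:
    """Eta-squared = SS_between / SS_total, with its Cohen band label."""
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise InsufficientDataError("effect size needs at least two groups")
    ss_between, _, ss_total = _sums_of_squares(groups)
    if ss_total <= 0:
        raise DegenerateDataError("zero total variance; effect size undefined")
    eta2 = ss_between / ss_total
    return float(eta2), cohen_label(eta2)


def velocity_anova(groups, parameter: str = "a1") -> AnovaResult:
    """Classical one-way ANOVA of fitted parameters across velocity groups.

    ``groups`` maps a group label (angular velocity) to that group's values,
    typically one fitted a1 or a2 per subject or per repeated set.
    """
    groups = _as_groups(groups)
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs at least two groups")
    for label, v in groups.items():
        if v.size < 2:
            raise InsufficientDataError(
                f"group {label!r} has {v.size} value(s); at least two are "
                "needed for a finite within-group variance")
    ss_between, ss_within, ss_total = _sums_of_squares(groups)
    if ss_total <= 0:
        raise DegenerateDataError("zero total variance in ANOVA input")
    k = len(groups)
    n_total = sum(v.size for v in groups.values())
    df_b = k - 1
    df_w = n_total - k
    if ss_within <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p = float(sps.f.sf(f_stat, df_b, df_w))
    eta2 = ss_between / ss_total
    return AnovaResult(parameter, groups, float(f_stat), p, float(eta2),
                       cohen_label(eta2), df_b, df_w)


@dataclass
class ErrorReport:
    """The five agreement indicators over an angle evaluation range.

    cc: Pearson correlation (NaN when either series has no variance);
    r_ma / r_rms in N*m; r_mr and r_m dimensionless fractions.
    """

    cc: float
    r_ma: float
    r_mr: float
    r_rms: float
    r_m: float
    eval_range: tuple
    n: int

    def as_dict(self) -> dict:
        return {"cc": self.cc, "r_ma": self.r_ma, "r_mr": self.r_mr,
                "r_rms": self.r_rms, "r_m": self.r_m,
                "eval_range": list(self.eval_range), "n": self.n}


def error_metrics(measured, predicted, angle,
                  eval_range=DEFAULT_EVAL_RANGE,
                  tm_floor: float = DEFAULT_TM_FLOOR) -> ErrorReport:
    """Compare measured and predicted torque over ``eval_range`` degrees.

    r_mr excludes samples with |measured| below ``tm_floor`` to avoid division
    blow-ups; r_m is the RMS error divided by the mean measured torque.
    Degenerate cases yield NaN indicators rather than exceptions.
    """
    tm = np.asarray(measured, dtype=float)
    tc = np.asarray(predicted, dtype=float)
    theta = np.asarray(angle, dtype=float)
    if not tm.size == tc.size == theta.size:
        raise ParameterError("measured, predicted and angle must align")
    lo, hi = eval_range
    sel = (theta >= lo) & (theta <= hi) & np.isfinite(tm) & np.isfinite(tc)
    n = int(sel.sum())
    if n < 2:
        raise InsufficientDataError(
            f"only {n} aligned samples inside evaluation range [{lo}, {hi}]")
    tm, tc = tm[sel], tc[sel]
    err = tm - tc
    r_ma = float(np.max(np.abs(err)))
    r_rms = float(np.sqrt(np.mean(err ** 2)))
    big = np.abs(tm) >= tm_floor
    r_mr = float(np.max(np.abs(err[big] / tm[big]))) if big.any() else float("nan")
    mean_tm = float(np.mean(tm))
    r_m = r_rms / mean_tm if abs(mean_tm) > 1e-12 else float("nan")
    if np.std(tm) == 0 or np.std(tc) == 0:
        cc = float("nan")
    else:
        cc = float(np.corrcoef(tm, tc)[0, 1])
    return ErrorReport(cc, r_ma, r_mr, r_rms, float(r_m),
                       (float(lo), float(hi)), n)


def mean_report(reports) -> ErrorReport:
    """Average several per-trial reports into one per-subject report."""
    reports = list(reports)
    if not reports:
        raise ParameterError("at least one report is required")
    def avg(attr):
        vals = np.asarray([getattr(r, attr) for r in reports], dtype=float)
        return float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return ErrorReport(avg("cc"), avg("r_ma"), avg("r_mr"), avg("r_rms"),
                       avg("r_m"), reports[0].eval_range,
                       int(sum(r.n for r in reports)))


def cohort_report(reports_by_mode: dict) -> dict:
    """Per-mode mean and sample SD of r_rms and r_m over subjects.

    ``reports_by_mode`` maps a mode name to a list of (subject_id,
    ErrorReport) pairs, one per subject.  A single-subject mode gets NaN SDs.
    """
    summary: dict = {}
    for mode, entries in reports_by_mode.items():
        entries = list(entries)
        if not entries:
            raise ParameterError(f"no subjects for mode {mode!r}")
        rows = [{"subject_id": sid, "r_rms": rep.r_rms, "r_m": rep.r_m,
                 "cc": rep.cc, "r_ma": rep.r_ma, "r_mr": rep.r_mr}
                for sid, rep in entries]
        r_rms = np.asarray([r["r_rms"] for r in rows])
        r_m = np.asarray([r["r_m"] for r in rows])
        nsub = len(rows)
        summary[mode] = {
            "rows": rows,
            "mean_r_rms": float(np.mean(r_rms)),
            "sd_r_rms": float(np.std(r_rms, ddof=1)) if nsub > 1 else float("nan"),
            "mean_r_m": float(np.mean(r_m)),
            "sd_r_m": float(np.std(r_m, ddof=1)) if nsub > 1 else float("nan"),
            "n_subjects": nsub,
        }
    return summary
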