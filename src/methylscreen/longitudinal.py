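"""Longitudinal concordance and case/control discrimination statistics.

The clinical verification of a circulating methylation marker rests on
two analyses:

* per-patient Pearson correlation between the marker's molecules/ml and
  CA-125 (U/ml) across serial post-resection serum draws, with a t test
  of the null r = 0 (two-sided, n − 2 degrees of freedom, significance
  at p < 0.05), plus a check that both channels drop after tumor
  resection;
* baseline case-vs-control discrimination by ROC AUC (midrank / Mann–
  Whitney statistic) with a stratified percentile bootstrap confidence
  interval (2000 resamples).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "PatientSeries",
    "ConcordanceResult",
    "RocResult",
    "pearson_with_test",
    "cohort_concordance",
    "post_resection_drop",
    "roc_auc",
    "bootstrap_auc_ci",
]


@dataclass
class PatientSeries:
    """Serial draws for one patient.

    ``draws`` columns: week (since baseline), ca125 (U/ml),
    marker_conc (molecules/ml serum); optional extras are carried
    through untouched.
    """

    patient_id: str
    draws: pd.DataFrame
    surgery_week: float | None = None
    relapse_week: float | None = None
    baseline_is_presurgery: bool = True

    def __post_init__(self) -> None:
        required = {"week", "ca125", "marker_conc"}
        missing = required - set(self.draws.columns)
        if missing:
            raise ValueError(f"draws missing columns: {sorted(missing)}")
        weeks = self.draws["week"].to_numpy(dtype=float)
        if not np.all(np.diff(weeks) > 0):
            raise ValueError("weeks must be strictly increasing")
        for col in ("ca125", "marker_conc"):
            vals = self.draws[col].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size and finite.min() < 0:
                raise ValueError(f"{col} must be >= 0")


@dataclass
class ConcordanceResult:
    patient_id: str
    n_pairs: int
    r: float
    t_stat: float
    p: float
    significant: bool


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def pearson_with_test(x, y, alpha: float = 0.05,
                      patient_id: str = "") -> ConcordanceResult:
    """Pearson r with a two-sided t test of r = 0.

    Pairs with a missing value in either series are dropped; at least
    three complete pairs and non-zero variance in both series are
    required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the series")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return ConcordanceResult(
        patient_id=patient_id,
        n_pairs=int(n),
        r=r,
        t_stat=float(t),
        p=float(p),
        significant=bool(p < alpha),
    )


def cohort_concordance(
    cohort: list[PatientSeries], alpha: float = 0.05
) -> tuple[list[ConcordanceResult | None], int, list[str]]:
    """Per-patient marker-vs-CA-125 concordance across a cohort.

    Returns (results aligned with the cohort, count significant at
    ``alpha``, ids of untestable patients). A patient failing the
    Pearson preconditions yields ``None`` in the results list and is
    reported as untestable rather than silently dropped.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    results: list[ConcordanceResult | None] = []
    untestable: list[str] = []
    n_sig = 0
    for series in cohort:
        try:
            res = pearson_with_test(
                series.draws["ca125"], series.draws["marker_conc"],
                alpha=alpha, patient_id=series.patient_id,
            )
        except ValueError:
            results.append(None)
            untestable.append(series.patient_id)
            continue
        results.append(res)
        n_sig += res.significant
    return results, n_sig, untestable


def post_resection_drop(series: PatientSeries) -> dict[str, bool]:
    """Did each channel fall from baseline at the first post-surgery draw?

    The baseline is the first draw of the series (pre- or post-surgery,
    per the carried flag); the comparison draw is the first one strictly
    after ``surgery_week``. Raises if no post-surgery draw exists.
    """
    if series.surgery_week is None:
        raise ValueError("surgery_week required")
    draws = series.draws
    post = draws[draws["week"] > series.surgery_week]
    if post.empty:
        raise ValueError(f"patient {series.patient_id}: no post-surgery draw")
    baseline = draws.iloc[0]
    first_post = post.iloc[0]
    return {
        "ca125": bool(first_post["ca125"] < baseline["ca125"]),
        "marker_conc": bool(first_post["marker_conc"] < baseline["marker_conc"]),
    }


def roc_auc(case_values, control_values) -> float:
    """Area under the ROC curve, midrank (Mann–Whitney) statistic.

    Equals (#{case > control} + 0.5·#{case = control}) / (n_case·n_control).
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both groups must be non-empty")
    y = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
    return float(roc_auc_score(y, np.concatenate([cases, controls])))


def bootstrap_auc_ci(
    case_values,
    control_values,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> RocResult:
    """Stratified percentile bootstrap CI for the ROC AUC.

    Cases and controls are resampled within their own group so each
    replicate keeps the study's group sizes. Deterministic under
    ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    point = roc_auc(cases, controls)
    if np.ptp(cases) == 0 and np.ptp(controls) == 0:
        warnings.warn("degenerate groups: bootstrap CI collapses", stacklevel=2)
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for i in range(n_boot):
        c = rng.choice(cases, size=cases.size, replace=True)
        u = rng.choice(controls, size=controls.size, replace=True)
        aucs[i] = roc_auc(c, u)
    lo, hi = np.percentile(aucs, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return RocResult(
        auc=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_boot=n_boot,
        seed=seed,
    )
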